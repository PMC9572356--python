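"""Batch workflow: sample sheet -> per-replicate fits -> grouped results.

``run_pipeline`` drives the full analysis for a roster of samples (e.g.
the ten-candy design: 5 syrup types x 2 syrup amounts x replicates):
T1 from saturation recovery, M2 from the MSE-refocused FID decomposition
and from SE back-extrapolation, and the Goldman-Shen interface thickness
from the MSE-channel M2.  Per-sample failures are quarantined — recorded
and reported, never allowed to abort the batch.

The report layer mirrors the conventional tabulation: M2 divided by 1e8
with two decimals, d in Angstrom, group means +/- sd with Tukey letters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tdio
from .fitting import fit_fid_rigid_mobile, fit_t1_sr, se_back_extrapolate
from .signal_models import M2_REPORT_SCALE
from .spin_diffusion import SpinDiffusionConfig, analyze_goldman_shen
from .stats import GroupComparison, group_compare

logger = logging.getLogger("tdnmr")

__all__ = ["PipelineConfig", "ResultsTable", "run_pipeline"]

#: Replicate-level metrics aggregated per (syrup_type, syrup_amount) group.
GROUP_METRICS = ("t1_ms", "m2_se_e8", "m2_mse_e8", "crystallinity_index", "d_angstrom")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; YAML-loadable via :meth:`from_yaml`."""

    spin: SpinDiffusionConfig = field(default_factory=SpinDiffusionConfig)
    alpha: float = 0.05
    fid_n_starts: int = 5
    fid_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spin = SpinDiffusionConfig(**raw.pop("spin", {}))
        return cls(spin=spin, **raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


@dataclass
class ResultsTable:
    """Per-replicate estimates plus grouped summary with Tukey letters."""

    per_sample: pd.DataFrame
    groups: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    failures: list[dict]

    @property
    def n_analyzed(self) -> int:
        return int((self.per_sample["status"] == "ok").sum())

    @property
    def n_failed(self) -> int:
        return len(self.per_sample) - self.n_analyzed

    @property
    def clean(self) -> bool:
        return self.n_failed == 0

    def to_csv(self, per_sample_path, groups_path) -> None:
        self.per_sample.to_csv(per_sample_path, index=False, float_format="%.6g")
        self.groups.to_csv(groups_path, index=False, float_format="%.6g")

    def to_json(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="records"),
            "groups": self.groups.to_dict(orient="records"),
            "failures": self.failures,
            "n_analyzed": self.n_analyzed,
            "n_failed": self.n_failed,
        }


def _analyze_row(row: pd.Series, config: PipelineConfig) -> tuple[dict, list[dict]]:
    rec: dict = {
        "sample": row["sample"],
        "syrup_type": row["syrup_type"],
        "syrup_amount": row["syrup_amount"],
        "replicate": row["replicate"],
    }
    failures: list[dict] = []
    for col in ("t1_ms", "m2_se_e8", "m2_mse_e8", "crystallinity_index",
                "dsd_nm2_s", "t_star_ms", "d_angstrom"):
        rec[col] = np.nan

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
            logger.info("%s: %s ok (%.3f s)", row["sample"], name,
                        time.perf_counter() - t0)
            return out
        except Exception as exc:  # quarantine, never abort the batch
            logger.warning("%s: %s FAILED: %s", row["sample"], name, exc)
            failures.append({"sample": row["sample"], "stage": name,
                             "error": str(exc)})
            return None

    sr = stage("read_sr", lambda: tdio.read_curve(row["sr_path"]))
    if sr is not None:
        t1 = stage("fit_t1", lambda: fit_t1_sr(sr))
        if t1 is not None:
            rec["t1_ms"] = t1.t1

    fid = stage("read_fid", lambda: tdio.read_curve(row["fid_path"]))
    mse_fit = None
    if fid is not None:
        mse_fit = stage("fit_fid", lambda: fit_fid_rigid_mobile(
            fid, n_starts=config.fid_n_starts, seed=config.fid_seed))
        if mse_fit is not None:
            rec["m2_mse_e8"] = mse_fit.m2.m2 / M2_REPORT_SCALE
            rec["crystallinity_index"] = mse_fit.crystallinity_index

    se = stage("read_se", lambda: tdio.read_curve(row["se_path"]))
    if se is not None:
        se_fit = stage("se_extrapolate", lambda: se_back_extrapolate(se))
        if se_fit is not None and not se_fit.flagged:
            rec["m2_se_e8"] = se_fit.m2 / M2_REPORT_SCALE

    gs = stage("read_gs", lambda: tdio.read_curve(row["gs_path"]))
    if gs is not None and mse_fit is not None:
        sd = stage("goldman_shen", lambda: analyze_goldman_shen(
            gs, mse_fit.m2, config.spin))
        if sd is not None:
            rec["dsd_nm2_s"] = sd.dsd
            rec["t_star_ms"] = sd.t_star
            rec["d_angstrom"] = sd.d

    rec["status"] = "ok" if not failures else "failed:" + ",".join(
        f["stage"] for f in failures)
    return rec, failures


def run_pipeline(sheet, config: PipelineConfig | None = None) -> ResultsTable:
    """Analyze every replicate in a sample sheet and aggregate by group.

    ``sheet`` is a path to a sample-sheet CSV or a pre-loaded DataFrame
    (see :func:`tdnmr.io.read_sample_sheet`).  Output is deterministic for
    fixed inputs and config.
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(sheet, pd.DataFrame):
        sheet = tdio.read_sample_sheet(sheet)

    records: list[dict] = []
    failures: list[dict] = []
    for _, row in sheet.iterrows():
        rec, fails = _analyze_row(row, config)
        records.append(rec)
        failures.extend(fails)
    per_sample = pd.DataFrame(records).sort_values(
        ["syrup_type", "syrup_amount", "replicate"]).reset_index(drop=True)

    # group aggregation: (syrup_type, syrup_amount) with >= 2 replicates
    comparisons: dict[str, GroupComparison] = {}
    group_rows: list[dict] = []
    keys = per_sample[["syrup_type", "syrup_amount"]].drop_duplicates()
    for metric in GROUP_METRICS:
        by_group: dict[str, np.ndarray] = {}
        for _, g in keys.iterrows():
            sel = (per_sample["syrup_type"] == g["syrup_type"]) & (
                per_sample["syrup_amount"] == g["syrup_amount"])
            vals = per_sample.loc[sel, metric].dropna().to_numpy()
            if vals.size:
                by_group[f"{g['syrup_type']}-{g['syrup_amount']}"] = vals
        if len([v for v in by_group.values() if v.size >= 2]) >= 2:
            try:
                comparisons[metric] = group_compare(by_group, alpha=config.alpha)
            except ValueError as exc:
                logger.warning("group comparison skipped for %s: %s", metric, exc)

    for _, g in keys.sort_values(["syrup_type", "syrup_amount"]).iterrows():
        label = f"{g['syrup_type']}-{g['syrup_amount']}"
        sel = (per_sample["syrup_type"] == g["syrup_type"]) & (
            per_sample["syrup_amount"] == g["syrup_amount"])
        row: dict = {"syrup_type": g["syrup_type"],
                     "syrup_amount": g["syrup_amount"],
                     "n": int(sel.sum())}
        for metric in GROUP_METRICS:
            vals = per_sample.loc[sel, metric].dropna()
            row[f"{metric}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan
            comp = comparisons.get(metric)
            row[f"{metric}_letters"] = (
                comp.letters.get(label, "") if comp is not None else "")
        group_rows.append(row)
    groups = pd.DataFrame(group_rows)

    return ResultsTable(per_sample=per_sample, groups=groups,
                        comparisons=comparisons, failures=failures)
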