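"""Synthetic TD-NMR phantoms: instrument-free test signals with known truth.

A :class:`Phantom` bundles the ground truth of a virtual sample -- rigid
fraction, second moment, mobile T2*, T1, lamellar domain geometry and
spin-diffusion coefficient.  Generators produce the four experiment types
an analysis run consumes:

* ``gen_fid`` -- two-component (Abragam + exponential) FIDs, optionally with
  a receiver dead time (SE-like) or starting at t=0 (MSE-refocused);
* ``gen_sr_curve`` -- saturation-recovery build-up curves;
* ``gen_se_series`` -- solid-echo amplitude versus echo delay;
* ``simulate_goldman_shen`` -- the long-component decay of a Goldman-Shen
  spin-diffusion experiment, obtained by explicit finite-difference solution
  of the 1D diffusion equation on a periodic two-phase lamellar unit cell.

Noise is additive white Gaussian with the SNR defined at the signal origin;
``snr=inf`` produces bit-reproducible noiseless output.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .records import EchoSeries, FidRecord, RecoveryCurve
from .signal_models import LineShapeParams, two_component_fid
from . import io as tdio

__all__ = [
    "Phantom",
    "NoiseSpec",
    "NOISELESS",
    "DiffusionGrid",
    "gen_fid",
    "gen_sr_curve",
    "gen_se_series",
    "simulate_goldman_shen",
    "default_mixing_times",
    "FixtureConfig",
    "export_fixture_set",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise level, as signal-origin SNR."""

    snr: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive (may be inf)")

    def apply(self, signal: np.ndarray, origin_amplitude: float) -> np.ndarray:
        if math.isinf(self.snr):
            return np.asarray(signal, dtype=float)
        rng = np.random.default_rng(self.seed)
        sigma = origin_amplitude / self.snr
        return np.asarray(signal, dtype=float) + rng.normal(0.0, sigma, np.shape(signal))


NOISELESS = NoiseSpec()


@dataclass(frozen=True)
class Phantom:
    """Ground truth of a virtual two-phase sample.

    The lamellar geometry (``d_true``, ``mobile_width``) and the FID
    amplitude split (``rigid_fraction``) are configured independently: the
    former controls spin-diffusion length scales, the latter the t=0 signal
    decomposition.  When ``mobile_width`` is omitted the unit cell is
    symmetric (``mobile_width = d_true``), the geometry in which the
    initial-rate intercept length of a Goldman-Shen run equals the rigid
    domain thickness.

    Units: ``m2_true`` Hz^2, ``t2_mobile`` us, ``t1_true`` ms, widths nm,
    ``dsd_true`` nm^2/s.
    """

    rigid_fraction: float = 0.30
    m2_true: float = 1.10e9
    t2_mobile: float = 500.0
    t1_true: float = 50.0
    d_true: float = 5.0
    mobile_width: float | None = None
    dsd_true: float = 1.5e3
    b_over_a: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rigid_fraction <= 1.0:
            raise ValueError("rigid_fraction must lie in [0, 1]")
        for name in ("m2_true", "t2_mobile", "t1_true", "d_true", "dsd_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mobile_width is not None and self.mobile_width <= 0:
            raise ValueError("mobile_width must be positive")
        if self.b_over_a < 0:
            raise ValueError("b_over_a must be non-negative")

    @property
    def mobile_width_nm(self) -> float:
        return self.d_true if self.mobile_width is None else self.mobile_width

    def lineshape(self) -> LineShapeParams:
        """Abragam/exponential parameters realizing the phantom truth.

        ``a`` is chosen so that a^2 + b^2/3 = m2_true at the configured
        b/a ratio; amplitudes are (rigid_fraction, 1 - rigid_fraction).
        """
        a = math.sqrt(self.m2_true / (1.0 + self.b_over_a**2 / 3.0))
        return LineShapeParams(
            amplitude_rigid=self.rigid_fraction,
            abragam_a=a,
            abragam_b=self.b_over_a * a,
            amplitude_mobile=1.0 - self.rigid_fraction,
            t2_mobile=self.t2_mobile,
        )


@dataclass(frozen=True)
class DiffusionGrid:
    """Explicit finite-difference grid for the 1D lamellar cell.

    The FTCS stability bound dt <= dx^2 / (2 D) is enforced at
    construction, so an unstable configuration fails loudly instead of
    diverging silently.
    """

    n_cells: int
    dx: float  # nm
    dt: float  # s
    dsd: float  # nm^2/s

    def __post_init__(self) -> None:
        if self.n_cells < 16:
            raise ValueError("n_cells must be >= 16")
        if self.dx <= 0 or self.dt <= 0 or self.dsd <= 0:
            raise ValueError("dx, dt and dsd must be positive")
        if self.dt > self.dx**2 / (2.0 * self.dsd) * (1 + 1e-12):
            raise ValueError(
                "unstable grid: dt exceeds the FTCS bound dx^2 / (2 D) "
                f"({self.dt:.3e} > {self.dx**2 / (2 * self.dsd):.3e} s)"
            )

    @classmethod
    def for_phantom(cls, ph: Phantom, n_cells: int = 128, safety: float = 0.8) -> "DiffusionGrid":
        """Grid resolving one unit cell (rigid + mobile slab) of a phantom."""
        period = ph.d_true + ph.mobile_width_nm
        dx = period / n_cells
        dt = safety * dx**2 / (2.0 * ph.dsd_true)
        return cls(n_cells=n_cells, dx=dx, dt=dt, dsd=ph.dsd_true)


def gen_fid(
    ph: Phantom,
    dwell: float = 1.0,
    n_points: int = 512,
    dead_time: float = 0.0,
    noise: NoiseSpec = NOISELESS,
    sequence: str = "MSE",
    sample: str = "",
) -> FidRecord:
    """Sample a two-component FID on t = dead_time + k * dwell (us).

    ``dead_time=0`` emulates an MSE-refocused FID; a positive dead time
    emulates a direct acquisition that misses the first microseconds.
    """
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    t = dead_time + dwell * np.arange(n_points)
    p = ph.lineshape()
    amps = two_component_fid(t, p)
    amps = noise.apply(amps, origin_amplitude=1.0)
    return FidRecord(
        times=t, amplitudes=amps, dead_time=dead_time, dwell=dwell,
        sample=sample, sequence=sequence,
        meta={"m2_true": ph.m2_true, "rigid_fraction": ph.rigid_fraction},
    )


def gen_sr_curve(
    t1: float,
    m0: float = 1.0,
    delays=None,
    noise: NoiseSpec = NOISELESS,
    sample: str = "",
) -> RecoveryCurve:
    """Saturation-recovery build-up m0 * (1 - exp(-t/T1)), delays in ms.

    The default delay ladder spans a 300 ms observation window.  A warning
    is raised when the window is shorter than 3 T1, where the plateau is
    poorly constrained and the fit becomes ill-posed.
    """
    if t1 <= 0:
        raise ValueError("t1 must be positive")
    if delays is None:
        delays = np.geomspace(1.0, 300.0, 16)
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0 or np.any(delays <= 0) or np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be positive and strictly increasing")
    if delays[-1] < 3.0 * t1:
        warnings.warn(
            f"maximum SR delay {delays[-1]:.1f} ms is below 3*T1 = {3 * t1:.1f} ms; "
            "the recovery plateau is poorly sampled",
            stacklevel=2,
        )
    amps = m0 * (1.0 - np.exp(-delays / t1))
    amps = noise.apply(amps, origin_amplitude=m0)
    return RecoveryCurve(delays=delays, amplitudes=amps, kind="SR", sample=sample,
                         meta={"t1_true": t1, "m0_true": m0})


def gen_se_series(
    ph: Phantom,
    tau_list=None,
    noise: NoiseSpec = NOISELESS,
    refocus_eff: float = 1.0,
    sample: str = "",
) -> EchoSeries:
    """Solid-echo amplitude versus echo delay tau (us).

    The rigid component is attenuated by the Gaussian factor
    exp(-M2 (2 tau)^2 / 2) of the full echo time 2 tau; the mobile
    component is unattenuated at these short delays.  ``refocus_eff``
    scales the rigid part for imperfect refocusing.
    """
    if tau_list is None:
        tau_list = np.linspace(6.0, 20.0, 8)
    tau = np.asarray(tau_list, dtype=float)
    if tau.size == 0:
        raise ValueError("tau_list must be non-empty")
    if not 0.0 < refocus_eff <= 1.0:
        raise ValueError("refocus_eff must lie in (0, 1]")
    te = 2.0 * tau * 1e-6  # full echo time, s
    a_r = ph.rigid_fraction * refocus_eff
    a_m = 1.0 - ph.rigid_fraction
    amps = a_r * np.exp(-0.5 * ph.m2_true * te**2) + a_m
    amps = noise.apply(amps, origin_amplitude=a_r + a_m)
    return EchoSeries(taus=tau, amplitudes=amps, sample=sample,
                      meta={"m2_true": ph.m2_true, "refocus_eff": refocus_eff})


def _lamellar_masks(ph: Phantom, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (rigid, mobile) cell masks for one periodic unit cell."""
    period = ph.d_true + ph.mobile_width_nm
    n_rigid = int(round(n_cells * ph.d_true / period))
    n_rigid = min(max(n_rigid, 1), n_cells - 1)
    rigid = np.zeros(n_cells, dtype=bool)
    rigid[:n_rigid] = True
    return rigid, ~rigid


def simulate_goldman_shen(
    ph: Phantom,
    t_sd_list,
    grid: DiffusionGrid | None = None,
    apply_t1: bool = False,
    noise: NoiseSpec = NOISELESS,
    sample: str = "",
) -> RecoveryCurve:
    """Long-component decay L(t_sd) of a Goldman-Shen experiment.

    The mobility filter leaves magnetization 1 in the mobile slab and 0 in
    the rigid slab of a periodic lamellar unit cell; during the mixing time
    t_sd it spreads by spin diffusion (uniform coefficient ``dsd_true``,
    explicit FTCS scheme, periodic boundaries).  The observable is the
    mobile-phase magnetization integral normalized to L(0) = 1; the rigid
    ("short") component integral is returned in ``meta["short_component"]``.

    T1 decay during t_sd is off by default; when enabled it multiplies
    L by exp(-t_sd / t1_true).
    """
    t_sd = np.asarray(t_sd_list, dtype=float)
    if t_sd.size == 0 or np.any(t_sd < 0) or np.any(np.diff(t_sd) <= 0):
        raise ValueError("t_sd_list must be non-negative, sorted, non-empty")
    if grid is None:
        grid = DiffusionGrid.for_phantom(ph)
    rigid_mask, mobile_mask = _lamellar_masks(ph, grid.n_cells)

    m = mobile_mask.astype(float)
    total0 = float(m.sum())
    alpha_full = grid.dsd * grid.dt / grid.dx**2

    t_targets = t_sd * 1e-3  # ms -> s
    long_comp = np.empty(t_sd.size)
    short_comp = np.empty(t_sd.size)
    total_drift = 0.0
    t_now = 0.0
    for i, t_target in enumerate(t_targets):
        remaining = t_target - t_now
        n_full = int(remaining // grid.dt)
        for _ in range(n_full):
            lap = np.roll(m, 1) - 2.0 * m + np.roll(m, -1)
            m = m + alpha_full * lap
        frac = remaining - n_full * grid.dt
        if frac > 1e-15:
            lap = np.roll(m, 1) - 2.0 * m + np.roll(m, -1)
            m = m + (grid.dsd * frac / grid.dx**2) * lap
        t_now = t_target
        long_comp[i] = m[mobile_mask].sum() / total0
        short_comp[i] = m[rigid_mask].sum() / total0
        total_drift = max(total_drift, abs(m.sum() - total0) / total0)

    if apply_t1:
        decay = np.exp(-t_sd / ph.t1_true)
        long_comp = long_comp * decay
        short_comp = short_comp * decay

    long_obs = noise.apply(long_comp, origin_amplitude=1.0)
    return RecoveryCurve(
        delays=t_sd, amplitudes=long_obs, kind="GS", sample=sample,
        meta={
            "short_component": short_comp,
            "long_component_clean": long_comp,
            "total_drift": total_drift,
            "equilibrium_long": float(mobile_mask.sum() / grid.n_cells),
            "d_true": ph.d_true,
            "mobile_width": ph.mobile_width_nm,
            "dsd_true": ph.dsd_true,
        },
    )


def default_mixing_times(ph: Phantom, n: int = 28, span: float = 2.0) -> np.ndarray:
    """Mixing-time ladder (ms) adapted to a phantom's transfer time scale.

    Geometric spacing from ~t_nom/256 to ``span * t_nom`` where
    t_nom = pi W^2 / (4 D) is the nominal initial-rate intercept time of
    the mobile slab; t_sd = 0 is prepended so curves are self-normalizing.
    """
    w = ph.mobile_width_nm
    t_nom_ms = math.pi * w**2 / (4.0 * ph.dsd_true) * 1e3
    ladder = np.geomspace(t_nom_ms / 256.0, span * t_nom_ms, n - 1)
    return np.concatenate([[0.0], ladder])


# ---------------------------------------------------------------------------
# Fixture export: a ten-sample virtual candy roster

@dataclass
class FixtureConfig:
    """Roster and acquisition settings for a synthetic fixture set."""

    out_dir: str | Path = "fixtures"
    seed: int = 0
    n_replicates: int = 3
    fid_snr: float = math.inf
    curve_snr: float = math.inf
    n_fid_points: int = 512
    fid_dwell: float = 1.0
    gs_n_cells: int = 128
    phantoms: dict[str, Phantom] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.phantoms:
            self.phantoms = default_candy_roster(self.seed)


def default_candy_roster(seed: int = 0) -> dict[str, Phantom]:
    """Ten virtual soft candies: 5 syrup types x 2 syrup levels.

    Ground truths follow the benchmark tables bundled in
    :mod:`tdnmr.datasets`: second moments from the MSE benchmark column,
    rigid-domain thicknesses from the interface-thickness benchmark, and
    T1 spread over the 35-65 ms span of gelatin candies.  Each phantom's
    spin-diffusion coefficient is the one its own M2 implies, so simulated
    transfer and downstream analysis share a consistent ground truth.
    """
    from .datasets import REFERENCE_M2_MSE, REFERENCE_THICKNESS_A, SAMPLE_LABELS
    from .spin_diffusion import compute_dsd

    m2_vals = np.array([REFERENCE_M2_MSE[s] for s in SAMPLE_LABELS])
    order = np.argsort(np.argsort(m2_vals))
    # T1 increasing with M2 rank over the 35-65 ms span of soft candies
    t1_vals = 35.0 + 30.0 * order / (len(SAMPLE_LABELS) - 1)
    roster: dict[str, Phantom] = {}
    for i, label in enumerate(SAMPLE_LABELS):
        roster[label] = Phantom(
            rigid_fraction=0.20 + 0.02 * i,
            m2_true=REFERENCE_M2_MSE[label] * 1e8,
            t2_mobile=500.0,
            t1_true=float(t1_vals[i]),
            d_true=REFERENCE_THICKNESS_A[label] / 10.0,  # A -> nm
            dsd_true=compute_dsd(REFERENCE_M2_MSE[label] * 1e8),
            seed=seed + i,
        )
    return roster


def export_fixture_set(config: FixtureConfig) -> dict:
    """Write the fixture roster as curve CSVs plus a ground-truth manifest.

    Per sample and replicate: an MSE-refocused FID, an SR curve, an SE echo
    series and a Goldman-Shen curve, in the two-column curve CSV dialect.
    Replicates share the phantom truth and differ only by noise seed (the
    expensive Goldman-Shen solve runs once per phantom).  A batch-ready
    ``sample_sheet.csv`` and a ``manifest.json`` with ground truths are
    written alongside.  Deterministic, byte-identical for a given config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "n_replicates": config.n_replicates,
                      "samples": {}}
    sheet_rows = []
    for i, (label, ph) in enumerate(sorted(config.phantoms.items())):
        syrup_type, _, syrup_amount = label.rpartition("-")
        grid = DiffusionGrid.for_phantom(ph, n_cells=config.gs_n_cells)
        gs_clean = simulate_goldman_shen(ph, default_mixing_times(ph),
                                         grid=grid, sample=label)
        truth = asdict(ph)
        truth["mobile_width"] = ph.mobile_width_nm
        entry: dict = {"truth": truth, "replicates": {}}
        for rep in range(1, config.n_replicates + 1):
            base_seed = (config.seed * 100003 + i * 1009 + rep * 13) % (2**31 - 1)
            tag = f"{label}-r{rep}"
            fid = gen_fid(
                ph, dwell=config.fid_dwell, n_points=config.n_fid_points,
                noise=NoiseSpec(config.fid_snr, base_seed + 1), sample=tag,
            )
            sr = gen_sr_curve(
                ph.t1_true, delays=np.geomspace(1.0, 300.0, 16),
                noise=NoiseSpec(config.curve_snr, base_seed + 2), sample=tag,
            )
            se = gen_se_series(
                ph, tau_list=np.geomspace(4.0, 100.0, 10),
                noise=NoiseSpec(config.curve_snr, base_seed + 3), sample=tag,
            )
            gs_amp = NoiseSpec(config.curve_snr, base_seed + 4).apply(
                gs_clean.amplitudes, origin_amplitude=1.0)
            gs = RecoveryCurve(delays=gs_clean.delays, amplitudes=gs_amp,
                               kind="GS", sample=tag, meta=dict(gs_clean.meta))
            paths = {
                "fid": out / f"{tag}_fid.csv",
                "sr": out / f"{tag}_sr.csv",
                "se": out / f"{tag}_se.csv",
                "gs": out / f"{tag}_gs.csv",
            }
            tdio.write_fid(paths["fid"], fid)
            tdio.write_recovery(paths["sr"], sr)
            tdio.write_echo_series(paths["se"], se)
            tdio.write_recovery(paths["gs"], gs)
            entry["replicates"][rep] = {k: p.name for k, p in paths.items()}
            sheet_rows.append({
                "sample": tag, "syrup_type": syrup_type,
                "syrup_amount": int(syrup_amount), "replicate": rep,
                "fid_path": paths["fid"].name, "sr_path": paths["sr"].name,
                "se_path": paths["se"].name, "gs_path": paths["gs"].name,
            })
        manifest["samples"][label] = entry
    import pandas as pd

    pd.DataFrame(sheet_rows).to_csv(out / "sample_sheet.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
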