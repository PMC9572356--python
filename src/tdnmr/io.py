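"""Curve CSV dialect and tabular I/O.

A curve file is a two-column CSV (``time,amplitude``) preceded by ``#``
header lines carrying the record kind and units, e.g.::

    # kind=gs
    # units=ms
    # sample=SCG40-30
    time,amplitude
    0.0,1.0
    ...

``kind`` is one of ``fid | sr | se | gs``; ``units`` is ``us`` for FID and
echo series, ``ms`` for recovery curves.  Extra ``key=value`` header lines
are preserved in the record's ``meta``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import EchoSeries, FidRecord, RecoveryCurve

__all__ = [
    "read_curve",
    "write_fid",
    "write_recovery",
    "write_echo_series",
    "read_sample_sheet",
]

_SCALAR_KEYS = {"dead_time", "dwell"}


def _write_curve(path, kind: str, units: str, time, amplitude, header: dict) -> None:
    path = Path(path)
    lines = [f"# kind={kind}", f"# units={units}"]
    for k, v in header.items():
        if v is None or (isinstance(v, str) and not v):
            continue
        lines.append(f"# {k}={v}")
    df = pd.DataFrame({"time": np.asarray(time), "amplitude": np.asarray(amplitude)})
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _read_header(path) -> dict:
    header: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                header[k.strip()] = v.strip()
    return header


def write_fid(path, fid: FidRecord) -> None:
    _write_curve(
        path, "fid", "us", fid.times, fid.amplitudes,
        {"sample": fid.sample, "sequence": fid.sequence,
         "dead_time": fid.dead_time, "dwell": fid.dwell},
    )


def write_recovery(path, curve: RecoveryCurve) -> None:
    _write_curve(
        path, curve.kind.lower(), "ms", curve.delays, curve.amplitudes,
        {"sample": curve.sample},
    )


def write_echo_series(path, series: EchoSeries) -> None:
    _write_curve(path, "se", "us", series.taus, series.amplitudes,
                 {"sample": series.sample})


def read_curve(path):
    """Read a curve CSV, dispatching on the ``kind`` header.

    Returns a :class:`FidRecord`, :class:`RecoveryCurve` or
    :class:`EchoSeries` according to the file's kind.
    """
    path = Path(path)
    header = _read_header(path)
    kind = header.pop("kind", None)
    if kind not in ("fid", "sr", "se", "gs"):
        raise ValueError(f"{path}: missing or unknown curve kind {kind!r}")
    units = header.pop("units", None)
    expected_units = "ms" if kind in ("sr", "gs") else "us"
    if units != expected_units:
        raise ValueError(f"{path}: kind={kind} requires units={expected_units}, got {units}")
    df = pd.read_csv(path, comment="#")
    if not {"time", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time, amplitude")
    t = df["time"].to_numpy(float)
    y = df["amplitude"].to_numpy(float)
    sample = header.pop("sample", "")
    if kind == "fid":
        return FidRecord(
            times=t, amplitudes=y,
            dead_time=float(header.pop("dead_time", t[0] if t.size else 0.0)),
            dwell=float(header.pop("dwell", t[1] - t[0] if t.size > 1 else 1.0)),
            sample=sample, sequence=header.pop("sequence", "FID"), meta=header,
        )
    if kind == "se":
        return EchoSeries(taus=t, amplitudes=y, sample=sample, meta=header)
    return RecoveryCurve(delays=t, amplitudes=y, kind=kind.upper(),
                         sample=sample, meta=header)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a batch sample sheet CSV.

    Required columns: ``sample, syrup_type, syrup_amount, replicate`` and
    the curve paths ``fid_path, sr_path, se_path, gs_path`` (relative paths
    are resolved against the sheet's directory).  Extra columns (Brix, a_w,
    hardness, ...) are carried through unanalyzed.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"sample", "syrup_type", "syrup_amount", "replicate",
                "fid_path", "sr_path", "se_path", "gs_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    keys = df[["syrup_type", "syrup_amount", "replicate"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        dupes = df.loc[keys.duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate (type, amount, replicate) rows: {dupes}")
    for col in ("fid_path", "sr_path", "se_path", "gs_path"):
        df[col] = [str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
                   for p in df[col]]
    return df
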