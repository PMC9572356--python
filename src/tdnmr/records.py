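"""Measurement containers shared by the simulator and the estimators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FidRecord", "RecoveryCurve", "EchoSeries"]


def _as_increasing(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(np.diff(arr) <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    return arr


@dataclass
class FidRecord:
    """Sampled free induction decay.

    times are us since excitation; for MSE-refocused acquisitions the
    effective dead time is 0 and the record may start at t=0.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    dead_time: float = 0.0
    dwell: float = 1.0
    sample: str = ""
    sequence: str = "FID"  # one of FID | SE | MSE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_increasing(self.times, "times")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.times.shape:
            raise ValueError("times and amplitudes must have matching length")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")
        if self.times[0] < self.dead_time - 1e-9:
            raise ValueError("times must start at or after the dead time")
        if self.sequence not in ("FID", "SE", "MSE"):
            raise ValueError("sequence must be FID, SE or MSE")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RecoveryCurve:
    """Delay/amplitude pairs from a saturation-recovery (SR) or
    Goldman-Shen (GS) experiment.  Delays in ms."""

    delays: np.ndarray
    amplitudes: np.ndarray
    kind: str = "SR"  # SR | GS
    sample: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        if delays.ndim != 1 or delays.size == 0:
            raise ValueError("delays must be a non-empty 1-D array")
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(delays < 0):
            raise ValueError("delays must be non-negative")
        self.delays = delays
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.delays.shape:
            raise ValueError("delays and amplitudes must have matching length")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.kind not in ("SR", "GS"):
            raise ValueError("kind must be SR or GS")

    def __len__(self) -> int:
        return self.delays.size


@dataclass
class EchoSeries:
    """Solid-echo amplitude versus echo delay tau (us).

    At least 4 delays are required: the back-extrapolation fits two
    parameters and needs residual degrees of freedom.
    """

    taus: np.ndarray
    amplitudes: np.ndarray
    sample: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taus = _as_increasing(self.taus, "taus")
        if np.any(self.taus <= 0):
            raise ValueError("echo delays must be positive")
        if self.taus.size < 4:
            raise ValueError("at least 4 echo delays are required")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.taus.shape:
            raise ValueError("taus and amplitudes must have matching length")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    def __len__(self) -> int:
        return self.taus.size
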