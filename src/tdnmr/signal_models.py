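"""Line-shape models for time-domain NMR free induction decays.

The rigid (crystalline) part of a proton FID in a dipolar-coupled solid is
modelled by the Abragam function

    f(t) = exp(-a^2 t^2 / 2) * sin(b t) / (b t),

which generalizes the Gaussian (``b = 0``) and has the closed-form second
moment ``M2 = a^2 + b^2/3``.  The mobile (liquid-like) part is a single
exponential.  All functions here are pure and shared by the phantom
simulator and the estimators.

Unit conventions
----------------
Time is in microseconds, the decay parameters ``a`` and ``b`` are in Hz
(ordinary frequency, no 2*pi), and M2 is in Hz^2.  Report layers divide M2
by 1e8 to match the conventional tabulation of second moments of food and
polymer samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LineShapeParams",
    "SecondMoment",
    "abragam",
    "m2_from_abragam",
    "two_component_fid",
]

#: Report-layer scale for second moments (tables print M2 / 1e8 Hz^2).
M2_REPORT_SCALE = 1e8


@dataclass(frozen=True)
class LineShapeParams:
    """Parameters of a two-component (rigid + mobile) FID.

    Attributes
    ----------
    amplitude_rigid : float
        Rigid (fast, Abragam-shaped) component amplitude at t=0, >= 0.
    abragam_a : float
        Gaussian decay parameter of the rigid shape, Hz, >= 0.
    abragam_b : float
        Oscillation parameter of the rigid shape, Hz, >= 0.
    amplitude_mobile : float
        Mobile (slow, exponential) component amplitude at t=0, >= 0.
    t2_mobile : float
        Apparent transverse decay constant of the mobile component, us, > 0.
    """

    amplitude_rigid: float
    abragam_a: float
    abragam_b: float
    amplitude_mobile: float
    t2_mobile: float

    def __post_init__(self) -> None:
        if self.amplitude_rigid < 0 or self.amplitude_mobile < 0:
            raise ValueError("component amplitudes must be non-negative")
        if self.amplitude_rigid + self.amplitude_mobile <= 0:
            raise ValueError("total amplitude must be positive")
        if self.abragam_a < 0 or self.abragam_b < 0:
            raise ValueError("abragam_a and abragam_b must be non-negative")
        if self.t2_mobile <= 0:
            raise ValueError("t2_mobile must be positive")

    @property
    def crystallinity_index(self) -> float:
        """Rigid amplitude fraction of the total t=0 signal, in [0, 1]."""
        return self.amplitude_rigid / (self.amplitude_rigid + self.amplitude_mobile)


@dataclass(frozen=True)
class SecondMoment:
    """Second moment of the rigid line shape, stored in plain Hz^2.

    ``reported`` renders the value on the conventional x1e8 Hz^2 table
    scale.  No angular-frequency (2*pi) conversion is applied anywhere.
    """

    m2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.m2) or self.m2 <= 0:
            raise ValueError("M2 must be finite and positive")

    @property
    def reported(self) -> float:
        """M2 on the x1e8 Hz^2 report scale."""
        return self.m2 / M2_REPORT_SCALE


def abragam(t, a: float, b: float):
    """Abragam rigid-lattice line shape exp(-a^2 t^2/2) sin(bt)/(bt).

    Parameters
    ----------
    t : array_like
        Time since excitation, us, >= 0.
    a, b : float
        Decay and oscillation parameters, Hz, >= 0.

    Returns
    -------
    ndarray or float
        Normalized signal; exactly 1 at t=0, and the Gaussian
        exp(-a^2 t^2/2) in the b -> 0 limit.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if a < 0 or b < 0:
        raise ValueError("a and b must be non-negative")
    ts = t * 1e-6  # us -> s; a, b are in Hz
    gauss = np.exp(-0.5 * (a * ts) ** 2)
    # sinc handles the bt -> 0 limit (value 1) without a 0/0.
    out = gauss * np.sinc(b * ts / np.pi)
    return out if out.ndim else float(out)


def m2_from_abragam(a: float, b: float) -> SecondMoment:
    """Second moment of the Abragam shape, M2 = a^2 + b^2/3.

    Equals the negative normalized curvature -f''(0)/f(0) of the line
    shape at t=0 (with time in seconds), hence Hz^2 in, Hz^2 out.
    """
    if a < 0 or b < 0:
        raise ValueError("a and b must be non-negative")
    if a == 0 and b == 0:
        raise ValueError("M2 undefined: both line-shape parameters are zero")
    return SecondMoment(a * a + b * b / 3.0)


def two_component_fid(t, p: LineShapeParams):
    """Rigid + mobile FID model.

    ``amplitude_rigid * abragam(t, a, b) + amplitude_mobile * exp(-t/t2_mobile)``
    with ``t`` and ``t2_mobile`` in us.
    """
    t = np.asarray(t, dtype=float)
    rigid = p.amplitude_rigid * abragam(t, p.abragam_a, p.abragam_b)
    mobile = p.amplitude_mobile * np.exp(-t / p.t2_mobile)
    out = rigid + mobile
    return out if out.ndim else float(out)
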