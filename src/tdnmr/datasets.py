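"""Published benchmark values for gelatin-based soft candies.

Ten formulations — five corn-syrup types (two glucose syrups SCG40/SCG60,
three fructose syrups SBF10/SHFSLF20/SMF42) at two syrup levels (30% with
sucrose, 60% without) — measured on a benchtop 22.34 MHz instrument.
Second moments are sample means on the conventional x1e8 Hz^2 scale, from
Solid Echo (SE) and Magic Sandwich Echo (MSE) channels; interface-layer
thicknesses (Angstrom) come from Goldman-Shen spin-diffusion analysis.

These serve two roles: cross-channel consistency checks (the SE and MSE
columns are strongly correlated) and realistic ground truths for the
default synthetic candy roster.
"""

from __future__ import annotations

__all__ = [
    "SAMPLE_LABELS",
    "SYRUP_TYPES",
    "SYRUP_AMOUNTS",
    "REFERENCE_M2_SE",
    "REFERENCE_M2_MSE",
    "REFERENCE_THICKNESS_A",
]

SYRUP_TYPES = ("SCG40", "SCG60", "SMF42", "SBF10", "SHFSLF20")
SYRUP_AMOUNTS = (30, 60)

SAMPLE_LABELS = tuple(f"{t}-{a}" for t in SYRUP_TYPES for a in SYRUP_AMOUNTS)

#: Second moment, SE channel, x1e8 Hz^2 (sample means).
REFERENCE_M2_SE = {
    "SCG40-30": 7.00, "SCG40-60": 7.46,
    "SCG60-30": 6.86, "SCG60-60": 7.25,
    "SMF42-30": 6.14, "SMF42-60": 5.31,
    "SBF10-30": 6.77, "SBF10-60": 6.75,
    "SHFSLF20-30": 7.19, "SHFSLF20-60": 6.69,
}

#: Second moment, MSE channel, x1e8 Hz^2 (sample means).
REFERENCE_M2_MSE = {
    "SCG40-30": 11.76, "SCG40-60": 11.99,
    "SCG60-30": 11.21, "SCG60-60": 12.02,
    "SMF42-30": 9.21, "SMF42-60": 8.55,
    "SBF10-30": 10.92, "SBF10-60": 11.00,
    "SHFSLF20-30": 11.60, "SHFSLF20-60": 11.14,
}

#: Goldman-Shen interface-layer thickness, Angstrom (sample means).
REFERENCE_THICKNESS_A = {
    "SCG40-30": 47.5, "SCG40-60": 62.2,
    "SCG60-30": 50.2, "SCG60-60": 69.4,
    "SMF42-30": 83.6, "SMF42-60": 641.0,
    "SBF10-30": 57.7, "SBF10-60": 95.8,
    "SHFSLF20-30": 60.0, "SHFSLF20-60": 113.0,
}
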