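# Methods

## Signal model

A proton FID from a two-phase soft solid is modelled as the sum of a
rigid-lattice component and a liquid-like component:

    S(t) = A_r · exp(−a²t²/2) · sin(bt)/(bt) + A_m · exp(−t/T2m)

The rigid part is the Abragam function, which generalizes the Gaussian
(b → 0 limit) and has the closed-form second moment M2 = a² + b²/3, equal
to the negative normalized curvature −S″(0)/S(0) of the rigid shape at the
origin.  Larger M2 means stronger dipolar coupling, i.e. a more rigid or
crystalline proton environment; the crystallinity index
A_r/(A_r + A_m) is a *relative* measure — no absolute calibration (e.g.
against XRD) is attempted.

Unit conventions: time in µs, the shape parameters a and b in Hz
(ordinary frequency), M2 in Hz².  No 2π conversion is applied anywhere;
the report layer divides M2 by 10⁸, the scale on which second moments of
sugar/biopolymer systems are conventionally tabulated.  Because the
spin-diffusion coefficient scales as √M2, adopting angular units
throughout would multiply D_sd by √(2π) ≈ 2.5 and d by ≈1.6; the
plain-Hz² convention is used consistently end to end, so all internal
comparisons and round trips are unaffected by this choice.

## Estimators

**T1 (saturation recovery).**  Nonlinear least squares of
M0(1 − exp(−t/T1)); initial guesses from the curve geometry (M0 ← max
amplitude, T1 ← delay nearest 63% recovery).  The 95% CI comes from the
linearized covariance with a Student-t quantile (n − 2 df); a bootstrap
is deliberately not used, for speed and determinism.  Non-convergence is
flagged on the result, never raised, so batch runs keep going.

**Rigid/mobile FID fit.**  Levenberg–Marquardt on the five parameters
(A_r, a, b, A_m, T2m), all bounded non-negative.  The fit is multistart:
a geometric initial guess (exponential tail → mobile part, early-time
curvature → rigid part), a Gaussian-only variant with b fixed at 0,
rigid-dominated variants for nearly mobile-free signals, and seeded
jitters of the base guess; the lowest-residual solution wins, making the
result deterministic for a given record and seed.  A solution with the
rigid amplitude pinned at zero while the early-time residuals remain
structured is flagged as degenerate.

**SE back-extrapolation.**  For short echo delays the rigid component of
the echo amplitude decays as exp(−M2(2τ)²/2) — Gaussian in the *full*
echo time 2τ, consistent with the Abragam short-time expansion — while
the mobile component is essentially unattenuated.  The mobile baseline is
estimated from the largest-τ plateau (top 20% of delays), subtracted, and
ln(A − baseline) is regressed on (2τ)² with weights (A − baseline)², the
correct weighting after a log transform.  Because the rigid part may not
have fully decayed at the largest τ, the plateau estimate is refined by
subtracting the fitted rigid contribution and repeating; the fixed point
is found with Steffensen acceleration, clamped to the physically
admissible band around the smallest amplitude, with a damped plain
iteration as fallback.  On noiseless data this converges to the exact
decomposition.  A flat series returns M2 = 0; a fitted negative M2 is
flagged; a series that *rises* by more than 25% of its decay range is
rejected as invalid input.

## Spin-diffusion chain

D_sd = √(π/6)·r²·√M2 with r² in nm² and √M2 in Hz gives nm²/s directly;
the √(π/6) prefactor applied to r²√M2 is the dimensionally consistent
reading, and with t* in the tens of ms it places d on the tens-to-hundreds
of Å scale observed for sugar gels.  The default r² = 0.0625 nm²
(r = 0.25 nm) with an allowed band 0.048–0.0625 nm², the inter-proton
distance range of saccharides; values outside the band require an explicit
override.  Whether the quoted 0.22–0.25 nm refers to r or r² is genuinely
ambiguous in the source literature for this application; this package
takes it as r and documents the alternative (r² = 0.22–0.25 nm² would
scale d by ≈2).

**t\* extraction.**  The Goldman–Shen long-component curve is normalized
to L(0) = 1 (using the t = 0 point when present), the initial region is
selected as all points with L ≥ 0.7 (at least 4 required), and a straight
line is fitted to L versus √t.  "Intercept to the x-axis" is read as the
zero crossing of that line, t* = (x-intercept)²; the alternative reading
(crossing of the equilibrium plateau) is available via
`intercept_mode="plateau"`.  The 0.7 threshold is a convention: it keeps
the fit inside the √t-linear regime (transfer depth ≲ 0.27 of the source
slab) while retaining enough points at realistic sampling.  A
non-negative slope raises a no-transfer error.

**Thickness.**  d = 2β√(D_sd·t*/π), computed in nm, reported in Å.  The
exact scaling laws d ∝ β, √t*, M2^¼, √r² are asserted numerically in the
test suite.  The M2 fed to the chain defaults to the MSE-channel estimate,
the channel with the least dead-time bias.

## Phantom simulator

Phantoms bundle the ground truth (rigid fraction, M2, T2m, T1, lamellar
geometry, D_sd) and generate all four experiment types.  Noise is
additive white Gaussian with SNR defined at the signal origin
(defaults: noiseless; typical benchtop values of 100 for FIDs and 50 for
curves are used in the Monte-Carlo tests); `snr=inf` is bit-reproducible.
Acquisition defaults mirror benchtop practice: a 300 ms saturation-recovery
observation window, a 25 µs mobility-filter gap (after which the rigid
signal is treated as fully dephased), MSE-refocused FIDs starting at
t = 0 with 1 µs dwell and 512 points.

**Goldman–Shen simulation.**  The mixing-time dynamics are solved on a
periodic 1D lamellar unit cell — one rigid slab of width d and one mobile
slab of width W — with a single uniform diffusion coefficient, explicit
FTCS finite differences, and the stability bound dt ≤ dx²/(2D) enforced
at grid construction (an unstable grid is a constructor error, never a
silent divergence).  The initial state is magnetization 1 in the mobile
slab, 0 in the rigid slab (ideal mobility filter); the observable is the
mobile-phase integral normalized to 1, with the rigid-phase integral
exported alongside.  T1 decay during mixing is available but off by
default, matching the uncorrected initial-rate analysis.  Tests verify
magnetization conservation (<10⁻⁶ relative drift), the √t early-time
law, grid convergence, and agreement with the exact Fourier-series
solution of the same initial-value problem.

**Geometry and what the intercept measures.**  For early times the
magnetization lost by the mobile slab per interface is √(Dt/π), so the
initial-rate line of L(t) reaches zero at 2√(Dt*/π) = W: the intercept
construction measures the *source* (mobile) slab width.  Default phantoms
therefore use a symmetric cell (W = d), in which this equals the rigid
domain thickness and d_true is recovered directly; for asymmetric cells
(configurable) the recovered length is the mobile width, and the package
documents rather than hides this.  The FID amplitude split
(rigid_fraction) and the geometry are configured independently — real
candies have no reason to tie proton counts to lamellar volumes.

**Default candy roster.**  Ten virtual samples (5 syrup types × 2 syrup
levels, 3 replicates by default) with M2 values taken from the bundled
MSE benchmark column (8.55–12.02 ×10⁸ Hz²), interface thicknesses from
the thickness benchmark (47.5–641 Å), T1 spread over 35–65 ms, rigid
fractions 0.20–0.38, T2m = 500 µs.  Each phantom's D_sd is the value its
own M2 implies through the chain, so simulation and analysis share a
consistent ground truth.  The mixing-time ladder is geometric,
t_nom/256 to 2·t_nom with t_nom = πW²/(4D), prepended with t = 0.

What the generator does *not* emulate: receiver ringing and B1
inhomogeneity, distributions of domain sizes, 2D/3D morphologies,
per-phase diffusion coefficients, multi-exponential T1.  Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to instrument artifacts.

## Batch pipeline and statistics

Per replicate: T1 fit, MSE FID decomposition, SE back-extrapolation, and
the Goldman–Shen chain (fed by the replicate's own MSE M2).  Failures at
any stage are quarantined — recorded with a stage label, reported in the
results table, never fatal to the batch; analyzed + failed counts always
reconcile with the sample sheet.  Groups are the (syrup type, amount)
pairs; statistics (mean ± sd) require ≥2 replicates.  Group separation
uses one-way ANOVA plus Tukey HSD at 95%, with compact letters assigned
by maximal cliques of the not-significantly-different graph (the exact
letter display, computed via networkx); when the within-group variance is
numerically zero (noiseless synthetic replicates) groups are compared by
exact mean equality instead of a degenerate studentized-range test.
Two-way type × amount analysis is out of scope; each factor can be
examined by regrouping.

## Problem sizes

Unit and acceptance tests use 512-point FIDs, 16-delay recovery curves,
6–10 echo delays, 28-point mixing ladders, 128-cell diffusion grids
(96/192 for the convergence check), 100-seed Monte-Carlo loops for FID
bias, and 200 for T1 — sizes chosen to match the statistical precision
the assertions need.  The full suite runs in about a minute.

## Known limitations

- The initial-rate construction is an approximation: even noiseless,
  curvature of L(√t) within the fitting window biases t* by a few
  percent (the end-to-end tests allow ±25%, observe ≲1%).
- M2 in plain Hz² is a convention (see above); comparisons across
  software using angular units require the √(2π) correction.
- The SE channel assumes the mobile component is unattenuated over the
  echo-delay range; strongly relaxing mobile phases would bias the
  plateau estimate.
- Tukey letters on heavily unbalanced designs inherit the limitations of
  the studentized-range approximation.
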