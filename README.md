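# tdnmr

Time-domain NMR (TD-NMR) relaxometry analysis for two-phase soft
materials — gelatin-based confectionery gels, hydrated biopolymers,
semicrystalline matrices — measured on benchtop low-field instruments.

Beyond the conventional relaxation times, benchtop TD-NMR can read out the
*rigid* (crystalline/glassy) versus *mobile* (gel water) composition of a
sample and the length scale of the interface between the two phases.  This
package implements that non-conventional analysis chain:

- **T1** from saturation-recovery curves, fitted to the mono-exponential
  model M(t) = M0 (1 − exp(−t/T1));
- **rigid/mobile FID decomposition**: the free induction decay is modelled
  as A_r·exp(−a²t²/2)·sin(bt)/(bt) + A_m·exp(−t/T2m) (Abragam rigid line
  shape plus exponential mobile part), giving the **second moment**
  M2 = a² + b²/3 (Hz²) and a relative **crystallinity index**
  A_r/(A_r+A_m).  Works on Magic Sandwich Echo (MSE)-refocused FIDs, which
  restore the receiver-dead-time-hidden initial decay;
- **Solid Echo (SE) back-extrapolation**: echo amplitudes A(τ) are
  extrapolated to zero echo delay on a ln A vs (2τ)² scale, providing an
  independent M2 channel;
- **Goldman–Shen spin diffusion**: from the decay of the mobile ("long")
  FID component with mixing time, the initial-rate approximation yields
  the interface-layer thickness

  D_sd = √(π/6) · r² · √M2  (nm²/s),  d = 2β·√(D_sd·t*/π),

  where r² is the mean-square inter-proton distance (≈0.048–0.0625 nm²
  for saccharides), β the transfer directionality (1 for 1D), and t* the
  squared x-axis intercept of the initial slope of the transfer curve
  plotted against √t.

A **phantom simulator** generates all four experiment types from samples
with known ground truth — including a finite-difference solver for spin
diffusion on a periodic two-phase lamellar unit cell — so every estimator
is testable end to end without an instrument.

## Worked example

```python
from tdnmr import (Phantom, SecondMoment, analyze_goldman_shen, compute_dsd,
                   default_mixing_times, simulate_goldman_shen)

# benchmark second moment 11.76e8 Hz^2 -> spin-diffusion coefficient
print(compute_dsd(11.76e8))          # 1550.8971195423262  (nm^2/s)

# a 5 nm lamellar phantom, simulated and analyzed end to end
ph = Phantom(d_true=5.0, dsd_true=1.5e3)
curve = simulate_goldman_shen(ph, default_mixing_times(ph))
res = analyze_goldman_shen(curve, SecondMoment(ph.m2_true))
print(res.t_star)                    # 13.168569197004146  (ms)
print(res.d)                         # 50.14898990597974   (Angstrom)
```

The analysis recovers the 50 Å ground truth to 0.3%; t* sits within 1% of
the closed-form value π·d²/(4·D_sd) ≈ 13.09 ms for a symmetric lamellar
cell.

The same workflow runs from the shell on a whole sample roster:

```sh
tdnmr simulate --out fixtures --seed 3 --replicates 2
tdnmr run fixtures/sample_sheet.csv --out results
tdnmr report results
```

which prints a grouped table (mean ± sd, Tukey letters at 95%):

```
sample        n   M2_SE(x1e8)  M2_MSE(x1e8)  T1(ms)   d(A)
SBF10-30   2   10.92+/-0.00 h 10.92+/-0.00 h 41.7+/-0.0 h 57.9+/-0.0 h
SBF10-60   2   11.00+/-0.00 g 11.00+/-0.00 g 45.0+/-0.0 g 96.1+/-0.0 c
SCG40-30   2   11.76+/-0.00 c 11.76+/-0.00 c 58.3+/-0.0 c 47.6+/-0.0 j
...
```

Second moments are reported on the conventional ×10⁸ Hz² scale and the
interface thickness in Å; letters separate groups that differ
significantly.

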