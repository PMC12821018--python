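# Methods

This note documents the physical model, the estimation procedures, the
synthetic-data generator and the numerical choices behind `elastimap`.
All in-memory quantities are SI; file columns carry unit suffixes
(`_Pa`, `_um`, `_nN`, ...).

## 1. Contact mechanics

A rigid sphere of radius `R` (default 44.65 µm) indents an isotropic,
homogeneous, linear-elastic half-space characterised by the reduced
modulus `K = E / (1 - nu^2)`. Reporting K avoids assuming a Poisson's
ratio for soft tissue.

**Hertz (paraboloid) model.**

```
F(delta) = (4/3) K sqrt(R) delta^{3/2}
```

The paraboloid approximation of the sphere is accurate for shallow
contact; fits are flagged when `delta_max / R >= 1/3`. The inverse
`delta(F)` and the tangent stiffness `dF/ddelta = 2 K sqrt(R delta)` are
closed-form.

**Sneddon (exact sphere) model.** Parametrised by the contact radius `a`:

```
delta(a) = (a/2) ln[(R + a)/(R - a)]
F(a)     = K [ ((a^2 + R^2)/2) ln((R + a)/(R - a)) - a R ]
```

Both legs are strictly monotone on `a ∈ [0, R)`, so depth→radius and
force→radius inversions are unique; they are solved with Brent's method
on `[0, (1 - 1e-9) R]` (absolute tolerance 1e-18 m, relative 1e-12 — the
absolute tolerance must sit far below the ~1e-5 m radius scale or it
dominates the bracketing). For small `delta/R`, Sneddon converges to
Hertz (relative force difference < 0.2 % at `delta/R = 0.01`).

Both models are **linear in K**, which the fitting exploits: with the
unit-modulus shape `g(delta) = F(delta; K = 1)`, the least-squares
modulus is closed-form, `K = Σ g F / Σ g²`. For Sneddon, `g` is
evaluated through a dense monotone `a`-grid interpolant (4096 nodes) of
the exact parametrisation, avoiding per-sample root-finding in batch
fits.

## 2. Per-curve pipeline

Given a raw extend segment (piezo height `z`, deflection `d`, spring
constant `k_c`):

1. **Calibration** — `F = k_c d` (idempotent; conflicting calibrations
   raise).
2. **Baseline** — straight line (offset + tilt) fitted to the leading
   50 % of the pre-contact span, then subtracted. The pipeline runs two
   passes: a provisional contact point restricts the second baseline fit
   to strictly pre-contact data.
3. **Contact point** — grid search minimising the fit residual sum of
   squares over candidate contact heights: a coarse pass on ~200
   decimated candidates, a full-resolution pass around the winner, and a
   parabolic refinement of the RSS vertex. Indentation is
   `delta = (z - z_c) - d` after baseline removal. A fitted curve whose
   predicted peak force stays below 5× the residual RMS is rejected as
   "no contact" — a never-touching baseline sweep must not produce a
   modulus.
4. **Modulus fit** — closed-form least-squares K over all post-contact
   samples (≥ 20 required); residual RMS and `delta_max/R` recorded.
5. **Stiffness fit** — model-free slope `k = dF/ddelta` over the top 10 %
   of the indentation range (`stiffness_window = (0.90, 1.00)`).
6. **Quality control** — a curve is kept only if the achieved maximum
   force and the achieved approach speed are within 10 % of their
   setpoints (`qc_tolerance = 0.10`) and every pipeline stage succeeded.
   Failures are verdicts with reasons (`force_deviation`,
   `speed_deviation`, `fit_failure`, ...), never silent drops: batch
   outputs contain one row per input curve.

## 3. Map analysis

* **Grid** — measurement positions are cell centres `(i + 1/2) * res` of
  a global lattice clipped to the section outline polygon (points on the
  boundary count as inside). The global anchoring makes grid building
  idempotent under re-building on the same outline.
* **Repeats** — repeated measurements at one position are averaged over
  QC-passing curves only.
* **Summary** — per compartment (gray/white) the **median** K; the map's
  ratio is `median_gray / median_white`, never a median of pointwise
  ratios. Each response carries its own paired x (per-compartment median
  time/temperature; the ratio uses the mean of the two medians).
* **Time binning** — fixed one-hour bins starting 1.5 h postmortem;
  earlier records land in a flagged underflow bin so counts are
  conserved; SD uses the n−1 denominator and needs n ≥ 2.
* **Half comparison** — a measurement-effect control: the last/first
  change of median K in a repeatedly measured half is divided by the
  same change in a sparsely measured half; 1 means measuring does not
  soften the tissue.

## 4. Statistics

* **Linear vs constant** — OLS line against the mean, decided by the
  extra-sum-of-squares F-test,
  `F = (RSS_null - RSS_alt) / (RSS_alt / (n - 2))`, p from `F(1, n-2)`.
  Adjusted r² uses the single-predictor correction.
* **Relative slope** — `100 a / (a T_ref + b)` in %/°C with
  `T_ref = 38 °C` (rat body temperature), making compartments of
  different absolute stiffness comparable. Undefined (raises) when the
  predicted response at `T_ref` is non-positive.
* **Strain and strain rate** — nominal strain `epsilon = delta / h` for
  section thickness `h`; strain rate `1/(2 t_delta)` treating one
  indentation of duration `t_delta` as half an oscillation period.
* **K–k correlation** — Pearson r plus the OLS line of `k` on `K`.

## 5. Synthetic generator

The generator exists to validate the pipeline against known truth; it is
a *phenomenological* model, not a tissue simulation.

**Response model.** Each compartment's true modulus is

```
K(F, s, t, T) = K_ref · [1 + A_F (1 - e^{-F/F_c})] · [1 + A_s (1 - e^{-s/s_c})]
                · f_pm(t) · [1 + (rho/100)(T - 38)]
```

with a logistic plateau–decline–plateau postmortem factor `f_pm`
(midpoint `(t_on + t_off)/2`, width `(t_off - t_on)/8`, terminal fraction
`f_end`). Saturating exponentials encode that force/speed stiffening is
strongest at the low end of the protocol ranges. Defaults (transverse
phantom): gray `K_ref = 200 Pa, A_F = 1.0, F_c = 200 nN, A_s = 0.6,
s_c = 150 µm/s, rho = -3.9 %/°C`; white `K_ref = 65 Pa, A_F = 3.0,
F_c = 300 nN, A_s = 0.1, s_c = 200 µm/s, rho = -3.7 %/°C`. White matter
stiffening harder with force/speed is what drives the gray-to-white
ratio down those axes, while the near-equal temperature slopes keep the
ratio temperature-invariant.

**Phantoms.** Elliptical outline with an interior elliptical gray region
(transverse/horizontal/sagittal presets; the longitudinal planes use
stiffer white matter, pulling the ratio toward 1). Animal-to-animal
variability multiplies `K_ref` by independent lognormal factors per
compartment — independence matters, because a shared factor cancels in
the ratio and produces unrealistically zero ratio scatter.

**Curve simulation.** Closed-loop kinematics: the piezo advances at the
setpoint speed; at travel `u` past contact the quasi-static balance
`u = delta + F(delta)/k_c` fixes the indentation (inverted on a dense
20 000-node table), the deflection is `u - delta`, and the ramp ends when
F reaches the setpoint. Pre-contact approach is 1.2× the contact travel.
Noise: Gaussian deflection noise (SD a fraction of the setpoint-force
equivalent, default 1 %), uniform baseline offset (±0.5 nN) and tilt
(±1e-5 N/m). A deliberately short `z_range` truncates the ramp below the
setpoint, producing curves that QC must exclude. The generating truth
(contact point, K, depth, duration, baseline) rides along in
`ForceCurve.ground_truth` and in per-experiment `ground_truth.csv`.

**Determinism.** One integer seed governs an experiment through
hierarchical `numpy` `SeedSequence` spawning (condition i, curve j);
identical inputs give byte-identical output files, and any subset is
independently reproducible.

## 6. Problem sizes and runtime

Chosen for desk-scale validation, not to mirror any particular
instrument campaign: default grids of 300–450 µm pitch give ~20–60
curves per map; the bundled temperature study uses 6 simulated animals ×
5 temperatures (20–38 °C) at ~30 positions each and runs in well under a
minute per seed on one CPU. Single-curve processing costs ~20–50 ms.

## 7. Limitations

* The contact models assume isotropy, homogeneity, pure elasticity and a
  flat, thick sample; viscoelasticity appears only phenomenologically
  through the generator's speed factor, and finite-thickness corrections
  are out of scope.
* The generator's quasi-static inversion neglects cantilever dynamics
  and hydrodynamic drag; retract segments are not modelled.
* Compartment labels come from the phantom geometry (or a user
  manifest); no image segmentation is performed.
* The statistics module covers the two-model F-test family only; no
  mixed-effects modelling of animal nesting is attempted — per-map
  summaries are treated as independent observations, as in the original
  analysis design.
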