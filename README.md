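# elastimap

Analysis and simulation of sphere-indentation atomic force microscopy (AFM)
elasticity maps of soft tissue, built around the gray-to-white-matter
stiffness contrast of spinal cord sections.

AFM indentation presses a bead-tipped cantilever into a sample while
recording cantilever deflection against piezo height. From each
force-distance curve one extracts the **reduced apparent elastic modulus**
`K = E / (1 - nu^2)` by fitting an elastic contact model past the contact
point. Mapping K over a tissue section and labelling positions as gray or
white matter yields per-map compartment medians and their ratio
`K_g / K_w` — a dimensionless stiffness contrast that can be compared
across measurement forces, speeds, temperatures and postmortem times.

`elastimap` implements the full chain:

* **contact models** — Hertz paraboloid `F = (4/3) K sqrt(R) delta^{3/2}`
  (valid for `delta/R < 1/3`) and the exact Sneddon rigid-sphere solution
  parametrised by contact radius `a`, with forward, inverse and tangent
  stiffness evaluation (`elastimap.contact`);
* **curve processing** — calibration, baseline (offset + tilt) removal,
  grid-search contact-point detection, closed-form least-squares K fit,
  model-free stiffness slope `k`, and 10 % setpoint quality control
  (`elastimap.processing`);
* **map analysis** — grid building on a section outline, repeat
  aggregation, per-map compartment medians and the `K_g/K_w` ratio,
  one-hour postmortem binning from 1.5 h, and a remeasurement control
  comparing section halves (`elastimap.mapping`);
* **statistics** — linear-vs-constant extra-sum-of-squares F-test,
  relative slopes normalised at 38 °C, nominal strain `delta/h`, strain
  rate `1/(2 t_delta)`, and K–k correlation (`elastimap.stats`);
* **synthetic data** — two-compartment tissue phantoms with a smooth
  ground-truth response model over force, speed, postmortem time and
  temperature, plus a closed-loop curve simulator, so every stage can be
  validated against known truth (`elastimap.synthetic`,
  `elastimap.workflows`);
* **CLI** — `elastimap simulate | fit | summarize` with YAML run
  configuration and per-run provenance records (`elastimap.cli`).

## Quick start

Simulate one noisy curve over a 250 Pa sample and run the full per-curve
pipeline:

```python
from elastimap import Cantilever, NoiseModel, process_curve, simulate_curve

curve = simulate_curve(
    K_true=250.0,                      # reduced modulus of the sample (Pa)
    cantilever=Cantilever(0.09),       # spring constant (N/m)
    setpoint_force=30e-9,              # ramp stops at 30 nN
    speed=20e-6,                       # 20 um/s piezo speed
    noise=NoiseModel(noise_fraction=0.01, seed=1),
)
fit, stiffness, verdict = process_curve(curve, model="hertz")
print(f"K = {fit.K:.1f} Pa (true 250.0)")
print(f"contact point z_c = {fit.contact_point*1e6:.2f} um "
      f"(true {curve.ground_truth['z_c']*1e6:.2f} um)")
print(f"max depth = {fit.delta_max*1e6:.2f} um  (delta/R = {fit.delta_max_over_R:.3f})")
print(f"stiffness k = {stiffness.k*1e3:.3f} mN/m,  keep = {verdict.keep}")
```

Output:

```
K = 249.1 Pa (true 250.0)
contact point z_c = 7.19 um (true 7.19 um)
max depth = 5.66 um  (delta/R = 0.127)
stiffness k = 7.631 mN/m,  keep = True
```

The same flow on the command line, over a whole simulated map:

```sh
elastimap simulate --seed 17 --resolution-um 300 --out run/
elastimap fit run/F30nN_s20ums_t1.5h_T32.5C --out run/results.csv
elastimap summarize run/results.csv run/F30nN_s20ums_t1.5h_T32.5C/manifest.csv \
    --out run/summary
```

`run/summary/map_summaries.csv` then holds the per-map medians and the
`K_g/K_w` ratio; with multiple temperatures or timepoints, regression and
binned-series CSVs are written alongside. Every step leaves a
`provenance.json` (config hash, seed, versions, counts).

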