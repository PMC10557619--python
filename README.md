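# tractspan

Lifespan trajectory analysis of white matter bundle features.

Diffusion MRI tractography reconstructs white matter pathways as bundles of
streamlines. Across the human lifespan — from infancy through development,
adulthood, and aging — the microstructure of those pathways (FA, MD, AD,
RD, ICVF, ISOVF, OD), their macrostructure (volume, length, span, curl,
diameter, elongation, surface areas), and the morphology of the cortex they
connect (thickness, area, volume, curvature, sulcal depth) all follow
nonlinear rise-and-decline trajectories whose rates and timing differ by
pathway. `tractspan` implements the quantitative machinery for
characterising those trajectories when the data come from several cohorts
that partition the age axis:

* **Bundle shape features** — the ten macrostructural features of a
  streamline bundle, computed from TRK/TCK tractograms on a voxel grid.
* **Scalar sampling** — tract-averaged microstructure from NIfTI maps, and
  cortical features probed at streamline endpoints (NaN-aware for
  pathways without associated cortex).
* **Continuity-based harmonization** — removal of an additive acquisition
  offset confined to one cohort, estimated from trajectory continuity at
  shared age boundaries (the situation where ComBat-style methods fail for
  lack of covariate overlap).
* **C-RCS trajectory modelling** — covariate-adjusted restricted cubic
  spline regression over knots at 2, 4, 22, 35, 75, 90 years; per-year and
  percent-per-year rates of change from the analytic derivative; peak /
  minimum ages; subject-level bootstrap bands and extremum-age confidence
  intervals; cohort-binned rate summaries.
* **Association analyses** — feature x feature (partial) correlations with
  Benjamini-Hochberg FDR, cross-pathway rate coupling, development-versus-
  aging rate coupling ("gain predicts loss"), and anterior-posterior
  gradient fits.
* **Synthetic study generator** — four age-partitioned cohorts with known
  ground-truth curves, an injected young-adult offset, sex effects, noise,
  longitudinal infant sessions, and parametric bundles (tube, arc, fan)
  with analytically known geometry — so every stage is testable end to end
  with no data download.

The model at the core: for each bundle and feature,

    value = b0 + b1 B1(age) + ... + b5 B5(age) + g 1[sex=F] + e,

where B1(age) = age and B2..B5 are Harrell's restricted cubic spline basis
functions — natural cubic splines, linear beyond the boundary knots. The
curve's derivative gives the *difference per year*; divided by the fitted
value it gives the *percent difference per year*; resampling subjects with
replacement and refitting gives 95% bands and peak-age confidence
intervals. See `docs/methods.md` for the full account.

## Worked example

```python
import tractspan as ts
from tractspan import synthetic, trajectory, harmonize

# a synthetic study: 4 cohorts x 100 subjects, 5 bundles x 4 features
truth = synthetic.default_truth()
table, _ = synthetic.generate_feature_table(
    truth, synthetic.default_cohorts(100), seed=1
)

# remove the young-adult acquisition offset by boundary continuity
estimates = harmonize.estimate_offset(table)
est = next(e for e in estimates if (e.bundle_id, e.feature) == ("AF_left", "FA"))
print(f"recovered offset {est.offset:.4f} (injected 0.02)")
table = harmonize.apply_offset(table, estimates)

# fit the FA trajectory of the left arcuate with bootstrap uncertainty
af = table[table["bundle"] == "AF_left"]
boot = trajectory.bootstrap_trajectory(
    af, "FA", config=trajectory.PipelineConfig(B=200, seed=1)
)
e = boot.extremum
print(f"FA peak at {e.age:.1f} y (95% CI {e.ci_low:.1f}-{e.ci_high:.1f})")

model = trajectory.fit_trajectory(af, "FA")
rates = trajectory.bin_rates(model)
print({k: round(v, 3) for k, v in rates.items()})
```

Output:

```
recovered offset 0.0134 (injected 0.02)
FA peak at 18.7 y (95% CI 16.4-20.6)
{'infant': 2.554, 'development': 0.66, 'young_adult': -0.279, 'aging': -0.257}
```

The recovered offset is the injected acquisition effect up to estimation
noise at this sample size; FA peaks in adolescence for this truth curve
(`0.32 + 0.0126 a exp(-0.055 a)` peaks at 1/0.055 ~ 18 y, and the fit
finds it); the binned rates show the expected pattern of fast infant
increase, slowing development, and slow decline thereafter.

A full run — simulate, harmonize, fit every bundle x feature, associate —
with a manifest of output hashes:

```bash
tractspan run --out out/ --n-per-cohort 100 --b 200 --seed 1
```

Other subcommands (`simulate`, `shape`, `sample`, `harmonize`, `fit`,
`associate`, `couple-rates`, `summarize`) expose the individual stages; see
`tractspan --help`.

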