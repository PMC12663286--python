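# thermacup

Analysis pipeline for thermography + colorimetry studies of
cupping-induced skin response, aimed at early pressure-injury (PrI)
detection research across diverse skin tones.

A 2″ suction cup at −30 kPa for 5 min over the posterior superior iliac
spine leaves a spatially structured response: warming around the rim,
transient ischemic cooling under it, and a slower-recovering cold spot
at the center. `thermacup` turns per-subject optical/thermal image
pairs and point erythema readings into cohort statistics:

1. **Registration** — a 6-DOF planar affine map between optical and
   thermal pixel coordinates, least-squares fitted to labeled fiducial
   corner points, with an RMS residual report.
2. **Concentric ROIs** — from the annotated cup-imprint ellipse
   (axes a, b), companions at 1.25× and 0.25× define three regions:
   Peri-ROI (between 1.25× and 1×), ROI Edge (between 1× and 0.25×),
   ROI Center (inside 0.25×), rasterized into disjoint pixel masks by a
   strict pixel-center test.
3. **Series** — per region and timepoint t ∈ {pre, 0–7 min}: median and
   IQR of masked temperatures; deltas ΔT(t) = med(t) − med(pre) and
   ΔE(t) = E(t) − E(pre).
4. **Statistics** — one-sample t-tests of every delta against zero;
   Pearson correlation of ΔT (ROI Center) with ΔE over minutes 1–7 with
   a Fisher-z 95% CI, tanh(atanh r ± z₀.₉₇₅/√(n−3)), overall and by
   eumelanin category; one-way ANOVA of deltas across sex, BMI category
   and skin-tone category at minutes 0 and 7; group mean ± SD tables.

Because raw study data of this kind are rarely shareable, the package
includes a first-class synthetic-data generator (`thermacup.synth`)
that emulates the study conditions — exponential regional temperature
kinetics anchored at minute-0 deltas of +0.37/−0.06/−0.54 °C,
MST-group-structured erythema deltas, fiducials with a known
ground-truth affine — so the full pipeline is testable end to end,
including exact parameter recovery on noise-free data. See
`docs/methods.md` for the model details and defaults.

## Worked example

```python
from thermacup.model import CuppingStudy
from thermacup.synth import generate_study

study = generate_study(n_darker=30, n_lighter=5, seed=0, render_optical=False)
results = CuppingStudy(dataset=study).fit()
print(results.summary())
```

prints (abridged):

```
Temperature delta vs baseline (cohort median, °C)
region           m0     m1     m2     m3     m4     m5     m6     m7
Peri-ROI       0.45   0.15   0.12   0.11   0.11   0.11   0.11   0.11
ROI Edge      -0.02   0.10   0.17   0.22   0.24   0.26   0.27   0.28
ROI Center    -0.49  -0.27  -0.12  -0.01   0.08   0.14   0.19   0.22

One-sample t-tests against zero (selected)
  Peri-ROI     m0: mean=+0.417 t=+4.28 p=0.0001456*
  ROI Center   m0: mean=-0.507 t=-4.76 p=3.546e-05*
  ROI Center   m7: mean=+0.204 t=+1.92 p=0.06363

Temperature/erythema correlation (minutes 1–7, ROI Center)
  all                n=245  r=+0.080 95% CI [-0.046, +0.203] p=0.2138
```

Reading it: immediately after cup removal the ROI Center has cooled by
about half a degree (strongly significant), the rim region is near
baseline, and the surrounding Peri-ROI is transiently warm; the center
recrosses baseline between minutes 3 and 4 and keeps warming. The
correlation is near zero here because the generator draws erythema and
temperature independently — on real data this is the estimate of
interest. Each subject's analysis runs fiducial registration, maps the
annotated ellipse into thermal coordinates, rasterizes the three
regions and reduces the frames; `results.cohort_table` holds the tidy
long table (one row per subject × region × timepoint plus erythema
rows) joined to covariates, and `results.to_report()` serializes every
test with its provenance.

The same pipeline runs from the shell on an on-disk dataset
(`cohort.csv`, `subjects/<id>/thermal_<tp>.csv`, `optical_<tp>.png`,
`fiducials.json`, `roi.json`, `erythema.csv`):

```sh
thermacup full --seed 42 --out runs/demo          # simulate + analyze
thermacup analyze --dataset runs/demo/dataset --out runs/again
```

Outputs: `cohort_long.csv`, `stats_report.json`, the effective config,
and a checksummed dataset manifest; identical config + seed gives
byte-identical outputs.

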