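# sweatpk

Dynamic metabolic phenotyping of caffeine catabolism from finger-sweat
time series.

Sweat sampled from fingertips is an attractive non-invasive matrix for
time-course metabolomics, but each sample's volume is tiny (hundreds of
nanolitres) and fluctuates strongly between collections, so the raw
LC-MS signal of a metabolite confounds its body concentration with the
unknown sampled volume. `sweatpk` resolves this by kinetic network
modelling: it simulates and fits a one-compartment, first-order model of
caffeine pharmacokinetics in which the signal at each time-point is the
product of the body concentration and a free, time-point-specific sweat
volume shared by all metabolites.

## The model

After ingestion of a dose D (bioavailability F), caffeine is absorbed
from the gut with rate k1, converted to its three primary metabolites
and eliminated, all first order:

```
gut --k1--> caffeine --k2--> paraxanthine --k6--> out
                     --k3--> theobromine  --k7--> out
                     --k4--> theophylline --k8--> out
                     --k5--> out
```

with bounds 0 <= k1 <= 10 h⁻¹ and 0 <= k2..k8 <= 0.2 h⁻¹, zero initial
caffeine (fasting) and product baselines C₀ in [0, 1] µg L⁻¹. Body
concentrations C(t) follow in closed form (sums of exponentials via
divided differences of e^(−kt)); the measured, internal-standard-
normalized signal is

```
M̃ᵢ(tⱼ) = V_sweat(tⱼ) · Cᵢ(tⱼ),     0.05 µL <= V_sweat(tⱼ) <= 4 µL
```

so each sampled time-point contributes one extra nuisance parameter.
Per-profile fitting is bounded trust-region-reflective least squares
under a generalized robust loss, restarted from 100 Monte-Carlo initial
points; the lowest-loss solution is reported with adjusted R², CV-based
confidence intervals and a per-start convergence log.

The package also ships the surrounding study machinery: a synthetic
cohort generator with known ground truth (published sampling grids,
technical duplicates, ~10% technical CV, LOD censoring), quantification
QC (calibration, LOD/LLOQ = blank mean + 3/10 SD, CVs, extraction
efficiency), and cohort statistics (exact tie-aware Wilcoxon signed-rank,
paired t, normality checks, Perseus-style s0/permutation-FDR volcano,
shared-control bootstrap intervals, PCA of metabolite profiles or fitted
constants).

**A caution on identifiability.** Because every time-point carries a free
volume, the model has an exact one-parameter degeneracy: shifting
(k1, k5..k8) by δ while rescaling the baselines and volumes reproduces
every signal identically. k2, k3, k4 and rate differences are
identifiable; k1, k5–k8 and the volume series individually are not.
See `docs/methods.md` and `examples/05_identifiability.py`.

## Worked example

`examples/02_fit_profile.py` simulates one capsule-study volunteer on
the long sampling grid (20 time-points over 24 h, technical duplicates,
10% CV) and fits it:

```
adjusted R^2 = 0.9940  (n = 160 observations, df = 129)
robust-loss alpha used: 2.0

conversion constants (identifiable):
  k2: truth 0.0645  fitted 0.0708  (9.9% off)
  k3: truth 0.0112  fitted 0.0135  (20.8% off)
  k4: truth 0.0062  fitted 0.0069  (10.8% off)

paraxanthine fraction k2/kappa: truth 0.65, fitted 0.69
```

The fit explains 99.4% of the signal variance; the paraxanthine
conversion fraction k2/κ — the phenotype of interest — is recovered to a
few percent despite the 10% technical noise and the unknown volumes.
The other examples cover forward simulation (`01`), quantification QC
(`03`), cohort statistics (`04`) and the identifiability gauge (`05`);
each prints a short, annotated result. A thin CLI mirrors the library:

```
sweatpk simulate --design C2 --n-volunteers 5 --out-dir sim/
sweatpk fit sim/volunteer_01.csv --n-starts 100 --out fit.json
```

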