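# Methods

## Kinetic model

The body is a single well-mixed compartment. An ingested caffeine dose
D (mg, default 200) with bioavailability F (default 1.0) sits in the
gut at t = 0 and is absorbed with first-order rate k1; absorbed caffeine
is converted to paraxanthine (k2), theobromine (k3) and theophylline
(k4) or eliminated directly (k5), and each product is eliminated first
order (k6, k7, k8). Volumes of distribution Vd (default 36 L for all
four species) are constant in time; concentrations are reported in
µg L⁻¹. Caffeine starts at zero (enforced fasting); product baselines
C₀ lie in [0, 1] µg L⁻¹.

Internal bookkeeping is molar: the gut load F·D/M_caf (mmol) feeds the
cascade, and branching fluxes are converted to mass concentration with
the product's molar mass (caffeine 194.19, dimethylxanthines
180.16 g mol⁻¹), i.e. one mole of converted caffeine yields one mole of
product. The linear cascade is solved in closed form: each species is a
short sum of exponentials written as divided differences of e^(−xt)
(the Bateman kernel and its three-node extension). Divided differences
are evaluated with the outermost nodes maximally separated, and nodes
closer than 1e-9 h⁻¹ coalesce to the analytic confluent limit, so the
evaluation is stable when rate constants (nearly) coincide — including
the textbook k1 = κ caffeine limit F·D·k1·t·e^(−k1·t)/Vd. An
independent stiff-capable integrator (`ode_oracle`, DOP853 at
rtol 1e-12 / atol 1e-20) exists purely for cross-checking; the two
agree to ~1e-11 relative on random in-bounds parameters.

Out of scope by construction: absorption lag, enterohepatic
recirculation, saturable kinetics, and metabolites downstream of the
dimethylxanthines.

## The sweat-volume observation model

The measured signal of species i at sampled time t_j is
M̃ᵢ(t_j) = V_sweat(t_j)·Cᵢ(t_j), with one free volume per time-point
shared by all four metabolites and bounded to [0.05, 4] µL. Fitting a
profile with T time-points therefore estimates 11 + T parameters:
eight rate constants, three product baselines, and T volumes.

### Structural identifiability

The model is *exactly* invariant under a one-parameter family: for any
admissible δ,

    k1 → k1 + δ;  k5, k6, k7, k8 → + δ;
    C₀ → C₀ · (k1 + δ)/k1;
    V_sweat(t_j) → V_sweat(t_j) · k1/(k1 + δ) · e^(δ·t_j)

reproduces every predicted signal identically (the volumes absorb the
common exponential factor the rate shift imprints on all
concentrations; verified against the independent integrator to ~1e-12).
Consequences, verified numerically in the test suite:

- k2, k3, k4, the differences k6−k5, k7−k5, k8−k5 and k1−κ
  (κ = k2+k3+k4+k5), and ratios of volumes at equal times are
  identifiable; k1, k5–k8 and the volume series individually are not.
- A multi-start optimizer reaches numerically zero loss on noise-free
  data but lands at an arbitrary point of the flat valley, so raw k5
  estimates from a single profile can differ from the generating values
  by large factors at a perfect fit. Derived phenotypes such as the
  conversion fraction k2/κ inherit a bounded distortion (κ shifts
  by δ, typically a few percent up to ~20%).
- A *constant* rescaling of (C, V) is **not** a symmetry — the
  absorption amplitude is pinned by F·D/Vd — which is why the fit still
  determines absolute concentrations up to the exponential family only.

The package exposes the family as `fitting.gauge_transform` and the
invariant combinations as `fitting.gauge_invariants`; interpretation of
per-profile results should rest on the invariants. Cross-profile
statistics (PCA of k2–k5, correlation summaries) are run on the raw
constants for fidelity to common practice, but the k5 axis carries
gauge noise and should be read with this caveat.

## Fitting procedure

- Objective: residuals r = V_sweat(t_j)·Cᵢ(t_j) − signal over every
  non-censored row; technical replicates enter individually (a C.1-type
  profile with 15 time-points and duplicates yields n = 120
  observations). Below-LOD rows are excluded, never imputed.
- Robust loss: the generalized family
  ρ(x; α, c) = (|α−2|/α)·[((x/c)²/|α−2| + 1)^(α/2) − 1] with the
  standard limits (α = 2 quadratic, α = 0 Cauchy, α = −∞ Welsch).
  Instead of learning α by the partition-function machinery of the
  adaptive formulation, the fit grids α over {2, 1, 0.5, 0} with the
  scale c fixed at the median absolute signal; within an α the
  lowest-loss start wins, across α the highest adjusted R² wins
  (robust losses at different α are not on a common scale). For purely
  log-normal noise the grid is redundant and α = 2 suffices; the grid
  earns its keep under contamination.
- Optimization: scipy's trust-region-reflective bounded least squares,
  tolerances 1e-8, with the loss's first two derivatives supplied.
  n_starts = 100 initial vectors drawn uniformly within bounds from
  per-start seed substreams (a longer run extends a shorter one, so the
  reported loss is non-increasing in n_starts, and results are
  bit-reproducible given the master seed). Starts with non-finite loss
  drop out of the selection pool.
- Goodness of fit: adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with
  p = 11 + T against the mean of the observed signals.
- Confidence intervals: estimate ± t(0.975, df)·CV·estimate, with CVs
  supplied per parameter (e.g. from a sensitivity study) and df
  defaulting to n − (11 + T). For a 15-time-point duplicate profile
  that default gives df = 94; df is caller-overridable because
  conventions for counting the loss's own hyperparameters differ.

## Synthetic data

The generator emulates the caffeine-capsule study conditions and is the
ground-truth source for every recovery experiment:

- Sampling grids: the published designs (A/B: 0–120 min, 7 points;
  C1: 15 points to 27 h; C2: 20 points to 24 h), technical duplicates,
  200 mg dose.
- Rate constants per volunteer: truncated normal around
  literature-informed centers (k1 = 4.0 h⁻¹; k2 = 0.06, k3 = 0.012,
  k4 = 0.008, k5 = 0.02; k6 = 0.12, k7 = 0.05, k8 = 0.08 h⁻¹ — overall
  caffeine turnover ≈ 0.1 h⁻¹, paraxanthine-dominant), relative
  SD 0.25. No published inter-individual distribution exists; these
  defaults are a documented choice.
- Baselines: long fasts (≥ 48 h) draw C₀ ~ U(0, 0.05) µg L⁻¹,
  short fasts U(0.05, 1) — mirroring the observed effect of fasting
  length on pre-dose dimethylxanthine levels.
- Sweat volumes: log-uniform on [0.05, 4] µL, independent per
  time-point (each volume is a free parameter in the model, so no
  smoothness is assumed); an AR(1)-in-log option with log-uniform
  marginals exists for realism studies.
- Noise: multiplicative log-normal with unit mean at CV 0.10 (the
  internal standard's observed AUC CV), optional additive blank floor,
  and LOD flagging. Signals are clipped at zero.

What passing recovery tests on these data do *not* show: robustness to
matrix effects, retention-time drift, correlated replicate errors, or
model misspecification (real metabolism is not exactly first order) —
none of which the generator emulates.

## Statistics

- Wilcoxon signed-rank: zero differences discarded, midranks for ties;
  exact two-tailed p by dynamic-programming convolution over doubled
  midranks for n ≤ 25 (identical to full 2ⁿ enumeration), normal
  approximation with continuity and tie corrections above. Thirteen
  concordant pairs give p = 2/2¹³ ≈ 0.000244.
- Paired t, D'Agostino-Pearson K² and Lilliefors KS (Dallal–Wilkinson
  p) follow the standard formulations (the latter two via
  scipy/statsmodels).
- s0 volcano: paired moderated statistic t_s0 = d̄/(SEM + s0), default
  s0 = 0.1. Reported p is the parametric t probability of t_s0
  (df = n−1); significance comes from a SAM-type procedure with
  subject-wise sign-flip permutations (default 10,000, full enumeration
  when 2ⁿ is smaller): the widest |t| cutoff whose estimated
  FDR = (mean null exceedances per permutation)/(observed exceedances)
  stays at or below the target (default 0.05). On a 100-metabolite
  global null the realized false-discovery proportion averages below
  the nominal level.
- Shared-control bootstrap: percentile 95% interval (not BCa) of the
  difference of means, both samples resampled, default 5000 draws,
  seeded.
- PCA: optional column z-scoring, rows with missing values dropped,
  eigendecomposition via scikit-learn; constant columns under scaling
  are an error rather than silently imputed.

## Numerical and design choices

- Sample (n−1) standard deviations throughout the QC module;
  calibration is unweighted OLS with an optional 1/x² weighting flag;
  the intercept is always free.
- Times are stored in minutes on disk (matching the study schedules)
  and hours in memory; species names are fixed to
  caffeine/paraxanthine/theobromine/theophylline.
- Degenerate inputs fail loudly: fully censored tables, constant
  calibration responses, all-zero paired differences, zero-variance
  normality samples and insufficient degrees of freedom all raise
  typed errors.
- Problem sizes in the shipped tests are desk-scale by design:
  recovery studies use 20 Monte-Carlo starts and 20 noise seeds on the
  20-time-point grid, the volcano null uses 50 replicates of 100
  metabolites at 2000 permutations, and calibration coverage uses 1000
  simulated curves.

## Known limitations

- The gauge degeneracy above is the binding limitation: per-profile
  k1/k5–k8 and absolute sweat volumes should not be over-interpreted.
- The adaptive-loss α is selected on a fixed grid, not learned; heavy
  contamination between grid points may be suboptimal.
- CIs require externally supplied CVs; the fit does not compute a
  Hessian-based covariance (it would be singular along the gauge).
- Real-data ingestion is limited to the documented CSV dialect; raw
  vendor files and compound identification are out of scope.
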