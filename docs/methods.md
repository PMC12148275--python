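# Methods

## Cell classification

Each segmented cell carries mean per-channel fluorescence intensities
(Hoechst, cytokeratin/CK, CD8, FoxP3) in arbitrary units. Classification
is a pure per-cell function of those intensities and three thresholds:

| condition (compared with ≥) | class |
|---|---|
| CD8 ≥ t_cd8 and FoxP3 ≥ t_foxp3 | treg (double positive) |
| CD8 ≥ t_cd8 and FoxP3 < t_foxp3 | cd8 |
| CD8 < t_cd8 and FoxP3 ≥ t_foxp3 | foxp3_only |
| otherwise, CK ≥ t_ck | tumor |
| otherwise | unclassified |

Lymphocyte markers take priority over CK: a CK+CD8+ cell is a lymphocyte,
never a tumor cell. The comparison is `>=` throughout — "exceeds" is
boundary-ambiguous, so the left-closed convention is fixed and used
everywhere. FoxP3-only cells are kept as their own class: they count
toward core totals but not toward the lymphocyte count (CD8 + Treg) and
are never NND targets. Threshold values are **required configuration**
with no numeric defaults: they are instrument- and staining-dependent and
must come from the upstream thresholding analysis. For simulated cohorts,
`SimulationConfig.matched_thresholds` places each channel's threshold at
the log-scale midpoint between the highest and lowest class locations.

### Core quality control

A core fails QC when it has fewer than 1000 tumor cells *and* fewer than
3000 total cells (`mode="and"`, the default, reading the rule as a literal
conjunction). Because a conjunctive removal rule is unusual for QC, a
disjunctive reading (`mode="or"`: fail either bound and the core is
removed) is also provided; the two disagree exactly on cores such as 500
tumor / 5000 total. Failed cores are flagged, never deleted; downstream
pooling uses only passed cores.

## Spatial biomarkers

Within each QC-passed core, the Euclidean distance from every tumor cell
to its nearest CD8 cell is computed with a KD-tree and truncated at a cap,
default 1000 µm (the physical bound set by a ~1 mm core). Distances are
never computed across cores: cores are physically distinct tissue.

Policy for a core with tumor cells but zero CD8 cells (the data give no
guidance, and the 1000 µm bound suggests every real core either had a CD8
cell or was capped): default `assign-cap` gives every tumor cell the cap,
keeping such participants in the analysis at proximity ≈ 0 rather than
silently dropping them; `drop-core` excludes the core instead.

Distances are log10-transformed (NNDs are strongly right-skewed) and
*pooled* across a participant's passed cores before moments are taken —
concatenation, not averaging of per-core moments; the two differ when core
sizes differ. Then

- proximity = 3 − mean(log10 NND), in [0, 3] when all NNDs ∈ [1, 1000] µm;
- consistency = 1 − var(log10 NND), ≤ 1 with equality iff all distances
  are equal. Values below 0 are possible in principle and flagged rather
  than clipped.

The variance is the sample variance (n − 1). With thousands of pooled
distances the n vs n − 1 choice is numerically immaterial, but it is fixed
so that small hand-computed examples are exactly testable. A participant
with a single distance has undefined consistency (NaN, excluded from the
analysis cohort with a recorded reason); zero or negative distances raise,
since coincident centroids of different classes indicate upstream
corruption.

The lymphocyte count is the raw sum of CD8 + Treg cells over passed cores
— deliberately not area-normalized, so it depends on how many cores a
participant contributed; the per-participant core count is carried in the
output for exactly this reason.

A sensitivity toggle (`include_double_positive`) adds Treg (CD8+FoxP3+)
cells to the NND target set. Adding targets can only shrink
nearest-neighbor distances, so proximity under the toggle is ≥ the
CD8-only value for every participant (a property the tests check).

### Binarization and cutpoints

Metrics are binarized on the analysis cohort (after exclusions); value ≥
cutpoint → high. Defaults: first quartile for proximity, median for
consistency and for lymphocyte count, with the linear-interpolation
quantile convention. The cutpoint value and rule are recorded in the run
manifest.

`explore_cutpoints` implements the quartile-collapse search that motivated
those defaults: split at Q1/Q2/Q3, fit a Cox model with quartile-group
indicators (top quartile referent), then agglomeratively merge adjacent
groups — closest pair first, block log-HR as the event-weighted mean —
while the gap is below `epsilon` (default log 1.5, halfway between the
null gap and a hazard ratio of 2 on the log scale). Zero-event groups are
pre-merged upward with a warning before fitting, since their coefficients
would diverge. If one block remains there is no cutpoint; otherwise the
boundary with the largest remaining log-HR gap is suggested. The explorer
is advisory only — pipeline defaults stay at the fixed rules above.

## Survival and association estimators

- Kaplan-Meier: product-limit estimate with pointwise 95% bounds on the
  log(−log S) scale (exponential Greenwood), clamped to [0, 1]; via
  lifelines.
- Log-rank: standard unweighted chi-square, df = groups − 1; via
  lifelines.
- Cox PH: partial-likelihood Newton-Raphson via statsmodels `PHReg`,
  chosen because it exposes both Efron (default, matching the R survival
  ecosystem) and Breslow tie handling — on tie-free data the two agree
  exactly, which the tests verify. Wald 95% intervals on the log-HR scale.
  Non-convergence, constant covariates, and monotone likelihoods
  (complete separation) raise explicit errors. A score test at β = 0 is
  provided; with one binary covariate and Breslow ties on tie-free data it
  equals the log-rank statistic (verified to 1e-8).
- Nested models: likelihood-ratio test, 2Δloglik against chi-square with
  df = covariate difference.
- Proportionality: Grambsch-Therneau test on scaled Schoenfeld residuals
  against KM-transformed time (the cox.zph default transform).
  Per-covariate statistics via lifelines; the global statistic is computed
  natively as T = (d/c)·uᵀVu with u = Σ(g_k − ḡ)s_k over event-time
  Schoenfeld residuals s_k, V the inverse information, d the event count
  and c = Σ(g_k − ḡ)²; its null calibration is checked by simulation.
- Kruskal-Wallis (midrank ties correction) and Spearman via scipy; a
  constant vector makes Spearman undefined and raises.
- Odds ratios: the sample OR (ad/bc) with Woolf log-normal CI is the
  default and is what the packaged published counts reproduce at one
  decimal. A zero cell raises with a recommendation to use
  `conditional_mle` (exact conditional estimate and interval via the
  noncentral hypergeometric) — no silent 0.5 continuity correction. The
  published intervals are wider at the top than Woolf intervals computed
  from the same counts, consistent with an exact/conditional method whose
  exact variant is not identifiable from the counts alone; interval values
  are therefore not treated as reproduction targets, only point estimates.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
chosen as a realistic moderately infiltrated TMA study:

- Geometry: disc cores of radius 500 µm; 4 cores/participant by default
  (up to 8 supported, matching participants with two tissue samples).
- Tumor: Thomas cluster process — Poisson(8) uniform parents, Poisson
  offspring (mean 1500/core) with 60 µm Gaussian offsets, rejection-kept
  inside the disc. Real epithelium is clumped; this is the simplest
  process with that property.
- Lymphocytes (mean 200/core): `diffuse` = homogeneous Poisson; `hotspot`
  = Gaussian clusters (3 centers, 75 µm sd); `peripheral` = radial
  intensity ∝ r. Phenotypes: a `treg_fraction` (0.3) of lymphocytes lie on
  the FoxP3+ regulatory lineage; of those, `double_positive_fraction`
  (0.5) are CD8+FoxP3+ (the Treg class), the rest FoxP3-only.
- A diffuse stromal background of unclassified cells (mean 1500/core)
  fills out core totals.
- Intensities: log-normal per class per channel; positive markers at
  location 4.0 (natural log), negatives at 1.0, sd 0.4/0.5 — ≈3 sd of
  separation at the midpoint threshold, giving a per-mille classification
  error rate (tunable by moving the locations together).
- Survival: event times exponential with hazard = baseline ×
  exp(Σ β·1[metric low]); independent exponential censoring; defaults
  baseline 0.015, censoring 0.085 and β = log 2 on low proximity give a
  ~20% event fraction, mirroring a cohort in which recurrence is uncommon.
- Labels: logistic in the binarized metrics with balanced margins;
  default log-odds log 5 on high proximity, so the recovered 2×2 odds
  ratio approaches 5.
- Truth: per-participant metrics are computed by running the production
  classification-free spatial-metrics code on the generated true classes,
  so truth equals recomputation by construction; an independent
  brute-force recomputation is tested separately.

Seeding: one global seed expands through `SeedSequence` spawn keys —
(0, participant, core) per core, (1,) survival, (2,) labels — so identical
config + seed is bit-identical and each core is independently
reproducible.

What the generator does **not** emulate: staining artifacts, intensity
drift across slides, segmentation errors, spatial interaction between
tumor and lymphocyte processes (they are independent given the mode), 3D
tissue, or correlated core sampling within a block. Passing tests
therefore demonstrate correctness of the computational pipeline and
calibration of the estimators under the assumed model — not robustness to
the measurement pathologies of real multiplex-IF data.

A degenerate simulated cohort (e.g. zero lymphocytes everywhere) makes
every metric constant; the analysis-side `binarize` treats a degenerate
quantile as an error, while the generator falls back to labelling all
participants high with a warning so the closure property (the full
spatial pipeline runs on every infiltration mode) holds.

## Numerical and design choices

- KD-tree NND equals the brute-force all-pairs minimum exactly (tested on
  100 random cores); rigid motions leave NNDs unchanged to 1e-9; scaling
  all distances ×10 shifts proximity by exactly −1 and leaves consistency
  unchanged.
- Cox Newton iterations: tolerance 1e-9, max 100; coefficients with
  |β| > 20 or non-finite standard errors are treated as separation.
- Quantiles use linear interpolation everywhere (recorded in manifests).
- Null-calibration simulations use sample sizes in the asymptotic regime
  of the tests they check (≈130 events per replicate for the log-rank
  type-I check): with substantially fewer events the log-rank test is
  conservative, which is a property of the test rather than the
  implementation.
- Test-suite and acceptance-script problem sizes (cohorts of 40–400
  participants with reduced per-core intensities and proportionally
  relaxed QC bounds; 100–500 replicate Monte-Carlo loops at n = 1500)
  were chosen as the smallest scales at which the checked properties are
  statistically sharp.

## Known limitations

- The classifier is deliberately the simple threshold rule; no
  cross-slide intensity normalization or learned classifier is provided.
- The lymphocyte count is core-count-dependent (see above).
- Whether the upstream analysis used population or sample variance, and
  its exact tie/CI conventions for Cox models, are not documented; the
  conventions here (n − 1, Efron, Wald) are fixed and tested but may
  differ in the last digit from other implementations.
- `explore_cutpoints` assumes monotone-in-quartile hazards when merging;
  non-monotone patterns (e.g. U-shaped risk) can merge non-adjacent-risk
  groups and should be inspected via the returned per-quartile log-HRs.
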