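# Methods

`adipoclock` re-implements, as a tested pipeline, a circadian analysis of
serially biopsied human white adipose tissue: a handful of subjects each
provide five biopsies at roughly six-hour intervals under constant-routine
conditions, every subject's samples are timestamped on their own circadian
axis (melatonin onset = time zero), and rhythmicity is assessed per probe by
a mixed-effects cosinor. Rhythmic profiles are clustered on a ring-topology
self-organising map, and the transcriptome is integrated with a
stoichiometric metabolic model to predict which reactions vary over the
cycle. Because the deposited microarray data are not required, a synthetic
generator reproduces the study's data structure with known ground truth;
every stage is validated by parameter recovery against it.

## Circadian alignment (DLMO)

Plasma melatonin is sampled hourly. Dim-light melatonin onset (DLMO) is the
linearly interpolated time of the first upward crossing of 25% of the
subject's own profile maximum, scanning the rise that precedes the maximum.
Flat or non-rising profiles raise an explicit "no onset" error; a profile
already above threshold at its first sample is clipped to the profile start
with a warning. The threshold basis (fraction of the individual maximum,
not an absolute concentration or a population mean) is a configurable
package choice; published threshold conventions differ and the fraction is
an argument.

Biopsy clock times are re-expressed as `t = clock − DLMO`, with the first
biopsy mapped into [−12, 12) h and later biopsies unwrapped across midnight
so each subject's series is monotone. All peak times downstream are
reported in [−12, 12) h relative to DLMO: a transcript peaking just before
melatonin onset reports a small negative peak time (biological evening),
one peaking mid-sleep/early morning reports around +9 h.

## Mixed-model cosinor

Each probe's log2 profile across all subjects is fitted with a linearised
single-component cosinor of fixed 24-h period plus a linear trend:

    y_ij = β0 + β1 t_ij + βc cos(ωt_ij) + βs sin(ωt_ij) + u_i + e_ij,
    u_i ~ N(0, τ²),  e_ij ~ N(0, σ²),  ω = 2π/24,

with a random intercept per subject — the only random-effects structure
identifiable from five points per subject. Amplitude `A = √(βc² + βs²)` and
peak time `φ = atan2(βs, βc)/ω` are derived quantities.

The fit profiles the REML criterion over the variance ratio `λ = τ²/σ²`.
With a single grouping factor, `V⁻¹ = I − Σ_i (λ/(1+λn_i)) 1_i 1_iᵀ`
block-wise, so every REML quantity reduces to per-subject sums. This makes
the search vectorisable across probes: a coarse grid over `λ` (including
the `λ = 0` fixed-effects boundary) followed by a golden-section refinement
runs simultaneously for tens of thousands of probe columns. The engine is
validated against `statsmodels` MixedLM (fixed effects agree to ~1e−4, the
variance ratio to ~1e−3) but is roughly three orders of magnitude faster in
aggregate, which is what makes the permutation FDR (10⁴–10⁵ complete
refits) affordable.

- **R²** is the squared Pearson correlation between conditional fitted
  values (fixed effects plus predicted random intercepts) and the
  observations; marginal R² (fixed effects only) is available via
  `r2_kind="marginal"`. The conditional choice means subject-level variance
  counts toward fit quality, which is why classification also requires the
  amplitude criterion below.
- **Amplitude CI**: delta-method standard error from the REML covariance of
  (βc, βs), `se = √(gᵀΣg)` with `g = (βc, βs)/A`, and a normal 95%
  interval. Near zero amplitude the delta method degenerates; the SE then
  falls back to the mean component variance, and a parametric-bootstrap
  interval (500 draws from N(β, Σ)) is available via `ci_method="bootstrap"`.
  Empirical coverage of the default interval is ~95% at the simulated
  study's signal-to-noise (asserted in [92%, 98%] over 500 probes).
- **Classification**: circadian iff `R² > 0.8` (strict) and the 95%
  amplitude CI excludes zero (lower bound > 0). Constant/singular profiles
  report amplitude 0 with a degenerate CI and are never circadian.
- **Permutation FDR**: per permutation, each probe's values are shuffled
  across the time labels *within* each subject (subject means preserved),
  independently per probe, and the identical fit-and-classify pipeline is
  re-run; FDR = mean permuted discovery count / observed count, reported
  capped at 1 and undefined when nothing is observed. 100 permutations by
  default; bit-reproducible given a seed.

No multiplicity correction beyond the permutation FDR is applied, matching
the analysis being reproduced. Alternative detectors that assume replicated
time points on a shared grid (JTK-style methods) are out of scope: this
design has replicated time *series* with subject-specific sampling times.

## Clustering

Circadian probes are summarised by their fixed-effect model profile
(cosinor + trend evaluated at the averaged sampling times — the mean
aligned time per sampling index across subjects) and z-scored, so
clustering sees phase and shape, not expression level or amplitude.

Profiles are clustered with a batch self-organising map whose `k` nodes lie
on a ring (node i neighbours i±1 mod k) — the natural topology for
phase-ordered curves. Neighbourhood is Gaussian in ring distance, radius
decaying geometrically from k/2 to 0.5 over 200 epochs; initialisation is
deterministic from phase-ordered quantiles of the data; empty nodes are
permitted; clusters are relabelled canonically by ascending circular-mean
peak time, making labels invariant to input order.

The cluster count is chosen by minimising a hard-assignment
spherical-Gaussian BIC over k = 1..6:

    BIC(k) = nd·ln(2πσ̂²) + nd + 2·Σ_j n_j ln(n/n_j) + (kd+1)·ln(nd),

where σ̂² is the mean squared deviation from the assigned cluster centroid
(the ML mean of members, not the neighbourhood-smoothed code vector). The
classification-entropy term `2Σ n_j ln(n/n_j)` is required: without it,
splitting even a single isotropic Gaussian always reduces the score (a
split along any direction explains ≈2/π of that direction's variance, and
the gain grows linearly in n while the parameter penalty grows only
logarithmically), so the criterion would select the largest k on any data.
Known limitation: a profile set whose within-group spread is a continuous
phase gradient is genuinely multi-modal to any hard-partition score and may
still be split; cluster-count selection is reliable for well-separated
phase groups and for modest n, and at desk scale (≈20 circadian probes) the
morning/evening pooling below is the robust summary, not k itself.

Clusters whose circular-mean peak time lies within ±5 h of DLMO are
labelled "evening", all others "morning" (melatonin onset marks the
biological evening), generalising the published two-of-three pooling rule
to any k; evening clusters are pooled for downstream reporting.

## Metabolic integration (iMAT-style)

Per sampling point: probes are averaged to genes, then across participants,
giving one log2 value per gene per time point. Values are discretised by
across-gene percentiles at that time point — state −1 if ≤ 20th percentile,
+1 if > 80th, else 0 (the alternative reading, percentiles across time
within a gene, is available via a flag but is not the default). Gene states
map to reactions through GPR boolean rules with AND = min, OR = max over
the ternary states; reactions without a GPR (or with an unparseable one,
logged) are neutral.

A mixed-integer programme (HiGHS via `scipy.optimize.milp`) then maximises
congruency: the number of state-1 reactions carrying flux `|v| ≥ ε` plus
the number of state-(−1) reactions with `|v| ≤ δ`, subject to `S v = 0` and
bounds, with exchange reactions unbounded at ±1000. Defaults `ε = 1`,
`δ = 1e−6`. Because optimal flux distributions are rarely unique, a second
lexicographic stage fixes the congruency at its optimum and minimises
`Σ|v|`, making the reported flux — and therefore the −1/0/1 activity states
read from it with the same ε/δ thresholds — reproducible. Note the
activity read-off means a reaction left unused by the canonical optimum
reports −1 (no flux), so "all states neutral" yields an all-(−1), constant
profile rather than noise.

On every toy catalogue model the MILP optimum is verified against
exhaustive enumeration of activation patterns with LP feasibility checks —
an independent oracle that scales only to desk-size networks but proves the
MILP encoding. The module reads any model in its native JSON schema or
SBML (via cobrapy, I/O only); genome-scale models such as the ~10⁴-reaction
human reconstructions are supported in principle but outside the test
surface, which runs on the 4–6 reaction catalogue.

Reactions whose activity profile changes state at least once are fitted by
ordinary least squares to a 24-h cosinor (mesor + cosine; one profile, no
subjects, hence no mixed model) at the averaged sampling times and called
rhythmic when R² ≥ 0.8 (inclusive). Constant profiles are excluded before
fitting. Genes of rhythmic reactions are reported as the union of their
GPR genes, grouped by subsystem.

## Preprocessing

Fixed order: sample QC → quantile normalization → replicate collapsing and
flag filtering → (for the metabolic view) gene averaging. Row order of the
input never affects the surviving set.

- **Sample QC**: per sample, the median coefficient of variation across
  replicated probes is computed separately for spike-in/control probes and
  for non-control replicated probes. A sample is retained when either set
  achieves median CV below the threshold (default 10%) and excluded only
  when both fail; the disjunctive-exclusion reading is available via
  `require_both_fail=False`. With no replicated probes, QC falls back to
  spike-ins with a warning.
- **Quantile normalization**: every column is mapped onto the across-column
  mean of order statistics; ties within a column receive the mean of the
  target quantiles they span (verified against Bioconductor limma's
  `normalizeQuantiles` on a tie-free fixture). Idempotent to 1e−12;
  single-column input is returned unchanged with a warning.
- **Replicate collapsing**: replicate rows are averaged; a collapsed probe
  counts as flagged in a sample when more than half of its replicates are
  flagged there. Control probes are dropped; probes with missing values
  after collapsing are dropped with a reason code; probes flagged in
  strictly more than 66% of samples are dropped. Every exclusion carries
  exactly one reason code in the QC report.
- **Gene averaging**: one row per gene symbol as the mean of its probes;
  probes without a symbol are excluded from this view only.

## Synthetic data generator

`simulate_expression` draws, per subject, a DLMO clock time U(20.5, 23.5) h
and a DLMO-referenced sampling grid (first biopsy U(2, 5) h after onset,
then 6-hourly, each point jittered U(±0.5) h — the within-subject jitter
magnitude is not reported for the emulated study and is a free parameter).
Rhythmic probes follow mesor + slope·t + A·cos(ω(t − φ)) plus a subject
baseline offset and additive Gaussian noise on the log2 scale (Student-t
noise available for robustness checks). Peak times come from a two-mode
wrapped-normal mixture at −1 h and +9 h relative to DLMO (SD 1.5 h, evening
weight 0.69), mimicking the observed evening/morning bimodality and split.

Defaults: 1000 probes, 2% rhythmic, amplitudes U(0.5, 2) log2, mesor
U(6, 12) log2, trend SD 0.01 log2/h, subject-intercept SD 0.25 log2,
residual SD 0.35 log2. The two noise SDs are not reported by the emulated
study; they were fixed once so that the default synthetic study lands on
the study's stated operating point — about 2% of probes classified
circadian at a permutation FDR below 10% — while remaining typical of
log2-scale microarray residuals. Subject intercepts are drawn
independently per probe × subject (a single shared offset per subject
would correlate all probes' errors and invalidate Monte-Carlo coverage
checks). Identical seed and config give bit-identical output.

`simulate_melatonin` produces a flat baseline (2 pg/ml), a sigmoidal
evening rise to a nocturnal plateau (60 pg/ml) and a morning decline; the
rise midpoint is calibrated by a three-step fixed-point solve so the
continuous curve crosses 25% of its own maximum exactly at the requested
onset, and the rise scale (1.2 h) is wide enough that hourly sampling plus
linear interpolation recovers the onset within 0.1 h. The toy metabolic
catalogue (`chain3`, `chain5`, `branch`, `loop`, `diamond`; 4–6 reactions)
provides flux-consistent networks with GPR rules on every internal
reaction.

What the generator does *not* emulate: probe-level hybridisation
artefacts, dye and batch effects, heteroskedastic intensity-dependent
noise, correlated probes within a gene, and missing data. Passing tests
therefore demonstrate correctness of the estimators and decision rules
under the study's sampling design, not robustness to raw-array artefacts.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: 1000-probe
studies, 500-probe Monte-Carlo batches, 100 permutations, 125-profile
clustering instances, and the toy network catalogue. Variance-ratio search
spans λ ∈ [0, 10⁶] (29-point log grid + 35 golden-section iterations);
constant profiles are detected at SD < 1e−10 and returned degenerate; MILP
tolerances are HiGHS defaults with ε/δ as above; BIC variance is floored at
1e−12. Ties in SOM assignment resolve to the lowest node index; circular
means use the vector mean with the [−12, 12) reporting convention.
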