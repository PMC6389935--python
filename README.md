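# adipoclock

Circadian analysis of serially biopsied human tissue transcriptomes —
mixed-model cosinor rhythm detection on melatonin-aligned, unevenly sampled
multi-subject time series, circular-SOM clustering of rhythmic profiles, and
integration of discretised expression with a stoichiometric metabolic model
to predict rhythmic reaction activity.

## The problem

Serial tissue biopsies from living humans are scarce: a typical
constant-routine study yields ~7 subjects × 5 samples at ~6-hour intervals,
with every subject sampled on their own circadian schedule (times are
referenced to each individual's dim-light melatonin onset, DLMO). Standard
rhythm detectors assume replicated time points on a shared grid and do not
apply. This package implements the appropriate model — for probe `j` and
subject `i`,

    y_ij = M + β t_ij + A·cos(2π (t_ij − φ)/24) + u_i + e_ij,
    u_i ~ N(0, τ²),  e_ij ~ N(0, σ²),

a fixed-period (24 h) cosinor with linear trend, fitted by REML with a
random intercept per subject, linearised through the cos/sin basis so
amplitude `A` and peak time `φ` are derived from the two rhythm
coefficients. A probe is **circadian** when the conditional R² exceeds 0.8
and the 95% amplitude CI excludes zero; the false discovery rate of that
rule is estimated by re-running the whole pipeline on within-subject
permutations of the time labels. The fit is vectorised across probes
(per-subject sufficient statistics + profiled variance ratio), so the
permutation FDR's tens of thousands of refits take seconds.

Downstream, circadian profiles are z-scored, clustered on a ring-topology
self-organising map with BIC-selected cluster count, and labelled
morning/evening by circular-mean peak time relative to DLMO. For metabolic
integration, participant-averaged gene expression at each time point is
discretised into −1/0/1 states by 20th/80th percentiles, mapped to
reactions through GPR rules (AND = min, OR = max), and an iMAT-style
mixed-integer programme finds the steady-state flux maximising agreement;
reactions whose predicted activity profile changes state and fits a 24-h
cosinor with R² ≥ 0.8 are reported rhythmic.

A synthetic-data module generates study-shaped inputs (expression,
melatonin curves, toy flux-consistent networks) with known ground truth, so
every stage has a parameter-recovery test surface without any data
download. See `docs/methods.md` for the full model description and design
choices.

## Worked example

The `analysis/` scripts run the whole pipeline on a synthetic study
(7 subjects × 5 biopsies, 1000 probes, 2% rhythmic, seed 1):

```bash
python analysis/01_simulate.py        # expression, melatonin, toy network
python analysis/02_preprocess.py      # quantile normalization
python analysis/03_align.py           # DLMO + aligned sample times
python analysis/04_detect_rhythms.py  # mixed cosinor + permutation FDR
python analysis/05_cluster.py         # circular SOM + morning/evening
python analysis/06_metabolic.py       # iMAT activity + rhythmic reactions
```

Output of step 04:

```
18 of 1000 probes classified circadian (1.8%)
permutation FDR: 0.088 (1.58 permuted vs 18 observed discoveries)
peak-time histogram mode in [+9, +10) h relative to DLMO
```

i.e. the detector recovers the simulated prevalence (2%) at an FDR below
10%, and the dominant peak time sits in the biological morning, with a
second evening mode near DLMO. Step 06 prints, for the toy
five-reaction chain whose genes oscillate:

```
5 reactions; 5 change state over the cycle; 5 rhythmic at R^2 >= 0.8
  R1: states [1, 1, -1, -1, 1] R^2 = 1.000
genes implicated, by subsystem: {'lower': ['g5'], 'upper': ['g1', 'g2', 'g3', 'g4']}
```

— the chain is predicted active around the genes' expression peak, silent
around the trough, and every reaction's activity profile fits the 24-h
cosinor exactly. All tables land under `results/`.

The library surface mirrors the scripts: `simulate.simulate_expression`,
`preprocess.quantile_normalize`, `align.dlmo_25pct` / `align_samples`,
`rhythm.fit_cosinor_batch` / `permutation_fdr`,
`cluster.select_k_by_bic` / `label_morning_evening`, and
`metabolic.activity_time_course` / `rhythmic_reactions`.

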