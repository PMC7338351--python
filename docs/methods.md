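# Methods

This note documents the models, procedures and design choices behind
`epiboost`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not establish.

## Data model

A cohort couples three components over one ordered subject list: a genotype
matrix of additive minor-allele counts (0/1/2, explicit missing marker), a
list of demographic features (categorical integer codes or continuous
values, each tagged `group1` = familial history, `group2` = oestrogen
metabolism, or `other`), and binary case/control labels. Genotypes arrive
as VCF (REF taken as major, ALT as minor allele; multi-allelic sites
rejected) or as a hand-editable TSV (cells `0/1/2/NA` or allele pairs, with
major/minor orientation inferred from allele counts, alphabetical
tie-break). Column-wise minor-allele frequencies above 0.5 indicate a
mis-declared orientation and are *reported, never silently flipped*.

**Missing data.** Any SNP column containing at least one missing call is
dropped before modelling (`filter_missing_snps`); per-call imputation is
deliberately not provided, matching the column-exclusion preprocessing the
method was designed around. Missing demographic values are handled at
design-matrix assembly: categorical → an explicit extra code
(max observed + 1), continuous → the training-subset median. Continuous
features are min-max scaled to [0, 1]; scalers are fitted on the training
subset only and applied with clipping to validation/test rows (constant
columns map to 0). Categorical codes are passed to the tree learner as
integers without one-hot expansion — tree splits handle small ordinal
codings directly.

## Classifier and sequential tuning

The classifier is an XGBoost binary-logistic ensemble (`tree_method=hist`,
single-threaded, per-tree subsampling without replacement, λ(L2) fixed
at 1). Eight hyperparameters are tunable, with default candidate lists equal
to the published search ranges (trees 50–300, depth {2,4,6,8}, learning rate
{0.001, 0.01, 0.1}, subsample 0.1–1.0, min child weight 0–5, γ 0–9,
α 1e-5–100, positive-class weight {0.56, 1}; 0.56 is the control/case ratio
of the reference cohort). Tuning is *sequential*, not exhaustive: the
(trees, depth, learning-rate) triple is grid-searched jointly under
stratified 5-fold CV, then the remaining five parameters are optimized one
at a time in a fixed order, each stage holding earlier winners fixed. This
costs |triple grid| + Σ later list sizes evaluations (117 for the default
grid) instead of the ~2.9M-point product grid. The selection criterion is
mean cross-validated average precision (log-loss available); exact score
ties break toward the more regularized model (fewer trees, shallower,
slower learning, larger α, larger γ), making tuning deterministic.

Feature ranking trains one ensemble on all candidate features and orders
them by total split-gain importance (configurable to weight/cover); features
never split on score 0 and keep input order, so rankings are deterministic
at a fixed seed.

## Adaptive interaction search

Candidates are the top-M importance-ranked SNPs (M = 18 by default, 15 when
both demographic groups are combined) followed by the demographic group's
features. The search is greedy forward selection in rank order with
strict-improvement acceptance: starting from the top candidate, each
remaining candidate is kept iff refitting the classifier from scratch on
the enlarged set raises validation AP by more than ε (default 0). The
upstream description of this search delegates its mechanics to earlier
work; greedy forward selection with strict improvement is the simplest
procedure consistent with "adaptive iterative search for the best validation
accuracy", and it is auditable: on ≤6 candidates the result is compared
against exhaustive enumeration of all subsets in the test suite. Whether the
original procedure also allowed backward removal of previously accepted
features is not inferable from the source; no backward steps are taken
here. Each examined candidate costs one full refit (no caching), so a
search is bounded by |candidates| fits.

Selection against a held-out validation fold is what admits genuinely
interacting features: a feature uninformative alone but informative jointly
with an already-selected one improves the refit and is kept.

## Resampling geometry

One experiment is K₁ repetitions of stratified K₂-fold CV (default 10 × 5 =
50 splits). Within a repetition, each outer fold serves once as the test
set; one stratified inner fold (1/K₂) of the remaining data is the
validation set and the rest is the training set. At K₂ = 5 this yields the
80:20 outer train/test geometry. This is the only arrangement simultaneously
consistent with "80:20 split", "10 repetitions of 5-fold stratified CV" and
"50 networks". Hyperparameters are tuned once per repetition by default
(configurable to per-fold) — one setting per repetition bounds compute and
matches how tuned settings were reported per iteration. The final per-split
model is refit on train ∪ validation before test scoring (standard practice;
the source is silent). Degenerate cohorts whose outer-training portion is
too small for a stratified inner split fall back to a plain 1/K₂ holdout.

mAP is the arithmetic mean of the per-split test APs with its sample
standard deviation (n−1). Leave-one-out importance refits each split's
network without each selected feature in turn and reports the mean relative
change in test AP over the splits that selected the feature; removing the
only feature of a singleton network is scored as a constant ranking
(AP = prevalence) and flagged.

## Evaluation metrics

The PR curve is traced at the unique prediction scores taken as descending
cut-offs (a subject is predicted positive iff score ≥ cut-off, so ties enter
together — this makes AP invariant under strictly monotone score
transforms), with a (recall 0, precision 1) anchor prepended. Precision at
zero predicted positives is defined as 1; the corresponding AP weight is 0,
so the convention does not affect AP. AP is the recall-increment-weighted
mean of precision. The implementation is verified against an independent
brute-force cut-off loop (≤1e-12 on 1,000 random vectors) and against
scikit-learn's `average_precision_score`.

Association tests mirror the published per-feature tables: chi-squared on
the class × category contingency table for categorical features (Yates
continuity correction on 2×2 tables — with correction the published
oral-contraceptive table gives p ≈ 5.6e-6, matching the printed 5e-6
magnitude; correction is configurable) and a two-sample t-test for
continuous features (Welch by default, pooled available). P-values are
reported unadjusted, as in the source tables. Note the corrected 2×2 test
is conservative under the null (its p-values are not uniform); the test
suite checks uniformity on the t-test path and the conservative direction
on the corrected categorical path.

## Baselines

The PRS is the standard weighted dosage sum `Σⱼ dⱼ ln ORⱼ` with the dosage
counted on the declared effect allele (code flipped when the effect allele
is the major allele). It is evaluated as a raw ranking score — no intercept,
no standardization, no refitting — because it is *derived from* published
effect sizes rather than trained. Weighted SNPs absent from the panel are
skipped with a logged count. Fixed-feature-list models train the boosted
classifier on a frozen feature set under the same split plan (tuning
allowed, no ranking or search).

## Gene-window annotation

A gene maps to a SNP iff the gene span intersects [pos − w, pos + w] with
closed intervals (default w = 5,000 bp, searched both upstream and
downstream; gene strand ignored because the window is defined around the
SNP). A gene starting exactly at pos + w is therefore included; one at
pos + w + 1 is not. Coordinates are 1-based inclusive internally (GFF3
convention); BED input is converted at the boundary. The interval-tree
implementation is validated against a brute-force all-pairs scan on
randomized instances. The exported gene network joins genes whose SNPs were
co-selected in at least one feature network (edge weight = co-selection
count), optionally merged with user-supplied curated edges; no online
database is queried.

## Synthetic cohorts

`generate_cohort` draws genotypes as independent Binomial(2, MAF) counts
(MAF ~ U(0.05, 0.5) by default, with per-SNP overrides for planted causal
variants, and an optional Gaussian-copula block-LD mode), demographics from
a declared schema, and labels from a logistic model whose linear predictor
sums main effects and *mean-centred* product interactions. Centring keeps
interaction terms orthogonal to main effects in expectation, so a planted
pure interaction carries signal that marginal tests miss — the situation
the interaction search exists for. The intercept is calibrated by root
finding on a Monte-Carlo prevalence estimate (n = 20,000, internal seed
derived from the spec seed); the default target prevalence 445/695 ≈ 0.64
mirrors the reference cohort's class balance.

`emulate_reference_margins` instead draws the 9 Group 1 and 11 Group 2
features class-conditionally from the published case/control marginal
distributions (counts and percentages for categorical features, mean/SD
normals for continuous ones) over 445 cases / 250 controls, with
label-independent null genotypes.

**What the generators do not emulate.** Independent features within a class
(no joint dependence structure beyond what the margins force); no linkage
disequilibrium unless the block-LD mode is enabled; Hardy–Weinberg
equilibrium by construction; continuous features are unbounded normals, so
duration-type features can realize negative values; no age matching,
ascertainment, genotyping error or batch structure. Passing benchmarks on
these cohorts therefore demonstrates the machinery's correctness and its
power under idealized conditions, not expected performance on real data.

## Benchmark study conditions

The planted-signal benchmark (`planted_epistasis_spec`) uses n = 700
subjects, 500 null SNPs, three causal SNPs at MAF 0.3 with per-allele main
log-odds ln 1.8 and pairwise epistatic terms ln 2.2 on all three pairs, and
two informative demographic features (binary at ln 2.2, continuous at 0.8
per SD), at the reference prevalence. The pipeline runs at K₁ = 3, K₂ = 3
with M = 18 and fixed hyperparameters (100 trees, depth 4, learning rate
0.1, subsample 0.8, min child weight 1 — a point inside the published
ranges; full sequential tuning at this scale is exercised separately on
small grids). The null-calibration benchmark uses 5 cohorts of n = 400 with
all effects zero.

A property of this benchmark worth knowing: because ranking screens SNPs by
*marginal* ensemble importance, an epistatic SNP whose realized marginal
association happens to be near zero in a given draw may not reach the
top-M candidate list at this sample size, and then cannot be selected. At
the benchmark's fixed seed all five planted features exceed the null
features' 95th-percentile selection count; across arbitrary seeds the
weakest SNP occasionally drops out while the other planted features remain
clearly separated. This mirrors the method's real limitation: it discovers
interactions *among features that carry at least some marginal signal*.

## Numerical and degenerate-input conventions

Deterministic outputs at fixed seeds throughout (single-threaded XGBoost,
seeded splitters, rank-order scan sequences, stable sorts). Tied CV scores
and tied importance scores break deterministically (regularization
preference; input order). Constant score vectors produce a single PR
cut-off with precision = prevalence. `mean_ap` of a single value reports
SD 0. Empty genotype panels after missing-data filtering are a warning, not
an error. All randomness flows from user-visible integer seeds; internal
seeds are derived via `SeedSequence` and kept below 2³¹.

## Known limitations

Greedy forward selection has no optimality guarantee (the exhaustive-oracle
gap is measured, not bounded); hyperparameters tuned once per repetition
can be mildly stale for later folds; the simulator's idealizations above;
LOO importance is conditional on the selected networks and inherits their
sampling variability; and headline mAP values on any *particular* private
cohort are not reproducible from this package — all reported numbers here
come from synthetic or published-table inputs.
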