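# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make every result
deterministic.

## Data model and conventions

Quantification tables are read in the MaxQuant dialect: per-sample linear
intensities (`Intensity <sample>` / `LFQ intensity <sample>`), per-sample
spectral counts (`MS/MS Count <sample>`), a `;`-separated protein-group
assignment and a `+`-marked decoy column. A zero or blank intensity means
*not observed* and becomes missing (NaN) on read; all downstream
missing-data statistics depend on this reading, and observed intensities are
strictly positive thereafter. A peptide is *unique* iff it maps to exactly
one protein group. Every column name is overridable through the dialect
dataclasses.

The design table assigns each sample one of three classes — whole-tissue
lysate control (technical replication), microdissected control (biological
replication of one tissue), experimental — and, for experimental samples, a
biological group label. All two-group statistics take the group order from
the design file; effects and mean differences are reported as group 2 −
group 1.

## Preprocessing

Log2 transformation followed by per-sample median centering (median of the
*observed* values only; idempotent). Centering before filtering is the
default order; both steps are exposed separately so the order can be
changed. Peptide filters, applied in this order with a per-criterion report:
uniqueness, decoy removal, and an observation floor of ⌈f·n_ref⌉ over the
reference samples (the experimental cohort by default). f = 0.5 reproduces
the 5-of-9 rule of a 5-vs-4 cohort; f = 0.3 is the documented choice for
cohorts above ~60 samples; f = 0 disables the criterion.

## LFQ rollup (pairwise median ratios)

For one protein, samples are nodes and each pair sharing at least
`min_shared` observed member peptides (default 1 — with 4–5 samples per
group a higher floor discards too much) contributes an edge valued at the
median peptide log2 ratio. Within each connected component the per-sample
abundances are the least-squares solution of x_a − x_b = r(a,b) over edges;
the component's free constant is fixed so the mean of the solved values
equals the mean of the per-sample median observed peptide log2 intensities,
keeping output on the absolute input scale. Samples with no observed member
peptide stay missing; an isolated sample with observations gets its median
peptide intensity. Only peptides unique to the protein group enter (razor
peptides would also qualify when a razor annotation column exists; the
synthetic tables carry none). Exact consequences, all tested: antisymmetric
edges; doubling one sample's intensities shifts exactly that sample's solved
value by +1; consistent ratios are reproduced exactly.

This rollup exists for peptide-only inputs and synthetic data; when a
protein-level LFQ table is supplied it is used as-is.

## Abundance branch

*Model.* Per protein, the ≤ `top_k` (default 10) member peptides with the
largest median observed log2 intensity (ties broken lexicographically by
peptide key) enter a fixed-effects fit on observed cells:
intercept + group + peptide offsets. With one measurement per sample and
peptide, a sample-level random effect is not separable from the residual, so
none is fitted; run-level bias is absorbed by the upstream per-sample median
centering. Abundance weighting beyond the top-k cut is not applied.

*Fitting.* Iteratively reweighted least squares with Huber weights, tuning
constant 1.345, scale = MAD of residuals / Φ⁻¹(0.75), at most 50 iterations,
convergence when no coefficient moves by more than 1e−8. With weighting
disabled the fit is ordinary least squares, and for a single peptide it
reduces exactly to the pooled two-sample t-test (tested against the closed
form). Peptide dummy columns collinear with the columns admitted so far are
dropped (greedy admission: intercept, group, then dummies); if the group
effect itself is inestimable — e.g. all observations in one group — the
protein is reported unconverged with a missing p-value, which is precisely
the case the presence branch exists for.

*Inference.* Wald t on the group coefficient with n_obs − n_params degrees
of freedom, σ̂² = Σ w r²/(n−p). Zero residual variance resolves to p = 1
when the effect is 0 and p → 0 otherwise. Across proteins, Benjamini-
Hochberg step-up adjustment (missing p-values excluded from m); adjusted
p < 0.05 defines the pre-selection.

*Refinement.* Welch two-sample t (unequal variances — the design is
unbalanced and homogeneity is not assumed) on per-sample protein log2
abundances of pre-selected proteins, requiring ≥ 2 observations per group.
The permutation FDR is SAM-style with s0 = 0: for each protein i,
q_i = (mean over permutations of #{|t_perm| ≥ |t_i|}) / #{|t_obs| ≥ |t_i|},
computed over the tested set, then made monotone non-increasing in |t|
(suffix minimum, the q-value convention) and capped at 1. When the number of
distinct group-label splits is at most `n_perm` (default 250) all splits are
enumerated, excluding the identity (and its complement for equal group
sizes); the 5-vs-4 design has 126 splits, so 125 permutations are enumerated
and q is deterministic. Otherwise splits are drawn uniformly from a seeded
generator. Selected = t-test p < 0.05 and q ≤ 0.05.

## Presence branch

Decoy protein groups are removed first. Per protein the 2×2 table

    [[ SpC_A, SpC_B ], [ Tot_A − SpC_A, Tot_B − SpC_B ]]

compares the protein's summed spectral counts per group against the rest of
each group's count library (an alternative `detection` mode tabulates
samples with/without detection per group). The two-sided Fisher exact
p-value is computed by hypergeometric enumeration — pmf via log binomial
coefficients, summing all outcomes with pmf ≤ pmf(observed)·(1+1e−7), the
customary tie tolerance — and agrees with an exact-rational oracle to below
1e−12 over every table of total size ≤ 30 (tested exhaustively). Proteins
with no counts in either group get p = 1 and an invalid-test flag.

Fisher hits (p < 0.05) are consolidated on imputed abundances: per sample
with observed mean m and standard deviation d over the full protein matrix,
each missing log2 cell is drawn from N(m − 1.8·d, (0.3·d)²). The defaults
are the established downshifted-normal parameters for intensity data whose
missingness is detection-limit driven; both are exposed. Draws are made in
row-major cell order from a seeded generator, so the completion is
reproducible, and observed cells are never modified. The imputation is done
once; group labels are then permuted on the completed matrix (re-imputing
per permutation would break the deterministic enumeration and changes little
when the imputed fraction is modest). The same Welch + permutation-FDR
machinery then defines the consolidated set.

The overlap report intersects the two branches' selected sets and flags
direction concordance: a positive abundance-branch mean difference
(group 2 − group 1) is concordant with a presence-branch count excess in
group 2.

## Clustering

Selected proteins' log2 abundances are median-centred per row, then samples
and proteins are clustered with Euclidean distance and complete linkage. On
incomplete vectors the distance is computed over the positions observed in
both items and rescaled by √(K/|O|) to the full vector length K (the
Cluster 3.0 convention; Euclidean distance on incomplete vectors is
otherwise undefined), and a pair with no shared position is an error —
matrices containing presence/absence proteins should be imputed first, as
the pipeline does. Merging is deterministic: among minimum-distance pairs
the lexicographically smallest (older, younger) node-id pair merges first;
in the leaf ordering the subtree containing the lower original index goes
left. Any tie resolution is biologically equivalent; determinism is a
testing requirement, and the merge sequence matches a recompute-from-scratch
oracle on every tested instance with up to 6 items. The `.gtr`/`.atr` score
column is 1 − h/h_max (similarity scale). The 2-cut purity of the sample
tree — the fraction of labelled samples in their cluster's majority group —
quantifies group separation.

## QC battery

"Identified in a sample" means a non-missing intensity in that sample's
column — the only reading computable from quantification tables alone.
Counts are summarised per class as mean, sample sd (n−1) and CV% =
100·sd/mean. Pearson correlations are computed on log2 values over
pairwise-complete positions (pairs with < 3 shared positions are excluded
with a warning); log2 is the conventional scale for abundance correlations
and a linear mode is available by passing untransformed values.
Reproducibility tiers classify each feature observed at least once in a
class by its observation fraction f: low f ≤ 1/3, high f ≥ 2/3, medium
between — boundaries chosen so the integer percent bands (≤33, 34–66, ≥67)
are reproduced for class sizes such as 12, 5 and 9. Per-feature CVs are
computed on *linear* intensities over features observed at least twice in
the class. Set overlaps report shared/exclusive counts and percentages of
the union.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, on
the log2 scale: peptide intensity = protein baseline N(25, 2) + peptide
ionization offset N(0, 1.5) + group effect (differential proteins only,
second group, sign random) + sample offset N(0, 0.2) + noise N(0, 0.4).
Defaults mirror a small two-group tissue cohort: 5 vs 4 samples, 500
proteins, 1 + Poisson(6) peptides per protein, 10 % differential at ±1 log2
unit. Detection is missing-not-at-random: a cell is observed with
probability logistic(slope·(x − midpoint)), slope 0.7 and midpoint 21 by
default (≈ 90 % average detection, dropping steeply for low-abundance
peptides); midpoint −∞ gives complete detection for noise-only experiments.
Observed cells carry spectral counts max(1, Poisson(2·2^((x−25)/4))),
coupling counts to intensity. Decoy peptides (2 %) and shared two-parent
peptides (5 %) exercise the filters; control classes reuse the no-effect
expectation with noise scaled ×0.5 (technical) and ×1.5 (microdissected
biological). The protein table is produced by the package's own rollup.

What it does not emulate: retention-time or mass-error structure, peptide
count correlations with protein size beyond Poisson, batch effects,
correlated proteins, razor-peptide assignment, or realistic decoy score
distributions. Passing the simulation suites therefore demonstrates the
statistics behave as designed under the assumed model — not that the model
captures every property of real tissue data.

Evaluation against ground truth reports TP/FP/TN/FN, empirical FDR
(FP/(TP+FP), 0 for an empty selection) and power (TP/(TP+FN)).

## Problem sizes and determinism

The simulation suites use 500-protein cohorts and 20 seeds for the null
(type-I) and power/FDR properties, 300-protein cohorts and 3 seeds for the
dropout-complementarity property; these sizes give stable averages while
keeping the full suite to a few minutes on one CPU. All randomness flows
from explicit integer seeds (numpy `default_rng`); enumeration replaces
sampling wherever the split count allows, and identical configuration plus
inputs produce byte-identical output bundles, including the run manifest.

## Known limitations

* Two-group contrasts only; the peptide-level model is written for the
  two-group design and multi-group analysis is an extension point.
* The permutation FDR is estimated over the pre-selected (enriched) set, as
  the refinement stage of this pipeline defines it; on very small candidate
  sets the estimate is noisy, and empirical FDR of the full cascade on tiny
  cohorts (tens of proteins) can exceed the nominal level even though it is
  controlled at the 500-protein scale (tested).
* No moderated/empirical-Bayes variance shrinkage, zero-inflated count
  models, or intensity-dependent (loess/quantile) normalization.
* The rollup does not implement delayed normalization; against MaxQuant's
  LFQ columns it can differ systematically for sparsely observed proteins.
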