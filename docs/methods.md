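# Methods

## Study design emulated by the simulator

The pipeline targets a three-arm perioperative design in a tumor-bearing
mouse model: no treatment (N), anesthesia only (A), and anesthesia plus a
futile-laparotomy-style surgical wound (AW), with tumors profiled at baseline
and at three post-intervention timepoints (T1 = 1 day, T2 = 1 week,
T3 = 2 weeks). That yields 10 subgroups. The synthetic generator defaults to
the unequal subgroup sizes of the emulated study — Base 5, T1 N/A/AW = 3/2/4,
T2 = 5/9/6, T3 = 5/6/3 — precisely because unequal, partly tiny groups are
the stress case for the downstream statistics.

## Count model

Counts are negative binomial, the standard over-dispersed noise model for
bulk RNA-seq: gene g in sample s has mean μ_g·m_{g,s} and variance
μ + φμ² with a shared dispersion φ (default 0.1, a typical bulk value).
Baseline means μ_g are log-normal (ln-scale location 5.0, scale 1.5, i.e.
median ≈ 150 counts with a realistic dynamic range); gene lengths are uniform
on [500, 10000] bp. Three planted programs per timepoint set the multiplier
m_{g,s}:

* **progression** genes (default 150) shift in all three arms vs baseline —
  tumor growth common to every animal;
* **anesthesia** genes (default 100) shift in A and AW;
* **wound** genes (default 200) shift only in AW, half up and half down at
  ±`effect_log2fc` (default 2).

Effects multiply the NB mean, so planted log2 fold changes are exact on the
mean scale. Classes are disjoint within a timepoint and drawn independently
across timepoints. Only the wound program should survive the Venn exclusion;
the other two exist to be excluded.

The tumor-weight generator draws normal weights per timepoint × arm. Defaults
(T1 means 1.0/1.1/1.6 g at sd 0.3; T2 1.4/1.5/1.8 at 0.5; T3 1.8/1.9/2.2 at
0.6, n = 10 per arm) encode the qualitative pattern the pipeline is meant to
detect: a clear wounding effect early, the same trend with wider spread
later.

## Normalization

TPM divides counts by gene length in kb and rescales each sample to 10⁶.
Upper-quartile scaling then divides each sample by the 75th percentile of its
*nonzero* TPM values (linear-interpolation percentile) and multiplies the
matrix by the geometric mean of those percentiles, keeping the output on a
TPM-like scale while removing residual per-sample composition shifts. The
nonzero restriction is deliberate: with many silent genes the all-gene upper
quartile can sit at or near zero. Testing happens on log2(TPM-UQ + 1); the
pseudocount of 1 is the conventional choice that maps zero expression to
zero.

## Differential expression

Each post-intervention subgroup is contrasted against baseline with a
two-sided Welch *t*-test per gene on the log2 values. Welch rather than
pooled Student because the subgroup sizes are very unequal and there is no
reason to assume equal variances; for balanced equal-variance data the two
coincide. log2FC is the difference of group means of log2 expression (a
geometric-mean ratio); a `fc_mode="log-of-means"` switch gives the
arithmetic-scale alternative. Genes with zero variance in both groups get
p = 1. DEG calling uses the two printed tiers with inclusive boundaries:
|log2FC| ≥ 0.58 (1.5-fold) with raw p ≤ 0.05, and a Top-DEG tier at
|log2FC| ≥ 4 (16-fold) with p ≤ 0.01.

Storey *q*-values are computed and reported but not used for calling: at
these group sizes FDR adjustment is expected to retain nothing, and the
calls are explicitly exploratory. π̂₀ is estimated on the λ grid
0.05…0.95 (step 0.05) with a least-squares cubic evaluated at the largest λ,
clipped to (0, 1]; below 100 p-values the grid estimate is unstable and π̂₀
is fixed at 1, the conservative limit. q_i = min over p_j ≥ p_i of
π̂₀·m·p_j/rank(p_j), with average ranks on ties so equal p always yields
equal q.

Tumor burden is compared with the pooled-variance Student *t* (AW vs N, AW vs
A, A vs N per timepoint). Identical constant groups give p = 1; zero pooled
variance with unequal means is degenerate and raises rather than inventing a
p-value.

## Wound-signature extraction

WsDEG(tp) = DEG(AW) \ (DEG(N) ∪ DEG(A)), computed on gene identity: a gene
is excluded even if it moves in the opposite direction in N or A (the count
of such discordant exclusions is recorded in provenance, and a
direction-aware mode is available). Within each direction, genes are ordered
by |log2FC| descending with gene-id tie-breaks, so truncating to the
connectivity tag-set cap (default 150 per direction, the usual tag-list scale
for L1000 queries) is deterministic. The bookkeeping identity
n_wsdeg + n_excluded_overlap = n_deg(AW) is asserted on every run.

Descriptive exports are data-only: row z-scores use the sample (n−1)
standard deviation with zero-variance rows emitted as flagged zeros; sample
similarity is all-pairs Pearson r on the log matrix with classical
(Torgerson) MDS on 1 − r, axis signs fixed so the largest-magnitude loading
is positive.

## Connectivity and prioritization

The KS enrichment statistic is the classic unweighted running-sum deviation
(formulas in the README). Unweighted was chosen deliberately: it admits an
exact brute-force oracle, and the whole statistic is verified against that
oracle for *every* tag subset of every list of size ≤ 8. Reference columns
are ranked by z descending with gene-id tie-breaks; the combined score is
(ES_up − ES_down)/2 when the signs differ and 0 otherwise, with no
cross-instance rescaling. The statistic's range is [−1, 1): −1 is attained
exactly when the whole tag set sits at the bottom of the ranking. Query
symbols are matched to the reference case-insensitively, with an optional
two-column ortholog map for murine-to-human translation; unmatched tags are
dropped with logged counts, and a signature with no match in either
direction is flagged and excluded from ranking.

Prioritization counts each perturbagen's signatures inside the K
most-negative scores (ties broken by signature id; only negative scores are
eligible, so the top set can be smaller than K). The 2×2 Fisher table takes
its margins over all scored signatures, and the test is one-sided for
over-representation. Filters follow the printed boundaries exactly: freq ≤ 3
out, p ≥ 0.05 out. K defaults to 1000 (LINCS scale) and is scaled to 100 in
the desk-scale analyses against a 2000-signature reference, keeping K/N at
5%. Per-query top-K is used rather than a pooled top-K across timepoints; a
pooled mode is left to the caller by concatenating score tables.

An optional permutation null draws random tag sets of the query's sizes and
reports the negative-tail p = (1 + #{null ≤ observed})/(n_perm + 1).

## Enrichment

ORA uses the one-sided hypergeometric tail with the universe fixed to the
genes tested at the DEG stage — the defensible background for an expression
study, since un-assayed genes had no chance to enter the query. Significance
requires overlap > 3 and p < 0.01; BH q-values are reported. Redundant terms
are grouped by Cohen's kappa of membership-indicator vectors over the
universe, single-linkage at κ > 0.3 — implemented as connected components of
the κ-threshold graph, which is exactly the single-linkage cut and is
order-independent. A query-restricted kappa mode (membership limited to each
term's overlap with the query, closer to how enrichment portals behave) is
available; the universe mode is default because it does not depend on the
query. Cluster representatives are the lowest-p members, ties by term id.

## Problem sizes and operating characteristics

The bundled analyses run at 5000 genes with the study subgroup sizes and a
978 × 2000 reference (200 compounds × 10 signatures, 5 planted reversers at
loading 2.0, K = 100); the whole chain completes in seconds. Under these
conditions the measured behavior (recomputed by `scripts/acceptance.py` and
the test suite, not quoted from elsewhere) is: null type-I rate of the DEG
caller ≈ 0.03 at the nominal thresholds; wound-gene recovery sensitivity
≈ 0.85–0.95 per timepoint; all planted reversers pass the filters and occupy
the top ranks; the planted gene set passes the ORA filters at T1.

## What the synthetic data does and does not show

The generator captures unequal group sizes, NB over-dispersion, planted
multiplicative effects, a many-signatures-per-compound reference and
tag-based reversal structure. It does **not** model library-size
confounding, batch effects, gene–gene correlation, length-dependent counting
bias, dose–response structure within a compound, or murine/human ortholog
loss. Passing tests therefore demonstrate correctness of the statistics and
plumbing under a faithful null/effect model — not that real wound biology
will be recovered at these sensitivities. Timepoint signatures extracted
from the same experiment are correlated (all contrasts share the baseline
samples, and planted classes can overlap across timepoints by chance), so a
compound that reverses one stage may legitimately score negative at a
neighboring stage; analysis script 06 measures this carryover rather than
assuming stage independence.

## Known limitations

* The Storey cubic-smoother convention (polynomial fit over the λ grid) is
  one of several in circulation; estimates on small m fall back to π̂₀ = 1.
* GCTX (HDF5) references are not supported; convert to GCT 1.3 first.
* No cell-line stratification or replicate collapsing of reference
  signatures; every signature column is scored independently.
* The emulated design's published sample accounting is internally
  inconsistent (a stated total of 32 samples vs per-subgroup sizes summing
  to 48); the simulator treats subgroup sizes as configuration and defaults
  to the per-subgroup values.
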