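# Statistical methods

This note documents the statistical conventions implemented in `leafendo`.
Defaults follow widely used practice in plant-microbiome community ecology
for two-condition (healthy HL vs non-healthy NL) leaf-endophyte studies.

## Data model and filtering

Count tables are taxa x samples integer matrices with unique taxon and
sample identifiers and no empty samples; violations raise
`CountTableFormatError` naming the offender. TSV and dense BIOM-JSON
round-trips preserve identifiers, order and counts exactly.

The prevalence prefilter keeps a taxon when it reaches ≥ `min_reads` reads
in ≥ `min_samples` samples; the defaults are 5 samples / 2 reads for
bacteria and 3 / 2 for fungi. The filter is idempotent and errors rather
than silently returning an empty table.

## Diversity and ordination

Alpha diversity is observed richness and the natural-log Shannon index
per sample, contrasted between groups by Welch's *t* or the Wilcoxon
rank-sum test. The Wilcoxon test uses mid-ranks and, whenever both groups
have ≤ 20 samples, an exact tie-aware enumeration of the rank-sum null
(a subset-sum dynamic program over doubled mid-ranks); larger samples use
the normal approximation.

Rarefaction curves are exact hypergeometric expectations,
`E[S(d)] = S − Σᵢ C(T−nᵢ, d)/C(T, d)`, which are deterministic and
monotone in depth; Monte-Carlo subsampling is available as an option.

Beta diversity uses Bray-Curtis dissimilarities. NMDS minimises Kruskal
stress-1 by SMACOF with isotonic regression from several random starts
plus one start at the classical (metric) MDS configuration, returning the
lowest-stress centred solution. PERMANOVA is the one-way distance-based
pseudo-F (`SS_total` from all squared pairwise distances / N; `SS_within`
from within-group squared distances / group size) with a label-permutation
p-value under the add-one convention.

## Health-sensitive ASVs

Two complementary screens are intersected.

**Differential abundance.** Per taxon, a negative-binomial model with log
link and effective-library offsets (library size x TMM factor) is fitted
under a common-mean null and a one-mean-per-group alternative; the
likelihood ratio is referred to χ²(1) and p-values are
Benjamini-Hochberg adjusted. Dispersions are per-taxon Pearson-moment
estimates — solving `Σ (y−μ)²/(μ + φμ²) = n − p` by bisection, with means
refitted under the current dispersion — taken around the *null* fit so
that chance group splits of heavy-tailed taxa inflate the dispersion
rather than the test statistic, then shrunk toward an abundance-binned
trend with 10 pseudo-samples of prior weight (empirical-Bayes moderation
in the edgeR spirit). TMM normalisation follows the standard
construction: reference library by the upper-quartile criterion, M/A
double trimming (30% / 5%), precision-weighted averaging, factors
rescaled to geometric mean 1.

**Indicator species analysis.** The group-size-corrected IndVal
(`√(specificity × fidelity)`) with a label-permutation test of the
max-over-groups statistic (add-one p-values).

A taxon is a health-sensitive ASV (hsASV) when it passes both screens
(default q < 0.05 and permutation p < 0.05). The enriched group is taken
from the indicator side and cross-checked against the fold-change sign;
disagreements are flagged discordant but remain hsASVs.

## Co-occurrence networks

Pairwise Spearman correlations (mid-rank Pearson-on-ranks with the
*t*-approximation for p-values) are computed on CPM profiles, restricted
to within-kingdom pairs for the meta network. Edges are positive
correlations passing `r > r_min` and `p < p_max`: the meta network uses
r > 0.6, p < 0.001; per-health-group networks use r > 0.8 (bacteria) or
r > 0.7 (fungi) with p < 0.01 after prevalence prefiltering of the group's
samples. Modules come from greedy (Clauset-Newman-Moore) modularity
maximisation with deterministic node ordering. Topology is summarised by
node/edge counts, mean normalised betweenness centrality (Brandes), and
degree assortativity (reported as undefined for degree-regular graphs).

## Assembly processes

**Levins' niche breadth** `B_j = 1 / Σᵢ P²ᵢⱼ`, with `P_ij` the proportion
of taxon *j*'s reads in community *i*: a perfect generalist over N
communities has B = N, a single-site specialist B = 1. Community breadth
averages B over the taxa present in a sample and is contrasted between
groups with the Wilcoxon test.

**Sloan's neutral community model** relates occurrence frequency to mean
relative abundance, `freq(p) = 1 − BetaCDF(d; Nmp, Nm(1−p))`, with `N`
the mean library size and detection limit `d = 1/N`. The migration rate
`m` is fitted by bounded least squares over log m with a multi-start
grid; R² is reported against the frequency variance. A 95% Wilson
binomial envelope around the fitted curve partitions taxa into
above/within/below the neutral expectation, and a bootstrap over taxa
yields the CI for m. The fit assumes a single community size; strongly
heterogeneous sequencing depths bias `m̂` and rarefaction or fixed-depth
designs are recommended when m itself is of interest.

**C-score / null model.** The checkerboard score is the mean of
`(Rᵢ−Sᵢⱼ)(Rⱼ−Sᵢⱼ)` over unordered taxon pairs of the presence/absence
matrix. The null distribution comes from a sequential-swap Markov chain
that flips random 2x2 checkerboard submatrices (row and column sums are
invariant), recording the score after a burn-in. The standardised effect
size SES = (observed − null mean)/null SD reads as segregation when
SES > 2 and aggregation when SES < −2; degenerate chains (zero null SD)
report SES as undefined rather than a number.

## Pipeline determinism

A single root seed is expanded into per-stage sub-seeds by hashing
`"<seed>:<stage>"` with SHA-256 and reducing below 2³¹, so any stage can
be re-run in isolation reproducibly. The configuration hash excludes the
output directory (a location, not an analytic parameter), and wall-clock
timings live in a separate artifact, which makes complete re-runs
byte-identical. Every artifact carries a `# leafendo <version> | config
<hash> | seed <seed>` provenance header.

## Synthetic benchmark

The generator draws a lognormal metacommunity, then samples each local
community by Sloan-style neutral migration at rate m followed by
multinomial read sampling at the requested depth. Group structure is
injected explicitly: a chosen number of differential taxa (symmetric
up/down fold changes in NL, drawn from the upper half of metacommunity
abundance so the effect is detectable), correlated taxon blocks (shared
lognormal factors), and optional deterministic selection on NL split into
a fixed per-taxon fitness component and per-sample fitness noise — the
latter is what degrades the neutral fit and narrows niche breadth in the
selected group. Ground truth (differential taxa with direction, block
membership, true m) is returned alongside the table, making the generator
usable as a benchmark for recovery and calibration studies.
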