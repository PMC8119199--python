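# Methods

## Bulk differential expression

Expression enters on an nRPKM-like normalized scale (non-negative reads
per kilobase of gene model per million reads). Values are transformed as
log2(nRPKM + c) with pseudocount c = 1e-4 by default; the pseudocount is
configurable because the convention only pins it to "small relative to 1".

Each contrast is a per-gene two-sample comparison on the log2 scale:
log2 fold change = mean(treated) − mean(control), and a pooled-variance t
statistic. With `moderation="empirical_bayes"` (the default) the pooled
variances s²_g (d_g = n₁ + n₂ − 2 df) are shrunk toward a prior:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),   t uses d₀ + d_g df.

(d₀, s₀²) are method-of-moments estimates from the log sample variances
under a scaled chi-square model, using the digamma/trigamma moment
equations (the trigamma equation is inverted by Newton iteration). When
the observed spread of log variances does not exceed pure sampling noise,
d₀ = ∞ and every gene uses s₀² with normal reference quantiles. This
captures the variance-moderation idea with closed, testable forms; it is
not a re-implementation of any specific linear-model package, and with
growing replication the moderated and plain t agree (the shrinkage weight
is d₀/(d₀ + d_g); note that on data whose true variances are nearly equal,
d₀ itself grows with n, so the two p-value sets converge without ever
being within ~1e-3 at a few hundred df — the agreement tolerance in the
tests reflects that).

Degenerate genes follow a continuity convention: zero variance with zero
difference → p = 1; zero variance with nonzero difference → p = 0 plus a
warning (only reachable with moderation off, since shrinkage keeps s̃ > 0).

Multiple-testing adjustment is Benjamini–Hochberg (the default, and what
the DE step of a genome-wide screen ordinarily reports) or Bonferroni.
`adjust_pvalues` delegates to statsmodels and is oracle-tested against a
brute-force step-up enumeration.

## Consensus signatures

`filter_de` keeps genes with fold change ≥ fc_min (default 2, i.e.
|log2 FC| ≥ 1 in the requested direction), adjusted P ≤ 0.05 and mean log2
expression ≥ 1.0 over all samples of the contrast ("mean over all samples"
is a choice; averaging over controls only would also be defensible).
`intersect_signatures` takes genes present in ≥ min_support of the
contributing signatures, defaulting to *all* — the strict common core.
Output order is support count then lexical, so derived signatures diff
cleanly. `overlap_counts` reports the exact inclusion–exclusion partition
for 2–4 signatures (beyond 4 a Venn report is unreadable).

Cross-contrast agreement is Spearman's ρ of log2 fold changes with a 95%
CI from Fisher's z: tanh(atanh ρ ± 1.96/√(n−3)). The gene universe
defaults to the union of genes passing the filter thresholds (either
direction) in at least one of the two contrasts; `all_genes` is available
because the universe behind published four-way ρ values of this kind is
usually not stated. |ρ| within 1e-15 of 1 yields the degenerate CI [ρ, ρ].

## Single-cell scoring

QC keeps cells with ≥ 500 detected features (≥ 1 UMI) and ≤ 5%
mitochondrial counts (gene ids with prefix `MT-`); both thresholds are
inclusive, and a matrix with no mito-prefixed genes passes that criterion
vacuously with a warning. Normalization is CP10K log1p: value =
ln(1 + count/total × 10⁴). The scale factor 10⁴ and the natural log are
the standard constants of "the log normalization method"; both are
configurable since only the method name, not its constants, is ever
reported.

The module score of a signature is mean(signature genes) − mean(control
genes) per cell, on log-normalized values. The default control set is one
seeded uniform draw of 100 detected non-signature genes shared by all
cells — the plain reading of "100 random control genes". A `binned` mode
draws controls matched on mean expression (25 equal-size bins, n_control
per signature gene, with replacement across genes), the common refinement
when gene-abundance heterogeneity would otherwise bias a uniform draw.
The draw, its seed and any signature genes missing from the matrix are
returned with the scores.

Cluster-level enrichment is a one-sided Wilcoxon rank-sum of each
cluster's scores against all other cells (alternative "greater"),
BH-corrected across clusters; all-tied comparisons get p = 1, clusters
with < 3 cells get p = NaN with a warning. With ≤ 10 cells on both sides
the exact permutation null over group assignments is enumerated (valid
under ties); otherwise a tie-corrected normal approximation without
continuity correction is used, matching the convention of the common
single-cell toolkits.

Cell-cycle phase: S and G2M marker lists (supplied by the user as GMT —
no marker list ships with the package) are scored as modules; a cell is S
if its S score is the strict maximum and positive, G2M analogously,
otherwise G1. Ties or two non-positive scores fall back to G1, the
"neither program active" state.

## Markers

`rank_markers` tests each gene in one cluster against all other cells
(two-sided rank-sum as above). avg_logfc is the difference of mean
log-normalized expression, i.e. natural-log units — the log base behind
the conventional 0.8 threshold is ambiguous in the wild, so the definition
is fixed and documented here rather than inherited. Detection fractions
pct_in/pct_out come from raw counts (≥ 1 UMI). The filter keeps
avg_logfc ≥ 0.8 AND (pct_in ≥ 0.5 OR pct_out ≤ 0.10); the disjunction is
the stated "either…or" rule, a conjunctive variant is available by flag.
`markers_to_signature` keeps genes with natural-scale fold change > 1.5
(avg_logfc > ln 1.5), ordered by descending avg_logfc. Ambient-RNA-driven
exclusions are a manual curation step; the functions accept pre-filtered
record tables, so such exclusions are applied by the caller.

## Correlates and overlap enrichment

`top_correlates` ranks genes by Spearman (default) or Pearson correlation
with an anchor gene across samples; the anchor is excluded, ties break
lexically, constant genes sort last with ρ = NaN, and a constant anchor is
an error. `enrich_hypergeometric` computes p = P(X ≥ k) for
X ~ Hypergeom(N, K, n) per set, BH q across the collection, and the
"k:K" overlap label. The default universe is the expression matrix's genes
restricted to the collection's union — hosted overlap tools rarely state
their universe, so it is explicit and configurable here.

## Synthetic data

Counts are Gamma-Poisson: count ~ Poisson(Gamma(1/α, μα)), Var = μ + αμ²,
with one dispersion α per simulation (default 0.1, a typical bulk/UMI
overdispersion magnitude). No generative model is implied by the analyses
themselves; this is the minimal standard choice.

**Bulk** (`simulate_bulk`): gene baselines are lognormal (ln-mean ln 500,
ln-sd 1.0) and shared across contrasts; each of the default four contrasts
has n = 4 treated and 4 control samples; treated means are multiplied by
fold 4 on that contrast's induced set — 200 shared planted genes plus 50
contrast-private ones by default. Counts are normalized per sample to
reads-per-million with a unit gene-model length (length cancels in
two-group contrasts, so all genes share one length; this keeps the truth
interpretable while giving realistic normalized magnitudes).

**Single cell** (`simulate_sc`): 3,000 cells in 6 clusters by default,
lognormal depths (median ≈ 5,000 UMIs, ln-sd 0.25). Every cluster carries
a mildly jittered copy (ln-sd 0.1) of a common gene profile; the planted
senescent cluster multiplies its 100 signature genes by 4, 20
proliferation genes by 0.25 and 20 SASP genes by 4, and draws phase G1
with probability 0.9 (G1 arrest); other clusters draw G1/S/G2M at
0.5/0.25/0.25. Phase marker genes (40 S, 50 G2M) sit at 0.25× baseline
and are boosted 8× in their active phase, so phase module scores are
negative outside the active phase — which is what makes a score-sign
phase rule meaningful. Mitochondrial genes (`MT-` prefix, 10 genes) carry
3% of depth in expectation. Gene-level baseline heterogeneity is modest
(ln-sd 0.1) by design: a uniformly drawn control set is then an unbiased
background for any signature (null module scores center within ±0.05),
the operating regime the score's "> 0 means enrichment" reading assumes;
for data with stronger abundance heterogeneity the binned control mode is
the appropriate tool, and the generator deliberately does not emulate
that regime.

What the generators do **not** emulate: gene-length variation, doublets,
ambient RNA, batch/subject effects (subject ids are round-robin labels
only), cluster-specific detection dropout beyond what NB sampling gives,
and correlated gene programs outside the planted modules. Recovery
results on this synthetic data therefore demonstrate the pipeline's
correctness and calibration under its own assumptions, not performance on
real tissue.

## Problem sizes used in tests and the acceptance script

Oracle checks run on instances of ≤ 20 observations where brute-force
enumeration (all rank splits, binomial-coefficient tails, step-up scans)
is exact. Calibration and recovery runs use the generators' defaults:
50 null-bulk seeds (200 genes), 15–20 consensus seeds (5,000 genes),
50–100 single-cell seeds (3,000 cells × 2,000 genes), 12–20 marker/phase
seeds — sizes at which the planted effects are comfortably identifiable
and a full run completes in minutes on one CPU.

## Known limitations

- The moderated t is a two-group contrast only: no covariates, batch
  terms, precision weights or count-level GLMs.
- Exact rank-sum enumeration is limited to ≤ 10 cells per side; beyond
  that the tie-corrected normal approximation is used.
- Signature derivation assumes the contrasts share a gene namespace;
  no identifier mapping is performed anywhere.
- GMT, TSV and MatrixMarket are the only interchange formats; no HDF5 or
  archive container support.
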