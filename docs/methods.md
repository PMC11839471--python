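# Methods

## Model and procedure

`oncopath` treats a panel of annotated cancer cell lines measured on two
omics layers — transcript abundance (RPKM) and protein abundance (log2) —
and asks, per cancer type, three nested questions: which features are
specifically expressed in that type (one-vs-rest), which biological pathways
those features implicate on *both* layers, and which drugs plausibly act on
that type through those pathways.

### Preprocessing

Per-cell-line RPKM maxima in bulk panels are dominated by a few extreme
transcripts. The capping rule replaces every value above a panel-wide
ceiling with the ceiling, where the ceiling is the *mode of the per-cell-line
maxima*. Continuous maxima have no exact mode, so maxima are binned at 4
significant digits before counting and ties among equally frequent bins are
resolved toward the smallest value (the most conservative cap); the returned
calibration value is the smallest raw maximum in the winning bin, so it is
always an observed value. Reading the rule as a global cap (rather than
"replace each cell line's own maximum") makes the operator idempotent and
order-free, which is what the tests verify. Capping is followed by
log2(x + 1); the pseudocount of 1 preserves zeros and is the community
default for RPKM. Protein matrices are tagged `log2` on ingestion and both
operators refuse them, so already-transformed data cannot be transformed
twice.

### Marker selection

A one-way ANOVA across all cancer types (default α = 0.05) screens out
features with no between-type signal; zero-variance features are assigned
p = 1 and dropped. Surviving features are tested one-vs-rest with the
pooled-variance two-tailed Student's t test (n₁+n₂−2 df; Welch is
deliberately not used), and p values are Benjamini–Hochberg adjusted per
cancer type.

Transcript selection does not fix a single FDR threshold. Instead the nine
cutoffs 10⁻¹⁰ … 10⁻² (tenfold steps) are each evaluated: the samples are
clustered on the surviving feature subset with complete-linkage Euclidean
agglomerative clustering, the dendrogram is cut at k = 2, and the clustering
is scored with Gini purity, Σ_c (n_c/N) Σ_j p²_{cj}, against binary
target-vs-rest labels. The chosen cutoff maximizes purity, with ties broken
toward the more stringent cutoff — a deterministic reading of "prefer
smaller FDR and higher purity". Both the cluster count and the label scheme
are genuinely open design points; k = 2/binary is the default because
selection is one-vs-rest, and a `multiclass` purity scheme plus arbitrary
`k_clusters` are exposed as parameters. Proteins use the raw t-test
p < 0.05 (not FDR-adjusted), reflecting the much smaller feature space of
proteomics panels; the FDR column is still reported for diagnostics.

Features without a gene symbol (most non-coding biotypes) participate in
selection but are excluded from all symbol-keyed joins downstream; symbols
are upper-cased at parse time to avoid silent case-mismatch join failures.

### Pathway enrichment

Enrichment of a significant gene set against a pathway is the one-sided
Fisher exact test, i.e. the hypergeometric upper tail P(X ≥ k) with
(k, K, n, N) = (overlap, pathway size in universe, significant genes,
universe size). The universe is the set of gene symbols measurable on the
layer's platform, not the genome — the standard guard against
platform-coverage bias. P values are BH-adjusted across pathways.

FDR-significant pathways (p < 0.05) are confirmed by a permutation
bootstrap: 1000 replicates each draw a uniform random gene set of size n
from the universe and compute its Fisher p for the pathway; the bootstrap p
is the fraction of replicates strictly beating the observed p (so 5 of 1000
gives exactly 0.005, and 0 of 1000 is reported as 0, not smoothed). Since
the replicate's Fisher p depends on the drawn set only through its overlap
with the pathway, the implementation samples the overlap directly from
Hypergeom(N, K, n) — an exactly equivalent, allocation-free realization of
the same random draw; reproducibility is bit-for-bit given a seed.

Transcript- and protein-layer results are combined per pathway as
(log₁₀ p_FDR,t + log₁₀ p_FDR,p)/2; base 10 is used because characteristic
scores in the −3…−26 range are naturally read as decimal exponents. A
pathway is *characteristic* for a cancer type when it passes FDR < 0.05 and
bootstrap < 0.05 on both layers; characteristic pathways are ranked
ascending by score with alphabetical tie-breaks. Zero FDR p values are
floored at the smallest positive normal float before taking logs.

### Drug linking

Target genes lying in ≥ `min_pathways` (default 2, the smallest reading of
"multiple") characteristic pathways qualify a drug for a cancer type when
the drug targets at least one of them; the drug's pathway count is then the
number of characteristic pathways containing *any* of its targets (union
over targets, which is what produces large per-drug counts when a hub gene
sits in many pathways). Candidates are sorted by descending pathway count,
ties alphabetical. DrugBank- and KEGG-style target tables are concatenated
and deduplicated on (drug, gene) at parse time.

### Validation

*mnAUC comparison.* mnAUC (mean normalized AUC) is the average fraction of
cells surviving drug exposure across a cell-line panel; lower means more
potent. It is consumed as an input table — re-estimating it from
dose–response curves is out of scope. Candidate and reference mnAUC samples
are compared with a two-sided Wilcoxon rank-sum test: the exact U
distribution when both samples have ≤ 25 values and no cross-group ties, the
normal approximation with tie correction otherwise.

*Randomization hit-rate test.* A predicted (drug, cancer type) pair is a
hit when the drug is an approved targeted therapy for the type. Each of
`n_reps` (default 100) replicates samples `n_pairs` (default 1000) pairs
uniformly *without replacement* from the pair universe; the mean replicate
hit rate estimates the background. The headline p value is a two-sided
Fisher exact test of the predictions against all replicates pooled into one
2×2 table (a single aggregate comparison); per-replicate Fisher p values are
available via `mode="per_replicate"` for diagnostics.

## Synthetic data: what it emulates and what it does not

The generator plants a complete causal chain: per-class marker blocks
(+`effect_size_log2` in log2 space on a Uniform(1, 8) baseline with Gaussian
noise `noise_sd`), exported on RPKM scale via 2^x − 1 so the preprocessing
path is exercised; a protein layer covering a random
`protein_coverage_fraction` of coding genes with independent noise but the
same planted shifts; planted pathways drawing
`planted_pathway_marker_fraction` of their members from the class's markers
(sharing a small marker core per class); one planted effective drug per
class targeting that core, so it is linkable through every planted pathway;
approved pairs equal to the planted (drug, class) pairs; and mnAUC drawn at
N(0.87, 0.15) for effective drugs vs N(0.96, 0.15) otherwise — centring the
two groups on the means a real potency comparison of this kind produces. A
`noncoding_fraction` of features carries a biotype but no gene symbol,
exercising the symbol-mapping exclusion path.

Defaults (4 types × 15 lines, 2000 features, 50 markers/class, effect 2.0
log2 units, sd 0.5, 50 pathways of 20 genes, 3 planted per class, 40 drugs)
are the conditions under which the recovery guarantees in the test suite are
stated. What the generator does *not* emulate: count-level sampling noise
(expression is Gaussian in log2 because that is all the pipeline consumes),
missing proteomics channels or TMT batch structure, correlated co-expression
modules, overlapping real pathway topology, or dose–response curves. Passing
tests therefore demonstrate correctness of the statistical machinery and
end-to-end wiring under a clean planted model, not robustness to the full
messiness of real panels.

## Numerical choices and degenerate inputs

- BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`
  and is property-tested against a brute-force step-up oracle; inputs
  outside [0, 1] raise.
- ANOVA/t statistics are computed vectorized across features with
  `nan_policy="omit"`; a feature with < 2 usable values on either side of a
  split is marked missing rather than tested. A class with < 2 samples
  raises, naming the class.
- Hierarchical clustering cannot digest NaN; protein matrices are mean-
  imputed per feature *only* inside the clustering step.
- Tie-breaks are everywhere deterministic: smallest tied cap, most stringent
  tied cutoff, alphabetical pathway/drug order at equal score/count.
- The global seed is expanded via `numpy.random.SeedSequence.spawn` into one
  substream per (cancer type, layer) bootstrap plus one for the
  randomization test, so any stage can be replayed in isolation and results
  are byte-identical across reruns of the same configuration.
- GCT values are written at 6 significant digits; round-tripping is
  identity up to that formatting.

## Problem sizes

The test suite and the worked example run the full chain on the default
synthetic study (2000 × 60 transcripts, ~1000 × 60 proteins, 50 pathways,
1000 bootstrap replicates) and on smaller 3-class studies for the
multi-seed null checks; these sizes give stable planted-truth recovery and
tight null calibration while keeping a full suite run in a few seconds.

## Known limitations

- The capping sentence admits a second reading ("recalibrate each cell
  line's own maximum"); the global-cap reading implemented here is the
  idempotent one. The per-sample alternative is not implemented.
- Cell-line identifier harmonization between RNA-seq and proteomics sources
  is not guessed: matrices are joined on exact sample ids, and unannotated
  samples are reported, not dropped silently.
- Real result tables from public panels (CCLE-scale inputs, curated pathway
  and drug databases) are not bundled; the package operates on whatever
  files of the supported formats the user supplies.
- GCT 1.3, HDF5 and network retrieval are unsupported by design.
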