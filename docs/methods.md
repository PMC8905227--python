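# Methods

This document records the modelling assumptions, default parameters and
numerical choices behind each module, what the synthetic generator does and
does not emulate, and the known limitations.

## Synthetic cohort generator (`lincforge.synthetic`)

**What it emulates.** An allotetraploid genome with two subgenomes (At, Dt),
each with chromosomes carrying interleaved protein-coding genes and
lincRNAs; a stranded reference annotation and an "assembled" transcript set;
EST support intervals; and an RNA-seq count matrix over a
2-genotype × 5-timepoint × 3-replicate design with planted differential
expression.

**Planted truth.** Every transcript carries: its true class code (u/i/x),
whether it should survive each filter rule (decoy transcripts each violate
exactly one rule: too short, too close to a gene, too lowly expressed,
ORF-bearing, or without EST support), its true DE status and log2 fold
change, its homolog partner and synteny status, and a cluster label. Counts
are negative binomial around log-normal baseline means; coding sequences are
GC-enriched relative to lincRNAs so the hexamer classifier has signal.

**Defaults** (`SimulationConfig`): seed 1; 2 chromosomes per subgenome of
200 kb; 50 genes per subgenome; 70 intergenic lincRNAs including 10 syntenic
homolog pairs and 4 relocated pairs; 5 decoys per filter rule; design
HR/ZS genotypes × 0/4/12/24/48 h × 3 replicates; DE fraction 0.25 with
planted |log2FC| = 3; NB dispersion 0.05; library size 2×10⁷.

**What it does not emulate.** Read-level RNA-seq (alignment, multimapping,
positional bias), splice isoform diversity beyond one transcript per locus
for lincRNAs, polyploid homoeolog cross-mapping, batch effects, and any real
genome sequence content beyond GC composition. Counts are generated directly
at the feature level.

## Transcript classification and filter cascade (`lincforge.classify`)

Class codes come from exon-level interval overlap against the reference:
`u` (intergenic), `i` (fully intronic, same locus span without exon
overlap), `x` (exonic overlap on the opposite strand), `overlapping_other`
otherwise. Nearest-gene distance is the gap to the closest gene span on the
same chromosome, ties broken to the lowest gene id.

The filter cascade applies rules in a fixed order — class code ∈ {u}, length
≥ 200 nt, max-sample FPKM > 0.5 (strict inequality), distance > 500 bp,
EST exon overlap — and records the *first* failed rule per transcript in a
rejection ledger, so the ledger partitions the input exactly into survivors
and one-rule rejections.

## Coding potential (`lincforge.coding`)

ORF finding scans all six frames for ATG…stop spans, reporting the earliest
ATG per stop, breaking on codons containing N, and flagging open-ended ORFs.
The coding score combines ORF coverage with a log-likelihood ratio of
in-frame hexamer frequencies trained on coding vs shuffled sequences
(Laplace-smoothed). Protein support is BLOSUM62 local alignment against a
peptide database with a score threshold (default 60). The label threshold on
the combined score is fixed at training time, independent of any test set.

## Differential expression (`lincforge.de`)

Median-of-ratios size factors (zero-safe geometric means); NB dispersion as
a fitted mean trend α(μ) = a₀ + a₁/μ over per-feature method-of-moments
estimates. The test statistic is a Wald ratio of the pseudocount-stabilised
log2 fold change (pseudocount 1 on normalised means) to its delta-method
standard error, referred to the standard normal. With n = 3–4 replicates the
trend dispersion is treated as known; this calibrates the null rejection
rate near nominal (measured ≈ 0.04–0.05 at α = 0.05 on simulated null data).
`shrink_weight` (default 0) can blend per-feature dispersion estimates back
in. DEL status requires p < α (default 0.05) and |log2FC| > 2; optional
Benjamini–Hochberg FDR.

## Subgenome homology (`lincforge.homology`)

Local alignment is affine-gap Smith–Waterman (match 2, mismatch −2, gap of
length k costs 5 + (k−1)·2) via Biopython's PairwiseAligner. Reciprocal best
hits require each side to be the other's top-scoring partner (score ties
broken to the lexicographically smallest id) and pass identity ≥ 0.85 over
aligned columns and coverage ≥ 0.8 of the shorter sequence. Synteny is
flagged when the two members share ≥ 2 anchor genes among their k = 5
flanking genes (via each gene's known cross-subgenome partner). Subgenome
expression bias over complete pairs uses the exact Wilcoxon signed-rank test
on paired log2 fold changes.

## Co-expression network (`lincforge.network`)

Unsigned WGCNA-style adjacency a_ij = |cor(i,j)|^β with β = 8 by default;
constant rows are dropped with a warning. At β = 1 the adjacency equals the
absolute Pearson correlation exactly. Edges are kept where a_ij ≥ cutoff
(default 0.9). The soft-threshold scan picks the smallest candidate β whose
degree distribution reaches a scale-free fit R² ≥ 0.9 (log-log regression
over binned degrees), else the argmax with a warning. Hubs are the
highest-degree lncRNA nodes with their neighbor sets.

## Clustering and enrichment (`lincforge.cluster`)

Profiles are per-feature z-scored (constant rows get a notice and zeros)
and clustered with k-means (fixed seed, k = 10 default). Enrichment is the
one-sided Fisher exact test (hypergeometric upper tail) of term membership
in a cluster versus the universe, with Benjamini–Hochberg FDR and three
presets: `cluster` (p < 0.01), `ko` (FDR < 1e-4), `network` (α = 0.05).
Function transfer annotates lincRNAs with the enriched terms of their
cluster, always labelled "associated" — co-expression is correlational, not
causal.

## Editing outcomes (`lincforge.editing`)

The guide is located by exact match with an NGG PAM (either strand; exactly
one site required); the cut position is 3 bp upstream of the PAM. Reads are
aligned to the amplicon with free end gaps; indels and substitution runs are
called within a ±10 bp window of the cut. Classification: deletion /
insertion / substitution (≥ 2 substitutions by default) / mixed / WT;
alignments scoring below half the self-score are "unaligned". The summary
reports efficiency (% edited of aligned), type counts and a deletion-length
histogram; a minimum read count (default 50) guards low-coverage calls.

## Group statistics (`lincforge.stats`)

`anova_lsd` is one-way fixed-effects ANOVA with Fisher's protected LSD:
pairwise t tests on the pooled within-group mean square (only when the
omnibus F is significant, unless `protected=False`), plus compact letter
display. With exactly two groups the LSD p equals the pooled two-sample t
test p. `rel_expression` implements 2^-ΔCt and 2^-ΔΔCt (calibrator-relative,
hence exactly 1 for the calibrator). Star labels: p < 0.05 `*`, < 0.01 `**`,
< 0.001 `***`, < 0.0001 `****`, else `ns` (boundaries excluded).

## Numerical choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline output is byte-identical across runs
  at the same seed (floats serialised with `%.6g`, JSON keys sorted).
- Exact tests (Fisher, Wilcoxon n ≤ 25) use scipy's exact modes; the test
  suite cross-checks them against factorial tail sums and full sign-flip
  enumeration.
- Alignment scoring is integral-valued, so score comparisons are exact.
- Size factors ignore features with zeros in the geometric-mean step rather
  than adding pseudocounts.

## Limitations

- The DE model uses a trend-only dispersion by default; with many replicates
  or strong per-feature dispersion heterogeneity, a shrinkage blend
  (`shrink_weight` > 0) or an established DE package is more appropriate.
- Homology search is all-vs-all dynamic programming — fine for hundreds of
  lincRNAs, not for genome-scale inputs.
- The coding-potential model is a simple hexamer/ORF combination, weaker
  than dedicated tools trained on large corpora.
- The editing classifier assumes amplicon reads from a single site; it does
  not model large rearrangements or chimeric reads beyond a dropout check.
- Synthetic benchmarks demonstrate correctness of the implementations, not
  biological performance on real data.
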