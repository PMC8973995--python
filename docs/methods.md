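# Methods

This note records the statistical and algorithmic choices behind each
module, the constants they use, and the known caveats.

## Fragment taxonomy

Reads are placed on mature and precursor tRNA sequences by exact (or
bounded-mismatch) ungapped search; the mature compartment is preferred,
ties broken by fewest mismatches, then smallest start, then reference id.
Classification applies the first matching positional rule, which makes the
six classes mutually exclusive:

1. read starts at mature position 0 and is 16–28 nt → **tRF-5**
2. read ends at the mature 3′ end (within `cca_slack`) and is 16–28 nt → **tRF-3**
3. read starts at trailer position 0 (precursor compartment) and is 16–28 nt → **tRF-1**
4. read starts at mature position 0 and is 29–50 nt → **tiRNA-5**
5. read ends at the mature 3′ end (within `cca_slack`) and is 29–50 nt → **tiRNA-3**
6. internal mature placement, 16–28 nt → **i-tRF**

tiRNA calls optionally require the cleavage point to fall inside the
anticodon window (anticodon start − 3 to + 6), reflecting the
angiogenin-mediated anticodon-loop cleavage that produces halves.

`cca_slack = 1` (default) accepts 3′-anchored fragments ending one base
before the CCA tail. Rationale: synthesised mimics of 3′ fragments are
commonly printed one base short of the genomically templated CCA — the
worked-example Thr-AGT mimic ends `UCC`, not `CCA` — and a strict 3′ anchor
would misclassify such fragments as i-tRF.

Type distributions are computed over classified reads only; unmapped or
unclassifiable reads are reported separately and excluded from
denominators.

## Differential expression

Counts are scaled per sample to counts-per-million (columns sum to 10⁶).
Fold change uses pseudocounted means, FC = (x̄_trt + 1)/(x̄_ctrl + 1).
Significance is a two-sided **pooled-variance** two-sample t-test on
log2(x + 1). With three replicates per group, Welch's unequal-variance test
is measurably conservative (type-I ≈ 0.033 at α = 0.05 even on exactly
normal data) because its Satterthwaite degrees of freedom are poorly
estimated at n = 3; the pooled test is exact under the equal-variance
design and holds the nominal rate (≈ 0.048–0.056 on simulated nulls).

Direction calls require both the class fold-change threshold (2.0 for
mRNA, 1.2 for miRNA and tRF/tiRNA) and p < 0.05. Features whose groups are
both constant have an indeterminate t and are assigned p = 1. No multiple-
testing correction is applied by default — the calling criterion is a raw-p
rule — but Benjamini–Hochberg q-values can be added with `fdr="bh"`.

*Caveat: composition bias.* CPM renormalization under strongly one-sided
differential expression shifts every null feature's apparent fold change in
the opposite direction; at the permissive 1.2-fold small-RNA cutoff this
can create spurious calls. The simulator's default planting is two-sided
and nearly balanced in total abundance, where the effect is negligible.

## Target scanning

`target_scan` implements a miRanda-style complementarity scan: the small
RNA is reversed (not complemented) and locally aligned to the UTR with a
Smith–Waterman recurrence under complementarity scoring — Watson–Crick
pair +5, G:U wobble +2, mismatch −3, affine gaps (open −8, extend −2).
Positions 2–8 from the small RNA 5′ end (the seed) carry a ×4 weight that
multiplies **both** the substitution score and the gap penalties at those
positions. Weighting only the match bonus would let gapped alignments
chain dispersed seed matches at low cost, inflating the null hit rate at
the score threshold by an order of magnitude; scaling the gap penalties
alongside (as miRanda does) keeps gaps in the seed as expensive as the
bonus they could harvest. Sites must score strictly above 140. A perfect
17-nt complement scores 7·5·4 + 10·5 = 190. Multiple sites per UTR are
extracted greedily: best site first, its window masked, repeat.

The fill and traceback kernels are numba-compiled (`cache=True`); the test
suite checks them against an independent pure-Python implementation.

## Network construction

An edge (regulator → mRNA) is kept iff a predicted target site exists and
the DE directions are opposite (regulator up & target down, or regulator
down & target up); non-significant features never enter the network.
Networks are bipartite `networkx` graphs; each node carries `node_type`,
`fold_change`, `p_value`, `degree` and `is_tf` (membership in a curated
transcription-factor list, with a small rat-gene default list shipped in
`trfnet/data/tf_list.txt`). Hubs are ranked by degree (descending), then
p-value (ascending), then id. miRNA and tRF/tiRNA networks are merged with
attribute-conflict checking for the combined view; exports are SIF
(`regulator targets mRNA`) and GraphML.

## Gene-set enrichment

For a list of n genes from a background of N, and a term with K background
members overlapping the list in k genes, the p-value is the hypergeometric
upper tail P(X ≥ k). The default **EASE** mode recomputes the tail with
k − 1 in place of k — the conservative DAVID variant that assigns p = 1 to
single-gene overlaps. Symbols are normalised to initial-capital (rat
convention) before matching; q-values are Benjamini–Hochberg and reported
without filtering. The enrichment score is −log10 p (bubble-plot axis).

## qPCR relative quantification

Livak's method: ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt − mean ΔCt over the calibrator group, RQ = 2^−ΔΔCt. By
construction the calibrator group's geometric-mean RQ is exactly 1. Group
comparison uses Student's t for two groups and one-way ANOVA with Tukey HSD
for more; Ct values must lie in (0, 45) with ≥ 2 replicates per group.

## Synthetic data

All generators draw from `numpy` `SeedSequence([seed, stream])` with a
distinct stream per generator, so components are independently
reproducible and a pipeline run is byte-identical across same-seed runs
(verified via the SHA-256 manifest).

- **tRNA references**: mature sequences 70–90 nt ending CCA, anticodon at
  the midpoint, precursor trailers with an early poly-U tract; the Thr-AGT
  locus embeds the worked-example fragment at its 3′ end.
- **Reads**: drawn per class to satisfy the positional rules exactly, so a
  noise-free run must classify 100%; i-tRF reads stay ≥ 2 bases clear of
  the 3′ end so the CCA slack cannot capture them, and tiRNA cut sites fall
  inside the anticodon window.
- **Expression**: lognormal noise with fixed coefficient of variation
  (mean-preserving), planted up/down features at a given effect fold. The
  defaults mirror the study design: 3 vs 3 samples, 2000 mRNAs with
  172 up / 34 down, 300 miRNAs with 11/24, 200 tRF/tiRNAs with 4/16,
  effect fold 4, CV 0.05.
- **UTRs and sites**: i.i.d. random UTRs; each DE small RNA's perfect
  complement is planted into DE mRNA UTRs at a configurable rate, plus one
  designated hub regulator planted into 25 down-regulated UTRs so hub
  recovery is testable.
- **Ct tables**: reference gene Ct ≈ 18, target ≈ 24, treated group shifted
  by a planted ΔΔCt (default 1.5), Gaussian noise.

The generator does **not** emulate sequencing error, ligation bias, tRNA
modification-induced misincorporation, isoform multi-mapping, or dispersed
(non-lognormal) count noise; its purpose is planted-truth validation of
the analysis code, not realistic read simulation.

## Problem sizes

Default sizes (20 tRNA loci, 2000 mRNAs, 300 miRNAs, 200 tRF/tiRNAs,
200-nt UTRs) were chosen so a full pipeline run completes in well under a
minute on one CPU while keeping every statistical check
(type-I calibration, planted recovery, hub ranking) adequately powered.

## Limitations

- The scanner models complementarity only; no free-energy term and no
  conservation filter, so absolute scores are not comparable to
  thermodynamics-aware tools.
- The anti-correlation rule is correlational; edges are hypotheses, not
  validated interactions.
- Raw-p DE calling at 1.2-fold for small RNAs is permissive by design and
  should be paired with q-values when used beyond planted-truth synthetic
  data.
- The pooled t-test assumes equal group variances; with real, strongly
  heteroscedastic data and larger n, a Welch or moderated (empirical-Bayes)
  test is preferable.
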