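# Methods

This note documents the statistical procedures `triadex` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not emulate.

## Study design and containers

The pipeline targets a reciprocal-cross design: inbred parents P1, P2, P3
and hybrids F12 (P1♀ × P2♂), F21, F13, F31, grouped into two crossing
combinations (P1×P2, P1×P3) that share P1, with three biological
replicates per genotype. Expression is a gene × sample FPKM table
(optionally raw counts plus gene lengths); methylation is a per-site,
per-genotype RPM table restricted to the CCGG and CCWGG restriction-motif
contexts; phenotypes are replicate trait values. All genomic coordinates
are 1-based inclusive; all tables are TSV with a provenance header line.

## Differential expression

The DE stage is a deliberately simple, fully documented substitute for a
count-model package: a two-sided Welch t on log2(FPKM + 1) per genotype
pair, with fold change log2((mean_A + 1)/(mean_B + 1)) on replicate-mean
FPKM. Significance requires p < 0.05 *and* |log2FC| > 1 (both strict);
the raw p is used, not the BH-adjusted one, which is reserved for
enrichment. No fold-change shrinkage and no cross-sample size-factor
normalization are applied — a known deviation from count-model DE tools,
accepted for transparency; an approximate negative-binomial Wald test on
counts (`method="nb_wald"`, moment dispersion, delta-method SE) is
available when counts exist.

Degenerate rows: if both groups are constant (zero range) and equal, the
gene cannot be called — p = 1. If both are constant but different, a
parametric p is meaningless and an exact permutation test over replicate
labels is used instead; with 3 vs 3 replicates its smallest attainable
two-sided p is 0.1, so such genes are never significant — constant data
should not manufacture certainty. The pseudocount of 1 FPKM bounds fold
changes at low expression and avoids division by zero.

The low-expression filter discards a gene only when every genotype's
replicate-mean FPKM is below 1 (strictly); one genotype at or above the
threshold retains the gene.

## Remodeling classification

A triad (parents A, B; hybrid F1) yields three DE relations and hence 27
patterns. The mapping to 14 subcategories is total and deterministic:

| pattern (A vs B, F1 vs A, F1 vs B) | subcategory | major |
|---|---|---|
| ns, >, > / ns, <, < | 1 / 6 | OPG (transgressive, parents conserved) |
| A>B, >, > / A<B, >, > | 2 / 3 | OPG (above both, high parent A / B) |
| A>B, <, < / A<B, <, < | 7 / 8 | OPG (below both) |
| A>B, ns, > / A<B, >, ns | 4 / 5 | BPG (F1 = high parent) |
| A>B, <, ns / A<B, ns, < | 9 / 10 | BPG (F1 = low parent) |
| A>B, <, > / A<B, >, < | 11 / 12 | AEG (strictly intermediate) |
| ns, ns, ns | 13 | conserved |
| all 14 remaining patterns | 14 | other (contradictory) |

"Equal to a parent" is operationalized as a non-significant call; no
equivalence test is performed. Two exact symmetries are asserted by
tests: relabeling A↔B applies the permutation (2 3)(4 5)(7 8)(9 10)(11 12)
and fixes 1, 6, 13, 14; reflecting the hybrid about its parents (negating
every contrast, then restoring the high parent's role) exchanges the
hyper/hypo pairs 1↔6, 2↔7, 3↔8, 4↔9, 5↔10 and fixes 11–14. The second
symmetry also defines "conflicting" methylation–expression pairs.

**Parent orientation.** The A/B labels are the *sorted* parent pair of
the crossing combination, shared by both reciprocal hybrids. If A were
tied to the maternal parent, reciprocal hybrids with identical expression
would land in systematically parent-swapped subcategories and the
reciprocal-consistent gene set (ReCGs) would be empty by construction;
the canonical orientation makes subcategories directly comparable across
a combination. ReCGs require the identical subcategory in both reciprocal
hybrids and exclude doubly-conserved genes, since consistency of
*remodeling* is what the set is about (identical-major-category matching
is a documented switch away).

## DEG set decomposition

Per combination: PEGs (parents DE), per-hybrid DEG sets vs each parent,
copDEGs (DE vs both parents; direction up/down when concordant, else
conflicting), HEGs (DE between two hybrids), H&P = HEGs ∩ PEGs. A gene is
a DIG between hybrids X and Y iff (i) X and Y are DE from each other,
(ii) each hybrid is non-significant versus exactly one of its own parents
(and DE versus the other), and (iii) the matched parents differ; the
matched parent is the gene's inheritance origin. This three-condition
rule is the minimal operationalization of "the hybrids selected different
expression levels from their parents" that keeps DIGs ⊆ HEGs and makes
origin attribution well-defined; admitting hybrids that match *both*
parents is a documented switch left off. Overlap percentages are
asymmetric (first-named set is the denominator), reported to two
decimals, and undefined (error, not 0) for an empty denominator.
Cross-combination hybrid pairs use the union of both combinations' PEGs.

## Heterosis metrics

MPH and BPH are computed on genotype means over replicates (not
per-replicate pairing); the optimal parent defaults to the larger mean
with a per-trait direction switch for smaller-is-better traits. Both
indices are scale-invariant, and BPH ≤ MPH holds algebraically for
positive traits. One-way ANOVA is the classical F test with explicit
degenerate handling (all-constant equal groups → p = 1; constant unequal
groups → p = 0 flagged degenerate). Trait correlations are Pearson on
genotype means by default (pooled replicates optional).

## Enrichment and hub screen

Term enrichment is the one-sided hypergeometric upper tail against the
background of all genes surviving the expression filter (the tested
universe — standard practice), BH-corrected across tested terms; a term
passes at padj < 0.05 with ≥ 5 study hits. The term map is taken as
already propagated; no ontology-graph traversal is done.

The hub screen's published-style ratio criteria (|E_F12/E_F21| < 1,
|E_comb1/E_comb2| > 1) cannot be meant literally — an absolute raw ratio
is almost always on one side of 1, making one criterion near-empty and
the other near-universal — so both are read as bounds on |log2 ratio|
with pseudocounted genotype means: reciprocal balance |log2 R| < 1,
combination difference |log2 R| > 1. A literal mode is provided for
comparison (`literal_ratio=True`). Genotype means (not medians) feed the
ratios.

## Methylation linkage

Sites are assigned strand-aware: body = [start, end], upstream2k = 2 kb
5′ of the TSS, downstream2k = 2 kb 3′ of the TES, windows clipped at
position 1 and *not* clipped against neighboring genes; a site may serve
several genes, and unassigned sites are intergenic. Regional level is the
**sum** of site RPM (an amount; per-site mean is an option), so the "all"
context is exactly the sum of the two motif contexts. The
methylation–expression correlation is Pearson across genes between
genotype-mean expression and genotype-mean regional level, per
(region × context) — nine combinations; a pooled (gene, genotype) mode
exists. Differential sites are classified with the *same* code path as
expression (major categories renamed OMS/BMS/AMS; NMS = subcategories
1–10). The faithful input mode ingests externally produced differential
methylation calls; when only genotype-level RPM exists, threshold-only
calls (|log2 ratio| > 1 on pseudocounted levels) are computed internally,
and with replicate RPM the Welch test applies as for expression.
Gene-level concordance uses "any site" semantics: a gene–hybrid–context
is consistent if any assigned site shares the gene's expression
subcategory and conflicting if any site carries its hyper/hypo dual;
both flags can hold at once and are reported separately.

## Synthetic data

Planted subcategories are realized as exact offsets on the
log2(FPKM + pseudocount) scale — the very scale the pipeline measures —
with offset e = `effect_size` (> the log2FC threshold t, enforced): e.g.
high-parent dominance plants (B, F1) at (−e, 0) relative to A, additive
classes place the parents 2e apart with F1 midway, and subcategory 14
uses the resolvable-but-contradictory pattern (ns, >, ns) with offsets
(0.6 t, 1.55 t). A generation-time check asserts that threshold-
classifying the noise-free mean matrix reproduces 100% of planted
classes. Counts are negative-binomial (gene-wise base mean log-uniform
over 5–500 FPKM, constant dispersion 0.05, the standard bulk RNA-seq
assumption), and FPKM = counts / (gene-length-kb × library-size-millions)
with the library size the realized column sum.

Default class proportions put 82% of genes in the conserved class and,
within the remodeled remainder, ~91% non-additive with ~68% biased-parent
dominance — matching the observed regime in this design family, where
pairwise DEG rates are a few to ~18% of the transcriptome and dominance
is the prevailing remodeled pattern. Because FPKM is normalized by the
realized library sum, heavily asymmetric remodeling would induce a
composition shift between genotypes; at the default (realistic) remodeled
fraction this shift is ≪ the threshold and planted classes remain
recoverable (the noisy-recovery test measures ~98% exact-subcategory
agreement at 5,000 genes).

Differential inheritance is planted in 3% of genes per combination: the
parents are set e apart and each reciprocal hybrid adopts a different
parent's level — the maternal parent's for both hybrids with probability
0.8 (the observed predominance of female-parent inheritance), else the
paternal parent's for both. As a consequence, reciprocal hybrids differ
*only* at planted DIG genes; real reciprocal pairs also differ for
reasons outside this model (cytoplasmic effects, imprinting noise), so
synthetic HEG counts between reciprocals are a lower bound in spirit.

Methylation couplings are planted per (region, context) with the signs:
body CCGG +0.5 / CCWGG −0.3, upstream the opposite, downstream negative.
The regional aggregate is *linear* in standardized per-genotype
expression plus gene-level Gaussian noise shared across genotypes, so
the Pearson correlation equals the configured coupling by construction
(a lognormal copula would attenuate Pearson r unpredictably); per-site
RPM splits the aggregate by symmetric Dirichlet weights shared across
genotypes, positions are drawn without replacement within each region,
and CCGG carries more signal (μ=10, σ=2) than CCWGG (μ=4, σ=1), so the
"all"-context sign follows CCGG. Planted DMS classes are the
deterministic threshold classification of the generated RPM, recorded at
generation time. Intergenic background sites are uncoupled.

Phenotypes plant population-level MPH exactly (hybrid mean = mid-parent ×
(1 + MPH/100)) with Gaussian replicate noise at CV 5%; defaults give the
P1×P2 hybrids positive heterosis in all six seedling traits (fresh
weights > 30% MPH) and the P1×P3 hybrids positive height only. Seed
traits are not modeled. The synthetic GO map plants genuine
over-representation of four focal processes among remodeled genes.

What passing tests show — and don't: the generator validates the
*pipeline logic* (mapping exactness, set identities, recovery under NB
noise, calibration, determinism). It does not emulate read-level
artifacts, transcript-length biases within a gene, batch effects,
correlated gene modules, or bisulfite/MethylRAD chemistry, so passing
tests certify the analysis, not the upstream measurement process.

## Numerical and reproducibility choices

Strict inequalities throughout (p < 0.05, |log2FC| > 1, FPKM < 1), so
boundary values are non-significant/retained exactly as documented. One
seeded generator per run; derived seeds (seed+1 methylation, seed+2
phenotypes, seed+3 term map) keep the streams independent but
reproducible. Output tables are written with full float precision and
read back with round-trip parsing, so write→read is the identity and
rerunning a pipeline with the same config and seed is byte-identical
(verified per run). Problem sizes used by the shipped checks — 5,000
genes for noisy recovery, 2,000 for calibration and methylation sign
recovery, 1,200 for the bundled end-to-end run — were chosen as the
smallest sizes at which the Monte-Carlo margins are comfortable.

## Known limitations

- The Welch-on-log substitute has no variance shrinkage; at 3 replicates
  its power is below that of moderated count models, and the acceptance
  thresholds account for this.
- FPKM carries library-composition effects; the pipeline deliberately
  does not re-normalize across samples (kept out of scope with the rest
  of the count-model machinery).
- The DIG rule requires each hybrid to match exactly one parent; genes
  matching both parents are excluded by design.
- Methylation concordance treats sites independently ("any site"
  semantics); it does not weight sites by RPM or resolve intra-gene
  disagreements beyond reporting both flags.
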