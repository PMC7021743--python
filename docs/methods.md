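# Methods

`tubervar` post-processes structural-variation calls for a panel of potato
genomes of mixed ploidy (2x-5x) analysed against a single reference. It
does not call variants: it starts from CNVnator-style read-depth CNV
tables and Freebayes-style VCFs and derives gene-level, region-level and
panel-level results. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## CNV filtering and gene impact

Raw read-depth CNV calls (deletions and duplications) are filtered on
three axes, with defaults `min_size_bp = 1000`, `max_p = 0.01`,
`max_q0 = 0.5`:

- event size **strictly greater** than `min_size_bp` — an exactly 1000-bp
  event is removed;
- significance `p ≤ max_p` (inclusive);
- fraction of zero-mapping-quality reads `q0 < max_q0` (strict).

The boundary semantics follow the different phrasings of each clause
("larger than", "cutoff", "< 0.5"); all three are configurable.

Per gene and sample, duplication and deletion calls are unioned
separately and intersected with the **gene body** (annotation start to
end, introns included; not the exon union). Coverage fractions therefore
never exceed 1 regardless of overlapping calls. A gene is CNV-impacted
when either fraction reaches 0.5, coded ternary: 3 duplicated, 2 deleted,
1 not impacted. A gene reaching 0.5 for both types is coded by the larger
fraction, ties to duplication — the ternary encoding cannot express
"both", and this rule keeps the matrix well-defined. A gene covered ≥50%
only jointly by the two types (each <50%) is *not* impacted; the
threshold applies per type.

The per-sample CNV footprint is the union of all filtered call intervals,
both types pooled, summed over chromosomes. All interval arithmetic uses
0-based half-open coordinates internally; GFF3 and VCF conventions are
converted at the file boundary. Genes with multiple mRNAs collapse to the
transcript with the longest summed CDS (ties to the lexicographically
smallest mRNA ID), giving one interval set per gene.

## CNV-enriched gene clusters

Each chromosome is tiled with overlapping fixed-width windows
(`bin_width = 200 kb`, `step = 10 kb`). Windows are placed wherever a
full-width bin fits (no ragged tail bins, so counts stay comparable);
chromosomes shorter than one bin get a single truncated bin. A gene
counts in every bin its body overlaps by ≥1 bp.

Significance uses a genome-wide threshold per sample: mean of all bin
counts plus `sd_multiplier = 3` population standard deviations, pooled
over chromosomes (not per chromosome). Choices the statistic's wording
leaves open, and how we resolved them:

- **population vs sample SD** — population SD by default, switchable;
- **inclusive comparison** — a "minimum threshold", so `count ≥ threshold`;
- **degenerate landscapes** — if the SD of the counts is zero the
  threshold equals the common count and every bin would qualify; the scan
  then reports nothing. Zero-count bins are never significant.

Significant bins that overlap or touch merge into maximal clusters; each
cluster reports its member impacted genes, its peak bin count, and the
dominant status among members (duplication vs deletion majority, tie to
duplication). "Top clusters" ranks by peak bin count with ties broken by
genomic position.

The threshold is honest only when clusters are local features on a much
larger genome: if planted clusters occupy a large share of the genome
they inflate the mean and SD and can suppress themselves. The default
synthetic conditions (three 200-kb clusters on 10 Mb) sit safely in the
regime where the statistic works; very small toy genomes do not.

## Ternary classification

The samples x genes status matrix (entries 1/2/3) feeds two analyses.

**Ordination.** Pairwise distances are Manhattan (Czekanowski; the
default) or Euclidean — both are offered because the source analyses used
both descriptions — followed by classical metric scaling (PCoA):
double-center −D²/2, eigendecompose, scale eigenvectors by the square
root of their eigenvalues. With Euclidean input this reproduces PCA
scores exactly (up to component sign), which is asserted against
scikit-learn's PCA as an independent implementation. Manhattan distances
need not be Euclidean-embeddable; negative eigenvalues are reported but
never embedded, and eigenvalues within `|λ|max·1e-12` of zero are treated
as zero rather than injecting √ε noise into the coordinates.

**Parsimony tree.** The three states are treated as unordered (Fitch
parsimony), following the discrete multi-state convention of PHYLIP's
PARS; there is no evidence the codes are ordered 1<2<3, and a Wagner
reading would impose one. The small-parsimony score is computed by
Fitch's bottom-up pass with states as bitmasks, vectorized over genes;
the score is invariant to the internal rooting node. Tree search is
heuristic: random-order stepwise addition followed by
nearest-neighbor-interchange hill climbing, best of `n_restarts = 10`
random orders, deterministic given (seed, restarts). Ties break on the
canonical newick string. On random 6-taxon matrices the search reaches
the exhaustive 105-topology optimum in ≈99% of trials (measured, not
guaranteed; NNI can stall in local optima). Genes constant across the
panel carry no signal and may be dropped (`informative_only`) without
changing any score — asserted in tests. Trees are serialized in a
canonical newick form (rooted on the internal edge next to the smallest
leaf label, children ordered by smallest leaf in subtree) so equal
topologies are byte-identical on disk.

Score bounds used as sanity checks: per gene at least
(distinct states − 1) changes on any tree, and never more than the
number of taxa carrying a non-modal state.

## SNP filtering, heterozygosity and effects

Filtering is ploidy-aware: minimum depth 4/6/8/10 for ploidy 2/3/4/5,
and site MQ, MQM (mean mapping quality of alt-supporting reads) and MQMR
(same for reference-supporting reads) each ≥ 20. The strand rule demands
alternate support on both strands (SAF > 0 and SAR > 0) — the standard
strand-bias intent of SAF/SAR filtering; the literal condition
"SAF && SAR < 0" is unsatisfiable since read counts are non-negative. A
record missing a field required by an active rule fails that rule.

Sites are typed from the ploidy-length genotype: `biallelic_B` (≥1
reference and ≥1 copies of exactly one alternate), `biallelic_other`
(purely one alternate), `multiallelic` (≥2 distinct alternates),
`homozygous_ref`. Heterozygosity has two modes: `strict` (≥2 distinct
allele indices; the standard definition and the default) and `alt-any`
(any non-reference allele counts), the looser reference-divergence
convention some pipelines use; both are reported because they answer
different questions. Per chromosome the profile emits site and het
counts, the within-chromosome het fraction, het sites per Mb, and the
chromosome's share of all het sites — the share is what the hotspot
ranking uses, and both metrics are emitted because either reading of
"percent heterozygous per chromosome" is defensible.

Effect classification is a deliberately lightweight re-implementation of
the standard annotator logic, substitutions only. Region priority is
exonic > intronic > upstream > downstream > intergenic across all genes,
with strand-aware flanks of `flank = 5000` bp (the common annotator
default). For CDS sites the affected codon is translated with and
without the alternate allele under the standard nuclear code
(reverse-complemented for minus-strand genes): same amino acid → silent,
stop gained → nonsense, else missense (stop-loss falls under missense).
Indels are counted by region but get no coding class. Not modelled:
splice-site classes, UTR subclasses, multi-nucleotide codons changes.

## Synthetic data: what it emulates, what it does not

The generator emulates the *shape* of the study inputs at desk scale,
one integer seed end to end (NumPy PCG64; byte-identical reruns):

- **Reference**: 5 chromosomes x 2 Mb, 600 non-overlapping two-exon genes
  (2-6 kb) whose spliced CDS always starts ATG, ends with a stop and
  translates without internal stops — so translation-based checks hold
  genome-wide. Real potato chromosomes (12 x ~70 Mb) are out of scope.
- **Panel**: twelve samples named and ploidy-typed after a mixed-ploidy
  landrace panel (six diploids, two triploids, three tetraploids, one
  pentaploid), grouped by taxonomic affinity so classification has
  recoverable structure.
- **CNV profiles**: three planted clusters of 20 consecutive genes inside
  200-kb regions (gene placement is densified there so the cluster fits),
  alternating duplication/deletion per cluster, shared across the panel;
  background genes impacted at 2% per group archetype, with samples
  copying their archetype at 95% per gene. Every impacted gene becomes
  one call covering the gene body (+500 bp) that passes the filter;
  optional decoy calls each violate exactly one filter rule, so the
  post-filter call set reproduces the planted statuses exactly — that
  exactness is what makes end-to-end truth tests sharp.
- **SNPs**: per-bp site rate 5e-4 with a 3x hotspot on chromosome 1
  (emulating uneven heterozygosity), genotypes of ploidy length (90%
  type-B heterozygous, 5% homozygous-alternate, 5% multiallelic), depth
  ~Poisson(2x the ploidy minimum), qualities in [25,60], both-strand alt
  support; an optional fraction of records violates exactly one filter
  rule, truth-labelled.

Passing tests on these data show the *computations* are correct (interval
math, thresholds, search optimality, effect translation, determinism).
They do not show robustness to real-data phenomena the generator omits:
read-depth noise and partial gene coverage, CNV boundary error, linkage,
population structure beyond three clean groups, annotation errors, or
caller-specific quirks. Claims about real potato panels require the real
inputs.

The group-structured matrix generator takes target pairwise agreement
probabilities (within 0.95, between 0.6) and converts them analytically
to retention probabilities (two rows copying a common row with retention
r agree with probability r² + (1−r²)/3), so the planted separation is
calibrated, not tuned.

## Problem sizes and determinism

The test suite and the acceptance script regenerate everything from
seeds; no data files ship with the package. The suite runs the planted
recovery, parsimony-optimality and group-recovery checks at 100 seeds or
trials each (~20 s total); the acceptance script uses 25 seeds / 40
trials per rate plus one full file-based panel run (~20 s), sizes chosen
to keep a single-CPU run interactive. Randomness enters only through
NumPy generators and `random.Random` seeded from the configuration; the
pipeline writes no timestamps, so rerunning any stage with the same
inputs, config and seed is byte-identical.
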