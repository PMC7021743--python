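"""Ploidy-aware SNP filtering, site typing, heterozygosity and effects.

Filtering follows the study design for a mixed-ploidy panel: the minimum
read depth scales with ploidy (4x for diploids up to 10x for pentaploids),
mapping qualities (site MQ, and the mean mapping qualities of alt- and
ref-supporting reads) must each reach 20, and the alternate allele must be
seen on both strands.  Effect classification re-implements the standard
region (exonic/intronic/upstream/downstream/intergenic) and coding
(silent/missense/nonsense) logic of variant annotators at gene-model
resolution; it is deliberately lightweight and handles substitutions only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from tubervar.io_formats import GeneModel, VariantRecord

#: Minimum per-site read depth by sample ploidy.
DEFAULT_MIN_DEPTH = {2: 4, 3: 6, 4: 8, 5: 10}

REGION_CLASSES = ("exonic", "intronic", "upstream", "downstream", "intergenic")
CODING_CLASSES = ("silent", "missense", "nonsense")


@dataclass(frozen=True)
class PloidyConfig:
    """Sample ploidies and the ploidy-dependent depth minima."""

    ploidy: Dict[str, int] = field(default_factory=dict)
    min_depth: Dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_DEPTH))

    def min_depth_for(self, sample_id: str) -> int:
        if sample_id not in self.ploidy:
            raise KeyError(f"unknown sample {sample_id!r}")
        p = self.ploidy[sample_id]
        if p not in self.min_depth:
            raise KeyError(f"no depth minimum configured for ploidy {p}")
        return self.min_depth[p]


@dataclass(frozen=True)
class SnpQualityThresholds:
    """Mapping-quality and strand-support thresholds.

    ``require_both_strands`` demands alternate-supporting reads on both the
    forward and the reverse strand (SAF > 0 and SAR > 0), the usual
    strand-bias guard for SAF/SAR annotations.
    """

    min_mq: float = 20.0
    min_mqm: float = 20.0
    min_mqmr: float = 20.0
    require_both_strands: bool = True


@dataclass(frozen=True)
class SnpEffectClass:
    region: str
    coding: str = "not_applicable"

    def __post_init__(self):
        if self.region not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region!r}")
        if self.coding not in CODING_CLASSES + ("not_applicable",):
            raise ValueError(f"unknown coding class {self.coding!r}")


def _passes(rec: VariantRecord, min_depth: int, q: SnpQualityThresholds) -> bool:
    if rec.depth is None or rec.depth < min_depth:
        return False
    if rec.mq is None or rec.mq < q.min_mq:
        return False
    if rec.mqm is None or rec.mqm < q.min_mqm:
        return False
    if rec.mqmr is None or rec.mqmr < q.min_mqmr:
        return False
    if q.require_both_strands:
        if rec.saf is None or rec.sar is None or rec.saf <= 0 or rec.sar <= 0:
            return False
    return True


def filter_variants(
    records: Iterable[VariantRecord],
    sample_id: str,
    quality: SnpQualityThresholds = SnpQualityThresholds(),
    ploidy_config: PloidyConfig = PloidyConfig(),
) -> List[VariantRecord]:
    """Keep records meeting the depth, mapping-quality and strand rules.

    A record missing a field that an active threshold needs fails that
    rule.  The filter is a subset operation and idempotent.
    """
    min_depth = ploidy_config.min_depth_for(sample_id)
    return [r for r in records if _passes(r, min_depth, quality)]


def classify_site(rec: VariantRecord) -> str:
    """One of homozygous_ref / biallelic_B / biallelic_other / multiallelic.

    ``biallelic_B`` is a biallelic genotype carrying at least one reference
    and at least one alternate allele; a genotype that is purely one
    alternate allele is ``biallelic_other``; two or more distinct alternate
    alleles make the site ``multiallelic``.
    """
    if not rec.genotype:
        raise ValueError(f"{rec.chrom}:{rec.pos}: empty genotype")
    alts = {a for a in rec.genotype if a != 0}
    if len(alts) >= 2:
        return "multiallelic"
    if not alts:
        return "homozygous_ref"
    if 0 in rec.genotype:
        return "biallelic_B"
    return "biallelic_other"


def is_heterozygous(genotype: Sequence[int], mode: str = "strict") -> bool:
    """Heterozygosity of a ploidy-length genotype.

    ``strict`` requires two distinct allele indices in the genotype (the
    standard definition); ``alt-any`` counts any genotype carrying at
    least one non-reference allele, the looser convention sometimes used
    when profiling divergence from a reference.
    """
    if not genotype:
        raise ValueError("empty genotype")
    if mode == "strict":
        return len(set(genotype)) >= 2
    if mode == "alt-any":
        return any(a != 0 for a in genotype)
    raise ValueError(f"unknown heterozygosity mode {mode!r}")


def het_profile(
    records: Iterable[VariantRecord],
    chrom_lengths: Dict[str, int],
    mode: str = "strict",
) -> pd.DataFrame:
    """Per-chromosome heterozygosity table for one sample's records.

    Emits, per chromosome: number of sites, heterozygous sites, the
    within-chromosome het fraction, heterozygous sites per Mb, and each
    chromosome's share of all heterozygous sites; rows are ranked by that
    share (descending).
    """
    n_sites: Counter = Counter()
    n_het: Counter = Counter()
    for rec in records:
        n_sites[rec.chrom] += 1
        if is_heterozygous(rec.genotype, mode=mode):
            n_het[rec.chrom] += 1
    total_het = sum(n_het.values())
    rows = []
    for chrom in sorted(chrom_lengths):
        sites = n_sites.get(chrom, 0)
        het = n_het.get(chrom, 0)
        rows.append(
            {
                "chrom": chrom,
                "length_bp": chrom_lengths[chrom],
                "n_sites": sites,
                "n_het": het,
                "het_fraction": het / sites if sites else 0.0,
                "het_per_mb": het / (chrom_lengths[chrom] / 1e6),
                "share_of_het": het / total_het if total_het else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["share_of_het", "chrom"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Effect classification


def _cds_offset(gene: GeneModel, pos0: int) -> Optional[int]:
    """0-based offset of genomic position within the spliced CDS, 5'->3'."""
    offset = 0
    for c in gene.cds:
        if c.start <= pos0 < c.end:
            if gene.strand == "+":
                return offset + (pos0 - c.start)
            return offset + (c.end - 1 - pos0)
        offset += c.length()
    return None


def _spliced_cds(gene: GeneModel, genome: Dict[str, str]) -> str:
    chrom_seq = genome[gene.body.chrom]
    parts = [chrom_seq[c.start : c.end] for c in sorted(gene.cds)]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def annotate_effect(
    rec: VariantRecord,
    genes: Sequence[GeneModel],
    genome: Dict[str, str],
    flank: int = 5000,
) -> SnpEffectClass:
    """Region and coding effect of a single-nucleotide substitution.

    Region priority is exonic > intronic > upstream > downstream >
    intergenic across all genes (flanks are strand-aware, ``flank`` bp
    from the gene body).  For sites inside a CDS, the affected codon is
    translated with and without the first alternate allele under the
    standard nuclear code.
    """
    if not rec.is_snv:
        raise ValueError("coding annotation supports single-nucleotide substitutions")
    pos0 = rec.pos - 1
    ref_base = genome[rec.chrom][pos0]
    if ref_base != rec.ref_allele:
        raise ValueError(
            f"{rec.chrom}:{rec.pos}: VCF REF {rec.ref_allele} does not match "
            f"genome base {ref_base}"
        )
    best_rank = len(REGION_CLASSES) - 1  # intergenic
    cds_gene: Optional[GeneModel] = None
    for g in genes:
        if g.body.chrom != rec.chrom:
            continue
        region = _region_for_gene(g, pos0, flank)
        if region is None:
            continue
        rank = REGION_CLASSES.index(region)
        if rank < best_rank:
            best_rank = rank
        if region == "exonic" and cds_gene is None and _cds_offset(g, pos0) is not None:
            cds_gene = g
    region = REGION_CLASSES[best_rank]
    if region != "exonic" or cds_gene is None:
        return SnpEffectClass(region=region)
    return SnpEffectClass(
        region="exonic",
        coding=_coding_effect(cds_gene, genome, pos0, rec.alt_alleles[0]),
    )


def _region_for_gene(gene: GeneModel, pos0: int, flank: int) -> Optional[str]:
    body = gene.body
    if body.start <= pos0 < body.end:
        for ex in gene.exons:
            if ex.start <= pos0 < ex.end:
                return "exonic"
        return "intronic" if gene.exons else "exonic"
    if gene.strand == "+":
        upstream = body.start - flank <= pos0 < body.start
        downstream = body.end <= pos0 < body.end + flank
    else:
        upstream = body.end <= pos0 < body.end + flank
        downstream = body.start - flank <= pos0 < body.start
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return None


def _coding_effect(
    gene: GeneModel, genome: Dict[str, str], pos0: int, alt: str
) -> str:
    offset = _cds_offset(gene, pos0)
    assert offset is not None
    cds = _spliced_cds(gene, genome)
    alt_base = alt if gene.strand == "+" else str(Seq(alt).reverse_complement())
    codon_i = offset // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon of an incomplete model
        return "not_applicable"
    mutated = codon[: offset % 3] + alt_base + codon[offset % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == aa_ref:
        return "silent"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


class GeneIndex:
    """Per-chromosome start-sorted gene lookup for flank-aware queries."""

    def __init__(self, genes: Sequence[GeneModel], flank: int):
        self.flank = flank
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        self._starts: Dict[str, List[int]] = {}
        self._max_span: Dict[str, int] = {}
        for g in sorted(genes, key=lambda g: (g.body.chrom, g.body.start)):
            self._by_chrom.setdefault(g.body.chrom, []).append(g)
        for chrom, gs in self._by_chrom.items():
            self._starts[chrom] = [g.body.start - flank for g in gs]
            self._max_span[chrom] = max(g.body.length() + 2 * flank for g in gs)

    def candidates(self, chrom: str, pos0: int) -> List[GeneModel]:
        import bisect

        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        starts = self._starts[chrom]
        hi = bisect.bisect_right(starts, pos0)
        out = []
        i = hi - 1
        floor = pos0 - self._max_span[chrom]
        while i >= 0 and starts[i] >= floor:
            g = gs[i]
            if g.body.start - self.flank <= pos0 < g.body.end + self.flank:
                out.append(g)
            i -= 1
        return out


def annotate_effects(
    records: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    genome: Dict[str, str],
    flank: int = 5000,
) -> List[SnpEffectClass]:
    """Classify many substitution records with one shared gene index."""
    index = GeneIndex(genes, flank) if genes else None
    out = []
    for rec in records:
        cands = index.candidates(rec.chrom, rec.pos - 1) if index else []
        out.append(annotate_effect(rec, cands, genome, flank=flank))
    return out


def summarize_effects(effects: Sequence[SnpEffectClass]) -> Dict[str, pd.DataFrame]:
    """Counts and fractions per region class and per coding class.

    Region fractions sum to 1 over all classified variants; coding
    fractions sum to 1 over CDS variants only.  When no CDS variant is
    present the ``coding`` table is omitted.
    """
    if not effects:
        raise ValueError("no effects to summarize")
    region_counts = Counter(e.region for e in effects)
    n = len(effects)
    region = pd.DataFrame(
        {
            "class": list(REGION_CLASSES),
            "count": [region_counts.get(c, 0) for c in REGION_CLASSES],
        }
    )
    region["fraction"] = region["count"] / n
    out = {"region": region}
    coding_counts = Counter(
        e.coding for e in effects if e.coding != "not_applicable"
    )
    n_coding = sum(coding_counts.values())
    if n_coding:
        coding = pd.DataFrame(
            {
                "class": list(CODING_CLASSES),
                "count": [coding_counts.get(c, 0) for c in CODING_CLASSES],
            }
        )
        coding["fraction"] = coding["count"] / n_coding
        out["coding"] = coding
    return out
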