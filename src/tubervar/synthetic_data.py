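"""Desk-scale synthetic inputs with known truth for every pipeline stage.

The generator emulates the shape of a mixed-ploidy potato panel analysed
against a single reference: a small multi-chromosome genome with intron
containing protein-coding genes, per-sample CNVnator-style call files with
planted CNV-enriched gene clusters and group-structured background
profiles, and per-sample VCFs whose genotype length and depth statistics
follow each sample's ploidy.  Everything derives from one integer seed and
is emitted in the same file dialects the real pipeline reads, so the I/O
layer is part of the tested surface.

What it does NOT emulate: realistic chromosome sizes, sequencing error,
linkage disequilibrium, or read-level data — the simulation starts at the
call level, where this pipeline's own computation begins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from tubervar.cnv_impact import STATUS_DELETED, STATUS_DUPLICATED, STATUS_NEUTRAL
from tubervar.io_formats import (
    CnvCall,
    GeneModel,
    GenomicInterval,
    write_cnv_calls,
    write_fasta,
    write_gff3,
)
from tubervar.snp_profile import DEFAULT_MIN_DEPTH, VariantRecord

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

#: The mixed-ploidy panel the generator emulates by default: twelve
#: accessions spanning 2x-5x, grouped by taxonomic affinity (the bitter
#: potatoes form one group, the wild outlier its own).
DEFAULT_PANEL = [
    ("GON1", 2, "stenotomum"),
    ("GON2", 2, "stenotomum"),
    ("PHU", 2, "stenotomum"),
    ("STN", 2, "stenotomum"),
    ("CHA", 3, "stenotomum"),
    ("ADG1", 4, "andigena"),
    ("ADG2", 4, "andigena"),
    ("TBR", 4, "andigena"),
    ("AJH", 2, "bitter"),
    ("JUZ", 3, "bitter"),
    ("CUR", 5, "bitter"),
    ("BUK", 2, "wild"),
]


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    ploidy: int
    group: str


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults give a 5 x 2-Mb genome with 600 genes, three planted
    CNV-enriched clusters of 20 genes each inside 200-kb regions, a 2%
    background per-gene impact rate, 95% within-group status agreement,
    and a heterozygosity hotspot on the first chromosome (3x the base
    per-bp site rate).
    """

    n_chroms: int = 5
    chrom_length: int = 2_000_000
    n_genes: int = 600
    gene_length_range: Tuple[int, int] = (2_000, 6_000)
    samples: List[SampleSpec] = field(
        default_factory=lambda: [SampleSpec(*row) for row in DEFAULT_PANEL]
    )
    n_planted_clusters: int = 3
    cluster_gene_count: int = 20
    cluster_span: int = 200_000
    background_impact_rate: float = 0.02
    within_group_agreement: float = 0.95
    decoy_fraction: float = 0.0
    het_rate_base: float = 5e-4
    het_hotspot_chrom_index: int = 0
    het_hotspot_multiplier: float = 3.0
    type_b_fraction: float = 0.90
    hom_alt_fraction: float = 0.05
    snp_violation_fraction: float = 0.0
    missing_gt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.gene_length_range
        if lo <= 1000:
            raise ValueError("minimum gene length must exceed 1000 bp so planted "
                             "calls pass the size filter")
        if lo > hi:
            raise ValueError("gene_length_range must be (low, high)")
        for rate in (
            self.background_impact_rate,
            self.within_group_agreement,
            self.decoy_fraction,
            self.snp_violation_fraction,
            self.missing_gt_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and probabilities must lie in [0,1]")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names}

    def het_rate(self, chrom: str) -> float:
        hotspot = self.chrom_names[self.het_hotspot_chrom_index]
        mult = self.het_hotspot_multiplier if chrom == hotspot else 1.0
        return self.het_rate_base * mult


@dataclass
class SimLayout:
    """Gene placement plus the planted cluster regions."""

    chrom_lengths: Dict[str, int]
    genes: List[GeneModel]
    cluster_regions: List[GenomicInterval]
    cluster_gene_ids: List[List[str]]


@dataclass
class SimTruth:
    """Ground truth recorded alongside the emitted files."""

    statuses: pd.DataFrame  # samples x genes, entries in {1,2,3}
    cluster_regions: List[GenomicInterval]
    cluster_gene_ids: List[List[str]]
    groups: Dict[str, str]
    het_rates: Dict[str, float]
    snp_pass: Dict[str, List[bool]] = field(default_factory=dict)
    n_decoys: Dict[str, int] = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


# ---------------------------------------------------------------------------
# Reference layout and sequence


def _build_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str
) -> GeneModel:
    """One two-exon gene with a complete CDS split across the intron."""
    # exon1 | intron | exon2, with short UTRs at both CDS ends
    e1 = start + max(300, int(length * 0.4))
    i2 = e1 + max(60, int(length * 0.2))
    end = start + length
    utr5, utr3 = 90, 90
    c0 = start + utr5
    c3 = end - utr3
    cds_len = (e1 - c0) + (c3 - i2)
    c3 -= cds_len % 3
    exons = [GenomicInterval(chrom, start, e1), GenomicInterval(chrom, i2, end)]
    cds = [GenomicInterval(chrom, c0, e1), GenomicInterval(chrom, i2, c3)]
    if strand == "-":
        cds = cds[::-1]
    return GeneModel(
        gene_id=gene_id,
        body=GenomicInterval(chrom, start, end),
        strand=strand,
        exons=exons,
        cds=cds,
    )


def simulate_layout(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> SimLayout:
    """Place cluster regions and genes; deterministic given the config seed.

    Each planted cluster is a ``cluster_span`` region holding
    ``cluster_gene_count`` consecutive genes; the remaining genes are
    spread in non-overlapping slots over the rest of the genome.
    """
    rng = rng if rng is not None else _rng(cfg.seed)
    n_cluster_genes = cfg.n_planted_clusters * cfg.cluster_gene_count
    if n_cluster_genes > cfg.n_genes:
        raise ValueError("cluster genes exceed total genes")
    if cfg.n_planted_clusters > cfg.n_chroms:
        raise ValueError("need at most one planted cluster per chromosome")
    if cfg.cluster_span >= cfg.chrom_length:
        raise ValueError("cluster_span must be smaller than the chromosome")
    lo, hi = cfg.gene_length_range
    cluster_slot = cfg.cluster_span // cfg.cluster_gene_count
    if cluster_slot - 10 <= lo:
        raise ValueError(
            "cluster genes do not fit: increase cluster_span or reduce "
            "cluster_gene_count / gene length"
        )

    cluster_regions: List[GenomicInterval] = []
    genes: List[GeneModel] = []
    cluster_gene_spans: List[List[Tuple[str, int, int]]] = []
    for ci in range(cfg.n_planted_clusters):
        chrom = cfg.chrom_names[ci]
        start = int(rng.integers(0, cfg.chrom_length - cfg.cluster_span))
        region = GenomicInterval(chrom, start, start + cfg.cluster_span)
        cluster_regions.append(region)
        spans = []
        for k in range(cfg.cluster_gene_count):
            slot_start = start + k * cluster_slot
            g_len = int(rng.integers(lo, min(hi, cluster_slot - 10) + 1))
            g_start = slot_start + int(rng.integers(0, max(1, cluster_slot - g_len)))
            spans.append((chrom, g_start, g_len))
        cluster_gene_spans.append(spans)

    # background genes in slots over the non-cluster genome
    n_background = cfg.n_genes - n_cluster_genes
    segments: List[Tuple[str, int, int]] = []
    for chrom in cfg.chrom_names:
        blocked = [r for r in cluster_regions if r.chrom == chrom]
        cursor = 0
        for r in sorted(blocked, key=lambda r: r.start):
            if r.start > cursor:
                segments.append((chrom, cursor, r.start))
            cursor = r.end
        if cursor < cfg.chrom_length:
            segments.append((chrom, cursor, cfg.chrom_length))
    total_free = sum(e - s for _, s, e in segments)
    # a spare slot per segment absorbs fragmentation at segment boundaries
    slot_size = (
        total_free // (n_background + len(segments)) if n_background else total_free
    )
    if n_background and slot_size < hi + 20:
        raise ValueError(
            "genes do not fit: increase chrom_length or reduce n_genes"
        )
    background_spans: List[Tuple[str, int, int]] = []
    remaining = n_background
    for chrom, seg_s, seg_e in segments:
        if remaining == 0:
            break
        seg_len = seg_e - seg_s
        n_here = min(remaining, seg_len // slot_size)
        for k in range(n_here):
            slot_start = seg_s + k * slot_size
            g_len = int(rng.integers(lo, hi + 1))
            g_start = slot_start + int(rng.integers(0, slot_size - g_len))
            background_spans.append((chrom, g_start, g_len))
        remaining -= n_here
    if remaining:
        raise ValueError("genes do not fit: increase chrom_length or reduce n_genes")

    all_spans = [s for spans in cluster_gene_spans for s in spans] + background_spans
    all_spans.sort(key=lambda t: (t[0], t[1]))
    span_to_id = {}
    for i, span in enumerate(all_spans):
        span_to_id[span] = f"g{i + 1:04d}"
    strands = rng.choice(["+", "-"], size=len(all_spans))
    for span, strand in zip(all_spans, strands):
        chrom, start, length = span
        genes.append(_build_gene(span_to_id[span], chrom, start, length, str(strand)))
    cluster_gene_ids = [
        sorted(span_to_id[s] for s in spans) for spans in cluster_gene_spans
    ]
    return SimLayout(
        chrom_lengths=cfg.chrom_lengths,
        genes=genes,
        cluster_regions=cluster_regions,
        cluster_gene_ids=cluster_gene_ids,
    )


def simulate_sequences(
    cfg: SimConfig, layout: SimLayout, rng: Optional[np.random.Generator] = None
) -> Dict[str, str]:
    """Random chromosomes with valid coding sequence written into each CDS.

    Every gene's spliced CDS starts with ATG, ends with a stop codon and
    contains no internal stop, so translation checks hold genome-wide.
    """
    rng = rng if rng is not None else _rng(cfg.seed + 1)
    chroms = {
        name: rng.choice(BASES, size=length)
        for name, length in layout.chrom_lengths.items()
    }
    comp = str.maketrans("ACGT", "TGCA")
    for gene in layout.genes:
        cds_len = gene.cds_length
        n_codons = cds_len // 3
        body_codons = rng.choice(SENSE_CODONS, size=n_codons - 2)
        stop = rng.choice(sorted(STOP_CODONS))
        coding = "ATG" + "".join(body_codons) + stop
        if gene.strand == "-":
            coding = coding.translate(comp)[::-1]
        cursor = 0
        for c in sorted(gene.cds):
            seg = coding[cursor : cursor + c.length()]
            chroms[c.chrom][c.start : c.end] = list(seg)
            cursor += c.length()
    return {name: "".join(arr) for name, arr in chroms.items()}


# ---------------------------------------------------------------------------
# CNV profiles


def simulate_statuses(
    cfg: SimConfig, layout: SimLayout, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Planted per-sample ternary statuses (samples x genes).

    Cluster genes carry their planted status in every sample (alternating
    duplication/deletion per cluster).  Background genes follow a
    per-group archetype drawn at ``background_impact_rate``; each sample
    copies its archetype gene-wise with probability
    ``within_group_agreement`` and otherwise redraws from the background
    distribution.
    """
    rng = rng if rng is not None else _rng(cfg.seed + 2)
    gene_ids = [g.gene_id for g in layout.genes]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cluster_status = {}
    for ci, ids in enumerate(layout.cluster_gene_ids):
        code = STATUS_DUPLICATED if ci % 2 == 0 else STATUS_DELETED
        for gid in ids:
            cluster_status[gid] = code

    def draw_background(n: int) -> np.ndarray:
        impacted = rng.random(n) < cfg.background_impact_rate
        types = rng.choice([STATUS_DUPLICATED, STATUS_DELETED], size=n)
        return np.where(impacted, types, STATUS_NEUTRAL).astype(np.int8)

    groups = sorted({s.group for s in cfg.samples})
    archetypes = {g: draw_background(len(gene_ids)) for g in groups}
    for gid, code in cluster_status.items():
        for g in groups:
            archetypes[g][gene_index[gid]] = code

    rows = []
    is_cluster = np.array([g in cluster_status for g in gene_ids])
    for spec in cfg.samples:
        base = archetypes[spec.group].copy()
        deviate = (rng.random(len(gene_ids)) >= cfg.within_group_agreement) & ~is_cluster
        redraw = draw_background(len(gene_ids))
        rows.append(np.where(deviate, redraw, base))
    return pd.DataFrame(
        np.vstack(rows), index=[s.sample_id for s in cfg.samples], columns=gene_ids
    )


def statuses_to_calls(
    cfg: SimConfig,
    layout: SimLayout,
    statuses: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, List[CnvCall]], Dict[str, int]]:
    """Realize planted statuses as CNVnator-style calls.

    Every impacted gene gets one call covering its whole body (plus a
    small margin) that passes the size/p/q0 filter; with a nonzero
    ``decoy_fraction`` extra calls each violating exactly one filter rule
    are mixed in, so the post-filter call set reproduces the truth
    exactly.
    """
    rng = rng if rng is not None else _rng(cfg.seed + 3)
    gene_by_id = {g.gene_id: g for g in layout.genes}
    calls: Dict[str, List[CnvCall]] = {}
    n_decoys: Dict[str, int] = {}
    for sample_id in statuses.index:
        row = statuses.loc[sample_id]
        sample_calls: List[CnvCall] = []
        for gid, status in row.items():
            if status == STATUS_NEUTRAL:
                continue
            g = gene_by_id[gid]
            chrom_len = layout.chrom_lengths[g.body.chrom]
            start = max(0, g.body.start - 500)
            end = min(chrom_len, g.body.end + 500)
            cnv_type = "duplication" if status == STATUS_DUPLICATED else "deletion"
            depth = (
                float(rng.uniform(1.5, 3.0))
                if cnv_type == "duplication"
                else float(rng.uniform(0.0, 0.5))
            )
            sample_calls.append(
                CnvCall(
                    sample_id=sample_id,
                    interval=GenomicInterval(g.body.chrom, start, end),
                    cnv_type=cnv_type,
                    norm_depth=depth,
                    p_value=float(10 ** rng.uniform(-8, -2.1)),
                    q0_fraction=float(rng.uniform(0.0, 0.45)),
                )
            )
        n_decoy = 0
        if cfg.decoy_fraction > 0 and sample_calls:
            n_true = len(sample_calls)
            n_decoy = round(n_true * cfg.decoy_fraction / (1 - cfg.decoy_fraction))
            for k in range(n_decoy):
                chrom = cfg.chrom_names[int(rng.integers(0, cfg.n_chroms))]
                violation = k % 3
                length = 800 if violation == 0 else 5000
                start = int(rng.integers(0, cfg.chrom_length - length))
                sample_calls.append(
                    CnvCall(
                        sample_id=sample_id,
                        interval=GenomicInterval(chrom, start, start + length),
                        cnv_type="deletion" if k % 2 else "duplication",
                        norm_depth=float(rng.uniform(0.0, 3.0)),
                        p_value=float(rng.uniform(0.02, 0.5))
                        if violation == 1
                        else float(10 ** rng.uniform(-8, -2.1)),
                        q0_fraction=float(rng.uniform(0.55, 0.95))
                        if violation == 2
                        else float(rng.uniform(0.0, 0.45)),
                    )
                )
        sample_calls.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.cnv_type))
        calls[sample_id] = sample_calls
        n_decoys[sample_id] = n_decoy
    return calls, n_decoys


def plant_cnv_profiles(
    cfg: SimConfig, layout: SimLayout, rng: Optional[np.random.Generator] = None
) -> Tuple[Dict[str, List[CnvCall]], SimTruth]:
    """Per-sample call sets plus the recorded truth."""
    rng = rng if rng is not None else _rng(cfg.seed + 2)
    statuses = simulate_statuses(cfg, layout, rng)
    calls, n_decoys = statuses_to_calls(cfg, layout, statuses, rng)
    truth = SimTruth(
        statuses=statuses,
        cluster_regions=layout.cluster_regions,
        cluster_gene_ids=layout.cluster_gene_ids,
        groups={s.sample_id: s.group for s in cfg.samples},
        het_rates={c: cfg.het_rate(c) for c in cfg.chrom_names},
        n_decoys=n_decoys,
    )
    return calls, truth


def simulate_group_matrix(
    n_groups: int = 3,
    samples_per_group: int = 4,
    n_genes: int = 300,
    within_agreement: float = 0.95,
    between_agreement: float = 0.6,
    seed: int = 0,
) -> Tuple["pd.DataFrame", Dict[str, str]]:
    """Ternary status matrix with planted sample groups.

    ``within_agreement`` and ``between_agreement`` are target pairwise
    gene-status agreement probabilities for sample pairs inside and across
    groups.  Internally each group archetype copies an ancestral uniform
    ternary row with a calibrated retention probability and each sample
    copies its archetype likewise, which makes the expected pairwise
    agreements hit the targets exactly.

    Returns the samples x genes status table and the sample -> group map.
    """
    if not (1 / 3 <= between_agreement <= within_agreement <= 1):
        raise ValueError(
            "need 1/3 <= between_agreement <= within_agreement <= 1"
        )
    rng = _rng(seed)
    # pairwise agreement of two rows that both copy a common row with
    # probability r (else redraw uniform over 3 states) is r^2 + (1-r^2)/3
    p_sq = (3 * within_agreement - 1) / 2
    arch_match = (between_agreement - (1 - p_sq) / 3) / p_sq
    q_sq = (3 * arch_match - 1) / 2
    if not (0 <= q_sq <= 1):
        raise ValueError("agreement targets are not jointly attainable")
    p, q = np.sqrt(p_sq), np.sqrt(q_sq)

    def copy_with_noise(base: np.ndarray, retain: float) -> np.ndarray:
        redraw = rng.random(base.size) >= retain
        fresh = rng.integers(1, 4, size=base.size)
        return np.where(redraw, fresh, base).astype(np.int8)

    ancestral = rng.integers(1, 4, size=n_genes).astype(np.int8)
    rows, index, groups = [], [], {}
    for gi in range(n_groups):
        group = f"G{gi + 1}"
        archetype = copy_with_noise(ancestral, q)
        for si in range(samples_per_group):
            sample = f"{group}_s{si + 1}"
            rows.append(copy_with_noise(archetype, p))
            index.append(sample)
            groups[sample] = group
    return pd.DataFrame(np.vstack(rows), index=index,
                        columns=[f"g{j + 1:04d}" for j in range(n_genes)]), groups


# ---------------------------------------------------------------------------
# SNPs


_VIOLATIONS = ("depth", "mq", "mqm", "mqmr", "saf", "sar")


def simulate_variant_records(
    cfg: SimConfig,
    sequences: Dict[str, str],
    sample: SampleSpec,
    rng: np.random.Generator,
) -> Tuple[List[VariantRecord], List[bool]]:
    """One sample's sites with ploidy-length genotypes and quality fields.

    Sites arise per chromosome at the configured per-bp rate (with the
    hotspot chromosome elevated).  A ``snp_violation_fraction`` of records
    is made to violate exactly one filter rule; the returned boolean list
    marks the records intended to pass.
    """
    min_depth = DEFAULT_MIN_DEPTH[sample.ploidy]
    records: List[VariantRecord] = []
    passes: List[bool] = []
    base_set = "ACGT"
    for chrom in cfg.chrom_names:
        seq = sequences[chrom]
        rate = cfg.het_rate(chrom)
        n_sites = int(rng.poisson(rate * len(seq)))
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False)
        )
        for pos0 in positions:
            ref = seq[pos0]
            if ref not in base_set:
                continue
            others = [b for b in base_set if b != ref]
            alt = others[int(rng.integers(0, 3))]
            u = rng.random()
            if u < cfg.type_b_fraction:
                n_alt = int(rng.integers(1, sample.ploidy))
                genotype = [0] * (sample.ploidy - n_alt) + [1] * n_alt
                alts = [alt]
            elif u < cfg.type_b_fraction + cfg.hom_alt_fraction:
                genotype = [1] * sample.ploidy
                alts = [alt]
            else:
                alt2 = [b for b in others if b != alt][int(rng.integers(0, 2))]
                alts = [alt, alt2]
                if sample.ploidy == 2:
                    genotype = [1, 2]
                else:
                    genotype = [0] * (sample.ploidy - 2) + [1, 2]
            depth = int(max(min_depth, rng.poisson(2 * min_depth)))
            n_alt_reads = max(2, int(round(depth * sum(a != 0 for a in genotype) / sample.ploidy)))
            saf = int(rng.integers(1, n_alt_reads))
            sar = n_alt_reads - saf
            rec = VariantRecord(
                chrom=chrom,
                pos=int(pos0) + 1,
                ref_allele=ref,
                alt_alleles=alts,
                genotype=genotype,
                depth=depth,
                mq=float(np.round(rng.uniform(25, 60), 1)),
                mqm=float(np.round(rng.uniform(25, 60), 1)),
                mqmr=float(np.round(rng.uniform(25, 60), 1)),
                saf=max(1, saf),
                sar=max(1, sar),
            )
            ok = True
            if rng.random() < cfg.snp_violation_fraction:
                ok = False
                rule = _VIOLATIONS[int(rng.integers(0, len(_VIOLATIONS)))]
                if rule == "depth":
                    rec.depth = int(rng.integers(0, min_depth))
                elif rule == "mq":
                    rec.mq = float(np.round(rng.uniform(0, 19.5), 1))
                elif rule == "mqm":
                    rec.mqm = float(np.round(rng.uniform(0, 19.5), 1))
                elif rule == "mqmr":
                    rec.mqmr = float(np.round(rng.uniform(0, 19.5), 1))
                elif rule == "saf":
                    rec.saf = 0
                else:
                    rec.sar = 0
            records.append(rec)
            passes.append(ok)
    return records, passes


def write_vcf(
    records: List[VariantRecord],
    sample: SampleSpec,
    chrom_lengths: Dict[str, int],
    path,
    missing_gt_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Write a single-sample VCF 4.2 with the fields the filter consumes."""
    rng = rng if rng is not None else _rng(0)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=tubervar-simulate",
    ]
    for chrom in sorted(chrom_lengths):
        lines.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQM,Number=A,Type=Float,Description="Mean mapping quality of alt-supporting reads">',
        '##INFO=<ID=MQMR,Number=1,Type=Float,Description="Mean mapping quality of ref-supporting reads">',
        '##INFO=<ID=SAF,Number=A,Type=Integer,Description="Alt-supporting reads on the forward strand">',
        '##INFO=<ID=SAR,Number=A,Type=Integer,Description="Alt-supporting reads on the reverse strand">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample.sample_id,
    ]
    for rec in records:
        n_alts = len(rec.alt_alleles)
        info = ";".join(
            [
                f"DP={rec.depth}",
                f"MQ={rec.mq:g}",
                "MQM=" + ",".join(f"{rec.mqm:g}" for _ in range(n_alts)),
                f"MQMR={rec.mqmr:g}",
                "SAF=" + ",".join(str(rec.saf) for _ in range(n_alts)),
                "SAR=" + ",".join(str(rec.sar) for _ in range(n_alts)),
            ]
        )
        if missing_gt_fraction > 0 and rng.random() < missing_gt_fraction:
            gt = "/".join("." for _ in range(len(rec.genotype)))
        else:
            gt = "/".join(str(a) for a in rec.genotype)
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    ".",
                    rec.ref_allele,
                    ",".join(rec.alt_alleles),
                    "60",
                    "PASS",
                    info,
                    "GT:DP",
                    f"{gt}:{rec.depth}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_snps(
    cfg: SimConfig,
    sequences: Dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, List[VariantRecord]], Dict[str, List[bool]]]:
    """All samples' variant records plus pass/fail truth labels."""
    rng = rng if rng is not None else _rng(cfg.seed + 4)
    records: Dict[str, List[VariantRecord]] = {}
    passes: Dict[str, List[bool]] = {}
    for spec in cfg.samples:
        recs, ok = simulate_variant_records(cfg, sequences, spec, rng)
        records[spec.sample_id] = recs
        passes[spec.sample_id] = ok
    return records, passes


# ---------------------------------------------------------------------------
# Full fixture emission


def generate_all(cfg: SimConfig, outdir) -> SimTruth:
    """Emit the full fixture tree (reference/, cnv/, vcf/, truth/).

    The files use exactly the dialects the pipeline readers consume; the
    truth tables record planted statuses, cluster regions, group labels,
    per-chromosome site rates and per-record SNP filter truth.
    """
    outdir = Path(outdir)
    for sub in ("reference", "cnv", "vcf", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    layout = simulate_layout(cfg)
    sequences = simulate_sequences(cfg, layout)
    write_fasta(sequences, outdir / "reference" / "genome.fa")
    write_gff3(layout.genes, outdir / "reference" / "annotation.gff3")
    calls, truth = plant_cnv_profiles(cfg, layout)
    for sample_id, sample_calls in calls.items():
        write_cnv_calls(sample_calls, outdir / "cnv" / f"{sample_id}.cnv.tsv")
    snp_records, snp_passes = simulate_snps(cfg, sequences)
    gt_rng = _rng(cfg.seed + 5)
    for spec in cfg.samples:
        write_vcf(
            snp_records[spec.sample_id],
            spec,
            cfg.chrom_lengths,
            outdir / "vcf" / f"{spec.sample_id}.vcf",
            missing_gt_fraction=cfg.missing_gt_fraction,
            rng=gt_rng,
        )
    truth.snp_pass = snp_passes
    with open(outdir / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tploidy\tgroup\n")
        for s in cfg.samples:
            fh.write(f"{s.sample_id}\t{s.ploidy}\t{s.group}\n")
    truth_json = {
        "cluster_regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end}
            for r in truth.cluster_regions
        ],
        "cluster_gene_ids": truth.cluster_gene_ids,
        "groups": truth.groups,
        "het_rates": truth.het_rates,
        "n_decoys": truth.n_decoys,
        "statuses": {
            s: [int(v) for v in truth.statuses.loc[s]]
            for s in truth.statuses.index
        },
        "genes": list(truth.statuses.columns),
        "snp_pass": {s: [bool(b) for b in v] for s, v in snp_passes.items()},
    }
    (outdir / "truth" / "truth.json").write_text(
        json.dumps(truth_json, indent=1, sort_keys=True)
    )
    return truth
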