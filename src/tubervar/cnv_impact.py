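"""CNV call filtering, gene-level impact annotation and genomic footprints.

Raw read-depth CNV calls are filtered on event size, significance and
mapping-quality contamination; surviving duplications and deletions are
intersected with gene bodies to give per-gene covered fractions; genes with
half or more of their body affected by one CNV type receive a ternary
status code (3 duplicated, 2 deleted, 1 not impacted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from tubervar.io_formats import CnvCall, GeneModel, GenomicInterval

#: Ternary gene status codes.
STATUS_DUPLICATED = 3
STATUS_DELETED = 2
STATUS_NEUTRAL = 1

#: Fraction of the gene body that must be covered for a gene to count as
#: CNV-impacted.
IMPACT_FRACTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class CnvFilterThresholds:
    """Size/significance thresholds for raw CNV calls.

    Defaults follow the study design: keep events strictly larger than
    1000 bp, with p <= 0.01 and a zero-mapping-quality read fraction
    strictly below 0.5.
    """

    min_size_bp: int = 1000
    max_p: float = 0.01
    max_q0: float = 0.5

    def __post_init__(self):
        if self.min_size_bp < 0:
            raise ValueError("min_size_bp must be >= 0")
        if not (0 <= self.max_p <= 1 and 0 <= self.max_q0 <= 1):
            raise ValueError("max_p and max_q0 must lie in [0,1]")


@dataclass
class GeneImpact:
    gene_id: str
    sample_id: str
    dup_fraction: float
    del_fraction: float
    status: int


def filter_cnv_calls(
    calls: Iterable[CnvCall], thresholds: CnvFilterThresholds = CnvFilterThresholds()
) -> List[CnvCall]:
    """Keep calls larger than ``min_size_bp`` with p <= max_p and q0 < max_q0.

    The size test is strict (an exactly 1000-bp event is removed under the
    defaults); order is preserved and the operation is idempotent.
    """
    return [
        c
        for c in calls
        if c.interval.length() > thresholds.min_size_bp
        and c.p_value <= thresholds.max_p
        and c.q0_fraction < thresholds.max_q0
    ]


def union_coverage(
    intervals: Sequence[GenomicInterval],
) -> Tuple[List[GenomicInterval], int]:
    """Merge intervals on one chromosome; return (merged, total bp covered).

    Touching intervals are merged, so the output is sorted, disjoint and
    non-adjacent.
    """
    if not intervals:
        return [], 0
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"union_coverage needs one chromosome, got {sorted(chroms)}")
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: List[GenomicInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end))
    return merged, sum(iv.length() for iv in merged)


def gene_impact_fraction(
    gene: GeneModel, calls: Sequence[CnvCall]
) -> Tuple[float, float]:
    """Fractions of the gene body covered by duplication and deletion calls.

    Same-type calls are unioned before intersecting with the gene body, so
    each fraction lies in [0,1] regardless of call overlap; the two types
    are measured independently.
    """
    if gene.body.length() == 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length body")
    out = {}
    for cnv_type in ("duplication", "deletion"):
        ivs = [
            c.interval
            for c in calls
            if c.cnv_type == cnv_type and c.interval.chrom == gene.body.chrom
        ]
        merged, _ = union_coverage(ivs) if ivs else ([], 0)
        covered = sum(iv.overlap_bp(gene.body) for iv in merged)
        out[cnv_type] = covered / gene.body.length()
    return out["duplication"], out["deletion"]


def assign_status(
    dup_fraction: float,
    del_fraction: float,
    threshold: float = IMPACT_FRACTION_THRESHOLD,
) -> int:
    """Ternary status from coverage fractions: 3 dup, 2 del, 1 neutral.

    A gene reaching the threshold for both types is coded by the larger
    fraction; an exact tie goes to duplication, keeping the ternary
    encoding well-defined.
    """
    if dup_fraction >= threshold and dup_fraction >= del_fraction:
        return STATUS_DUPLICATED
    if del_fraction >= threshold and del_fraction > dup_fraction:
        return STATUS_DELETED
    return STATUS_NEUTRAL


def gene_impacts(
    genes: Sequence[GeneModel],
    calls: Sequence[CnvCall],
    sample_id: str,
    threshold: float = IMPACT_FRACTION_THRESHOLD,
) -> List[GeneImpact]:
    """Per-gene impact rows for one sample's filtered calls."""
    by_chrom: Dict[str, List[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    out = []
    for g in genes:
        chrom_calls = by_chrom.get(g.body.chrom, [])
        relevant = [c for c in chrom_calls if c.interval.overlaps(g.body)]
        dup, dele = gene_impact_fraction(g, relevant)
        out.append(
            GeneImpact(
                gene_id=g.gene_id,
                sample_id=sample_id,
                dup_fraction=dup,
                del_fraction=dele,
                status=assign_status(dup, dele, threshold),
            )
        )
    return out


def cnv_footprint(calls: Sequence[CnvCall]) -> int:
    """Total bp of the genome covered by any CNV call (both types pooled)."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c.interval)
    return sum(union_coverage(ivs)[1] for ivs in by_chrom.values())


def shared_impacted_genes(
    impacts: Dict[str, Sequence[GeneImpact]],
    samples: Iterable[str] | None = None,
) -> Tuple[Set[str], Set[str], Set[str]]:
    """Genes impacted in every sample of the panel.

    Returns (shared_any, shared_dup, shared_del): genes with a non-neutral
    status in every sample, with status 3 in every sample, and with status
    2 in every sample.  The dup and del sets are disjoint subsets of
    shared_any.
    """
    sample_ids = list(samples) if samples is not None else list(impacts)
    unknown = [s for s in sample_ids if s not in impacts]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    shared_any: Set[str] | None = None
    shared_dup: Set[str] | None = None
    shared_del: Set[str] | None = None
    for s in sample_ids:
        any_s = {i.gene_id for i in impacts[s] if i.status != STATUS_NEUTRAL}
        dup_s = {i.gene_id for i in impacts[s] if i.status == STATUS_DUPLICATED}
        del_s = {i.gene_id for i in impacts[s] if i.status == STATUS_DELETED}
        shared_any = any_s if shared_any is None else shared_any & any_s
        shared_dup = dup_s if shared_dup is None else shared_dup & dup_s
        shared_del = del_s if shared_del is None else shared_del & del_s
    if shared_any is None:
        return set(), set(), set()
    return shared_any, shared_dup, shared_del


def impacts_to_frame(impacts: Sequence[GeneImpact]) -> pd.DataFrame:
    """Impact rows as a tidy table (gene_id, sample, fractions, status)."""
    return pd.DataFrame(
        {
            "gene_id": [i.gene_id for i in impacts],
            "sample": [i.sample_id for i in impacts],
            "dup_fraction": [i.dup_fraction for i in impacts],
            "del_fraction": [i.del_fraction for i in impacts],
            "status": [i.status for i in impacts],
        }
    )
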