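"""Sliding-window scan for CNV-enriched gene clusters.

Each chromosome is tiled with overlapping fixed-width bins (200 kb wide,
10 kb apart by default); the number of CNV-impacted genes overlapping each
bin is counted, and bins whose count reaches the genome-wide
mean + 3 standard deviations are merged into reportable clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from tubervar.cnv_impact import (
    GeneImpact,
    STATUS_DELETED,
    STATUS_DUPLICATED,
    STATUS_NEUTRAL,
)
from tubervar.io_formats import GeneModel, GenomicInterval


@dataclass(frozen=True)
class ScanParams:
    """Window geometry and significance multiplier for the scan."""

    bin_width: int = 200_000
    step: int = 10_000
    sd_multiplier: float = 3.0
    population_sd: bool = True

    def __post_init__(self):
        if not (0 < self.step <= self.bin_width):
            raise ValueError("need 0 < step <= bin_width")


@dataclass
class Cluster:
    """A maximal run of overlapping significant bins."""

    interval: GenomicInterval
    gene_ids: List[str]
    max_bin_count: int
    dominant_status: int  # 3 dup-majority / 2 del-majority among member genes


@dataclass
class ScanResult:
    bins: List[GenomicInterval]
    counts: np.ndarray
    threshold: float
    significant: List[Tuple[GenomicInterval, int]]
    clusters: List[Cluster] = field(default_factory=list)


def make_bins(chrom: str, chrom_length: int, params: ScanParams = ScanParams()) -> List[GenomicInterval]:
    """Overlapping fixed-width bins starting every ``step`` bp.

    Bins are placed at 0, step, 2*step, ... wherever a full-width bin fits;
    a chromosome shorter than one bin yields a single truncated bin.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if chrom_length < params.bin_width:
        return [GenomicInterval(chrom, 0, chrom_length)]
    starts = range(0, chrom_length - params.bin_width + 1, params.step)
    return [GenomicInterval(chrom, s, s + params.bin_width) for s in starts]


def count_impacted_per_bin(
    bins: Sequence[GenomicInterval], impacted_genes: Sequence[GeneModel]
) -> np.ndarray:
    """Impacted genes overlapping each bin by at least one bp.

    A gene spanning several overlapping bins is counted in every one.
    """
    counts = np.zeros(len(bins), dtype=int)
    if not bins or not impacted_genes:
        return counts
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in impacted_genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    starts = np.array([b.start for b in bins])
    ends = np.array([b.end for b in bins])
    chroms = np.array([b.chrom for b in bins])
    for chrom, genes in by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        bs, be = starts[mask], ends[mask]
        sub = np.zeros(bs.shape, dtype=int)
        for g in genes:
            sub += (g.body.start < be) & (bs < g.body.end)
        counts[mask] += sub
    return counts


def significance_threshold(
    all_counts: Sequence[int], params: ScanParams = ScanParams()
) -> float:
    """mean + sd_multiplier * SD over every bin genome-wide (one sample).

    The SD is the population SD by default (switchable to the sample SD).
    """
    counts = np.asarray(all_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cannot compute a threshold from zero bins")
    ddof = 0 if params.population_sd else 1
    sd = counts.std(ddof=ddof) if counts.size > ddof else 0.0
    return float(counts.mean() + params.sd_multiplier * sd)


def find_significant_bins(
    bins: Sequence[GenomicInterval],
    counts: np.ndarray,
    threshold: float,
) -> List[Tuple[GenomicInterval, int]]:
    """Bins whose count reaches the threshold.

    On a flat landscape (SD of counts == 0) the threshold degenerates to
    the common count and every bin would qualify; that case returns no
    bins.  Zero-count bins are never significant.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or counts.std(ddof=0) == 0:
        return []
    return [
        (b, int(c)) for b, c in zip(bins, counts) if c >= threshold and c > 0
    ]


def merge_to_clusters(
    significant: Sequence[Tuple[GenomicInterval, int]],
    impacted_genes: Sequence[GeneModel],
    impacts: Dict[str, int] | None = None,
) -> List[Cluster]:
    """Merge overlapping/adjacent significant bins into maximal clusters.

    Each cluster lists its member impacted genes and the dominant status
    among them (duplication vs deletion majority, tie to duplication).
    ``impacts`` maps gene_id -> status code for the scanned sample.
    """
    if not significant:
        return []
    by_chrom: Dict[str, List[Tuple[GenomicInterval, int]]] = {}
    for b, c in significant:
        by_chrom.setdefault(b.chrom, []).append((b, c))
    clusters: List[Cluster] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        cur_start, cur_end = items[0][0].start, items[0][0].end
        cur_max = items[0][1]
        merged: List[Tuple[GenomicInterval, int]] = []
        for b, c in items[1:]:
            if b.start <= cur_end:
                cur_end = max(cur_end, b.end)
                cur_max = max(cur_max, c)
            else:
                merged.append((GenomicInterval(chrom, cur_start, cur_end), cur_max))
                cur_start, cur_end, cur_max = b.start, b.end, c
        merged.append((GenomicInterval(chrom, cur_start, cur_end), cur_max))
        for iv, max_count in merged:
            members = [g for g in impacted_genes if g.body.overlaps(iv)]
            gene_ids = sorted(g.gene_id for g in members)
            n_dup = n_del = 0
            if impacts:
                statuses = [impacts.get(gid, STATUS_NEUTRAL) for gid in gene_ids]
                n_dup = sum(1 for s in statuses if s == STATUS_DUPLICATED)
                n_del = sum(1 for s in statuses if s == STATUS_DELETED)
            dominant = STATUS_DUPLICATED if n_dup >= n_del else STATUS_DELETED
            clusters.append(
                Cluster(
                    interval=iv,
                    gene_ids=gene_ids,
                    max_bin_count=max_count,
                    dominant_status=dominant,
                )
            )
    return clusters


def top_clusters(clusters: Sequence[Cluster], k: int = 3) -> List[Cluster]:
    """The ``k`` clusters with the highest peak bin count.

    Ties are broken by genomic position (chrom, start) ascending; fewer
    than ``k`` clusters are returned as-is.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        clusters,
        key=lambda c: (-c.max_bin_count, c.interval.chrom, c.interval.start),
    )
    return list(ranked[:k])


def scan_sample(
    genes: Sequence[GeneModel],
    impacts: Sequence[GeneImpact],
    chrom_lengths: Dict[str, int],
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Run the whole scan for one sample against one reference.

    Counts are pooled across all chromosomes before the threshold is
    computed, so the mean and SD describe the genome-wide bin landscape.
    """
    status = {i.gene_id: i.status for i in impacts}
    impacted = [g for g in genes if status.get(g.gene_id, STATUS_NEUTRAL) != STATUS_NEUTRAL]
    bins: List[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        bins.extend(make_bins(chrom, chrom_lengths[chrom], params))
    counts = count_impacted_per_bin(bins, impacted)
    threshold = significance_threshold(counts, params)
    significant = find_significant_bins(bins, counts, threshold)
    clusters = merge_to_clusters(significant, impacted, status)
    return ScanResult(
        bins=bins,
        counts=counts,
        threshold=threshold,
        significant=significant,
        clusters=clusters,
    )
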