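"""Domain types and file I/O for the pipeline's standard formats.

Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based
closed) and VCF (1-based positions) are converted at the boundary, so all
overlap arithmetic uses a single convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tubervar.tree import UnrootedTree, read_newick, write_newick  # noqa: F401

CNV_TYPES = ("deletion", "duplication")


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """One gene: body span, strand, and exon/CDS sub-intervals.

    ``cds`` is ordered 5'->3' on the coding strand (descending genomic
    coordinates for minus-strand genes).  ``complete`` marks models whose
    total CDS length is a multiple of three.
    """

    gene_id: str
    body: GenomicInterval
    strand: str
    exons: List[GenomicInterval] = field(default_factory=list)
    cds: List[GenomicInterval] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(c.length() for c in self.cds)

    @property
    def complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0


@dataclass
class CnvCall:
    """One read-depth CNV event for one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    norm_depth: float
    p_value: float
    q0_fraction: float

    def __post_init__(self):
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"unknown CNV type {self.cnv_type!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0,1]")
        if not 0.0 <= self.q0_fraction <= 1.0:
            raise ValueError(f"q0_fraction {self.q0_fraction} outside [0,1]")


@dataclass
class VariantRecord:
    """One VCF site for one sample, with the quality fields filtered on.

    ``pos`` keeps the VCF 1-based convention; ``genotype`` is the
    ploidy-length list of allele indices (0 = reference).  Quality fields
    absent from the file are ``None``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: List[str]
    genotype: List[int]
    depth: Optional[int] = None
    mq: Optional[float] = None
    mqm: Optional[float] = None
    mqmr: Optional[float] = None
    saf: Optional[int] = None
    sar: Optional[int] = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    path, line_no, f"expected 9 tab-separated columns, got {len(cols)}"
                )
            if cols[2] == "CDS" and "Parent=" not in cols[8]:
                raise ParseError(path, line_no, "CDS feature without Parent attribute")


def read_gff3(path) -> List[GeneModel]:
    """Read gene models from a GFF3 file.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Genes with multiple mRNAs collapse to the transcript with the longest
    summed CDS (ties broken by lexicographically smallest mRNA ID), so gene
    level counts always see one interval set per gene.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        body = GenomicInterval(gene.seqid, gene.start - 1, gene.end)
        mrnas = list(db.children(gene, featuretype="mRNA"))
        exons: List[GenomicInterval] = []
        cds: List[GenomicInterval] = []
        if mrnas:
            def cds_len(m):
                return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

            best = sorted(mrnas, key=lambda m: (-cds_len(m), m.id))[0]
            exon_feats = list(db.children(best, featuretype="exon"))
            cds_feats = list(db.children(best, featuretype="CDS"))
        else:
            exon_feats = list(db.children(gene, featuretype="exon"))
            cds_feats = list(db.children(gene, featuretype="CDS"))
        exons = sorted(
            GenomicInterval(f.seqid, f.start - 1, f.end) for f in exon_feats
        )
        cds = sorted(GenomicInterval(f.seqid, f.start - 1, f.end) for f in cds_feats)
        if gene.strand == "-":
            cds = cds[::-1]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                body=body,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                cds=cds,
            )
        )
    return genes


def write_gff3(genes: List[GeneModel], path, source: str = "tubervar") -> None:
    """Write gene models as GFF3 (one mRNA per gene), 1-based closed."""

    def line(chrom, ftype, iv, strand, attrs):
        return "\t".join(
            [chrom, source, ftype, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(line(g.body.chrom, "gene", g.body, g.strand, f"ID={g.gene_id}") + "\n")
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                line(g.body.chrom, "mRNA", g.body, g.strand,
                     f"ID={mrna_id};Parent={g.gene_id}") + "\n"
            )
            for i, ex in enumerate(sorted(g.exons), start=1):
                fh.write(
                    line(g.body.chrom, "exon", ex, g.strand,
                         f"ID={mrna_id}.exon{i};Parent={mrna_id}") + "\n"
                )
            for i, c in enumerate(sorted(g.cds), start=1):
                fh.write(
                    line(g.body.chrom, "CDS", c, g.strand,
                         f"ID={mrna_id}.cds{i};Parent={mrna_id}") + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CNVnator-style TSV

#: Column indices in CNVnator v0.3.x output: the reader keys on the first
#: two columns (type, region), norm-depth and the first e-val column, and
#: takes q0 as the last column.  Override via ``column_map`` for dialect
#: drift across versions.
DEFAULT_CNV_COLUMNS = {
    "cnv_type": 0,
    "region": 1,
    "length": 2,
    "norm_depth": 3,
    "p_value": 4,
    "q0": -1,
}


def read_cnv_calls(
    path,
    sample_id: str,
    column_map: Optional[Dict[str, int]] = None,
) -> List[CnvCall]:
    """Read a CNVnator-style whitespace-delimited call table.

    Region strings are 1-based closed and converted to half-open intervals.
    Rows whose type is neither ``deletion`` nor ``duplication`` are dropped.
    When the length column disagrees with the region coordinates, the
    coordinates win (with a warning).
    """
    cols = dict(DEFAULT_CNV_COLUMNS)
    if column_map:
        cols.update(column_map)
    calls: List[CnvCall] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(path, line_no, "too few columns for a CNV call row")
            cnv_type = fields[cols["cnv_type"]]
            if cnv_type not in CNV_TYPES:
                continue
            region = fields[cols["region"]]
            try:
                chrom, span = region.rsplit(":", 1)
                start_s, end_s = span.split("-")
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, line_no, f"malformed region string {region!r}") from None
            interval = GenomicInterval(chrom, start1 - 1, end1)
            try:
                stated_len = int(float(fields[cols["length"]]))
                norm_depth = float(fields[cols["norm_depth"]])
                p_value = float(fields[cols["p_value"]])
                q0 = float(fields[cols["q0"]])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric field: {exc}") from None
            if stated_len != interval.length():
                warnings.warn(
                    f"{path}:{line_no}: stated length {stated_len} != region length "
                    f"{interval.length()}; using coordinates"
                )
            calls.append(
                CnvCall(
                    sample_id=sample_id,
                    interval=interval,
                    cnv_type=cnv_type,
                    norm_depth=norm_depth,
                    p_value=p_value,
                    q0_fraction=q0,
                )
            )
    return calls


def write_cnv_calls(calls: List[CnvCall], path) -> None:
    """Write calls in the CNVnator-style dialect read by :func:`read_cnv_calls`."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            region = f"{iv.chrom}:{iv.start + 1}-{iv.end}"
            fh.write(
                "\t".join(
                    [
                        c.cnv_type,
                        region,
                        str(iv.length()),
                        f"{c.norm_depth:.6g}",
                        f"{c.p_value:.6g}",
                        f"{c.q0_fraction:.6g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def _first(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


class VcfReader:
    """Iterate a single sample's records from a VCF as :class:`VariantRecord`.

    Records with a missing genotype are skipped and counted in
    ``n_skipped``; a genotype whose ploidy differs from the declared one
    raises an error naming the record.
    """

    def __init__(self, path, sample_id: str, ploidy: int):
        self.path = path
        self.sample_id = sample_id
        self.ploidy = ploidy
        self.n_skipped = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        with pysam.VariantFile(str(self.path)) as vcf:
            if self.sample_id not in vcf.header.samples:
                raise KeyError(
                    f"sample {self.sample_id!r} not in VCF {self.path}"
                )
            declared = set(vcf.header.info)

            def info_get(info, key):
                return _first(info.get(key)) if key in declared else None

            for rec in vcf.fetch() if vcf.index is not None else vcf:
                sample = rec.samples[self.sample_id]
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    self.n_skipped += 1
                    continue
                if len(gt) != self.ploidy:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: genotype ploidy {len(gt)} != "
                        f"declared ploidy {self.ploidy} for {self.sample_id}"
                    )
                depth = sample.get("DP")
                if depth is None:
                    depth = info_get(rec.info, "DP")
                yield VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or ()),
                    genotype=list(gt),
                    depth=None if depth is None else int(depth),
                    mq=_maybe_float(info_get(rec.info, "MQ")),
                    mqm=_maybe_float(info_get(rec.info, "MQM")),
                    mqmr=_maybe_float(info_get(rec.info, "MQMR")),
                    saf=_maybe_int(info_get(rec.info, "SAF")),
                    sar=_maybe_int(info_get(rec.info, "SAR")),
                )


def _maybe_float(v):
    return None if v is None else float(v)


def _maybe_int(v):
    return None if v is None else int(v)


def read_vcf(path, sample_id: str, ploidy: int) -> VcfReader:
    """Open a VCF for one sample; iterate the result for its records."""
    return VcfReader(path, sample_id, ploidy)


# ---------------------------------------------------------------------------
# BED


def write_bed6(
    rows: List[Tuple[GenomicInterval, str, float, str]], path
) -> None:
    """Write (interval, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for iv, name, score, strand in rows:
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), name, f"{score:g}", strand]
                )
                + "\n"
            )
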