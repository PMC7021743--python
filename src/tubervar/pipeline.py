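"""End-to-end orchestration: from call files to reports.

``run_all`` executes filter -> impact -> scan -> matrix -> ordination ->
tree -> SNP stages over a directory of per-sample inputs and writes a
manifest plus per-stage result tables.  Every stage is a pure function of
(inputs, config, seed), so a rerun with the same config and inputs is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

import tubervar
from tubervar import classification, cnv_impact, enrichment_scan, snp_profile
from tubervar.cnv_impact import CnvFilterThresholds
from tubervar.enrichment_scan import ScanParams
from tubervar.io_formats import (
    read_cnv_calls,
    read_fasta,
    read_gff3,
    read_vcf,
    write_bed6,
    write_newick,
)
from tubervar.snp_profile import PloidyConfig, SnpQualityThresholds


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run."""

    annotation: str
    cnv_dir: str
    sample_sheet: str
    output_dir: str
    genome: Optional[str] = None
    vcf_dir: Optional[str] = None
    cnv_thresholds: CnvFilterThresholds = field(default_factory=CnvFilterThresholds)
    scan_params: ScanParams = field(default_factory=ScanParams)
    metric: str = "manhattan"
    snp_thresholds: SnpQualityThresholds = field(default_factory=SnpQualityThresholds)
    het_mode: str = "strict"
    flank: int = 5000
    n_restarts: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "cnv_thresholds" in kwargs:
            kwargs["cnv_thresholds"] = CnvFilterThresholds(**kwargs["cnv_thresholds"])
        if "scan_params" in kwargs:
            kwargs["scan_params"] = ScanParams(**kwargs["scan_params"])
        if "snp_thresholds" in kwargs:
            kwargs["snp_thresholds"] = SnpQualityThresholds(**kwargs["snp_thresholds"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "annotation": self.annotation,
            "genome": self.genome,
            "cnv_dir": self.cnv_dir,
            "vcf_dir": self.vcf_dir,
            "sample_sheet": self.sample_sheet,
            "output_dir": self.output_dir,
            "cnv_thresholds": vars(self.cnv_thresholds),
            "scan_params": {
                "bin_width": self.scan_params.bin_width,
                "step": self.scan_params.step,
                "sd_multiplier": self.scan_params.sd_multiplier,
                "population_sd": self.scan_params.population_sd,
            },
            "metric": self.metric,
            "snp_thresholds": vars(self.snp_thresholds),
            "het_mode": self.het_mode,
            "flank": self.flank,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "ploidy"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _float_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the summary dict it also writes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FileNotFoundError as exc:
            raise StageError(name, f"missing input file: {exc.filename}") from exc
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    sheet = stage("sample-sheet", read_sample_sheet, config.sample_sheet)
    samples = list(sheet["sample_id"])
    ploidy_config = PloidyConfig(
        ploidy=dict(zip(sheet["sample_id"], sheet["ploidy"].astype(int)))
    )
    genes = stage("annotation", read_gff3, config.annotation)
    gene_ids = [g.gene_id for g in genes]
    chrom_lengths: Dict[str, int] = {}
    if config.genome:
        genome = stage("genome", read_fasta, config.genome)
        chrom_lengths = {c: len(s) for c, s in genome.items()}
    else:
        genome = None
        for g in genes:
            chrom_lengths[g.body.chrom] = max(
                chrom_lengths.get(g.body.chrom, 0), g.body.end
            )

    summary: dict = {"samples": samples}

    # --- CNV stages ---------------------------------------------------
    impacts: Dict[str, list] = {}
    footprints: Dict[str, int] = {}
    n_calls: Dict[str, List[int]] = {}
    cluster_rows = []
    for s in samples:
        path = Path(config.cnv_dir) / f"{s}.cnv.tsv"
        calls = stage("read-cnv", read_cnv_calls, path, s)
        kept = cnv_impact.filter_cnv_calls(calls, config.cnv_thresholds)
        n_calls[s] = [len(calls), len(kept)]
        impacts[s] = cnv_impact.gene_impacts(genes, kept, s)
        footprints[s] = cnv_impact.cnv_footprint(kept)
        scan = stage(
            "scan",
            enrichment_scan.scan_sample,
            genes,
            impacts[s],
            chrom_lengths,
            config.scan_params,
        )
        for rank, cl in enumerate(
            enrichment_scan.top_clusters(scan.clusters, k=3)
            if scan.clusters
            else [],
            start=1,
        ):
            cluster_rows.append(
                {
                    "sample": s,
                    "rank": rank,
                    "chrom": cl.interval.chrom,
                    "start": cl.interval.start,
                    "end": cl.interval.end,
                    "n_genes": len(cl.gene_ids),
                    "max_bin_count": cl.max_bin_count,
                    "threshold": scan.threshold,
                    "dominant_status": cl.dominant_status,
                }
            )

    impact_frames = pd.concat(
        [cnv_impact.impacts_to_frame(impacts[s]) for s in samples], ignore_index=True
    )
    _float_csv(impact_frames, out / "gene_impacts.tsv")
    clusters_df = pd.DataFrame(
        cluster_rows,
        columns=[
            "sample", "rank", "chrom", "start", "end", "n_genes",
            "max_bin_count", "threshold", "dominant_status",
        ],
    )
    _float_csv(clusters_df, out / "top_clusters.tsv")
    write_bed6(
        [
            (
                enrichment_scan.GenomicInterval(r["chrom"], r["start"], r["end"]),
                f"{r['sample']}_cluster{r['rank']}",
                float(r["max_bin_count"]),
                ".",
            )
            for r in cluster_rows
        ],
        out / "top_clusters.bed",
    )

    shared_any, shared_dup, shared_del = cnv_impact.shared_impacted_genes(impacts)
    summary["cnv"] = {
        "n_calls": n_calls,
        "footprint_bp": footprints,
        "shared_impacted_genes": len(shared_any),
        "shared_duplicated": len(shared_dup),
        "shared_deleted": len(shared_del),
        "n_clusters_reported": len(cluster_rows),
    }

    # --- classification -----------------------------------------------
    matrix = classification.build_status_matrix(impacts, gene_ids)
    matrix.to_tsv(out / "status_matrix.tsv")
    coords, eigvals = classification.ordination_frame(
        matrix, metric=config.metric, n_components=2
    )
    coords.round(6).to_csv(out / "ordination.tsv", sep="\t", index_label="sample")
    pd.DataFrame({"eigenvalue": eigvals.round(6)}).to_csv(
        out / "eigenvalues.tsv", sep="\t", index_label="component"
    )
    tree_newick = None
    parsimony = None
    if len(samples) >= 4:
        tree, parsimony = classification.search_parsimony_tree(
            matrix.informative_only() if len(gene_ids) > 0 else matrix,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        write_newick(tree, out / "cnv_tree.nwk")
        tree_newick = tree.to_newick()
    summary["classification"] = {
        "metric": config.metric,
        "top_eigenvalues": [round(float(v), 3) for v in eigvals[:2]],
        "tree": tree_newick,
        "parsimony_score": parsimony,
    }

    # --- SNP stages ----------------------------------------------------
    if config.vcf_dir:
        het_rows = []
        snp_summary = {}
        effect_tables = []
        for s in samples:
            path = Path(config.vcf_dir) / f"{s}.vcf"
            reader = stage("read-vcf", read_vcf, path, s, ploidy_config.ploidy[s])
            records = list(reader)
            kept = snp_profile.filter_variants(
                records, s, config.snp_thresholds, ploidy_config
            )
            profile = snp_profile.het_profile(kept, chrom_lengths, mode=config.het_mode)
            profile.insert(0, "sample", s)
            het_rows.append(profile)
            snp_summary[s] = {
                "n_records": len(records),
                "n_skipped_gt": reader.n_skipped,
                "n_pass": len(kept),
                "top_het_chrom": profile.iloc[0]["chrom"] if len(profile) else None,
            }
            if genome is not None:
                snvs = [r for r in kept if r.is_snv]
                effects = snp_profile.annotate_effects(
                    snvs, genes, genome, flank=config.flank
                )
                tables = snp_profile.summarize_effects(effects) if effects else {}
                for kind, table in tables.items():
                    t = table.copy()
                    t.insert(0, "sample", s)
                    t.insert(1, "kind", kind)
                    effect_tables.append(t)
        _float_csv(pd.concat(het_rows, ignore_index=True), out / "het_profile.tsv")
        if effect_tables:
            _float_csv(pd.concat(effect_tables, ignore_index=True), out / "effects.tsv")
        summary["snp"] = snp_summary

    manifest = {
        "tool": "tubervar",
        "version": tubervar.__version__,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
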