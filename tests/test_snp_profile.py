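"""Ploidy-aware filtering, site typing, het profiles and effect classes."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from tubervar.io_formats import GeneModel, GenomicInterval, VariantRecord
from tubervar.snp_profile import (
    PloidyConfig,
    SnpQualityThresholds,
    annotate_effect,
    annotate_effects,
    classify_site,
    filter_variants,
    het_profile,
    is_heterozygous,
    summarize_effects,
)

PLOIDY = PloidyConfig(ploidy={"dip": 2, "tri": 3, "tet": 4, "pent": 5})


def rec(genotype=(0, 1), depth=30, mq=55.0, mqm=50.0, mqmr=50.0, saf=6, sar=5,
        chrom="chr1", pos=100, ref="A", alts=("G",)):
    return VariantRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=list(alts),
        genotype=list(genotype), depth=depth, mq=mq, mqm=mqm, mqmr=mqmr,
        saf=saf, sar=sar,
    )


class TestFilterVariants:
    def test_depth_scales_with_ploidy(self):
        shallow = rec(depth=3)
        assert filter_variants([shallow], "dip", ploidy_config=PLOIDY) == []
        ok_pent = rec(genotype=(0, 0, 0, 1, 1), depth=10, mq=60, mqm=60,
                      mqmr=60, saf=5, sar=4)
        assert filter_variants([ok_pent], "pent", ploidy_config=PLOIDY) == [ok_pent]

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mq=19.9), dict(mqm=19.0), dict(mqmr=10.0), dict(saf=0), dict(sar=0)],
    )
    def test_single_quality_violations(self, kwargs):
        assert filter_variants([rec(**kwargs)], "dip", ploidy_config=PLOIDY) == []

    def test_missing_field_fails_active_threshold(self):
        assert filter_variants([rec(mqm=None)], "dip", ploidy_config=PLOIDY) == []
        loose = SnpQualityThresholds(require_both_strands=False)
        assert filter_variants([rec(saf=None, sar=None)], "dip", loose, PLOIDY) != []

    def test_constructed_fixture_retains_exact_subset(self):
        good = [rec(pos=p) for p in range(1, 8)]
        bad = [rec(pos=10, depth=2), rec(pos=11, mq=5), rec(pos=12, mqm=19.9),
               rec(pos=13, mqmr=0), rec(pos=14, saf=0)]
        kept = filter_variants(good + bad, "dip", ploidy_config=PLOIDY)
        assert kept == good
        assert filter_variants(kept, "dip", ploidy_config=PLOIDY) == kept

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError):
            filter_variants([rec()], "ghost", ploidy_config=PLOIDY)


class TestClassifySite:
    @pytest.mark.parametrize(
        "genotype,expected",
        [
            ((0, 1), "biallelic_B"),
            ((0, 0, 1, 1), "biallelic_B"),
            ((1, 1, 1, 1), "biallelic_other"),
            ((0, 0, 1, 2), "multiallelic"),
            ((0, 0), "homozygous_ref"),
        ],
    )
    def test_examples(self, genotype, expected):
        assert classify_site(rec(genotype=genotype)) == expected

    def test_partition_and_het_implication(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            ploidy = int(rng.integers(2, 6))
            genotype = tuple(rng.integers(0, 3, size=ploidy))
            label = classify_site(rec(genotype=genotype))
            assert label in {
                "biallelic_B", "biallelic_other", "multiallelic", "homozygous_ref"
            }
            if label == "biallelic_B":
                assert is_heterozygous(genotype, "strict")

    def test_empty_genotype_rejected(self):
        with pytest.raises(ValueError):
            classify_site(rec(genotype=()))


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "genotype,strict,alt_any",
        [((0, 1), True, True), ((1, 1), False, True), ((0, 0), False, False),
         ((1, 2), True, True), ((0, 0, 1, 1), True, True)],
    )
    def test_modes(self, genotype, strict, alt_any):
        assert is_heterozygous(genotype, "strict") is strict
        assert is_heterozygous(genotype, "alt-any") is alt_any

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            is_heterozygous((0, 1), "loose")


class TestHetProfile:
    def test_single_chromosome_has_full_share(self):
        records = [rec(chrom="chr1", pos=p) for p in range(1, 6)]
        df = het_profile(records, {"chr1": 1000, "chr2": 1000})
        row = df.set_index("chrom").loc["chr1"]
        assert row["share_of_het"] == 1.0
        assert row["het_fraction"] == 1.0
        assert df.iloc[0]["chrom"] == "chr1"

    def test_no_sites_all_zero(self):
        df = het_profile([], {"chr1": 1000})
        assert df["n_sites"].tolist() == [0]
        assert df["het_fraction"].tolist() == [0.0]

    def test_hotspot_chromosome_ranks_first(self):
        """A 3x elevated site rate on one chromosome tops the ranking."""
        rng = np.random.default_rng(1)
        wins = 0
        lengths = {f"chr{i}": 100_000 for i in range(1, 5)}
        for _ in range(50):
            records = []
            for chrom, length in lengths.items():
                rate = 3e-3 if chrom == "chr1" else 1e-3
                for p in rng.choice(length, rng.poisson(rate * length), replace=False):
                    records.append(rec(chrom=chrom, pos=int(p) + 1))
            df = het_profile(records, lengths)
            wins += df.iloc[0]["chrom"] == "chr1"
        assert wins >= 48


# ---------------------------------------------------------------------------
# Effects


def toy_gene(chrom="c", strand="+"):
    """Gene on [100, 190): exon1 100-130, intron 130-160, exon2 160-190.

    CDS covers 106-130 and 160-181 (45 bp, 15 codons).
    """
    exons = [GenomicInterval(chrom, 100, 130), GenomicInterval(chrom, 160, 190)]
    cds = [GenomicInterval(chrom, 106, 130), GenomicInterval(chrom, 160, 181)]
    if strand == "-":
        cds = cds[::-1]
    return GeneModel("toy", GenomicInterval(chrom, 100, 190), strand, exons, cds)


def build_genome(gene, cds_seq, chrom_len=10_200):
    """Embed a designed CDS into a fixed background sequence."""
    seq = list("ACGT" * (chrom_len // 4))
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    cursor = 0
    for c in sorted(gene.cds):
        seq[c.start : c.end] = list(cds_seq[cursor : cursor + c.length()])
        cursor += c.length()
    return {gene.body.chrom: "".join(seq)}


CDS_45 = "ATG" + "GGA" + "TGG" + "CATTCA" * 6 + "TAA"  # 15 codons


class TestAnnotateEffect:
    def setup_method(self):
        self.gene = toy_gene()
        self.genome = build_genome(self.gene, CDS_45)

    def _classify(self, pos0, alt):
        r = rec(chrom="c", pos=pos0 + 1, ref=self.genome["c"][pos0], alts=(alt,))
        return annotate_effect(r, [self.gene], self.genome)

    def test_silent_ggaggg(self):
        # codon 2 (GGA, glycine) at CDS offsets 3-5; A->G keeps glycine
        eff = self._classify(106 + 5, "G")
        assert (eff.region, eff.coding) == ("exonic", "silent")

    def test_nonsense_tggtga(self):
        # codon 3 (TGG, tryptophan) at CDS offsets 6-8; G->A gives TGA stop
        eff = self._classify(106 + 8, "A")
        assert (eff.region, eff.coding) == ("exonic", "nonsense")

    def test_missense_start_codon(self):
        eff = self._classify(106, "C")  # ATG -> CTG, Met -> Leu
        assert (eff.region, eff.coding) == ("exonic", "missense")

    def test_intronic(self):
        eff = self._classify(140, "A" if self.genome["c"][140] != "A" else "T")
        assert (eff.region, eff.coding) == ("intronic", "not_applicable")

    def test_exonic_utr_has_no_coding_class(self):
        eff = self._classify(102, "A" if self.genome["c"][102] != "A" else "T")
        assert eff.region == "exonic"
        assert eff.coding == "not_applicable"

    def test_upstream_within_flank(self):
        pos0 = 100 - 60
        eff = self._classify(pos0, "A" if self.genome["c"][pos0] != "A" else "T")
        assert eff.region == "upstream"

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="c:103"):
            annotate_effect(
                rec(chrom="c", pos=103, ref="N", alts=("A",)),
                [self.gene], self.genome,
            )

    def test_downstream_strand_aware(self):
        plus = self._classify(190 + 10, "A" if self.genome["c"][200] != "A" else "T")
        assert plus.region == "downstream"
        minus_gene = toy_gene(strand="-")
        genome = build_genome(minus_gene, CDS_45)
        r = rec(chrom="c", pos=201, ref=genome["c"][200],
                alts=("A" if genome["c"][200] != "A" else "T",))
        assert annotate_effect(r, [minus_gene], genome).region == "upstream"

    def test_intergenic_beyond_flank(self):
        pos0 = 190 + 5000
        eff = self._classify(pos0, "A" if self.genome["c"][pos0] != "A" else "T")
        assert eff.region == "intergenic"

    def test_minus_strand_coding(self):
        gene = toy_gene(strand="-")
        genome = build_genome(gene, CDS_45)
        # CDS offset 5 (third base of GGA) sits at genomic 180-1-5 = 175
        pos0 = 181 - 1 - 5
        ref = genome["c"][pos0]
        alt = str(Seq("G").reverse_complement())  # genomic C for coding G
        r = rec(chrom="c", pos=pos0 + 1, ref=ref, alts=(alt,))
        eff = annotate_effect(r, [gene], genome)
        assert (eff.region, eff.coding) == ("exonic", "silent")


class TestSummarizeEffects:
    def test_flank_split(self):
        from tubervar.snp_profile import SnpEffectClass

        effects = [SnpEffectClass("upstream")] * 2 + [SnpEffectClass("downstream")] * 2
        tables = summarize_effects(effects)
        region = tables["region"].set_index("class")
        assert region.loc["upstream", "fraction"] == 0.5
        assert region.loc["downstream", "fraction"] == 0.5
        assert region["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert "coding" not in tables  # no CDS variants -> no coding table

    def test_exhaustive_mutagenesis_matches_codon_enumeration(self):
        """All 3L substitutions of a CDS agree with direct codon-table counts."""
        gene = toy_gene()
        genome = build_genome(gene, CDS_45)
        records = []
        for offset in range(45):
            # map CDS offset back to genomic position
            pos0 = (106 + offset) if offset < 24 else (160 + offset - 24)
            ref = genome["c"][pos0]
            for alt in "ACGT":
                if alt != ref:
                    records.append(
                        rec(chrom="c", pos=pos0 + 1, ref=ref, alts=(alt,))
                    )
        effects = annotate_effects(records, [gene], genome)
        tables = summarize_effects(effects)
        counts = tables["coding"].set_index("class")["count"]

        expect = {"silent": 0, "missense": 0, "nonsense": 0}
        for i in range(0, 45, 3):
            codon = CDS_45[i : i + 3]
            for j, alt in itertools.product(range(3), "ACGT"):
                if alt == codon[j]:
                    continue
                mutated = codon[:j] + alt + codon[j + 1 :]
                aa0, aa1 = str(Seq(codon).translate()), str(Seq(mutated).translate())
                if aa1 == aa0:
                    expect["silent"] += 1
                elif aa1 == "*":
                    expect["nonsense"] += 1
                else:
                    expect["missense"] += 1
        assert counts.to_dict() == expect
        assert tables["region"]["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_effects([])
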