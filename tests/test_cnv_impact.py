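"""CNV filtering, interval math against a per-base oracle, shared genes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tubervar.cnv_impact import (
    CnvFilterThresholds,
    assign_status,
    cnv_footprint,
    filter_cnv_calls,
    gene_impact_fraction,
    gene_impacts,
    shared_impacted_genes,
    union_coverage,
    STATUS_DELETED,
    STATUS_DUPLICATED,
    STATUS_NEUTRAL,
)
from tubervar.io_formats import CnvCall, GeneModel, GenomicInterval


def call(start, end, cnv_type="deletion", p=1e-5, q0=0.1, chrom="chr1", sample="S"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), cnv_type, 1.0, p, q0)


def gene(gene_id, start, end, chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end), "+")


def per_base_covered(intervals, lo, hi):
    """Brute-force oracle: per-base boolean coverage over [lo, hi)."""
    mask = np.zeros(hi - lo, dtype=bool)
    for iv in intervals:
        a, b = max(iv.start, lo), min(iv.end, hi)
        if a < b:
            mask[a - lo : b - lo] = True
    return int(mask.sum())


class TestFilter:
    def test_boundary_semantics(self):
        kept = call(0, 5000, p=1e-4, q0=0.1)
        exactly_1000 = call(0, 1000, p=1e-4, q0=0.1)  # size test is strict
        at_p_cutoff = call(0, 5000, p=0.01, q0=0.1)  # p test is inclusive
        at_q0_cutoff = call(0, 5000, p=1e-4, q0=0.5)  # q0 test is strict
        out = filter_cnv_calls([kept, exactly_1000, at_p_cutoff, at_q0_cutoff])
        assert out == [kept, at_p_cutoff]

    def test_single_rule_violators(self):
        good = [call(i * 10000, i * 10000 + 5000) for i in range(5)]
        bad = [
            call(100000, 100900),  # too small
            call(110000, 115000, p=0.02),  # p too large
            call(120000, 125000, q0=0.6),  # q0 too large
        ]
        out = filter_cnv_calls(good + bad)
        assert out == good

    def test_idempotent_and_order_preserving(self):
        calls = [call(0, 5000), call(10000, 10500), call(20000, 26000, p=0.5)]
        once = filter_cnv_calls(calls)
        assert filter_cnv_calls(once) == once
        assert once == [calls[0]]

    def test_empty_input(self):
        assert filter_cnv_calls([]) == []

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            CnvFilterThresholds(max_p=1.5)


class TestUnionCoverage:
    def test_overlap_merges(self):
        merged, total = union_coverage(
            [GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)]
        )
        assert merged == [GenomicInterval("c", 0, 150)]
        assert total == 150

    def test_empty_identity(self):
        assert union_coverage([]) == ([], 0)

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            union_coverage([GenomicInterval("a", 0, 10), GenomicInterval("b", 0, 10)])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=1, max_size=12
        )
    )
    def test_union_property(self, spans):
        """Total covered bp always equals the per-base boolean count."""
        ivs = [GenomicInterval("c", s, s + ln) for s, ln in spans]
        merged, total = union_coverage(ivs)
        assert total == per_base_covered(ivs, 0, 1000)
        assert total == sum(iv.length() for iv in merged)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 12)
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 950))
                ivs.append(GenomicInterval("c", s, s + int(rng.integers(1, 50))))
            merged, total = union_coverage(ivs)
            assert total == per_base_covered(ivs, 0, 1000)
            # merged list is sorted, disjoint, non-touching
            for a, b in zip(merged, merged[1:]):
                assert a.end < b.start


class TestGeneImpactFraction:
    def test_half_deleted(self):
        g = gene("g", 100, 200)
        assert gene_impact_fraction(g, [call(100, 150)]) == (0.0, 0.5)

    def test_duplications_clipped_to_body(self):
        g = gene("g", 100, 200)
        dups = [call(0, 120, "duplication"), call(180, 300, "duplication")]
        assert gene_impact_fraction(g, dups) == (0.4, 0.0)

    def test_no_overlap(self):
        assert gene_impact_fraction(gene("g", 100, 200), []) == (0.0, 0.0)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            gs, glen = int(rng.integers(0, 500)), int(rng.integers(50, 400))
            g = gene("g", gs, gs + glen)
            calls = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, 900))
                calls.append(
                    call(s, s + int(rng.integers(1, 200)),
                         "duplication" if rng.random() < 0.5 else "deletion")
                )
            dup, dele = gene_impact_fraction(g, calls)
            for frac, cnv_type in ((dup, "duplication"), (dele, "deletion")):
                ivs = [c.interval for c in calls if c.cnv_type == cnv_type]
                expect = per_base_covered(ivs, g.body.start, g.body.end)
                assert frac == expect / glen


class TestAssignStatus:
    @pytest.mark.parametrize(
        "dup,dele,expected",
        [
            (0.6, 0.0, STATUS_DUPLICATED),
            (0.0, 0.0, STATUS_NEUTRAL),
            (0.6, 0.6, STATUS_DUPLICATED),  # tie goes to duplication
            (0.5, 0.7, STATUS_DELETED),
            (0.49, 0.49, STATUS_NEUTRAL),
            (0.0, 0.5, STATUS_DELETED),
        ],
    )
    def test_examples(self, dup, dele, expected):
        assert assign_status(dup, dele) == expected

    def test_neutral_iff_below_half(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            dup, dele = rng.random(), rng.random()
            status = assign_status(dup, dele)
            assert (status == STATUS_NEUTRAL) == (max(dup, dele) < 0.5)


class TestFootprint:
    def test_single_call(self):
        assert cnv_footprint([call(0, 10000)]) == 10000

    def test_types_pooled(self):
        assert cnv_footprint([call(0, 100, "duplication"), call(50, 150)]) == 150

    def test_matches_per_base_oracle_across_chromosomes(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            calls = []
            for _ in range(int(rng.integers(1, 15))):
                chrom = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(0, 900))
                calls.append(call(s, s + int(rng.integers(1, 120)), chrom=chrom))
            expect = sum(
                per_base_covered(
                    [c.interval for c in calls if c.interval.chrom == chrom], 0, 1100
                )
                for chrom in {c.interval.chrom for c in calls}
            )
            assert cnv_footprint(calls) == expect

    def test_monotone_under_added_calls(self):
        rng = np.random.default_rng(9)
        calls = []
        prev = 0
        for _ in range(30):
            s = int(rng.integers(0, 5000))
            calls.append(call(s, s + int(rng.integers(1, 500))))
            cur = cnv_footprint(calls)
            assert cur >= prev
            prev = cur


class TestSharedGenes:
    def _impacts(self, table):
        # table: sample -> {gene: status}
        genes = sorted({g for d in table.values() for g in d})
        out = {}
        for s, d in table.items():
            out[s] = [
                gene_impacts(
                    [gene(g, 0, 100)],
                    [call(0, 100, "duplication")] if d.get(g) == 3
                    else [call(0, 100)] if d.get(g) == 2 else [],
                    s,
                )[0]
                for g in genes
            ]
        return out

    def test_shared_sets(self):
        impacts = self._impacts(
            {"s1": {"g1": 3, "g2": 3}, "s2": {"g1": 3, "g2": 2}}
        )
        any_, dup, dele = shared_impacted_genes(impacts)
        assert any_ == {"g1", "g2"}
        assert dup == {"g1"}
        assert dele == set()
        assert dup.isdisjoint(dele) and dup <= any_ and dele <= any_

    def test_unknown_sample_rejected(self):
        impacts = self._impacts({"s1": {"g1": 3}})
        with pytest.raises(KeyError):
            shared_impacted_genes(impacts, samples=["s1", "ghost"])

    def test_planted_truth_recovered(self, cfg, layout, cnv_profiles):
        calls, truth = cnv_profiles
        impacts = {
            s: gene_impacts(layout.genes, filter_cnv_calls(calls[s]), s)
            for s in truth.statuses.index
        }
        any_, dup, dele = shared_impacted_genes(impacts)
        cluster_ids = {g for ids in truth.cluster_gene_ids for g in ids}
        assert cluster_ids <= any_
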