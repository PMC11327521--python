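"""SNV calling: pileup construction, genotype likelihoods, caller concordance."""

import itertools
from math import comb

import numpy as np
import pytest

from ncats.snv import (
    SNVCall,
    build_pileup,
    call_snvs,
    depth_effect,
    genotype_posteriors,
    intersect_callsets,
    kd_region_span_bp,
    qual_depth_correlation,
    read_vcf,
    write_vcf,
)
from ncats.synthetic_data import ToyGenome
from conftest import make_sam


def bayes_oracle(depth, alt, e):
    """Brute-force flat-prior Bayes over RR/RA/AA with Binomial(depth, f)."""
    e = max(e, 1e-3)
    likes = [comb(depth, alt) * f**alt * (1 - f) ** (depth - alt) for f in (e, 0.5, 1 - e)]
    total = sum(likes)
    return [l / total for l in likes]


def _call(pos=0, qual=10.0, depth=100, genotype="het", chrom="c", ref="A", alt="T"):
    return SNVCall(chrom, pos, ref, alt, genotype, depth, 0.5, qual)


class TestBuildPileup:
    GENOME = ToyGenome({"c1": "ACGTA" * 20})

    def test_error_free_reads_count_as_reference(self, tmp_path):
        records = [
            {"name": f"r{i}", "chrom": "c1", "pos": 0, "cigar": "50M",
             "seq": self.GENOME.chromosomes["c1"][:50]}
            for i in range(10)
        ]
        path = make_sam(tmp_path / "a.sam", {"c1": 100}, records)
        pile = build_pileup(path, self.GENOME, ("c1", 0, 50))
        for col in pile:
            assert col.depth == 10
            assert col.counts.sum() == 10
            assert col.counts["ACGT".index(col.ref)] == 10

    def test_deletion_counts_without_base(self, tmp_path):
        seq = self.GENOME.chromosomes["c1"][:10] + self.GENOME.chromosomes["c1"][12:20]
        path = make_sam(
            tmp_path / "a.sam", {"c1": 100},
            [{"name": "r", "chrom": "c1", "pos": 0, "cigar": "10M2D8M", "seq": seq}],
        )
        pile = build_pileup(path, self.GENOME, ("c1", 0, 20))
        assert pile[10].n_del == 1 and pile[10].counts.sum() == 0
        assert pile[10].depth == 1

    def test_insertion_tallied_against_anchor_column(self, tmp_path):
        seq = self.GENOME.chromosomes["c1"][:10] + "TT" + self.GENOME.chromosomes["c1"][10:20]
        path = make_sam(
            tmp_path / "a.sam", {"c1": 100},
            [{"name": "r", "chrom": "c1", "pos": 0, "cigar": "10M2I10M", "seq": seq}],
        )
        pile = build_pileup(path, self.GENOME, ("c1", 0, 20))
        assert pile.insertions == {9: 1}

    def test_low_quality_bases_are_masked(self, tmp_path):
        path = make_sam(
            tmp_path / "a.sam", {"c1": 100},
            [{"name": "r", "chrom": "c1", "pos": 0, "cigar": "10M",
              "seq": self.GENOME.chromosomes["c1"][:10], "qual": "!" * 10}],  # Q0
        )
        pile = build_pileup(path, self.GENOME, ("c1", 0, 10))
        assert all(col.depth == 0 for col in pile)

    def test_simulated_columns_match_coverage_and_planted_alleles(
        self, clean_bundle, clean_sam_path
    ):
        from ncats.alignment_io import read_alignments
        from ncats.enrichment_qc import coverage_track

        kd = clean_bundle.genome.feature("ABL1_KD")
        region = (kd.chrom, kd.start, kd.start + 1000)
        pile = build_pileup(clean_sam_path, clean_bundle.genome, region)
        segs = read_alignments(clean_sam_path)
        depth = coverage_track(segs, *region)
        snv_by_pos = {s.pos: s for s in clean_bundle.truth.snvs}
        for i, col in enumerate(pile):
            assert col.depth == depth[i]
            ref_i = "ACGT".index(col.ref)
            if col.pos in snv_by_pos:
                alt_i = "ACGT".index(snv_by_pos[col.pos].alt)
                assert col.counts[ref_i] + col.counts[alt_i] == col.depth
                assert col.counts[alt_i] > 0
            else:
                assert col.counts[ref_i] == col.depth

    def test_unknown_chromosome_rejected(self, tmp_path, clean_sam_path, clean_bundle):
        with pytest.raises(ValueError):
            build_pileup(clean_sam_path, clean_bundle.genome, ("chrUn", 0, 10))


class TestCallSnvs:
    @staticmethod
    def _column(ref_count, alt_count, ref="A", alt="T", qual=20.0, pos=0):
        from ncats.snv import PileupColumn

        counts = np.zeros(4, dtype=np.int64)
        counts["ACGT".index(ref)] = ref_count
        counts["ACGT".index(alt)] = alt_count
        n = ref_count + alt_count
        return PileupColumn("c", pos, ref, counts, 0, qual * n)

    def test_balanced_deep_column_called_het_with_oracle_posterior(self):
        (call,) = call_snvs([self._column(50, 50)])
        assert call.genotype == "het" and call.alt == "T"
        assert np.allclose(call.posterior, bayes_oracle(100, 50, 0.01), atol=1e-9)

    def test_below_min_alt_count_not_called(self):
        assert call_snvs([self._column(99, 1)]) == []

    def test_below_min_depth_not_called(self):
        assert call_snvs([self._column(0, 8)]) == []

    def test_homozygous_alt_genotype(self):
        (call,) = call_snvs([self._column(1, 99)])
        assert call.genotype == "hom_alt"

    def test_qual_monotone_in_depth_at_fixed_half_fraction(self):
        quals = []
        for depth in (10, 20, 40, 80, 160, 320):
            p_rr, _, _ = genotype_posteriors(depth, depth // 2, 0.01)
            quals.append(5000.0 if p_rr == 0 else min(-10 * np.log10(p_rr), 5000.0))
        assert all(b >= a for a, b in zip(quals, quals[1:]))

    def test_empty_pileup_gives_empty_calls(self):
        assert call_snvs([]) == []


class TestIntersectCallsets:
    def test_two_set_cells_by_hand(self):
        comp = intersect_callsets(
            {"A": [("c", 1, "A", "T"), ("c", 2, "A", "T")],
             "B": [("c", 2, "A", "T"), ("c", 3, "A", "T")]}
        )
        assert comp.cells[frozenset(["A"])] == 1
        assert comp.cells[frozenset(["B"])] == 1
        assert comp.cells[frozenset(["A", "B"])] == 1

    def test_identical_triplicate_sets(self):
        keys = [("c", i, "A", "T") for i in range(10)]
        comp = intersect_callsets({"x": keys, "y": keys, "z": keys})
        assert comp.cells[frozenset("xyz")] == 10
        assert all(n == 0 for combo, n in comp.cells.items() if combo != frozenset("xyz"))

    def test_matches_brute_force_enumeration_and_partitions_union(self):
        rng = np.random.default_rng(0)
        universe = [("c", int(i), "A", "T") for i in range(40)]
        sets = {
            name: [universe[i] for i in rng.choice(40, size=rng.integers(5, 30), replace=False)]
            for name in ("p", "q", "r")
        }
        comp = intersect_callsets(sets)
        union = set().union(*map(set, sets.values()))
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(sets), r):
                expected = sum(
                    1
                    for v in union
                    if all((v in set(sets[n])) == (n in combo) for n in sets)
                )
                assert comp.cells[frozenset(combo)] == expected
        assert sum(comp.cells.values()) == len(union)

    def test_single_callset_rejected(self):
        with pytest.raises(ValueError):
            intersect_callsets({"A": []})


class TestDepthEffect:
    def test_constant_depth_gives_zero_correlation(self):
        comp = intersect_callsets(
            {"A": [("c", 1, "A", "T")], "B": [("c", 1, "A", "T"), ("c", 2, "A", "T")]}
        )
        depths = {("c", 1, "A", "T"): 50, ("c", 2, "A", "T"): 50}
        df = depth_effect(comp, depths)
        assert df.attrs["point_biserial"] == 0.0
        present = df[df.n > 0]
        assert (present.median_depth == 50).all()

    def test_median_by_hand(self):
        keys = [("c", i, "A", "T") for i in (1, 2, 3)]
        comp = intersect_callsets({"A": keys, "B": keys})
        df = depth_effect(comp, dict(zip(keys, [10, 20, 30])))
        row = df[df.combination == "A&B"].iloc[0]
        assert row.median_depth == 20 and row.n == 3

    def test_deep_shared_vs_shallow_private_is_positive(self):
        shared = [("c", i, "A", "T") for i in range(5)]
        private = [("c", 100 + i, "A", "T") for i in range(5)]
        comp = intersect_callsets({"A": shared + private, "B": shared})
        depths = {**{k: 100 for k in shared}, **{k: 10 for k in private}}
        df = depth_effect(comp, depths)
        # sign check by hand: all-caller variants are the deep ones
        assert df.attrs["point_biserial"] > 0.9


class TestQualDepthCorrelation:
    def test_exact_linear_relation_gives_unit_r(self):
        calls = [_call(pos=i, qual=2.0 * d, depth=d) for i, d in enumerate([10, 20, 30, 40])]
        r, n, reason = qual_depth_correlation(calls)
        assert r == pytest.approx(1.0) and n == 4 and reason is None

    def test_constant_qual_reported_absent(self):
        calls = [_call(pos=i, qual=30.0, depth=d) for i, d in enumerate([10, 20, 30])]
        r, n, reason = qual_depth_correlation(calls)
        assert r is None and reason == "zero variance"

    def test_worked_four_point_example(self):
        depths = [1, 2, 3, 4]
        quals = [1.0, 3.0, 2.0, 4.0]
        calls = [_call(pos=i, qual=q, depth=d) for i, (q, d) in enumerate(zip(quals, depths))]
        r, n, _ = qual_depth_correlation(calls)
        assert r == pytest.approx(0.8)

    def test_too_few_calls_reported_absent(self):
        r, n, reason = qual_depth_correlation([_call(), _call(pos=1)])
        assert r is None and reason == "fewer than 3 calls"


class TestVcfIO:
    GENOME = ToyGenome({"c": "A" * 2000})

    def test_pos_is_one_based(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf([_call(pos=999)], self.GENOME, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[1] == "1000"

    def test_empty_call_list_header_only(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf([], self.GENOME, str(path))
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_write_read_write_fixpoint(self, tmp_path):
        calls = [
            _call(pos=10, qual=31.25, depth=55, genotype="het"),
            _call(pos=700, qual=1000.0, depth=80, genotype="hom_alt", alt="G"),
        ]
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(calls, self.GENOME, str(p1))
        write_vcf(read_vcf(str(p1)), self.GENOME, str(p2))
        assert p1.read_text() == p2.read_text()


def test_kd_region_span_matches_published_coordinates():
    """The kinase-domain evaluation region spans ~157 kb on chromosome 9."""
    assert kd_region_span_bp() == 157_048
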