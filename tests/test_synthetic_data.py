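"""Simulator: determinism, Cas9 geometry, truth bookkeeping, error model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncats.synthetic_data import (
    _inject_errors,
    BSASRecord,
    ConfigurationError,
    Feature,
    ToyGenome,
    default_genome_config,
    make_fusion_allele,
    make_toy_genome,
    methylation_profile,
    plant_snvs,
    revcomp,
    simulate_bsas,
    simulate_reads,
    simulate_run,
)


class TestToyGenome:
    def test_seed_determinism_is_byte_identical(self):
        g1, c1 = make_toy_genome(seed=1)
        g2, c2 = make_toy_genome(seed=1)
        assert g1.chromosomes == g2.chromosomes
        assert c1 == c2
        g3, _ = make_toy_genome(seed=2)
        assert g3.chromosomes != g1.chromosomes

    def test_feature_layout_passes_through(self):
        g, _ = make_toy_genome(seed=0)
        island = g.feature("BCR_CpG_island")
        assert (island.chrom, island.start, island.end, island.role) == (
            "toy22", 5000, 7000, "CpG_island",
        )
        assert g.fetch(island.chrom, island.start, island.end).count("CG") >= 20

    def test_all_planted_pams_are_ngg_on_spacer_strand(self):
        g, crrnas = make_toy_genome(seed=5)
        assert len(crrnas) == 4
        for cr in crrnas:
            pam = cr.pam_seq(g)
            assert pam[1:] == "GG", f"{cr.name}: {pam}"
            # cut is 3 nt PAM-proximal within the protospacer
            if cr.strand == "+":
                assert cr.expected_cut == cr.pam_start - 3
                spacer_on_ref = g.fetch(cr.chrom, cr.pam_start - 20, cr.pam_start)
                assert spacer_on_ref == cr.spacer_seq
            else:
                assert cr.expected_cut == cr.pam_start + 6
                spacer_on_ref = g.fetch(cr.chrom, cr.pam_start + 3, cr.pam_start + 23)
                assert revcomp(spacer_on_ref) == cr.spacer_seq

    def test_undersized_chromosome_rejected(self):
        cfg = default_genome_config()
        cfg["chromosomes"] = {"toy22": 5000, "toy9": 34_000}
        with pytest.raises(ConfigurationError):
            make_toy_genome(cfg, seed=0)

    def test_feature_outside_chromosome_rejected(self):
        cfg = default_genome_config()
        cfg["features"] = list(cfg["features"]) + [("bad", "toy9", 33_000, 40_000, "ROI")]
        with pytest.raises(ConfigurationError):
            make_toy_genome(cfg, seed=0)

    def test_fasta_bed_round_trip(self, tmp_path):
        g, _ = make_toy_genome(seed=3)
        g.write_fasta(tmp_path / "g.fa")
        g.write_bed(tmp_path / "g.bed")
        g2 = ToyGenome.from_files(str(tmp_path / "g.fa"), str(tmp_path / "g.bed"))
        assert g2.chromosomes == g.chromosomes
        assert g2.features == g.features


class TestFusionAllele:
    def test_degenerate_boundary_gives_acceptor_only(self):
        g, _ = make_toy_genome(seed=0)
        al = make_fusion_allele(g, 0, 10_000)
        assert al.seq == g.chromosomes["toy9"][10_000:]

    def test_length_conservation_and_junction_context(self):
        g, _ = make_toy_genome(seed=0)
        bpA, bpB = 15_200, 10_000
        al = make_fusion_allele(g, bpA, bpB)
        assert len(al.seq) == bpA + (len(g.chromosomes["toy9"]) - bpB)
        assert al.seq[bpA - 5 : bpA + 5] == (
            g.chromosomes["toy22"][bpA - 5 : bpA] + g.chromosomes["toy9"][bpB : bpB + 5]
        )

    def test_out_of_bounds_boundary_rejected(self):
        g, _ = make_toy_genome(seed=0)
        with pytest.raises(ConfigurationError):
            make_fusion_allele(g, 100_000, 10_000)


class TestPlantSnvs:
    def test_zero_requested_gives_empty(self):
        g, _ = make_toy_genome(seed=0)
        assert plant_snvs(g, ("toy9", 19_500, 25_000), 0, seed=1) == []

    def test_positions_unique_contained_and_ref_matches_genome(self):
        g, _ = make_toy_genome(seed=0)
        snvs = plant_snvs(g, ("toy9", 20_000, 21_000), 10, seed=1)
        positions = [s.pos for s in snvs]
        assert len(set(positions)) == 10
        assert all(20_000 <= p < 21_000 for p in positions)
        for s in snvs:
            assert g.chromosomes[s.chrom][s.pos] == s.ref
            assert s.alt != s.ref

    def test_overfull_region_rejected(self):
        g, _ = make_toy_genome(seed=0)
        with pytest.raises(ConfigurationError):
            plant_snvs(g, ("toy9", 20_000, 20_005), 10, seed=1)


class TestMethylationProfile:
    @staticmethod
    def _genome_with_n_cpgs(n, spacing=10):
        seq = list("AT" * (spacing * (n + 2)))
        for k in range(n):
            seq[spacing * (k + 1)] = "C"
            seq[spacing * (k + 1) + 1] = "G"
        return ToyGenome({"c": "".join(seq)}), spacing

    def test_three_runs_split_counts(self):
        g, spacing = self._genome_with_n_cpgs(30)
        start, end = spacing, spacing * 31
        profile = methylation_profile(g, ("c", start, end), 0.9, 0.1)
        values = list(profile.values())
        assert len(profile) == 30
        assert set(values) <= {0.9, 0.1}
        assert values.count(0.9) == 20 and values.count(0.1) == 10

    def test_degenerate_equal_probabilities_give_flat_profile(self):
        g, spacing = self._genome_with_n_cpgs(12)
        profile = methylation_profile(g, ("c", 0, spacing * 13), 0.5, 0.5)
        assert set(profile.values()) == {0.5}

    def test_boundaries_outside_island_rejected(self):
        g, spacing = self._genome_with_n_cpgs(12)
        with pytest.raises(ConfigurationError):
            methylation_profile(g, ("c", 0, 100), boundaries=(50, 200))


class TestSimulateReads:
    def test_noiseless_reads_match_reference_at_expected_cut(self, clean_bundle):
        g = clean_bundle.genome
        by_guide = {c.name: c for c in clean_bundle.crrnas}
        snv_positions = {(s.chrom, s.pos) for s in clean_bundle.truth.snvs}
        for read in clean_bundle.reads:
            cr = by_guide[read.crrna]
            seg0 = read.segments[0]
            ref = g.fetch(seg0.chrom, seg0.ref_start, seg0.ref_end)
            if read.strand == "+":
                assert seg0.ref_start == cr.expected_cut
                obs = read.sequence[: seg0.query_end]
            else:
                assert seg0.ref_end == cr.expected_cut
                obs = revcomp(read.sequence[: seg0.query_end])
            # only planted SNV alleles may differ from the reference
            diffs = {
                (seg0.chrom, seg0.ref_start + i)
                for i, (x, y) in enumerate(zip(obs, ref))
                if x != y
            }
            assert diffs <= snv_positions

    def test_fusion_spanning_reads_have_two_adjacent_segments(self, clean_bundle):
        spanning = [r for r in clean_bundle.reads if len(r.segments) == 2]
        assert spanning, "expected chimeric reads from the fusion allele"
        bpA, bpB = clean_bundle.truth.fusion[1], clean_bundle.truth.fusion[3]
        for r in spanning:
            a, b = r.segments
            assert a.chrom != b.chrom
            assert a.query_end == b.query_start  # adjacent in query coordinates
            assert (a.ref_end, b.ref_start) == (bpA, bpB)

    def test_observed_mismatch_rate_matches_substitution_rate(self):
        sub = 0.05
        b = simulate_run(
            seed=13, n_reads_per_cut=3, sub_rate=sub, ins_rate=0.0, del_rate=0.0,
            jitter=0, fusion_bp=None,
        )
        n_total, n_mismatch = 0, 0
        for read in b.reads:
            for seg in read.segments:
                ref = b.genome.fetch(seg.chrom, seg.ref_start, seg.ref_end)
                if read.strand == "-":
                    ref = revcomp(ref)
                obs = read.sequence[seg.query_start : seg.query_end]
                assert len(obs) == len(ref)
                # discount planted SNV alleles
                snv_pos = {
                    s.pos for s in b.truth.snvs
                    if s.chrom == seg.chrom and seg.ref_start <= s.pos < seg.ref_end
                }
                for i, (x, y) in enumerate(zip(obs, ref)):
                    rpos = (
                        seg.ref_start + i
                        if read.strand == "+"
                        else seg.ref_end - 1 - i
                    )
                    if rpos in snv_pos:
                        continue
                    n_total += 1
                    n_mismatch += x != y
        assert n_total > 10_000
        sd = np.sqrt(sub * (1 - sub) / n_total)
        assert abs(n_mismatch / n_total - sub) < 3 * sd

    def test_base_conservation_cigar_accounts_for_sequence(self, bundle):
        for read in bundle.reads:
            consumed = sum(
                n for seg in read.segments for op, n in seg.cigar if op in "MI"
            )
            assert consumed == len(read.sequence)
            assert read.segments[-1].query_end == len(read.sequence)

    def test_negative_rate_rejected(self, bundle):
        with pytest.raises(ConfigurationError):
            simulate_reads(
                bundle.genome, bundle.crrnas, bundle.truth, sub_rate=-0.1, seed=0
            )

    def test_read_level_determinism(self, bundle):
        again = simulate_run(seed=7, n_reads_per_cut=50)
        assert [r.sequence for r in again.reads] == [r.sequence for r in bundle.reads]
        assert [r.cpg_states for r in again.reads] == [r.cpg_states for r in bundle.reads]


class TestErrorInjection:
    """Every emitted base is attributable to a kept reference base or an
    insertion, and the CIGAR reconciles both sequence lengths."""

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.integers(1, 500),
        sub=st.floats(0, 0.5),
        ins=st.floats(0, 0.5),
        dele=st.floats(0, 0.5),
        seed=st.integers(0, 2**16),
    )
    def test_cigar_accounts_for_query_and_reference(self, n, sub, ins, dele, seed):
        rng = np.random.default_rng(seed)
        seg = rng.integers(0, 4, size=n, dtype=np.uint8)
        new, cigar, idx_map, unchanged = _inject_errors(seg, sub, ins, dele, rng)
        q_len = sum(length for op, length in cigar if op in "MI")
        r_len = sum(length for op, length in cigar if op in "MD")
        assert q_len == len(new)
        assert r_len == n
        # unchanged bases land at their mapped output position, identical
        for i in np.flatnonzero(unchanged):
            assert new[idx_map[i]] == seg[i]
        # op runs are maximal (no two adjacent runs share an op)
        assert all(a[0] != b[0] for a, b in zip(cigar, cigar[1:]))


class TestSimulateBsas:
    def test_fully_methylated_site_fully_retained(self):
        recs = simulate_bsas({100: 1.0}, [("r1", "toy22", 0, 200)], depth=50, seed=0)
        assert recs[0].freq == 1.0

    def test_unmethylated_site_fully_converted_at_perfect_conversion(self):
        recs = simulate_bsas({100: 0.0}, [("r1", "toy22", 0, 200)], depth=100, seed=0)
        assert recs[0].n_retained == 0

    def test_incomplete_conversion_inflates_unmethylated_sites(self):
        recs = simulate_bsas(
            {100: 0.0}, [("r1", "toy22", 0, 200)],
            depth=200_000, conversion_efficiency=0.95, seed=0,
        )
        assert recs[0].freq == pytest.approx(0.05, abs=0.005)

    def test_region_without_cpgs_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            recs = simulate_bsas({100: 0.5}, [("r1", "toy22", 500, 700)], depth=10, seed=0)
        assert recs == []
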