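"""Base-count profiles, depth summaries and the strict heteroplasmy caller."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopunct import depthmap as dm
from mitopunct import synthetic
from mitopunct.depthmap import BaseCountProfile
from mitopunct.synthetic import Feature
from conftest import random_profile


def brute_force_caller(counts, min_depth=100, min_minor_freq=0.10):
    """Literal position-by-position application of the three conditions."""
    out = []
    for pos in range(len(counts)):
        row = sorted(counts[pos], reverse=True)
        depth = sum(row)
        if len([c for c in row if c > 0]) < 2:
            continue  # single nucleotide observed
        if depth <= min_depth:
            continue
        if Fraction(int(row[1]), depth) <= Fraction(str(min_minor_freq)):
            continue
        out.append(pos)
    return out


def _write_sam(path, reads, ref_len=60, ref="ref"):
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{ref}\tLN:{ref_len}"]
    for name, pos, cigar, seq in reads:
        lines.append(f"{name}\t0\t{ref}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*")
    path.write_text("\n".join(lines) + "\n")


class TestProfileConstruction:
    def test_identical_reads_give_uniform_monoallelic_depth(self, tmp_path):
        sam = tmp_path / "reads.sam"
        seq = "ACGTACGTAC"
        _write_sam(sam, [(f"r{i}", 1, "10M", seq) for i in range(10)],
                   ref_len=10)
        prof = BaseCountProfile.from_sam(sam, 10)
        assert (prof.depth == 10).all()
        assert ((prof.counts > 0).sum(axis=1) == 1).all()

    def test_deleted_position_excluded_from_depth(self, tmp_path):
        sam = tmp_path / "reads.sam"
        _write_sam(sam, [
            ("full", 1, "10M", "ACGTACGTAC"),
            ("gapped", 1, "4M1D5M", "ACGTCGTAC"),
        ], ref_len=10)
        prof = BaseCountProfile.from_sam(sam, 10)
        assert prof.depth[4] == 1  # only the full read covers the deletion
        assert prof.depth[3] == 2 and prof.depth[5] == 2

    def test_soft_clips_do_not_contribute(self, tmp_path):
        sam = tmp_path / "reads.sam"
        _write_sam(sam, [("clip", 3, "2S6M2S", "TTACGTACTT")], ref_len=20)
        prof = BaseCountProfile.from_sam(sam, 20)
        assert prof.depth.sum() == 6
        assert prof.depth[2:8].tolist() == [1] * 6

    def test_excess_malformed_records_abort(self, tmp_path):
        sam = tmp_path / "reads.sam"
        # second read runs off the reference end -> malformed (1 of 2 > 10%)
        _write_sam(sam, [
            ("ok", 1, "10M", "ACGTACGTAC"),
            ("overhang", 55, "10M", "ACGTACGTAC"),
        ], ref_len=60)
        with pytest.raises(dm.MalformedAlignmentError):
            BaseCountProfile.from_sam(sam, 60)

    def test_tsv_round_trip(self, tmp_path):
        prof = random_profile(seed=1, length=50)
        prof.to_tsv(tmp_path / "counts.tsv")
        back = BaseCountProfile.from_tsv(tmp_path / "counts.tsv")
        assert (back.counts == prof.counts).all()

    def test_generator_profile_passes_through(self, toy):
        # noiseless generator output re-read from TSV is bit-identical
        seq, truth = toy
        prof = synthetic.simulate_read_pileup(seq, truth, error_rate=0.0,
                                              seed=2)
        assert prof.counts.shape == (len(seq), 4)
        assert (prof.counts.sum(axis=1) == prof.depth).all()


class TestDepthSummary:
    def test_constant_depth(self):
        counts = np.zeros((20, 4), dtype=int)
        counts[:, 0] = 7
        summary = dm.depth_summary(BaseCountProfile(counts))
        assert summary["genome_median"] == 7
        assert summary["genome_mean"] == 7

    def test_even_count_median_is_midpoint(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[:, 1] = [1, 2, 3, 1000]
        summary = dm.depth_summary(BaseCountProfile(counts))
        assert summary["genome_median"] == 2.5

    def test_zero_coverage_positions_excluded(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[:5, 0] = 10
        summary = dm.depth_summary(BaseCountProfile(counts))
        assert summary["genome_median"] == 10
        assert summary["covered_positions"] == 5

    def test_per_feature_medians_track_tiers(self, toy):
        seq, truth = toy
        tiers = {"cox1": 1000, "nad1": 100}
        prof = synthetic.simulate_read_pileup(seq, truth, tiers, seed=5)
        summary = dm.depth_summary(prof, truth.features)
        assert summary["per_feature"]["cox1"] == pytest.approx(1000, rel=0.1)
        assert summary["per_feature"]["nad1"] == pytest.approx(100, rel=0.1)


class TestHeteroplasmyCaller:
    @pytest.mark.parametrize("row, called", [
        ((120, 0, 30, 0), True),    # depth 150, minor freq 0.20
        ((80, 20, 0, 0), False),    # depth 100: not > 100
        ((180, 20, 0, 0), False),   # freq exactly 0.10: not > 0.10
        ((181, 20, 0, 0), False),   # freq just below 0.10
        ((178, 20, 0, 0), True),    # depth 198, freq 0.101...
        ((101, 0, 0, 0), False),    # monoallelic
    ])
    def test_three_conditions_strict(self, row, called):
        counts = np.zeros((3, 4), dtype=int)
        counts[1] = row
        sites = dm.call_heteroplasmic_sites(BaseCountProfile(counts))
        assert (len(sites) == 1 and sites[0].position == 1) == called

    def test_planted_sites_recovered_without_false_positives(self, toy):
        seq, truth = toy
        truth = synthetic.plant_random_heteroplasmies(
            seq, truth, 8, depth=500, minor_freq=0.2, seed=21)
        prof = synthetic.simulate_read_pileup(
            seq, truth, synthetic.punctuated_depth_tiers(truth), seed=22)
        sites = dm.call_heteroplasmic_sites(prof)
        assert sorted(s.position for s in sites) == \
            sorted(h.position for h in truth.heteroplasmies)

    def test_matches_brute_force_on_random_profiles(self):
        for seed in range(10):
            prof = random_profile(seed)
            called = [s.position for s in dm.call_heteroplasmic_sites(prof)]
            assert called == brute_force_caller(prof.counts), seed

    def test_minor_support_floor_on_all_outputs(self):
        for seed in range(10):
            sites = dm.call_heteroplasmic_sites(random_profile(seed))
            assert all(s.minor_count >= 10 for s in sites)

    def test_base_label_permutation_invariance(self):
        prof = random_profile(seed=33)
        base = {(s.position, s.depth, s.minor_count)
                for s in dm.call_heteroplasmic_sites(prof)}
        for perm in ((1, 0, 3, 2), (3, 2, 1, 0), (2, 3, 0, 1)):
            permuted = BaseCountProfile(prof.counts[:, list(perm)])
            got = {(s.position, s.depth, s.minor_count)
                   for s in dm.call_heteroplasmic_sites(permuted)}
            assert got == base

    @settings(derandomize=True, max_examples=50)
    @given(depth=st.integers(1, 400), minor=st.integers(0, 200),
           bump_depth=st.integers(0, 50), bump_freq=st.sampled_from(
               [0.10, 0.12, 0.15, 0.20]))
    def test_raising_thresholds_never_adds_sites(self, depth, minor,
                                                 bump_depth, bump_freq):
        minor = min(minor, depth)
        counts = np.array([[depth, minor, 0, 0]])
        prof = BaseCountProfile(counts)
        base = dm.call_heteroplasmic_sites(prof, 100, 0.10)
        stricter = dm.call_heteroplasmic_sites(prof, 100 + bump_depth,
                                               bump_freq)
        assert {s.position for s in stricter} <= {s.position for s in base}

    def test_triallelic_site_flagged(self):
        counts = np.array([[200, 60, 50, 0]])
        sites = dm.call_heteroplasmic_sites(BaseCountProfile(counts))
        assert len(sites) == 1
        assert sites[0].minor_base == "C" and sites[0].triallelic

    def test_tsv_report_columns(self, tmp_path, toy):
        seq, truth = toy
        truth = synthetic.plant_random_heteroplasmies(seq, truth, 3, seed=8)
        prof = synthetic.simulate_read_pileup(seq, truth, seed=9)
        sites = dm.call_heteroplasmic_sites(prof)
        out = tmp_path / "het.tsv"
        dm.write_heteroplasmy_tsv(sites, out, features=truth.features,
                                  counts=prof.counts)
        header = out.read_text().splitlines()[0].split("\t")
        for col in ("position", "gene", "total_reads", "A_count", "T_prop"):
            assert col in header


class TestPunctuationProfile:
    def test_flat_depth_gives_zero_fold_changes(self, toy):
        seq, truth = toy
        counts = np.zeros((len(seq), 4), dtype=int)
        counts[:, 0] = 100
        table = dm.punctuation_profile(BaseCountProfile(counts),
                                       truth.features)
        inner = table["boundary_log2fc"].dropna()
        assert (inner == 0).all()

    def test_boundary_signs_match_generator_truth(self, toy):
        seq, truth = toy
        tiers = synthetic.punctuated_depth_tiers(truth)
        prof = synthetic.simulate_read_pileup(seq, truth, tiers, seed=13)
        table = dm.punctuation_profile(prof, truth.features).set_index(
            "feature")
        # mRNA -> tRNA boundaries drop, tRNA -> mRNA boundaries rise
        assert table.loc["cox1", "boundary_log2fc"] < 0  # into trnS2
        assert table.loc["trnD", "boundary_log2fc"] > 0  # into cox2

    def test_bicistronic_pairs_flagged_and_coupled(self, toy):
        seq, truth = toy
        tiers = synthetic.punctuated_depth_tiers(truth)
        prof = synthetic.simulate_read_pileup(seq, truth, tiers, seed=14)
        table = dm.punctuation_profile(prof, truth.features)
        coupled = table[table.expected_coupled]
        assert set(zip(coupled.feature, coupled.next_feature)) == \
            {("nad4l", "nad4"), ("atp8", "atp6")}
        assert (coupled.boundary_log2fc.abs() < 0.5).all()

    def test_cox_genes_have_highest_medians(self, toy):
        seq, truth = toy
        tiers = synthetic.punctuated_depth_tiers(truth)
        prof = synthetic.simulate_read_pileup(seq, truth, tiers, seed=15)
        table = dm.punctuation_profile(prof, truth.features)
        top3 = set(table.nlargest(3, "median_depth")["feature"])
        assert top3 == {"cox1", "cox2", "cox3"}
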