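"""Ortholog extraction, codon-aware alignment, supermatrix, PNI, indels."""

import numpy as np
import pytest

from mitopunct import compara as cp
from mitopunct import synthetic
from mitopunct.compara import AnnotatedGenome, GeneAlignment


def brute_force_pni(rows):
    out = {}
    for i, (ta, ra) in enumerate(rows):
        for j, (tb, rb) in enumerate(rows):
            if j <= i:
                continue
            comp = [(a, b) for a, b in zip(ra, rb)
                    if a in "ACGT" and b in "ACGT"]
            if comp:
                out[(ta, tb)] = round(
                    100 * sum(a == b for a, b in comp) / len(comp), 1)
    return out


class TestExtractOrthologs:
    def test_cohort_lengths_match_truth(self, toy_cohort):
        genomes, truth = toy_cohort
        orth = cp.extract_orthologs(genomes, "cox1")
        cox1 = truth.feature("cox1")
        assert len(orth) == 4
        assert all(len(s) == cox1.end - cox1.start for _, s, _ in orth)

    def test_light_strand_gene_in_coding_orientation(self, toy_cohort):
        genomes, _ = toy_cohort
        for _, seq, _ in cp.extract_orthologs(genomes, "nad6"):
            assert seq.startswith("ATG")
            assert seq.endswith("TAA")

    def test_missing_gene_omits_taxon(self, toy_cohort):
        genomes, truth = toy_cohort
        stripped = AnnotatedGenome(
            "stripped", genomes[0].sequence,
            [f for f in truth.features if f.name != "atp8"])
        orth = cp.extract_orthologs([genomes[0], genomes[1], stripped],
                                    "atp8")
        assert [t for t, _, _ in orth] == ["taxon0", "taxon1"]

    def test_gene_absent_everywhere_is_error(self, toy_cohort):
        genomes, truth = toy_cohort
        bare = [AnnotatedGenome(g.taxon, g.sequence, []) for g in genomes]
        with pytest.raises(ValueError, match="not annotated"):
            cp.extract_orthologs(bare, "cox2")


class TestAlignGene:
    def test_identical_sequences_align_without_gaps(self, toy_cohort):
        genomes, _ = toy_cohort
        seqs = [(f"t{i}", cp.extract_orthologs(genomes[:1], "cox2")[0][1])
                for i in range(3)]
        aln = cp.align_gene(seqs, "codon-aware", "cox2")
        assert all("-" not in row for _, row in aln.rows)
        assert len({row for _, row in aln.rows}) == 1

    def test_single_codon_deletion_creates_3nt_gap_at_site(self):
        from mitopunct.genetic_code import SENSE_CODONS
        rng = np.random.default_rng(1)
        body = "".join(rng.choice(list(SENSE_CODONS), size=55))
        full = "ATG" + body + "TAA"
        missing40 = full[:39 * 3] + full[40 * 3:]  # drop the 40th codon
        aln = cp.align_gene([("ref", full), ("gapped", missing40)],
                            "codon-aware", "atp8")
        gapped_row = dict(aln.rows)["gapped"]
        assert gapped_row[39 * 3:40 * 3] == "---"
        assert gapped_row.replace("-", "") == missing40

    def test_back_translation_round_trip(self, toy_cohort):
        genomes, _ = toy_cohort
        for gene in ("cox1", "nad3", "atp6", "nad6"):
            orth = cp.extract_orthologs(genomes, gene)
            aln = cp.align_gene([(t, s) for t, s, _ in orth],
                                "codon-aware", gene)
            for (taxon, row), (_, original, _) in zip(aln.rows, orth):
                assert row.replace("-", "") == original, (gene, taxon)

    def test_codon_mode_gap_runs_are_codon_sized(self, toy_cohort):
        genomes, _ = toy_cohort
        full = cp.extract_orthologs(genomes, "nad4l")[0][1]
        dropped = full[:30] + full[36:]  # remove codons 11-12
        aln = cp.align_gene([("a", full), ("b", dropped), ("c", full)],
                            "codon-aware", "nad4l")
        import re
        for _, row in aln.rows:
            for run in re.finditer("-+", row.rstrip("-")):
                assert (run.end() - run.start()) % 3 == 0

    def test_internal_stop_names_taxon(self):
        good = "ATG" + "CTA" * 20 + "TAA"
        bad = "ATG" + "CTA" * 5 + "TAA" + "CTA" * 14 + "TAA"
        with pytest.raises(cp.InternalStopError, match="taxonB"):
            cp.align_gene([("taxonA", good), ("taxonB", bad)],
                          "codon-aware", "cob")

    def test_nucleotide_mode_for_rrna(self, toy_cohort):
        genomes, _ = toy_cohort
        orth = cp.extract_orthologs(genomes, "rrnS")
        aln = cp.align_gene([(t, s) for t, s, _ in orth], "nucleotide",
                            "rrnS")
        assert aln.mode == "nucleotide"
        for (taxon, row), (_, original, _) in zip(aln.rows, orth):
            assert row.replace("-", "") == original

    def test_duplicate_taxon_rejected(self):
        seq = "ATG" + "CTA" * 5 + "TAA"
        with pytest.raises(ValueError, match="duplicate"):
            cp.align_gene([("t", seq), ("t", seq)], "codon-aware")


class TestSupermatrix:
    def _toy_alignments(self):
        a = GeneAlignment("g1", "nucleotide",
                          [("t1", "ACGTACGTAC" * 3), ("t2", "ACGTACGTAC" * 3)])
        b = GeneAlignment("g2", "nucleotide",
                          [("t1", "GGCC" * 15), ("t2", "GGCC" * 15),
                           ("t3", "GGCC" * 15)])
        return a, b

    def test_column_additivity_and_partitions(self):
        a, b = self._toy_alignments()
        sm = cp.concatenate([a, b])
        assert sm.width == 30 + 60
        assert sm.partitions == {"g1": (0, 30), "g2": (30, 90)}

    def test_missing_taxon_block_is_n(self):
        a, b = self._toy_alignments()
        sm = cp.concatenate([a, b])
        row = dict(zip(sm.taxa, sm.rows))["t3"]
        assert row[:30] == "N" * 30
        assert row[30:] == "GGCC" * 15

    def test_slicing_reproduces_input_alignments(self, toy_cohort):
        genomes, _ = toy_cohort
        alns = []
        for gene in ("nad3", "atp8"):
            orth = cp.extract_orthologs(genomes, gene)
            alns.append(cp.align_gene([(t, s) for t, s, _ in orth],
                                      "codon-aware", gene))
        sm = cp.concatenate(alns)
        for aln in alns:
            assert sm.slice_gene(aln.gene) == aln.rows

    def test_partition_tiling_enforced(self):
        with pytest.raises(ValueError, match="tile"):
            cp.Supermatrix(["t"], ["ACGT"], {"g": (0, 3)})


class TestPNI:
    def test_identical_rows_are_100(self):
        pni = cp.pairwise_nucleotide_identity(
            [("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert pni[("a", "b")] == 100.0

    def test_hand_counted_example(self):
        # comparable columns: 1,2,3,4,6 (gap excluded pairwise);
        # matches at 1,2,4,6; mismatch G/T at 3 -> 4/5 = 80.0
        pni = cp.pairwise_nucleotide_identity(
            [("a", "ACGT-A"), ("b", "ACTTAA")])
        assert pni[("a", "b")] == 80.0
        assert pni.counts[0, 1] == 5

    def test_symmetry_diagonal_and_range(self):
        rng = np.random.default_rng(3)
        rows = [(f"t{i}", "".join(rng.choice(list("ACGT-N"), size=300)))
                for i in range(8)]
        pni = cp.pairwise_nucleotide_identity(rows)
        v = pni.values
        assert np.allclose(v, v.T, equal_nan=True)
        assert (np.diag(v) == 100.0).all()
        finite = v[np.isfinite(v)]
        assert ((finite >= 0) & (finite <= 100)).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        rows = [(f"t{i}", "".join(rng.choice(list("ACGT-N"), size=500)))
                for i in range(10)]
        pni = cp.pairwise_nucleotide_identity(rows)
        for (ta, tb), expected in brute_force_pni(rows).items():
            assert pni[(ta, tb)] == expected

    def test_removing_taxon_leaves_other_cells_unchanged(self):
        rng = np.random.default_rng(5)
        rows = [(f"t{i}", "".join(rng.choice(list("ACGT"), size=200)))
                for i in range(5)]
        full = cp.pairwise_nucleotide_identity(rows)
        reduced = cp.pairwise_nucleotide_identity(rows[:-1])
        for a in range(4):
            for b in range(4):
                assert full.values[a, b] == reduced.values[a, b]

    def test_no_comparable_positions_flagged_undefined(self):
        pni = cp.pairwise_nucleotide_identity(
            [("a", "ACGT----"), ("b", "----ACGT")])
        assert ("a", "b") in pni.undefined
        assert np.isnan(pni[("a", "b")])

    def test_pni_decreases_with_divergence(self, toy_cohort):
        genomes, _ = toy_cohort  # diverged by 0/60/120/180 substitutions
        orth = cp.extract_orthologs(genomes, "nad5")
        aln = cp.align_gene([(t, s) for t, s, _ in orth], "codon-aware",
                            "nad5")
        sm = cp.concatenate([aln])
        pni = cp.pairwise_nucleotide_identity(sm)
        row = pni.values[0]
        assert row[1] >= row[2] >= row[3]


class TestConservationAndIndels:
    def test_all_identical_alignment_fully_invariable(self):
        rows = [("a", "MKVL"), ("b", "MKVL")]
        assert cp.invariable_amino_acid_percent(rows) == 100

    def test_one_variable_column_in_ten(self):
        rows = [("a", "MKVLITAGQW"), ("b", "MKVLITAGQC")]
        assert cp.invariable_amino_acid_percent(rows) == 90

    def test_sparse_columns_do_not_count(self):
        rows = [("a", "M---"), ("b", "MKVL"), ("c", "MKVL"), ("d", "-KVL")]
        # column 0: M present in 3/4 -> counts; columns 1-3 present 3/4
        assert cp.invariable_amino_acid_percent(rows) == 100

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            ncol, ntaxa = int(rng.integers(5, 40)), int(rng.integers(2, 8))
            rows = [(f"t{i}",
                     "".join(rng.choice(list("ACDEFG-"), size=ncol)))
                    for i in range(ntaxa)]
            expected_cols = 0
            for j in range(ncol):
                res = [r[j] for _, r in rows if r[j] != "-"]
                if res and 2 * len(res) >= ntaxa \
                        and all(x == res[0] for x in res):
                    expected_cols += 1
            assert cp.invariable_amino_acid_percent(rows) == round(
                100 * expected_cols / ncol)

    def test_gapless_alignment_has_no_indels(self):
        rows = [("a", "ACGTACGT"), ("b", "ACGTACGT")]
        assert cp.detect_alignment_indels(rows) == []

    def test_private_gap_run_reported_with_length(self):
        rows = [("a", "ACGTACGTACGT"), ("b", "ACG------GT".ljust(12, "T")),
                ("c", "ACGTACGTACGT")]
        events = cp.detect_alignment_indels(rows, gene="nad6")
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "deletion" and ev.length == 6
        assert ev.taxa == ("b",) and ev.gene == "nad6"

    def test_random_gap_patterns_match_run_length_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ntaxa, ncol = int(rng.integers(2, 6)), int(rng.integers(10, 60))
            rows = [(f"t{i}", "".join(
                rng.choice(["A", "-"], p=[0.8, 0.2], size=ncol)))
                    for i in range(ntaxa)]
            events = cp.detect_alignment_indels(rows)
            # oracle: group columns by gap pattern, maximal runs
            patterns = ["".join(r[j] for _, r in rows) for j in range(ncol)]
            expected = 0
            prev = None
            for pat in patterns + [None]:
                if pat != prev:
                    if prev is not None and "-" in prev:
                        expected += 1
                    prev = pat
            assert len(events) == expected

    def test_junction_insertions_join_the_event_stream(self, toy):
        from mitopunct import annotate as an
        from mitopunct.synthetic import Feature
        _, truth = toy
        cox3 = truth.feature("cox3")
        shifted = [Feature(f.name, f.start + 17, f.end + 17, f.strand)
                   if f.start >= cox3.start else f for f in truth.features]
        devs = an.verify_gene_order(shifted)
        events = cp.junction_insertion_events(devs)
        assert len(events) == 1
        assert events[0].length == 17 and events[0].kind == "insertion"
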