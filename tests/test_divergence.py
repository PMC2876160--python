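import math

import numpy as np
import pytest

from funcdiv.divergence import (
    CodonAlignment,
    DivergenceError,
    ProteinAlignment,
    _scoring_matrix,
    backtranslate_alignment,
    global_protein_align,
    import_divergence_table,
    ng86_divergence,
)
from funcdiv.simulate import simulate_cds_pair

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestProteinAlignment:
    def test_identical_sequences_align_gapless_with_self_score(self):
        seq = "MKTAYIAK"
        mat = _scoring_matrix("BLOSUM62")
        aln = global_protein_align(seq, seq)
        assert aln.aligned1 == aln.aligned2 == seq
        assert aln.score == sum(mat[c, c] for c in seq)

    def test_single_residue_against_two(self):
        aln = global_protein_align("A", "AA")
        assert sorted((aln.aligned1, aln.aligned2)) == ["A-", "AA"] or sorted(
            (aln.aligned1, aln.aligned2)
        ) == ["-A", "AA"]

    def test_illegal_residue_names_position(self):
        with pytest.raises(DivergenceError, match="position 2"):
            global_protein_align("MKJ", "MK")

    def test_empty_sequence_fails(self):
        with pytest.raises(DivergenceError):
            global_protein_align("", "MK")

    def test_score_invariant_under_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s1 = "".join(rng.choice(list(AA), size=rng.integers(3, 12)))
            s2 = "".join(rng.choice(list(AA), size=rng.integers(3, 12)))
            assert global_protein_align(s1, s2).score == pytest.approx(
                global_protein_align(s2, s1).score
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_score_matches_exhaustive_enumeration(self, seed):
        from oracles import brute_global_align_score

        rng = np.random.default_rng(seed)
        mat = _scoring_matrix("BLOSUM62")
        s1 = "".join(rng.choice(list(AA), size=rng.integers(1, 7)))
        s2 = "".join(rng.choice(list(AA), size=rng.integers(1, 7)))
        expected = brute_global_align_score(
            s1, s2, lambda a, b: mat[a, b], gap_open=10.0, gap_extend=0.5
        )
        assert global_protein_align(s1, s2).score == pytest.approx(expected)

    def test_no_all_gap_columns_allowed(self):
        with pytest.raises(DivergenceError):
            ProteinAlignment("A-", "--", score=0)


class TestBacktranslate:
    def test_gap_becomes_triplet(self):
        aln = ProteinAlignment("M-K", "MAK", score=0)
        codon = backtranslate_alignment(aln, "ATGAAA", "ATGGCTAAA")
        assert codon.row1 == "ATG---AAA"
        assert codon.row2 == "ATGGCTAAA"

    def test_terminal_stop_stripped(self):
        aln = ProteinAlignment("MK", "MK", score=0)
        codon = backtranslate_alignment(aln, "ATGAAATAA", "ATGAAG")
        assert codon.row1 == "ATGAAA"

    def test_translation_mismatch_reports_codon_index(self):
        aln = ProteinAlignment("MKMKMK", "MKMKMK", score=0)
        cds = "ATGAAA" * 3
        bad = cds[:15] + "GGG"  # codon 5 now codes G, protein says K
        with pytest.raises(DivergenceError, match="codon index 5"):
            backtranslate_alignment(aln, bad, cds)

    def test_internal_stop_fails(self):
        aln = ProteinAlignment("MK", "MK", score=0)
        with pytest.raises(DivergenceError, match="stop"):
            backtranslate_alignment(aln, "ATGTAA", "ATGAAA")

    def test_length_mismatch_fails(self):
        aln = ProteinAlignment("MK", "MK", score=0)
        with pytest.raises(DivergenceError, match="length"):
            backtranslate_alignment(aln, "ATGAAAGGG", "ATGAAA")


class TestNG86:
    def test_identical_rows(self):
        aln = CodonAlignment("ATGAAA", "ATGAAA")
        est = ng86_divergence(aln)
        assert est.dn == 0.0 and est.ds == 0.0
        assert est.omega is None and "omega_undefined" in est.flags

    def test_hand_computed_four_codon_example(self):
        est = ng86_divergence(CodonAlignment("TTTAAAGGGCCC", "TTCAAAGGGCCC"))
        assert est.s_sites == pytest.approx(8 / 3, abs=1e-12)
        assert est.sd == pytest.approx(1.0)
        assert est.ds == pytest.approx(-0.75 * math.log(0.5), abs=1e-9)
        assert est.dn == 0.0
        assert est.omega == 0.0

    def test_nonsynonymous_only_changes_leave_ds_zero(self):
        cds1, cds2, _, _, _ = simulate_cds_pair(50, 0, 6, seed=5)
        est = ng86_divergence(CodonAlignment(cds1, cds2))
        assert est.ds == 0.0 and est.omega is None

    def test_site_counts_sum_to_three_per_codon(self):
        for seed in range(5):
            cds1, cds2, _, _, _ = simulate_cds_pair(40, 4, 4, seed=seed)
            est = ng86_divergence(CodonAlignment(cds1, cds2))
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons)

    def test_symmetric_under_row_swap(self):
        cds1, cds2, _, _, _ = simulate_cds_pair(60, 5, 7, seed=9)
        a = ng86_divergence(CodonAlignment(cds1, cds2))
        b = ng86_divergence(CodonAlignment(cds2, cds1))
        assert a.dn == pytest.approx(b.dn) and a.ds == pytest.approx(b.ds)

    def test_gap_and_ambiguous_columns_skipped(self):
        est = ng86_divergence(CodonAlignment("ATG---AANTTT", "ATGGCTAAATTC"))
        assert est.n_codons == 2  # only ATG and TTT columns compared

    def test_zero_comparable_codons_fails(self):
        with pytest.raises(DivergenceError):
            ng86_divergence(CodonAlignment("---", "ATG"))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_biopython_estimator(self, seed):
        from Bio.Align import Alignment
        from Bio.Align import analysis

        rng = np.random.default_rng(seed)
        cds1, cds2, _, _, _ = simulate_cds_pair(
            120, int(rng.integers(2, 12)), int(rng.integers(2, 15)), seed=seed
        )
        aln = Alignment(
            [cds1, cds2], coordinates=np.array([[0, len(cds1)], [0, len(cds2)]])
        )
        dn_ref, ds_ref = analysis.calculate_dn_ds(aln, method="NG86")
        est = ng86_divergence(CodonAlignment(cds1, cds2))
        assert est.dn == pytest.approx(dn_ref, abs=1e-9)
        assert est.ds == pytest.approx(ds_ref, abs=1e-9)

    def test_recovery_of_planted_per_site_rates(self):
        # light version of the full calibration: 40 replicates
        rel_dn, rel_ds = [], []
        for seed in range(40):
            cds1, cds2, _, _, truth = simulate_cds_pair(300, 20, 30, seed=seed)
            est = ng86_divergence(CodonAlignment(cds1, cds2))
            rel_dn.append(est.dn)
            rel_ds.append(est.ds)
            assert est.sd + est.nd == pytest.approx(50.0)
        # planted proportions are low, so the JC correction stays small
        truth_ds = truth["p_syn"]
        assert abs(np.mean(rel_ds) - truth_ds) / truth_ds < 0.15


class TestImportTable:
    def test_omega_derived(self):
        table = "gene1\tgene2\tdN\tdS\ng1\tg2\t0.1\t0.2\n"
        est = import_divergence_table(table)[("g1", "g2")]
        assert est.omega == pytest.approx(0.5)

    def test_zero_ds_flagged(self):
        table = "gene1\tgene2\tdN\tdS\ng1\tg2\t0.1\t0.0\n"
        est = import_divergence_table(table)[("g1", "g2")]
        assert est.omega is None and "omega_undefined" in est.flags

    def test_reversed_gene_order_same_key(self):
        table = "gene1\tgene2\tdN\tdS\ngB\tgA\t0.1\t0.2\n"
        assert ("gA", "gB") in import_divergence_table(table)

    def test_missing_column_fails(self):
        with pytest.raises(DivergenceError, match="missing"):
            import_divergence_table("gene1\tgene2\tdN\ng1\tg2\t0.1\n")

    def test_non_numeric_fails_with_row(self):
        with pytest.raises(DivergenceError, match="row 1"):
            import_divergence_table("gene1\tgene2\tdN\tdS\ng1\tg2\tx\t0.2\n")
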