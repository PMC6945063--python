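"""Alignment conservation, motif construction/scoring, and site annotation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosbind.msa import (Alignment, ColumnProfile, column_profiles,
                          conservation_score, read_alignment, AMINO_ACIDS,
                          LOG2_20)
from phosbind.motif import (CENTER, WINDOW, build_motif, extract_window,
                            score_site)
from phosbind.sites import annotate_sites, relative_accessibility
from phosbind.structures import assign_parameters

from conftest import make_peptide, make_shell


def aln_from_rows(rows, reference=None):
    ids = [f"s{i}" for i in range(len(rows))]
    return Alignment(ids=ids, sequences=rows,
                     reference=reference or ids[0])


class TestColumnProfiles:
    def test_simple_count_arithmetic(self):
        rows = ["A"] * 8 + ["G"] * 2
        profs = column_profiles(aln_from_rows(rows))
        assert profs[0].frequencies["A"] == pytest.approx(0.8)
        assert profs[0].consensus == "A"

    def test_all_gap_column_flagged(self):
        profs = column_profiles(aln_from_rows(["-A", "-G", "-A"]))
        assert profs[0].gap_fraction == 1.0
        assert profs[0].consensus is None
        assert profs[0].low_confidence

    def test_gap_rule_hand_count(self):
        profs = column_profiles(aln_from_rows(["A", "A", "-", "G"]))
        assert profs[0].frequencies["A"] == pytest.approx(2 / 3)
        assert profs[0].gap_fraction == pytest.approx(0.25)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            aln_from_rows(["AA", "A"])

    def test_tie_breaks_alphabetical(self):
        profs = column_profiles(aln_from_rows(["G", "A"]))
        assert profs[0].consensus == "A"


class TestConservationScore:
    def test_fully_conserved_is_9(self):
        profs = column_profiles(aln_from_rows(["W"] * 5))
        assert conservation_score(profs[0]) == 9

    def test_uniform_20_is_0(self):
        profs = column_profiles(aln_from_rows(list(AMINO_ACIDS)))
        assert conservation_score(profs[0]) == 0

    def test_two_state_entropy_arithmetic(self):
        # H = 1 bit -> floor(9 * (1 - 1/log2(20))) = 6
        profs = column_profiles(aln_from_rows(["A", "A", "G", "G"]))
        assert conservation_score(profs[0]) == 6

    def test_all_gap_rejected(self):
        prof = ColumnProfile(counts={}, gap_fraction=1.0, frequencies={},
                             consensus=None)
        with pytest.raises(ValueError):
            conservation_score(prof)


class TestBuildMotif:
    def test_identical_windows_full_information(self):
        seq = "ARNDCQEGHILKMFY"   # 15-mer, site at position 8
        motif = build_motif([(seq, 8)] * 5, alpha=0.0)
        assert np.allclose(motif.information_bits, LOG2_20)
        assert motif.consensus() == seq

    def test_uniform_windows_zero_information(self):
        subs = [(AMINO_ACIDS[i % 20] * WINDOW, 8) for i in range(20)]
        motif = build_motif(subs, alpha=0.0)
        assert np.allclose(motif.information_bits, 0.0, atol=1e-12)

    def test_counts_match_scripted_oracle(self):
        s1 = "AAAAAAAAAAAAAAA"
        s2 = "AAAAAAAWAAAAAAA"
        motif = build_motif([(s1, 8), (s2, 8)], alpha=0.01)
        a_idx = AMINO_ACIDS.index("A")
        w_idx = AMINO_ACIDS.index("W")
        # position 8 (index 7): one A, one W
        expected_a = (1 + 0.01) / (2 + 20 * 0.01)
        assert motif.ppm[7, a_idx] == pytest.approx(expected_a)
        assert motif.ppm[7, w_idx] == pytest.approx(expected_a)
        # entropy at that position, computed independently
        probs = np.full(20, 0.01 / 2.2)
        probs[a_idx] = probs[w_idx] = 1.01 / 2.2
        h = -(probs * np.log2(probs)).sum()
        assert motif.information_bits[7] == pytest.approx(LOG2_20 - h)

    def test_window_edge_padding(self):
        w = extract_window("MSAR", 2)     # site near the N-terminus
        assert len(w) == WINDOW
        assert w == "XXXXXXMSARXXXXX"
        assert w[CENTER - 1] == "S"

    def test_out_of_range_site_named(self):
        with pytest.raises(IndexError, match="substrate 1"):
            build_motif([("AAAA", 2), ("AAAA", 9)])

    def test_ppm_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        subs = [("".join(rng.choice(list(AMINO_ACIDS), WINDOW)), 8)
                for _ in range(10)]
        motif = build_motif(subs, alpha=0.05)
        assert np.allclose(motif.ppm.sum(axis=1), 1.0)

    def test_information_invariant_under_residue_relabeling(self):
        rng = np.random.default_rng(1)
        subs = [("".join(rng.choice(list(AMINO_ACIDS), WINDOW)), 8)
                for _ in range(30)]
        perm = rng.permutation(list(AMINO_ACIDS))
        mapping = dict(zip(AMINO_ACIDS, perm))
        subs_perm = [("".join(mapping[c] for c in s), p) for s, p in subs]
        m1 = build_motif(subs, alpha=0.0)
        m2 = build_motif(subs_perm, alpha=0.0)
        assert np.allclose(m1.information_bits, m2.information_bits)


class TestScoreSite:
    def test_motif_equals_background_scores_zero(self):
        subs = [(AMINO_ACIDS[i % 20] * WINDOW, 8) for i in range(20)]
        motif = build_motif(subs, alpha=0.0)   # uniform PPM
        assert score_site("W" * WINDOW, 8, motif) == pytest.approx(0.0, abs=1e-9)

    def test_all_x_window_scores_zero(self):
        motif = build_motif([("ARNDCQEGHILKMFY", 8)], alpha=0.01)
        assert score_site("X" * WINDOW, 8, motif) == 0.0

    def test_own_window_beats_random_windows(self):
        seq = "ARNDCQEGHILKMFY"
        motif = build_motif([(seq, 8)], alpha=0.01)
        own = score_site(seq, 8, motif)
        rng = np.random.default_rng(2)
        for _ in range(100):
            w = "".join(rng.choice(list(AMINO_ACIDS), WINDOW))
            assert score_site(w, 8, motif) <= own

    def test_out_of_range_rejected(self):
        motif = build_motif([("A" * WINDOW, 8)], alpha=0.01)
        with pytest.raises(IndexError):
            score_site("AAAA", 9, motif)


class TestRelativeAccessibility:
    def test_extended_central_residue_mostly_exposed(self, ala_ser_ala):
        s = assign_parameters(ala_ser_ala)
        rsa = relative_accessibility(s, [("A", 2)])[0]
        assert 80.0 <= rsa <= 110.0

    def test_enclosed_residue_zero(self):
        shell = make_shell()
        for a in shell.atoms:
            a.res_name = "ALA" if a.res_seq == 1 else a.res_name
        rsa = relative_accessibility(shell, [("A", 1)])[0]
        assert rsa == 0.0

    def test_monotone_under_approaching_blocker(self, ala_ser_ala):
        s = assign_parameters(ala_ser_ala)
        base = relative_accessibility(s, [("A", 2)])[0]
        vals = [base]
        for dy in (8.0, 5.0):
            blocked = s.copy()
            extra = make_peptide(["ALA", "ALA", "ALA"], chain="B")
            extra = assign_parameters(extra)
            for a in extra.atoms:
                a.xyz = a.xyz + np.array([0.0, -dy, 0.0])
                a.serial += 100
            from phosbind.structures import ParamStructure
            blocked = ParamStructure(blocked.atoms + extra.atoms)
            vals.append(relative_accessibility(blocked, [("A", 2)])[0])
        assert vals[0] > vals[1] > vals[2]

    def test_missing_residue_rejected(self, ala_ser_ala):
        with pytest.raises(KeyError):
            relative_accessibility(assign_parameters(ala_ser_ala), [("A", 99)])


class TestAnnotateSites:
    def _setup(self):
        seq = "AMSRALSGA"
        rows = [seq, seq, seq.replace("S", "T"), seq]
        aln = aln_from_rows(rows)
        motif = build_motif([("AAAAAAASAAAAAAA", 8)] * 3, alpha=0.01)
        return seq, aln, motif

    def test_fully_conserved_site(self):
        seq, aln, motif = self._setup()
        annos = annotate_sites(seq, aln, None, motif, [1])
        assert annos[0].conservation == 9
        assert annos[0].residue == "A"

    def test_partial_data_flagged(self):
        seq, aln, motif = self._setup()
        annos = annotate_sites(seq, aln, None, motif, [3])
        assert annos[0].rsa_percent is None
        assert "no_structure" in annos[0].flags
        assert annos[0].conservation is not None
        assert annos[0].motif_score_bits is not None

    def test_matches_piecewise_ops(self, ala_ser_ala):
        s = assign_parameters(ala_ser_ala)
        seq = "ASA"
        aln = aln_from_rows(["ASA", "ASA", "AGA"])
        motif = build_motif([("AAAAAAASAAAAAAA", 8)] * 2, alpha=0.01)
        annos = annotate_sites(seq, aln, s, motif, [2])
        profs = column_profiles(aln)
        assert annos[0].conservation == conservation_score(profs[1])
        assert annos[0].rsa_percent == pytest.approx(
            relative_accessibility(s, [("A", 2)])[0])
        assert annos[0].motif_score_bits == pytest.approx(
            score_site(seq, 2, motif))

    def test_reference_mismatch_rejected(self):
        seq, aln, motif = self._setup()
        with pytest.raises(ValueError):
            annotate_sites("WRONG", aln, None, motif, [1])


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">ref\nAC-GT\n>o1\nACAGT\n")
        aln = read_alignment(p)
        assert aln.reference == "ref"
        assert aln.n_columns == 5
        assert aln.column_of_reference_position(3) == 3   # gap skipped

    def test_stockholm(self, tmp_path):
        p = tmp_path / "aln.sto"
        p.write_text("# STOCKHOLM 1.0\nref  ACDEF\no1   ACDEG\n//\n")
        aln = read_alignment(p)
        assert len(aln.sequences) == 2
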