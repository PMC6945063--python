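"""Generators: determinism, ground-truth bookkeeping, and recovery."""
import numpy as np
import pytest

from phosbind.energetics import binding_energy
from phosbind.msa import column_profiles, conservation_score
from phosbind.motif import CENTER, build_motif
from phosbind.structures import read_pqr, write_pqr
from phosbind.synthetic import (AlignmentSpec, TelegraphSpec, ToyComplexSpec,
                                default_motif_ppm, gen_alignment,
                                gen_born_system, gen_contact_trajectory,
                                gen_substrate_windows, gen_toy_complex,
                                stream_seed)


class TestBornSystem:
    def test_single_atom(self):
        sys = gen_born_system(1.0, 2.0)
        assert len(sys.structure) == 1
        assert sys.structure.total_charge() == 1.0

    def test_pqr_roundtrip(self, tmp_path):
        sys = gen_born_system(-2.0, 1.5)
        p = tmp_path / "born.pqr"
        write_pqr(sys.structure, p)
        s2 = read_pqr(p)
        assert s2.atoms[0].charge == -2.0 and s2.atoms[0].radius == 1.5

    def test_analytic_energy_metadata(self):
        sys = gen_born_system(1.0, 2.0)
        # Born formula, scripted independently
        f = 1389.35458
        assert sys.analytic_energy(2.0, 80.0) == pytest.approx(
            -f / 2 * 1 / 2.0 * (1 / 2 - 1 / 80))

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            gen_born_system(1.0, 0.0)


class TestToyComplex:
    def test_single_atom_chains_closed_form(self):
        spec = ToyComplexSpec(atoms_per_chain=1, separation=10.0,
                              cluster_radius=0.0, seed=0)
        s, ref = gen_toy_complex(spec)
        f = 1389.35458
        sr6 = (spec.lj_sigma / 10.0) ** 6
        expected = -f / 10.0 + 4 * spec.lj_epsilon * (sr6 ** 2 - sr6)
        assert ref == pytest.approx(expected, rel=1e-12)
        # and the energetics path reproduces the generator's reference
        b = binding_energy(s, "A", "B", include_polar=False)
        assert b.total[0] == pytest.approx(ref, rel=1e-9)

    def test_zero_charges_pure_lj(self):
        s, ref = gen_toy_complex(ToyComplexSpec(charge_pattern="zero", seed=1))
        b = binding_energy(s, "A", "B", include_polar=False)
        assert b.e_elec[0] == 0.0
        assert b.e_vdw[0] == pytest.approx(ref, rel=1e-9)

    def test_determinism(self):
        s1, r1 = gen_toy_complex(ToyComplexSpec(seed=42))
        s2, r2 = gen_toy_complex(ToyComplexSpec(seed=42))
        assert np.array_equal(s1.coords, s2.coords)
        assert r1 == r2

    def test_dipole_chains_are_neutral(self):
        s, _ = gen_toy_complex(ToyComplexSpec(charge_pattern="dipole", seed=2))
        for chain in ("A", "B"):
            q = sum(s.atoms[i].charge for i in s.chain_indices(chain))
            assert q == pytest.approx(0.0, abs=1e-12)

    def test_overlap_guard(self):
        s, _ = gen_toy_complex(ToyComplexSpec(seed=5))
        d = np.linalg.norm(s.coords[:, None] - s.coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 2.0


class TestTelegraph:
    def test_k_on_zero_no_events(self):
        traj, states, events = gen_contact_trajectory(
            TelegraphSpec(k_on=0.0, n_frames=500, seed=0))
        assert events == []
        assert np.all(states == 0)

    def test_deterministic_alternation(self):
        _, states, _ = gen_contact_trajectory(
            TelegraphSpec(k_on=1.0, k_off=1.0, n_frames=10, seed=0))
        assert np.array_equal(states, np.arange(10) % 2)

    def test_stationary_bound_fraction(self):
        spec = TelegraphSpec(k_on=0.02, k_off=0.01, n_frames=100_000, seed=3)
        _, states, _ = gen_contact_trajectory(spec)
        expected = spec.k_on / (spec.k_on + spec.k_off)
        assert abs(states.mean() - expected) < 0.02

    def test_distance_reflects_state(self):
        traj, states, _ = gen_contact_trajectory(TelegraphSpec(n_frames=800, seed=1))
        d = np.array([np.linalg.norm(f[3] - f[1]) for f in traj.frames])
        assert abs(d[states == 1].mean() - 4.5) < 0.1
        assert abs(d[states == 0].mean() - 9.0) < 0.1


class TestAlignmentGenerator:
    def test_fully_conserved_column(self):
        spec = AlignmentSpec(n_sequences=50, n_columns=3,
                             conservation=np.array([1.0, 1.0, 1.0]), seed=0)
        aln = gen_alignment(spec)
        for col in range(3):
            assert len({s[col] for s in aln.sequences}) == 1

    def test_near_uniform_column_low_score(self):
        spec = AlignmentSpec(n_sequences=500, n_columns=2,
                             conservation=np.array([0.05, 0.05]), seed=0)
        aln = gen_alignment(spec)
        profs = column_profiles(aln)
        assert conservation_score(profs[0]) <= 1

    def test_seed_reproducibility(self):
        a1 = gen_alignment(AlignmentSpec(n_sequences=20, seed=9))
        a2 = gen_alignment(AlignmentSpec(n_sequences=20, seed=9))
        assert a1.sequences == a2.sequences

    def test_conservation_recovery(self):
        """Column max frequency tracks the generating p (n = 500)."""
        spec = AlignmentSpec(n_sequences=500, seed=0)
        aln = gen_alignment(spec)
        profs = column_profiles(aln)
        ok = 0
        for p, prof in zip(spec.conservation, profs):
            maxf = max(f for a, f in prof.frequencies.items() if a != "X")
            ok += abs(maxf - p) <= 0.05
        assert ok / len(profs) >= 0.95


class TestSubstrateWindows:
    def test_degenerate_ppm_identical_windows(self):
        ppm = np.zeros((15, 20)); ppm[:, 3] = 1.0
        wins = gen_substrate_windows(ppm, 5, seed=0, force_central_serine=False)
        assert len(set(wins)) == 1

    def test_recovery_tv_bound(self):
        ppm = default_motif_ppm()
        wins = gen_substrate_windows(ppm, 1000, seed=0)
        motif = build_motif([(w, CENTER) for w in wins], alpha=0.0)
        tv = 0.5 * np.abs(motif.ppm - ppm).sum(axis=1)
        assert tv.max() <= 0.05

    def test_central_serine_forced(self):
        ppm = np.full((15, 20), 1 / 20)
        wins = gen_substrate_windows(ppm, 20, seed=1)
        assert all(w[CENTER - 1] == "S" for w in wins)


class TestSeedFanout:
    def test_stable_and_independent(self):
        assert stream_seed("a", 1) == stream_seed("a", 1)
        assert stream_seed("a", 1) != stream_seed("b", 1)
        assert 0 <= stream_seed("x", 12345) < 2 ** 31
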