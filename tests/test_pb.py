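"""Linearized Poisson-Boltzmann solver: closed forms and linearity."""
import numpy as np
import pytest

from phosbind.pb import (PBConfig, born_energy, debye_length, polar_binding,
                         solve_lpbe)
from phosbind.structures import Atom, ParamStructure
from phosbind.synthetic import gen_born_system


def ion(q, radius, xyz=(0, 0, 0), serial=1, chain="A", res_seq=1):
    return Atom(serial=serial, name=f"Q{serial}", res_name="ION",
                res_seq=res_seq, chain_id=chain, xyz=np.array(xyz, dtype=float),
                charge=q, radius=radius, element="C")


FAST = dict(ionic_strength=0.0, temperature=298.0, fine_spacing=0.5,
            solver_tol=1e-6)


class TestClosedForms:
    def test_born_ion_within_3_percent(self):
        sys = gen_born_system(1.0, 2.0)
        cfg = PBConfig(**{**FAST, "fine_spacing": 0.25})
        res = solve_lpbe(sys.structure, cfg)
        exact = sys.analytic_energy(2.0, 80.0)
        assert exact == pytest.approx(-169.3275894375)
        assert abs(res.g_polar - exact) / abs(exact) < 0.03

    def test_refinement_reduces_error(self):
        sys = gen_born_system(1.0, 2.0)
        exact = sys.analytic_energy(2.0, 80.0)
        errs = []
        for h in (1.0, 0.5, 0.25):
            res = solve_lpbe(sys.structure, PBConfig(**{**FAST, "fine_spacing": h}))
            errs.append(abs(res.g_polar - exact))
        assert errs[0] > errs[1] > errs[2]

    def test_debye_length_closed_form(self):
        lam = debye_length(0.150, 298.0, 78.54)
        assert lam == pytest.approx(7.86, rel=0.01)

    def test_no_dielectric_contrast_gives_zero(self):
        s = ParamStructure([ion(1.0, 2.0)])
        cfg = PBConfig(eps_solute=79.999999, eps_solvent=80.0, **{
            k: v for k, v in FAST.items() if k != "fine_spacing"},
            fine_spacing=0.5)
        res = solve_lpbe(s, cfg)
        assert abs(res.g_polar) < 0.05


class TestLinearity:
    def test_superposition_of_charges(self):
        """The LPBE is linear: the two-charge potential equals the sum of
        single-charge solves on the same grid."""
        from phosbind.pb import _build_grids

        cfg = PBConfig(**FAST)
        a1 = ion(1.0, 1.8, (0, 0, 0), serial=1)
        a2 = ion(-0.5, 1.8, (4, 0, 0), serial=2, res_seq=2)
        both = ParamStructure([a1, a2])
        grids = _build_grids(both.coords, both.radii, cfg)
        res_both = solve_lpbe(both, cfg, grids=grids)

        # single-charge systems keep BOTH cavities so the dielectric map
        # (and hence the linear operator) is identical
        def zero_charge(atom):
            c = atom.copy()
            c.charge = 0.0
            return c

        only1 = ParamStructure([a1.copy(), zero_charge(a2)])
        only2 = ParamStructure([zero_charge(a1), a2.copy()])
        r1 = solve_lpbe(only1, cfg, grids=grids)
        r2 = solve_lpbe(only2, cfg, grids=grids)
        diff = np.abs(res_both.phi - (r1.phi + r2.phi))
        assert diff.max() <= 1e-3 * np.abs(res_both.phi).max()


class TestPolarBinding:
    def test_neutral_chains_zero_exactly(self):
        s = ParamStructure([ion(0.0, 1.9, (0, 0, 0), 1, "A"),
                            ion(0.0, 1.9, (6, 0, 0), 2, "B")])
        ddg, per_atom, _ = polar_binding(s, "A", "B", PBConfig(**FAST))
        assert ddg == 0.0
        assert np.all(per_atom == 0.0)

    def test_matches_three_independent_solves(self):
        """The convenience routine equals raw solver calls scripted by hand."""
        from phosbind.pb import _build_grids

        cfg = PBConfig(**FAST)
        s = ParamStructure([ion(1.0, 1.9, (0, 0, 0), 1, "A"),
                            ion(-1.0, 1.9, (5, 0, 0), 2, "B", res_seq=1)])
        ddg, per_atom, _ = polar_binding(s, "A", "B", cfg)
        grids = _build_grids(s.coords, s.radii, cfg)
        g_ab = solve_lpbe(s, cfg, grids=grids).g_polar
        g_a = solve_lpbe(s.subset([0]), cfg, grids=grids).g_polar
        g_b = solve_lpbe(s.subset([1]), cfg, grids=grids).g_polar
        assert ddg == pytest.approx(g_ab - g_a - g_b, abs=1e-9)
        assert per_atom.sum() == pytest.approx(ddg, abs=1e-9)

    def test_far_separated_neutral_chains_near_zero(self):
        """Polar binding of net-neutral chains vanishes beyond the screening
        range. (For net-charged chains it instead tends to the negative of
        the solute-dielectric Coulomb term — the long-range limit is only
        zero for neutral species.)"""
        cfg = PBConfig(ionic_strength=0.150, temperature=298.0,
                       fine_spacing=0.6, solver_tol=1e-6)
        lam = debye_length(0.150, 298.0, 80.0)
        sep = 4 * lam + 2 * cfg.fine_margin
        atoms = [ion(1.0, 1.9, (0, 0, 0), 1, "A"),
                 ion(-1.0, 1.9, (3.0, 0, 0), 2, "A", res_seq=2),
                 ion(-1.0, 1.9, (sep, 0, 0), 3, "B", res_seq=1),
                 ion(1.0, 1.9, (sep + 3.0, 0, 0), 4, "B", res_seq=2)]
        s = ParamStructure(atoms)
        ddg, _, _ = polar_binding(s, "A", "B", cfg)
        assert abs(ddg) < 0.5

    def test_charged_chains_polar_cancels_coulomb(self):
        """For two distant unit charges with eps_in = 1, the polar binding
        term cancels the vacuum Coulomb interaction (screened limit)."""
        from phosbind.constants import COULOMB_KJ

        cfg = PBConfig(eps_solute=1.0, ionic_strength=0.150, temperature=298.0,
                       fine_spacing=0.6, solver_tol=1e-6)
        lam = debye_length(0.150, 298.0, 80.0)
        sep = 4 * lam + 2 * cfg.fine_margin
        s = ParamStructure([ion(1.0, 1.9, (0, 0, 0), 1, "A"),
                            ion(-1.0, 1.9, (sep, 0, 0), 2, "B", res_seq=1)])
        ddg, _, _ = polar_binding(s, "A", "B", cfg)
        e_vac = -COULOMB_KJ / sep
        assert abs(e_vac + ddg) < 0.5


class TestErrors:
    def test_escaping_solute_rejected(self):
        from phosbind.pb import Grid

        s = ParamStructure([ion(1.0, 2.0)])
        tiny = Grid(origin=np.array([-1.0, -1.0, -1.0]), spacing=0.5,
                    shape=(5, 5, 5))
        with pytest.raises(ValueError, match="escapes"):
            solve_lpbe(s, PBConfig(**FAST), grids=(tiny, tiny))

    def test_nonconvergence_reported(self):
        s = ParamStructure([ion(1.0, 2.0)])
        cfg = PBConfig(**{**FAST, "max_iter": 2})
        with pytest.raises(RuntimeError, match="residual"):
            solve_lpbe(s, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PBConfig(eps_solute=90.0)
        with pytest.raises(ValueError):
            PBConfig(coarse_factor=0.5)
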