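"""MM-PBSA binding free energies of two-chain complexes.

In the single-trajectory scheme, receptor and ligand conformations are the
chains of each complex frame, so bonded terms cancel identically and the
per-frame binding energy is

    dG = E_vdW + E_elec + ddG_polar + ddG_nonpolar

with the inter-chain molecular-mechanics terms evaluated in vacuum
(eps = 1) over all atom pairs (no cutoff), the polar term from the focused
FD-LPBE solver (:mod:`phosbind.pb`), and the nonpolar term from the SASA
model, ddG_nonpolar = gamma * (SASA_AB - SASA_A - SASA_B); the constant
offset of the per-species SASA model cancels in the difference. The
configurational-entropy term -T dS of the full free-energy decomposition is
not evaluated and is reported as absent, never silently folded into totals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_KJ
from .pb import PBConfig, polar_binding
from .sasa import SASAConfig, sasa
from .structures import ParamStructure, Selection, Trajectory

__all__ = ["EnergyBreakdown", "ResidueEnergyMap", "coulomb_energy", "lj_energy",
           "nonpolar_energy", "binding_energy", "residue_decomposition",
           "compare_states", "SASAConfig", "PBConfig"]

_COMPONENTS = ("e_vdw", "e_elec", "g_polar", "g_nonpolar", "total")


def _pair_arrays(s: ParamStructure, groupA: Selection, groupB: Selection):
    ia, ib = groupA.indices, groupB.indices
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap")
    ca = s.coords[ia]; cb = s.coords[ib]
    r = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    if np.any(r == 0):
        raise ValueError("coincident atoms between groups (r = 0)")
    return ia, ib, r


def coulomb_energy(s: ParamStructure, groupA: Selection, groupB: Selection,
                   eps: float = 1.0, per_atom: bool = False):
    """Inter-group Coulomb energy, f*qi*qj/(eps*r), all pairs, no cutoff."""
    ia, ib, r = _pair_arrays(s, groupA, groupB)
    q = s.charges
    e_pair = COULOMB_KJ * np.outer(q[ia], q[ib]) / (eps * r)
    total = float(e_pair.sum())
    if not per_atom:
        return total
    split = np.zeros(len(s))
    split[ia] += 0.5 * e_pair.sum(axis=1)
    split[ib] += 0.5 * e_pair.sum(axis=0)
    return total, split


def lj_energy(s: ParamStructure, groupA: Selection, groupB: Selection,
              per_atom: bool = False):
    """Inter-group Lennard-Jones energy, Lorentz-Berthelot combination."""
    ia, ib, r = _pair_arrays(s, groupA, groupB)
    epss = np.array([a.lj_epsilon for a in s.atoms])
    sigs = np.array([a.lj_sigma for a in s.atoms])
    eps_ij = np.sqrt(np.outer(epss[ia], epss[ib]))
    sig_ij = 0.5 * (sigs[ia][:, None] + sigs[ib][None, :])
    sr6 = (sig_ij / r) ** 6
    e_pair = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    total = float(e_pair.sum())
    if not per_atom:
        return total
    split = np.zeros(len(s))
    split[ia] += 0.5 * e_pair.sum(axis=1)
    split[ib] += 0.5 * e_pair.sum(axis=0)
    return total, split


def nonpolar_energy(area: float, cfg: SASAConfig | None = None) -> float:
    """SASA-model nonpolar solvation energy: gamma * area + b."""
    if cfg is None:
        cfg = SASAConfig()
    if area < 0:
        raise ValueError("negative area")
    return cfg.gamma * area + cfg.offset_b


@dataclass
class EnergyBreakdown:
    """Frame-resolved energy terms with (mean, SD) summaries, kJ/mol.

    ``entropy_term`` records that -T dS is omitted; it is never part of
    ``total``.
    """

    e_vdw: np.ndarray
    e_elec: np.ndarray
    g_polar: np.ndarray
    g_nonpolar: np.ndarray
    entropy_term: None = None

    def __post_init__(self):
        for name in ("e_vdw", "e_elec", "g_polar", "g_nonpolar"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=float)))

    @property
    def total(self) -> np.ndarray:
        return self.e_vdw + self.e_elec + self.g_polar + self.g_nonpolar

    @property
    def n_frames(self) -> int:
        return len(self.e_vdw)

    def mean_sd(self, component: str) -> tuple[float, float]:
        x = getattr(self, component) if component != "total" else self.total
        m = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return m, sd

    def summary_rows(self) -> list[tuple[str, float, float]]:
        labels = {"e_vdw": "van der Waals", "e_elec": "Electrostatic",
                  "g_polar": "Polar solvation", "g_nonpolar": "SASA",
                  "total": "Total binding energy"}
        return [(labels[c], *self.mean_sd(c)) for c in _COMPONENTS]


def binding_energy(traj: Trajectory | ParamStructure, chain_a: str, chain_b: str,
                   pb: PBConfig | None = None,
                   sasa_cfg: SASAConfig | None = None,
                   frame_interval_ps: float = 0.0,
                   include_polar: bool = True) -> EnergyBreakdown:
    """MM-PBSA binding energy over (subsampled) trajectory frames.

    A bare :class:`ParamStructure` is treated as a single-frame trajectory.
    ``frame_interval_ps`` subsamples frames (default: use every frame;
    production analyses of long trajectories conventionally use 10 ns).
    ``include_polar=False`` skips the PB solve (vacuum-matched dielectrics),
    for fixtures with closed-form references.
    """
    if pb is None:
        pb = PBConfig()
    if sasa_cfg is None:
        sasa_cfg = SASAConfig()
    if isinstance(traj, ParamStructure):
        traj = Trajectory(traj, [traj.coords], [0.0])
    if frame_interval_ps > 0:
        traj = traj.subsample(frame_interval_ps)
    if len(traj) < 1:
        raise ValueError("no frames left after subsampling")

    top = traj.topology
    ia = top.chain_indices(chain_a)
    ib = top.chain_indices(chain_b)
    if len(ia) + len(ib) != len(top):
        raise ValueError("chains A and B must partition the structure")

    vdw, elec, pol, npol = [], [], [], []
    for frame in traj.frames:
        s = top.copy()
        s.coords = frame
        ga = Selection(ia, f"chain {chain_a}")
        gb = Selection(ib, f"chain {chain_b}")
        vdw.append(lj_energy(s, ga, gb))
        elec.append(coulomb_energy(s, ga, gb, eps=1.0))
        if include_polar:
            ddg_pol, _, _ = polar_binding(s, chain_a, chain_b, pb)
        else:
            ddg_pol = 0.0
        pol.append(ddg_pol)
        _, areas = sasa(s, sasa_cfg)
        _, areas_a = sasa(s.subset(ia), sasa_cfg)
        _, areas_b = sasa(s.subset(ib), sasa_cfg)
        d_area = areas.sum() - areas_a.sum() - areas_b.sum()
        npol.append(sasa_cfg.gamma * d_area)   # offsets b cancel in the difference
    return EnergyBreakdown(e_vdw=np.array(vdw), e_elec=np.array(elec),
                           g_polar=np.array(pol), g_nonpolar=np.array(npol))


@dataclass
class ResidueEnergyMap:
    """Per-residue (chain, res_seq) -> component energies, kJ/mol."""

    components: dict[tuple[str, int], dict[str, float]]

    def totals(self) -> dict[str, float]:
        out = {c: 0.0 for c in _COMPONENTS}
        for vals in self.components.values():
            for c in _COMPONENTS:
                out[c] += vals[c]
        return out

    def as_bfactor_values(self, component: str = "total") -> dict:
        return {k: v[component] for k, v in self.components.items()}


def residue_decomposition(traj: Trajectory | ParamStructure, chain_a: str,
                          chain_b: str, pb: PBConfig | None = None,
                          sasa_cfg: SASAConfig | None = None,
                          frame_interval_ps: float = 0.0,
                          include_polar: bool = True) -> ResidueEnergyMap:
    """Residue-wise split of the binding energy (frame-averaged).

    Pairwise MM terms are split half to each partner atom; polar and
    nonpolar per-atom splits come from the PB solver and the SASA
    difference. Summing any component over all residues reproduces the
    complex-level component exactly (to floating-point round-off).
    """
    if pb is None:
        pb = PBConfig()
    if sasa_cfg is None:
        sasa_cfg = SASAConfig()
    if isinstance(traj, ParamStructure):
        traj = Trajectory(traj, [traj.coords], [0.0])
    if frame_interval_ps > 0:
        traj = traj.subsample(frame_interval_ps)
    top = traj.topology
    ia = top.chain_indices(chain_a)
    ib = top.chain_indices(chain_b)
    n = len(top)
    acc = {c: np.zeros(n) for c in ("e_vdw", "e_elec", "g_polar", "g_nonpolar")}
    for frame in traj.frames:
        s = top.copy()
        s.coords = frame
        ga = Selection(ia, f"chain {chain_a}")
        gb = Selection(ib, f"chain {chain_b}")
        _, vdw_split = lj_energy(s, ga, gb, per_atom=True)
        _, elec_split = coulomb_energy(s, ga, gb, eps=1.0, per_atom=True)
        acc["e_vdw"] += vdw_split
        acc["e_elec"] += elec_split
        if include_polar:
            _, pol_split, _ = polar_binding(s, chain_a, chain_b, pb)
            acc["g_polar"] += pol_split
        _, areas = sasa(s, sasa_cfg)
        _, areas_a = sasa(s.subset(ia), sasa_cfg)
        _, areas_b = sasa(s.subset(ib), sasa_cfg)
        d_areas = areas.copy()
        d_areas[ia] -= areas_a
        d_areas[ib] -= areas_b
        acc["g_nonpolar"] += sasa_cfg.gamma * d_areas
    nf = len(traj.frames)
    for c in acc:
        acc[c] /= nf
    comps: dict[tuple[str, int], dict[str, float]] = {}
    for chain_id, res_seq, _name in top.residues():
        idx = top.residue_atoms(chain_id, res_seq)
        vals = {c: float(acc[c][idx].sum()) for c in acc}
        vals["total"] = sum(vals.values())
        comps[(chain_id, res_seq)] = vals
    return ResidueEnergyMap(components=comps)


def compare_states(b1: EnergyBreakdown, b2: EnergyBreakdown,
                   allow_unequal_n: bool = False) -> dict[str, tuple[float, float]]:
    """Component-wise ddG = state2 - state1 with SD propagated in quadrature."""
    if b1.n_frames != b2.n_frames and not allow_unequal_n:
        raise ValueError("frame counts differ; pass allow_unequal_n=True "
                         "to compare anyway")
    out = {}
    for c in _COMPONENTS:
        m1, s1 = b1.mean_sd(c)
        m2, s2 = b2.mean_sd(c)
        out[c] = (m2 - m1, math.hypot(s1, s2))
    return out
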