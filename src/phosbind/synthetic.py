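"""Synthetic fixtures with known ground truth.

Every pipeline stage can be exercised without external data: Born ions and
toy two-chain charge systems with closed-form energies, two-state
(telegraph) contact trajectories with Gaussian noise, ortholog-like
alignments with controlled per-column conservation, and substrate windows
drawn from a known position probability matrix. All generators are
deterministic given (spec, seed); a single global seed fans out to
independent per-generator streams by stable hashing of the generator name.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KJ
from .msa import AMINO_ACIDS, Alignment
from .motif import CENTER, WINDOW
from .pb import born_energy
from .structures import Atom, ParamStructure, Trajectory

__all__ = ["stream_seed", "BornSystem", "gen_born_system", "ToyComplexSpec",
           "gen_toy_complex", "TelegraphSpec", "gen_contact_trajectory",
           "AlignmentSpec", "gen_alignment", "gen_substrate_windows",
           "default_motif_ppm", "gen_peptide"]


def stream_seed(name: str, seed: int) -> int:
    """Derive an independent, stable sub-stream seed below 2^31."""
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Born ion
# ---------------------------------------------------------------------------

@dataclass
class BornSystem:
    structure: ParamStructure
    charge: float
    radius: float

    def analytic_energy(self, eps_in: float, eps_out: float) -> float:
        """Closed-form Born solvation energy for this ion (kJ/mol)."""
        return born_energy(self.charge, self.radius, eps_in, eps_out)


def gen_born_system(q: float, radius: float) -> BornSystem:
    """A single ion at the origin — the canonical PB validation fixture."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = Atom(serial=1, name="Q", res_name="ION", res_seq=1, chain_id="A",
                xyz=np.zeros(3), charge=q, radius=radius, element="Na")
    return BornSystem(structure=ParamStructure([atom], title="Born ion"),
                      charge=q, radius=radius)


# ---------------------------------------------------------------------------
# toy two-chain complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    atoms_per_chain: int = 4
    charge_pattern: str = "opposite"    # "opposite" | "dipole" | "zero"
    charge_magnitude: float = 1.0       # e
    separation: float = 10.0            # A between chain centroids
    cluster_radius: float = 2.5         # A spread within a chain
    atom_radius: float = 1.9            # A
    lj_epsilon: float = 0.45            # kJ/mol
    lj_sigma: float = 3.4               # A
    min_pair_distance: float = 2.0      # A overlap guard
    seed: int = 0

    def __post_init__(self):
        if self.atoms_per_chain < 1:
            raise ValueError("need at least one atom per chain")
        if self.charge_pattern not in ("opposite", "dipole", "zero"):
            raise ValueError(f"unknown charge pattern {self.charge_pattern!r}")
        if self.charge_pattern == "dipole" and self.atoms_per_chain < 2:
            raise ValueError("dipole pattern needs >= 2 atoms per chain")


def _chain_charges(spec: ToyComplexSpec, chain: str) -> np.ndarray:
    n, q = spec.atoms_per_chain, spec.charge_magnitude
    if spec.charge_pattern == "zero":
        return np.zeros(n)
    if spec.charge_pattern == "opposite":
        return np.full(n, q if chain == "A" else -q)
    # dipole: +q/-q pairs within each chain, net zero
    charges = np.zeros(n)
    charges[0::2] = q
    charges[1::2] = -q
    if n % 2 == 1:
        charges[-1] = 0.0
    return charges


def gen_toy_complex(spec: ToyComplexSpec) -> tuple[ParamStructure, float]:
    """Two-chain charge cluster plus its closed-form vacuum interaction.

    The reference energy is the brute-force inter-chain Coulomb + LJ pair
    sum evaluated in plain Python, independent of the vectorized energetics
    path. Placement retries up to 100 times to satisfy the overlap guard.
    """
    rng = np.random.default_rng(stream_seed("toy_complex", spec.seed))
    n = spec.atoms_per_chain
    for _attempt in range(100):
        pos_a = rng.uniform(-spec.cluster_radius, spec.cluster_radius, (n, 3))
        pos_b = rng.uniform(-spec.cluster_radius, spec.cluster_radius, (n, 3))
        pos_b[:, 0] += spec.separation
        allpos = np.vstack([pos_a, pos_b])
        d = np.linalg.norm(allpos[:, None] - allpos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > spec.min_pair_distance:
            break
    else:
        raise RuntimeError("could not place atoms without overlap in 100 attempts")

    atoms = []
    serial = 1
    for chain, pos in (("A", pos_a), ("B", pos_b)):
        charges = _chain_charges(spec, chain)
        for i in range(n):
            atoms.append(Atom(serial=serial, name=f"Q{i + 1}", res_name="TOY",
                              res_seq=i + 1, chain_id=chain, xyz=pos[i],
                              charge=float(charges[i]), radius=spec.atom_radius,
                              lj_epsilon=spec.lj_epsilon, lj_sigma=spec.lj_sigma,
                              element="C"))
            serial += 1
    s = ParamStructure(atoms, title="toy two-chain complex")

    # brute-force reference: plain double loop over inter-chain pairs
    ref = 0.0
    qa = _chain_charges(spec, "A")
    qb = _chain_charges(spec, "B")
    for i in range(n):
        for j in range(n):
            r = math.dist(pos_a[i], pos_b[j])
            ref += COULOMB_KJ * qa[i] * qb[j] / r
            sr6 = (spec.lj_sigma / r) ** 6
            ref += 4.0 * spec.lj_epsilon * (sr6 * sr6 - sr6)
    return s, float(ref)


# ---------------------------------------------------------------------------
# telegraph contact trajectory
# ---------------------------------------------------------------------------

@dataclass
class TelegraphSpec:
    """Two-state (bound/unbound) switching distance process.

    Per-frame switch probabilities emulate salt-bridge formation/rupture
    kinetics; the defaults give a handful of long-lived bound episodes per
    trajectory, the regime in which dwell-filtered event counting is used.
    """

    k_on: float = 0.01          # P(unbound -> bound) per frame
    k_off: float = 0.002        # P(bound -> unbound) per frame
    mean_bound: float = 4.5     # A
    mean_unbound: float = 9.0   # A
    noise_sd: float = 0.3       # A
    n_frames: int = 2000
    start_bound: bool = False
    timestep_ps: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.k_on <= 1.0 and 0.0 <= self.k_off <= 1.0):
            raise ValueError("switch probabilities must be in [0, 1]")
        if self.mean_bound <= 0 or self.mean_unbound <= 0:
            raise ValueError("state means must be positive")


def gen_contact_trajectory(spec: TelegraphSpec
                           ) -> tuple[Trajectory, np.ndarray, list[int]]:
    """Trajectory whose inter-residue side-chain distance is a noisy telegraph.

    Returns (trajectory, state array, true formation frames). The topology
    is two single-side-chain-atom residues on chains A and B: per frame the
    B side-chain sits at x = d(t). States: 1 = bound. True formation frames
    are unbound->bound switches (a bound start is not a formation event).
    """
    rng = np.random.default_rng(stream_seed("telegraph", spec.seed))
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = 1 if spec.start_bound else 0
    flips = rng.random(spec.n_frames)
    for t in range(1, spec.n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if flips[t] < spec.k_on else 0
        else:
            states[t] = 0 if flips[t] < spec.k_off else 1
    means = np.where(states == 1, spec.mean_bound, spec.mean_unbound)
    dist = means + rng.normal(0.0, spec.noise_sd, spec.n_frames)
    np.clip(dist, 0.5, None, out=dist)

    atoms = [
        Atom(serial=1, name="CA", res_name="GLY", res_seq=1, chain_id="A",
             xyz=np.array([0.0, 3.0, 0.0]), element="C"),
        Atom(serial=2, name="CB", res_name="ALA", res_seq=2, chain_id="A",
             xyz=np.zeros(3), element="C"),
        Atom(serial=3, name="CA", res_name="GLY", res_seq=1, chain_id="B",
             xyz=np.array([0.0, -3.0, 10.0]), element="C"),
        Atom(serial=4, name="CB", res_name="ALA", res_seq=2, chain_id="B",
             xyz=np.array([10.0, 0.0, 0.0]), element="C"),
    ]
    top = ParamStructure(atoms, title="telegraph contact fixture")
    base = top.coords
    frames = []
    for d in dist:
        f = base.copy()
        f[3] = [d, 0.0, 0.0]
        frames.append(f)
    times = np.arange(spec.n_frames) * spec.timestep_ps
    true_events = [int(t) for t in range(1, spec.n_frames)
                   if states[t] == 1 and states[t - 1] == 0]
    return Trajectory(top, frames, times), states, true_events


# ---------------------------------------------------------------------------
# alignments and motif windows
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSpec:
    n_sequences: int = 500
    n_columns: int = 60
    conservation: np.ndarray | None = None   # per-column p, in [0.05, 1]
    seed: int = 0

    def __post_init__(self):
        if self.conservation is None:
            rng = np.random.default_rng(stream_seed("alignment_p", self.seed))
            self.conservation = rng.uniform(0.4, 1.0, self.n_columns)
        self.conservation = np.asarray(self.conservation, dtype=float)
        if len(self.conservation) != self.n_columns:
            raise ValueError("conservation vector length != n_columns")
        if np.any(self.conservation < 0.05) or np.any(self.conservation > 1.0):
            raise ValueError("per-column conservation must lie in [0.05, 1]")


def gen_alignment(spec: AlignmentSpec) -> Alignment:
    """Ungapped ortholog-like alignment with known per-column conservation.

    Column c carries its consensus residue with probability p_c, otherwise
    a uniform draw from the remaining 19 residues. The first row (id
    ``query``) is the pure consensus and serves as the reference.
    """
    rng = np.random.default_rng(stream_seed("alignment", spec.seed))
    consensus_idx = rng.integers(0, 20, spec.n_columns)
    consensus = "".join(AMINO_ACIDS[i] for i in consensus_idx)
    rows = [consensus]
    ids = ["query"]
    for s in range(spec.n_sequences - 1):
        keep = rng.random(spec.n_columns) < spec.conservation
        subs = rng.integers(0, 19, spec.n_columns)
        chars = []
        for c in range(spec.n_columns):
            if keep[c]:
                chars.append(AMINO_ACIDS[consensus_idx[c]])
            else:
                alt = subs[c]
                if alt >= consensus_idx[c]:
                    alt += 1            # uniform over the other 19
                chars.append(AMINO_ACIDS[alt])
        rows.append("".join(chars))
        ids.append(f"ortholog_{s + 1:04d}")
    return Alignment(ids=ids, sequences=rows, reference="query")


def default_motif_ppm(rng_seed: int = 0) -> np.ndarray:
    """A deterministic informative kinase-style PPM (15 x 20).

    Center position is pure serine; the position after the phosphosite is
    strongly hydrophobic (leucine-dominated), emulating the general
    preference of serine/threonine kinase substrate motifs; remaining
    positions each favour one residue (p = 0.7) with a secondary choice
    (p = 0.2) over a uniform remainder, giving an informative but not
    degenerate motif.
    """
    ppm = np.zeros((WINDOW, 20))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    rng = np.random.default_rng(stream_seed("motif_ppm", rng_seed))
    for p in range(WINDOW):
        if p == CENTER - 1:
            ppm[p, aa_index["S"]] = 1.0
        elif p == CENTER:     # position +1: hydrophobic, mostly leucine
            for a, pr in (("L", 0.7), ("I", 0.1), ("V", 0.08), ("M", 0.06),
                          ("F", 0.04)):
                ppm[p, aa_index[a]] = pr
            rest = np.flatnonzero(ppm[p] == 0)
            ppm[p, rest] = 0.02 / len(rest)
        else:
            fav, sec = rng.choice(20, size=2, replace=False)
            ppm[p, fav] = 0.7
            ppm[p, sec] = 0.2
            rest = np.flatnonzero(ppm[p] == 0)
            ppm[p, rest] = 0.1 / len(rest)
    assert np.allclose(ppm.sum(axis=1), 1.0)
    return ppm


def gen_substrate_windows(ppm: np.ndarray, n: int, seed: int = 0,
                          force_central_serine: bool = True) -> list[str]:
    """n 15-mers drawn i.i.d. per position from a (15, 20) PPM."""
    ppm = np.asarray(ppm, dtype=float)
    if ppm.shape != (WINDOW, 20) or not np.allclose(ppm.sum(axis=1), 1.0):
        raise ValueError("ppm must be (15, 20) with rows summing to 1")
    rng = np.random.default_rng(stream_seed("substrate_windows", seed))
    out = []
    s_idx = AMINO_ACIDS.index("S")
    for _ in range(n):
        chars = [AMINO_ACIDS[rng.choice(20, p=ppm[p])] for p in range(WINDOW)]
        if force_central_serine:
            chars[CENTER - 1] = AMINO_ACIDS[s_idx]
        out.append("".join(chars))
    return out

# ---------------------------------------------------------------------------
# small peptides
# ---------------------------------------------------------------------------

def gen_peptide(residues: list[str], chain: str = "A") -> ParamStructure:
    """Extended heavy-atom peptide along x with idealized local geometry.

    Supports GLY/ALA/SER side chains — enough for the phosphate builder and
    accessibility fixtures. Side chains alternate above/below the backbone
    plane so consecutive residues stay clash-free.
    """
    atoms: list[Atom] = []
    serial = 1
    for i, res in enumerate(residues):
        off = np.array([3.9 * i, 0.0, 0.0])
        flip = 1.0 if i % 2 == 0 else -1.0
        for name, el, x in (("N", "N", [0.0, 0.0, 0.0]),
                            ("CA", "C", [1.45, 0.0, 0.0]),
                            ("C", "C", [2.15, 1.30, 0.0]),
                            ("O", "O", [1.60, 2.40, 0.0])):
            atoms.append(Atom(serial=serial, name=name, res_name=res,
                              res_seq=i + 1, chain_id=chain,
                              xyz=np.array(x) + off, element=el))
            serial += 1
        if res in ("ALA", "SER"):
            cb = off + np.array([1.95, -0.85, 1.15 * flip])
            atoms.append(Atom(serial=serial, name="CB", res_name=res,
                              res_seq=i + 1, chain_id=chain, xyz=cb,
                              element="C"))
            serial += 1
            if res == "SER":
                og = cb + np.array([0.35, -0.85, 1.05 * flip])
                atoms.append(Atom(serial=serial, name="OG", res_name=res,
                                  res_seq=i + 1, chain_id=chain, xyz=og,
                                  element="O"))
                serial += 1
    return ParamStructure(atoms, title="-".join(residues))
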