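"""Structures, parameters, trajectories, and atom selections.

The central container is :class:`ParamStructure`: an ordered list of atoms
carrying coordinates plus the per-atom partial charge, radius, and
Lennard-Jones parameters that all energetics downstream consume. Structures
are read from PDB (coordinates only; charges/radii zero until assigned) or
PQR (charges/radii from the file), and parameters can be assigned from the
bundled minimal point-charge table.

Internal length unit is the angstrom throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .constants import BACKBONE_ATOMS

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "ParamStructure", "Trajectory", "Selection", "ParameterTable",
    "ParseError", "read_pdb", "write_pdb", "read_pqr", "write_pqr",
    "assign_parameters", "read_trajectory", "read_trajectory_binary", "write_trajectory_tsv",
    "read_trajectory_tsv", "write_bfactor_map", "load_bundled_parameters",
]

_DATA_DIR = Path(__file__).parent / "data"


class ParseError(ValueError):
    """Raised for malformed structure files; message names the line."""


def _element_from_name(name: str, res_name: str) -> str:
    """Infer the element symbol from an atom name.

    Monatomic-ion residues (NA, CL, MG, K) use the residue name directly;
    otherwise the first alphabetic character of the atom name decides, which
    is correct for standard protein heavy atoms and hydrogens.
    """
    if res_name.strip() in {"NA", "CL", "MG", "K", "ZN", "CA2"} and len(name.strip()) <= 2:
        return res_name.strip().capitalize()
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    return "X"


@dataclass
class Atom:
    """One atom with coordinates and (optional) energetic parameters."""

    serial: int
    name: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray                     # (3,) in A
    element: str = ""
    charge: float = 0.0                 # e
    radius: float = 0.0                 # A
    lj_epsilon: float = 0.0             # kJ/mol
    lj_sigma: float = 0.0               # A

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: negative radius {self.radius}")
        if not self.element:
            self.element = _element_from_name(self.name, self.res_name)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_ATOMS

    def copy(self) -> "Atom":
        a = replace(self)
        a.xyz = self.xyz.copy()
        return a


class ParamStructure:
    """An ordered collection of atoms grouped into chains and residues."""

    def __init__(self, atoms: Sequence[Atom], title: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty structure")
        keys = [(a.chain_id, a.res_seq, a.name) for a in atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} in structure")
        self.atoms = atoms
        self.title = title

    def __len__(self) -> int:
        return len(self.atoms)

    # -- array views ------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, r in zip(self.atoms, xyz):
            a.xyz = r.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain_indices(self, chain_id: str) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(self.atoms) if a.chain_id == chain_id],
                       dtype=int)
        if idx.size == 0:
            raise KeyError(f"no chain {chain_id!r} in structure")
        return idx

    # -- residue access ---------------------------------------------------
    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_seq, res_name) triples."""
        out, seen = [], set()
        for a in self.atoms:
            k = (a.chain_id, a.res_seq)
            if k not in seen:
                seen.add(k)
                out.append((a.chain_id, a.res_seq, a.res_name))
        return out

    def residue_atoms(self, chain_id: str, res_seq: int) -> list[int]:
        idx = [i for i, a in enumerate(self.atoms)
               if a.chain_id == chain_id and a.res_seq == res_seq]
        if not idx:
            raise KeyError(f"no residue {chain_id}/{res_seq} in structure")
        return idx

    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def copy(self) -> "ParamStructure":
        return ParamStructure([a.copy() for a in self.atoms], title=self.title)

    def subset(self, indices: Iterable[int], title: str | None = None) -> "ParamStructure":
        idx = list(indices)
        return ParamStructure([self.atoms[i].copy() for i in idx],
                              title=self.title if title is None else title)


@dataclass
class Selection:
    """A resolved, duplicate-free list of atom indices plus its provenance."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection contains duplicate indices")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def where(cls, s: ParamStructure, predicate: Callable[[Atom], bool],
              description: str = "") -> "Selection":
        idx = [i for i, a in enumerate(s.atoms) if predicate(a)]
        return cls(np.array(idx, dtype=int), description)

    @classmethod
    def chain(cls, s: ParamStructure, chain_id: str) -> "Selection":
        return cls(s.chain_indices(chain_id), f"chain {chain_id}")

    @classmethod
    def sidechain_heavy(cls, s: ParamStructure, chain_id: str, res_seq: int) -> "Selection":
        idx = [i for i in s.residue_atoms(chain_id, res_seq)
               if s.atoms[i].is_sidechain and s.atoms[i].is_heavy]
        return cls(np.array(idx, dtype=int),
                   f"side-chain heavy atoms of {chain_id}/{res_seq}")


class Trajectory:
    """Ordered coordinate frames congruent with one topology."""

    def __init__(self, topology: ParamStructure, frames: Sequence[np.ndarray],
                 times: Sequence[float]):
        frames = [np.asarray(f, dtype=float) for f in frames]
        n = len(topology)
        for i, f in enumerate(frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: expected {n} atoms, got {f.shape[0]}")
        times = np.asarray(times, dtype=float)
        if len(times) != len(frames):
            raise ValueError("times/frames length mismatch")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    def __len__(self) -> int:
        return len(self.frames)

    def subsample(self, interval_ps: float) -> "Trajectory":
        """Keep frames spaced at least ``interval_ps`` apart (first kept)."""
        if len(self) == 0:
            raise ValueError("empty trajectory")
        keep = [0]
        for i in range(1, len(self)):
            if self.times[i] - self.times[keep[-1]] >= interval_ps - 1e-9:
                keep.append(i)
        return Trajectory(self.topology, [self.frames[i] for i in keep],
                          self.times[keep])


# ---------------------------------------------------------------------------
# PDB / PQR input and output
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    return Atom(serial=serial, name=name, res_name=res_name, res_seq=res_seq,
                chain_id=chain_id, xyz=np.array([x, y, z]),
                element=element or _element_from_name(name, res_name))


def read_pdb(path) -> ParamStructure:
    """Read the first model of a PDB file.

    Charges and radii are zero until :func:`assign_parameters` is called.
    Multi-model files return the first model with a logged warning; use
    :func:`read_trajectory` to read all models.
    """
    atoms: list[Atom] = []
    n_models = 0
    in_first_model = True
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "MODEL":
                n_models += 1
                if n_models > 1:
                    in_first_model = False
            elif rec in ("ATOM", "HETATM") and in_first_model:
                atoms.append(_parse_pdb_atom(line, lineno))
    if n_models > 1:
        logger.warning("%s: %d MODELs found; returning first model only", path, n_models)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return ParamStructure(atoms, title=title)


def write_pdb(s: ParamStructure, path, bfactors: np.ndarray | None = None) -> None:
    if bfactors is None:
        bfactors = np.zeros(len(s))
    with open(path, "w") as fh:
        if s.title:
            fh.write(f"TITLE     {s.title}\n")
        for a, b in zip(s.atoms, bfactors):
            name = a.name if len(a.name) == 4 else f" {a.name}"
            fh.write(
                f"ATOM  {a.serial:5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
                f"{a.res_seq:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{b:6.2f}          {a.element:>2s}\n")
        fh.write("END\n")


def read_pqr(path) -> ParamStructure:
    """Read a whitespace-delimited PQR file (charge and radius columns).

    Both the 10-field (no chain) and 11-field (with chain) conventions are
    accepted; a missing chain identifier defaults to ``A``.
    """
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0] not in ("ATOM", "HETATM"):
                continue
            try:
                if len(tok) == 11:
                    _, serial, name, res_name, chain_id, res_seq = tok[:6]
                    vals = tok[6:]
                elif len(tok) == 10:
                    _, serial, name, res_name, res_seq = tok[:5]
                    chain_id, vals = "A", tok[5:]
                else:
                    raise ValueError(f"expected 10 or 11 fields, got {len(tok)}")
                x, y, z, charge, radius = (float(v) for v in vals)
                atom = Atom(serial=int(serial), name=name, res_name=res_name,
                            res_seq=int(res_seq), chain_id=chain_id,
                            xyz=np.array([x, y, z]), charge=charge, radius=radius)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed PQR record: {exc}") from None
            atoms.append(atom)
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return ParamStructure(atoms)


def write_pqr(s: ParamStructure, path) -> None:
    with open(path, "w") as fh:
        for a in s.atoms:
            fh.write(f"ATOM {a.serial} {a.name} {a.res_name} {a.chain_id} "
                     f"{a.res_seq} {a.xyz[0]:.6f} {a.xyz[1]:.6f} {a.xyz[2]:.6f} "
                     f"{a.charge:.6f} {a.radius:.6f}\n")


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

class ParameterTable:
    """(res_name, atom_name) -> (charge, radius, lj_epsilon, lj_sigma).

    A wildcard entry ``("*", "H")`` matches any hydrogen atom.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float, float]]):
        self.entries = dict(entries)

    @classmethod
    def from_file(cls, path) -> "ParameterTable":
        entries = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                res, name, q, r, eps, sig = line.split("\t")
                entries[(res, name)] = (float(q), float(r), float(eps), float(sig))
        return cls(entries)

    def lookup(self, atom: Atom):
        key = (atom.res_name, atom.name)
        if key in self.entries:
            return self.entries[key]
        if atom.element == "H" and ("*", "H") in self.entries:
            return self.entries[("*", "H")]
        return None

    def residue_formal_charge(self, res_name: str) -> float:
        q = sum(v[0] for (r, _), v in self.entries.items() if r == res_name)
        return float(round(q))


def load_bundled_parameters() -> ParameterTable:
    """The versioned minimal point-charge set shipped with the package."""
    return ParameterTable.from_file(_DATA_DIR / "ff_minimal.tsv")


def load_max_asa() -> dict[str, float]:
    """Theoretical maximum ASA per residue type (A^2), for RSA normalization."""
    out = {}
    with open(_DATA_DIR / "max_asa.tsv") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            res, val, _note = line.split("\t")
            out[res] = float(val)
    return out


def assign_parameters(s: ParamStructure, table: ParameterTable | None = None
                      ) -> ParamStructure:
    """Return a copy of ``s`` with charges, radii, and LJ parameters assigned.

    Every atom must be found in the table (no silent zeros); unknown atoms
    are collected and reported in a single error. Idempotent: assigning
    twice gives the same result. Per-residue charge sums are validated
    against the table's formal charges to 1e-6 e.
    """
    if table is None:
        table = load_bundled_parameters()
    out = s.copy()
    misses = []
    for a in out.atoms:
        params = table.lookup(a)
        if params is None:
            misses.append(f"{a.res_name}/{a.name} (chain {a.chain_id}, residue {a.res_seq})")
        else:
            a.charge, a.radius, a.lj_epsilon, a.lj_sigma = params
    if misses:
        raise KeyError("no parameters for: " + "; ".join(misses))
    for chain_id, res_seq, res_name in out.residues():
        idx = out.residue_atoms(chain_id, res_seq)
        qsum = sum(out.atoms[i].charge for i in idx)
        expected = table.residue_formal_charge(res_name)
        if abs(qsum - expected) > 1e-6:
            # incomplete residues (missing atoms) legitimately break the sum
            logger.warning("residue %s/%s %s: charge sum %.4f != formal %.1f "
                           "(incomplete residue?)", chain_id, res_seq, res_name,
                           qsum, expected)
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path, topology: ParamStructure, timestep_ps: float = 1.0
                    ) -> Trajectory:
    """Read a multi-model PDB or a coordinate TSV as a trajectory.

    Times are synthesized as ``frame_index * timestep_ps`` for multi-model
    PDB (which carries no time metadata); the TSV format may carry an
    explicit ``time_ps`` column.
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt", ".dat"):
        return read_trajectory_tsv(path, topology, timestep_ps=timestep_ps)
    frames: list[np.ndarray] = []
    current: list[np.ndarray] | None = None
    n = len(topology)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                current.append(_parse_pdb_atom(line, lineno).xyz)
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                if len(current) != n:
                    raise ValueError(f"frame {len(frames)}: expected {n} atoms, "
                                     f"got {len(current)}")
                frames.append(np.array(current))
                current = None
    if current:
        if len(current) != n:
            raise ValueError(f"frame {len(frames)}: expected {n} atoms, got {len(current)}")
        frames.append(np.array(current))
    if not frames:
        raise ParseError(f"{path}: no coordinate frames")
    times = np.arange(len(frames)) * timestep_ps
    return Trajectory(topology, frames, times)


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for a, xyz in zip(traj.topology.atoms, frame):
                name = a.name if len(a.name) == 4 else f" {a.name}"
                fh.write(
                    f"ATOM  {a.serial:5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
                    f"{a.res_seq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    """Plain-text per-frame coordinate table (full float precision)."""
    with open(path, "w") as fh:
        fh.write("frame\tserial\ttime_ps\tx\ty\tz\n")
        for f, (frame, t) in enumerate(zip(traj.frames, traj.times)):
            for a, xyz in zip(traj.topology.atoms, frame):
                fh.write(f"{f}\t{a.serial}\t{t:.6f}\t{float(xyz[0])!r}\t"
                         f"{float(xyz[1])!r}\t{float(xyz[2])!r}\n")


def read_trajectory_tsv(path, topology: ParamStructure, timestep_ps: float = 1.0
                        ) -> Trajectory:
    serial_order = {a.serial: i for i, a in enumerate(topology.atoms)}
    n = len(topology)
    per_frame: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    times: dict[int, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for name in ("frame", "serial", "x", "y", "z"):
            if name not in col:
                raise ParseError(f"{path}: missing column {name!r}")
        for lineno, line in enumerate(fh, start=2):
            tok = line.rstrip("\n").split("\t")
            try:
                f = int(tok[col["frame"]]); serial = int(tok[col["serial"]])
                xyz = [float(tok[col[c]]) for c in "xyz"]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: malformed coordinate row: {exc}") from None
            if serial not in serial_order:
                raise ValueError(f"frame {f}: unknown atom serial {serial}")
            if f not in per_frame:
                per_frame[f] = np.full((n, 3), np.nan)
                counts[f] = 0
            per_frame[f][serial_order[serial]] = xyz
            counts[f] += 1
            if "time_ps" in col:
                times[f] = float(tok[col["time_ps"]])
    if not per_frame:
        raise ParseError(f"{path}: no coordinate rows")
    order = sorted(per_frame)
    for f in order:
        if counts[f] != n or np.isnan(per_frame[f]).any():
            raise ValueError(f"frame {f}: expected {n} atoms, got {counts[f]}")
    frames = [per_frame[f] for f in order]
    if times:
        tvec = np.array([times[f] for f in order])
    else:
        tvec = np.arange(len(order)) * timestep_ps
    return Trajectory(topology, frames, tvec)


def read_trajectory_binary(topology_path, trajectory_path,
                           topology: ParamStructure) -> Trajectory:
    """Optional adapter for binary trajectory formats (XTC/DCD/TRR).

    Delegates to MDAnalysis when it is installed (``pip install
    phosbind[traj]``); the text formats handled by :func:`read_trajectory`
    are the fully supported path. Coordinates are converted from nm to A
    where the reader reports nm (MDAnalysis already normalizes to A).
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:
        raise ImportError(
            "binary trajectory support requires MDAnalysis "
            "(install the 'traj' extra)") from exc
    u = mda.Universe(str(topology_path), str(trajectory_path))
    n = len(topology)
    if len(u.atoms) != n:
        raise ValueError(f"topology has {n} atoms but trajectory frames "
                         f"have {len(u.atoms)}")
    frames, times = [], []
    for ts in u.trajectory:
        frames.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))
    if len(times) > 1 and times[1] <= times[0]:
        times = list(np.arange(len(frames), dtype=float))
    return Trajectory(topology, frames, times)


# ---------------------------------------------------------------------------
# B-factor mapping
# ---------------------------------------------------------------------------

_B_MIN, _B_MAX = -99.99, 999.99


def write_bfactor_map(s: ParamStructure, per_residue_values: dict, path) -> None:
    """Write a PDB whose B-factor column carries a per-residue scalar.

    Every key of ``per_residue_values`` — ``(chain_id, res_seq)`` tuples —
    must exist in the structure; residues without a value get B = 0. Values
    outside the PDB column range are clamped with a logged warning.
    """
    resset = {(c, r) for c, r, _ in s.residues()}
    for key in per_residue_values:
        if key not in resset:
            raise KeyError(f"residue {key} not in structure")
    bf = np.zeros(len(s))
    for i, a in enumerate(s.atoms):
        v = per_residue_values.get((a.chain_id, a.res_seq))
        if v is None:
            continue
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for residue {(a.chain_id, a.res_seq)}")
        if v < _B_MIN or v > _B_MAX:
            clamped = min(max(v, _B_MIN), _B_MAX)
            logger.warning("B-factor %.4g clamped to %.2f for residue %s/%s",
                           v, clamped, a.chain_id, a.res_seq)
            v = clamped
        bf[i] = v
    write_pdb(s, path, bfactors=bf)
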