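"""Build phosphoserine (SEP) residues onto serines.

The phosphate is placed with ideal internal geometry (P-OG 1.61 A, P-O
1.48 A, tetrahedral angles) and the torsion of the whole group about the
CB-OG bond is scanned in 10-degree steps; the rotamer maximizing the
minimum non-bonded heavy-atom distance to the rest of the structure is
kept. The residue is renamed SEP, any hydroxyl hydrogen is removed, and
the residue is re-parameterized from the bundled table so its net charge
is -2 e (fully deprotonated phosphate, the physiological-pH convention;
configurable via a custom parameter table).
"""
from __future__ import annotations

import numpy as np

from .structures import Atom, ParamStructure, ParameterTable, load_bundled_parameters

__all__ = ["build_phosphoserine"]

P_OG_BOND = 1.61      # A
P_O_BOND = 1.48       # A
ANGLE_CB_OG_P = 119.0   # deg
ANGLE_OG_P_O = 109.47   # deg


def _orthonormal_frame(e1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, e1)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(e1, ref)
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    return u, v


def _phosphate_coords(cb: np.ndarray, og: np.ndarray, tau_deg: float) -> np.ndarray:
    """Coordinates of (P, O1P, O2P, O3P) for a given CB-OG torsion."""
    e1 = og - cb
    e1 /= np.linalg.norm(e1)
    u, v = _orthonormal_frame(e1)
    tau = np.deg2rad(tau_deg)
    theta = np.deg2rad(180.0 - ANGLE_CB_OG_P)  # angle between e1 and OG->P
    d = np.cos(theta) * e1 + np.sin(theta) * (np.cos(tau) * u + np.sin(tau) * v)
    p = og + P_OG_BOND * d
    a = (p - og) / np.linalg.norm(p - og)
    ua, va = _orthonormal_frame(a)
    phi = np.deg2rad(ANGLE_OG_P_O)
    coords = [p]
    for k in range(3):
        t = tau + np.deg2rad(60.0 + 120.0 * k)  # staggered about the OG-P axis
        perp = np.cos(t) * ua + np.sin(t) * va
        direction = -np.cos(phi) * a + np.sin(phi) * perp
        coords.append(p + P_O_BOND * direction)
    return np.array(coords)


def build_phosphoserine(s: ParamStructure, chain_id: str, res_seq: int,
                        table: ParameterTable | None = None) -> ParamStructure:
    """Return a copy of ``s`` with SER ``chain_id``/``res_seq`` phosphorylated.

    Exactly one residue changes; all other atoms are untouched. Raises if
    the target is not a serine (in particular if it is already SEP) or if
    its OG atom is missing.
    """
    out = s.copy()
    idx = out.residue_atoms(chain_id, res_seq)
    res_name = out.atoms[idx[0]].res_name
    if res_name == "SEP":
        raise ValueError(f"residue {chain_id}/{res_seq} is already phosphorylated (SEP)")
    if res_name != "SER":
        raise ValueError(f"residue {chain_id}/{res_seq} is {res_name}, not SER")
    by_name = {out.atoms[i].name: i for i in idx}
    if "OG" not in by_name or "CB" not in by_name:
        raise ValueError(f"residue {chain_id}/{res_seq}: OG/CB atom missing")
    cb = out.atoms[by_name["CB"]].xyz
    og = out.atoms[by_name["OG"]].xyz

    # candidate environment: heavy atoms excluding bonded partners of the
    # new atoms (OG bonds P; P bonds its oxygens, which are scanned jointly)
    env = np.array([a.xyz for i, a in enumerate(out.atoms)
                    if a.is_heavy and i != by_name["OG"]])

    best_tau, best_score, best_coords = None, -np.inf, None
    for tau in range(0, 360, 10):
        coords = _phosphate_coords(cb, og, float(tau))
        d = np.linalg.norm(env[None, :, :] - coords[:, None, :], axis=-1)
        score = d.min()
        if score > best_score:
            best_tau, best_score, best_coords = tau, score, coords

    # drop hydroxyl hydrogen, rename residue
    hg_names = {"HG", "HG1", "1HG"}
    keep = [i for i in range(len(out.atoms))
            if not (i in idx and out.atoms[i].name in hg_names)]
    atoms = [out.atoms[i] for i in keep]
    for a in atoms:
        if a.chain_id == chain_id and a.res_seq == res_seq:
            a.res_name = "SEP"

    max_serial = max(a.serial for a in atoms)
    last_pos = max(i for i, a in enumerate(atoms)
                   if a.chain_id == chain_id and a.res_seq == res_seq)
    new_atoms = [Atom(serial=max_serial + 1 + k, name=nm, res_name="SEP",
                      res_seq=res_seq, chain_id=chain_id, xyz=best_coords[k],
                      element=el)
                 for k, (nm, el) in enumerate(
                     [("P", "P"), ("O1P", "O"), ("O2P", "O"), ("O3P", "O")])]
    atoms = atoms[:last_pos + 1] + new_atoms + atoms[last_pos + 1:]
    result = ParamStructure(atoms, title=out.title)

    # re-parameterize only the modified residue
    if table is None:
        table = load_bundled_parameters()
    for i in result.residue_atoms(chain_id, res_seq):
        a = result.atoms[i]
        params = table.lookup(a)
        if params is None:
            raise KeyError(f"no SEP parameters for atom {a.name}")
        a.charge, a.radius, a.lj_epsilon, a.lj_sigma = params
    return result
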