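"""Solvent-accessible surface area by the Shrake-Rupley method.

Each heavy atom is inflated by the probe radius and sampled with a
deterministic Fibonacci point set; a sample point is accessible if it lies
outside every neighbouring inflated sphere. Hydrogens carry no surface
(radius treated as zero). Per-atom areas sum to the total by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import ParamStructure

logger = logging.getLogger(__name__)

__all__ = ["SASAConfig", "sasa"]


@dataclass
class SASAConfig:
    probe_radius: float = 1.4        # A
    gamma: float = 0.0226            # kJ/mol/A^2, surface-tension coefficient
    offset_b: float = 3.84           # kJ/mol, additive offset of the SASA model
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(s: ParamStructure, cfg: SASAConfig | None = None
         ) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area (A^2).

    Hydrogens and zero-radius atoms get zero area; a zero-radius heavy atom
    triggers a warning (its parameters are probably missing).
    """
    if cfg is None:
        cfg = SASAConfig()
    coords = s.coords
    radii = s.radii.copy()
    active = np.array([a.is_heavy for a in s.atoms]) & (radii > 0)
    for a, r in zip(s.atoms, radii):
        if a.is_heavy and r == 0:
            logger.warning("heavy atom %s/%s %s has zero radius; excluded from SASA",
                           a.chain_id, a.res_seq, a.name)
    radii[~np.array([a.is_heavy for a in s.atoms])] = 0.0

    sphere = _fibonacci_sphere(cfg.n_sphere_points)
    inflated = radii + cfg.probe_radius
    areas = np.zeros(len(s))
    act_idx = np.flatnonzero(active)
    if act_idx.size == 0:
        return 0.0, areas
    tree = cKDTree(coords[act_idx])
    max_r = inflated[act_idx].max()
    for i in act_idx:
        ri = inflated[i]
        # neighbours whose inflated spheres can intersect atom i's surface
        nb = tree.query_ball_point(coords[i], ri + max_r)
        nb = [act_idx[j] for j in nb if act_idx[j] != i]
        pts = coords[i] + ri * sphere
        if nb:
            nb = np.array(nb)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=-1)
            buried = np.any(d2 < (inflated[nb][None, :]) ** 2, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return float(areas.sum()), areas
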