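"""Salt-bridge contact dynamics from trajectories.

A contact is defined on the minimum distance between the side-chain heavy
atoms of a residue pair; the contact cutoff is 6.0 A (0.6 nm), the
conventional threshold for a stable electrostatic contact. A *formation
event* is a maximal run of in-contact frames of length >= ``dwell_min``
that is entered by a downward crossing of the cutoff; a run already in
contact at frame 0 is reported but flagged as an initial contact and
excluded from the formation count (no crossing was observed). A distance
exactly equal to the cutoff counts as in contact.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SALT_BRIDGE_CUTOFF
from .structures import ParamStructure, Selection, Trajectory

__all__ = ["ContactSeries", "FormationEvent", "ReplicaSummary",
           "min_sidechain_distance", "count_formation_events",
           "summarize_replicas", "plot_contact_series"]

#: any inter-atom distance beyond this (A) suggests a broken/wrapped
#: trajectory; distances are computed without minimum-image handling
BOX_SANITY_BOUND = 500.0


@dataclass
class FormationEvent:
    start_frame: int
    end_frame: int            # inclusive
    initial_contact: bool = False

    @property
    def dwell(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class ContactSeries:
    """Per-frame minimum side-chain heavy-atom distance for one residue pair."""

    pair: tuple[tuple[str, int, str], tuple[str, int, str]]
    distances: np.ndarray     # A
    times: np.ndarray         # ps
    cutoff: float = SALT_BRIDGE_CUTOFF
    dwell_min: int = 1

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.distances.ndim != 1 or len(self.distances) != len(self.times):
            raise ValueError("distances/times length mismatch")
        if not np.all(np.isfinite(self.distances)) or np.any(self.distances <= 0):
            raise ValueError("distances must be finite and positive")
        if np.any(self.distances > BOX_SANITY_BOUND):
            raise ValueError("distance exceeds box sanity bound; trajectory "
                             "may be wrapped across periodic boundaries")

    @property
    def in_contact(self) -> np.ndarray:
        return self.distances <= self.cutoff

    def contact_fraction(self) -> float:
        return float(np.mean(self.in_contact))


def min_sidechain_distance(traj: Trajectory,
                           resA: tuple[str, int],
                           resB: tuple[str, int],
                           cutoff: float = SALT_BRIDGE_CUTOFF,
                           dwell_min: int = 1) -> ContactSeries:
    """Per-frame minimum distance between side-chain heavy atoms of two residues."""
    top = traj.topology
    sels = []
    names = []
    for chain_id, res_seq in (resA, resB):
        idx = top.residue_atoms(chain_id, res_seq)
        res_name = top.atoms[idx[0]].res_name
        sel = Selection.sidechain_heavy(top, chain_id, res_seq)
        if len(sel) == 0:
            raise ValueError(f"residue {chain_id}/{res_seq} ({res_name}) has no "
                             "side-chain heavy atoms")
        sels.append(sel.indices)
        names.append((chain_id, res_seq, res_name))
    ia, ib = sels
    dists = np.empty(len(traj))
    for f, frame in enumerate(traj.frames):
        d = np.linalg.norm(frame[ia][:, None, :] - frame[ib][None, :, :], axis=-1)
        dists[f] = d.min()
    return ContactSeries(pair=(names[0], names[1]), distances=dists,
                         times=traj.times, cutoff=cutoff, dwell_min=dwell_min)


def count_formation_events(series: ContactSeries) -> list[FormationEvent]:
    """All qualifying contact runs; initial contacts flagged, not counted.

    Returned events include flagged initial-contact runs; use
    ``[e for e in events if not e.initial_contact]`` (or
    :func:`summarize_replicas`) for the formation count.
    """
    contact = series.in_contact
    events: list[FormationEvent] = []
    n = len(contact)
    i = 0
    while i < n:
        if contact[i]:
            j = i
            while j + 1 < n and contact[j + 1]:
                j += 1
            dwell = j - i + 1
            if dwell >= series.dwell_min:
                events.append(FormationEvent(start_frame=i, end_frame=j,
                                             initial_contact=(i == 0)))
            i = j + 1
        else:
            i += 1
    return events


@dataclass
class ReplicaSummary:
    """Event counts over a set of replica simulations of one system."""

    per_replica_counts: list[int]
    contact_fractions: list[float]
    n_initial_contacts: int

    @property
    def pooled_events(self) -> int:
        return int(sum(self.per_replica_counts))


def summarize_replicas(series_list: list[ContactSeries]) -> ReplicaSummary:
    if not series_list:
        raise ValueError("need at least one replica series")
    counts, fractions, n_init = [], [], 0
    for s in series_list:
        ev = count_formation_events(s)
        counts.append(sum(1 for e in ev if not e.initial_contact))
        n_init += sum(1 for e in ev if e.initial_contact)
        fractions.append(s.contact_fraction())
    return ReplicaSummary(per_replica_counts=counts, contact_fractions=fractions,
                          n_initial_contacts=n_init)


def plot_contact_series(series: ContactSeries, ax=None):
    """Distance trace with the contact cutoff as a horizontal line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    ax.plot(series.times / 1000.0, series.distances, lw=0.7)
    ax.axhline(series.cutoff, color="black", lw=1.0)
    (ca, ra, na), (cb, rb, nb) = series.pair
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("min. side-chain distance (A)")
    ax.set_title(f"{na}{ra} ({ca}) - {nb}{rb} ({cb})", fontsize=9)
    return ax
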