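"""Ortholog-alignment column conservation.

Per-column residue frequencies are computed over non-gap symbols; the
0-9 conservation score is a deterministic entropy-based surrogate for
phylogenetic rate-based scores (ConSurf-style scales): a fully conserved
column scores 9, a uniformly variable one 0. It deliberately ignores
phylogenetic correlation between sequences, which a rate-inference method
would model; see the package methods note for what this does and does not
capture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = ["Alignment", "ColumnProfile", "read_alignment", "column_profiles",
           "conservation_score", "AMINO_ACIDS"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = {"-", "."}
LOG2_20 = math.log2(20.0)


@dataclass
class Alignment:
    """Equal-length gapped sequences with a designated reference row."""

    ids: list[str]
    sequences: list[str]
    reference: str

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids/sequences length mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference not in self.ids:
            raise ValueError(f"reference {self.reference!r} not among sequence ids")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_row(self) -> str:
        return self.sequences[self.ids.index(self.reference)]

    def column_of_reference_position(self, pos: int) -> int:
        """Alignment column (0-based) of 1-based reference position ``pos``."""
        count = 0
        for col, ch in enumerate(self.reference_row):
            if ch not in GAP_CHARS:
                count += 1
                if count == pos:
                    return col
        raise IndexError(f"reference position {pos} beyond ungapped length {count}")

    def reference_position_map(self) -> dict[int, int]:
        """1-based reference position -> 0-based alignment column."""
        out, count = {}, 0
        for col, ch in enumerate(self.reference_row):
            if ch not in GAP_CHARS:
                count += 1
                out[count] = col
        return out


def read_alignment(path, reference: str | None = None,
                   fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    ``reference`` defaults to the first record.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
            else "fasta"
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    seqs = [str(rec.seq) for rec in aln]
    return Alignment(ids=ids, sequences=seqs,
                     reference=reference if reference is not None else ids[0])


@dataclass
class ColumnProfile:
    """Residue counts and frequencies of one alignment column."""

    counts: dict[str, int]              # over 20 residues + X
    gap_fraction: float
    frequencies: dict[str, float]       # over non-gap symbols
    consensus: str | None               # None for all-gap columns
    low_confidence: bool = False        # gap_fraction > 0.5

    def entropy_bits(self) -> float:
        h = 0.0
        for p in self.frequencies.values():
            if p > 0:
                h -= p * math.log2(p)
        return h


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """Per-column profiles: non-gap frequencies, consensus, gap fraction.

    X is counted in the frequencies but never chosen as consensus; ties on
    the maximum frequency break alphabetically.
    """
    if len(aln.sequences) < 2:
        raise ValueError("need at least 2 sequences")
    out = []
    n_rows = len(aln.sequences)
    for col in range(aln.n_columns):
        symbols = [s[col] for s in aln.sequences]
        n_gap = sum(1 for c in symbols if c in GAP_CHARS)
        counts = {a: 0 for a in AMINO_ACIDS + "X"}
        for c in symbols:
            if c in GAP_CHARS:
                continue
            counts[c if c in counts else "X"] += 1
        n_nongap = n_rows - n_gap
        if n_nongap == 0:
            out.append(ColumnProfile(counts=counts, gap_fraction=1.0,
                                     frequencies={}, consensus=None,
                                     low_confidence=True))
            continue
        freqs = {a: c / n_nongap for a, c in counts.items() if c > 0}
        candidates = [(a, f) for a, f in freqs.items() if a != "X"]
        consensus = (min((a for a, f in candidates
                          if f == max(f2 for _, f2 in candidates)))
                     if candidates else None)
        gap_fraction = n_gap / n_rows
        out.append(ColumnProfile(counts=counts, gap_fraction=gap_fraction,
                                 frequencies=freqs, consensus=consensus,
                                 low_confidence=gap_fraction > 0.5))
    return out


def conservation_score(profile: ColumnProfile) -> int:
    """Entropy-based conservation on the conventional 0-9 scale.

    score = floor(9 * (1 - H / log2(20))), clamped to [0, 9]; H is the
    Shannon entropy of the column's non-gap frequencies.
    """
    if not profile.frequencies:
        raise ValueError("conservation score undefined for an all-gap column")
    h = profile.entropy_bits()
    return int(min(9, max(0, math.floor(9.0 * (1.0 - h / LOG2_20)))))
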