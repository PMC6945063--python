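"""Kinase-substrate sequence motifs from 15-residue windows.

Substrate windows span seven residues either side of the phosphosite
(position 8 of 15, 1-based). Windows truncated by sequence ends are padded
with X, which is excluded from counts. The position probability matrix uses
a pseudocount alpha, and per-position information content is
IC = log2(20) - H(PPM) in bits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa import AMINO_ACIDS, LOG2_20

__all__ = ["MotifMatrix", "build_motif", "extract_window", "score_site",
           "WINDOW", "CENTER"]

WINDOW = 15
CENTER = 8          # 1-based position of the phosphosite within the window
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MotifMatrix:
    counts: np.ndarray          # (15, 20) integer counts
    alpha: float                # pseudocount
    ppm: np.ndarray             # (15, 20), rows sum to 1
    information_bits: np.ndarray  # (15,)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.ppm.argmax(axis=1))

    def to_counts_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\tIC_bits\n")
            for p in range(WINDOW):
                row = "\t".join(str(int(c)) for c in self.counts[p])
                fh.write(f"{p + 1}\t{row}\t{self.information_bits[p]:.6g}\n")

    def to_meme(self, path, name: str = "motif") -> None:
        """MEME minimal motif format (letter-probability matrix)."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
            fh.write(f"MOTIF {name}\n")
            n = int(self.counts[CENTER - 1].sum()) or int(self.counts.sum(axis=1).max())
            fh.write(f"letter-probability matrix: alength= 20 w= {WINDOW} "
                     f"nsites= {n}\n")
            for p in range(WINDOW):
                fh.write(" ".join(f"{v:.6f}" for v in self.ppm[p]) + "\n")


def extract_window(seq: str, site_pos: int) -> str:
    """15-mer around 1-based ``site_pos``, X-padded at sequence ends."""
    if not (1 <= site_pos <= len(seq)):
        raise IndexError(f"site position {site_pos} out of range 1..{len(seq)}")
    lo = site_pos - CENTER          # 0-based start
    chars = []
    for i in range(lo, lo + WINDOW):
        chars.append(seq[i] if 0 <= i < len(seq) else "X")
    return "".join(chars).upper()


def build_motif(substrates: list[tuple[str, int]], alpha: float = 0.0
                ) -> MotifMatrix:
    """Position probability matrix from (sequence, 1-based site) pairs.

    PPM[p, a] = (count + alpha) / (n_eff + 20 alpha) with n_eff the non-X
    count at position p; with alpha = 0 a position seen in no window is
    uniform by convention.
    """
    counts = np.zeros((WINDOW, 20), dtype=int)
    for k, (seq, pos) in enumerate(substrates):
        try:
            window = extract_window(seq, pos)
        except IndexError as exc:
            raise IndexError(f"substrate {k}: {exc}") from None
        for p, ch in enumerate(window):
            if ch in _AA_INDEX:
                counts[p, _AA_INDEX[ch]] += 1
    n_eff = counts.sum(axis=1, keepdims=True)
    denom = n_eff + 20.0 * alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        ppm = np.where(denom > 0, (counts + alpha) / denom, 1.0 / 20.0)
    ent = np.zeros(WINDOW)
    for p in range(WINDOW):
        pr = ppm[p][ppm[p] > 0]
        ent[p] = float(-(pr * np.log2(pr)).sum())
    return MotifMatrix(counts=counts, alpha=alpha, ppm=ppm,
                       information_bits=LOG2_20 - ent)


def score_site(seq: str, pos: int, motif: MotifMatrix,
               background: np.ndarray | None = None) -> float:
    """Log-odds motif score (bits) of the 15-mer window around ``pos``.

    X positions (including end padding) contribute zero. A zero PPM entry
    (possible at alpha = 0) scores -inf; use a positive pseudocount for
    scoring applications.
    """
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    window = extract_window(seq, pos)
    score = 0.0
    for p, ch in enumerate(window):
        if ch not in _AA_INDEX:
            continue
        a = _AA_INDEX[ch]
        pr = motif.ppm[p, a]
        if pr == 0.0:
            return -math.inf
        score += math.log2(pr / background[a])
    return score
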