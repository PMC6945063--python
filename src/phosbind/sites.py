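"""Phosphosite annotation: conservation, solvent accessibility, motif score."""
from __future__ import annotations

from dataclasses import dataclass

from .msa import Alignment, column_profiles, conservation_score
from .motif import MotifMatrix, score_site
from .sasa import SASAConfig, sasa
from .structures import ParamStructure, load_max_asa

__all__ = ["SiteAnnotation", "relative_accessibility", "annotate_sites"]


@dataclass
class SiteAnnotation:
    position: int                   # 1-based in the reference sequence
    residue: str
    conservation: int | None        # 0-9; None if the column is all gaps
    rsa_percent: float | None       # None if absent from the structure
    motif_score_bits: float | None
    flags: list[str]


def relative_accessibility(s: ParamStructure, sites: list[tuple[str, int]],
                           cfg: SASAConfig | None = None) -> list[float]:
    """Residue SASA as a percentage of the theoretical maximum ASA.

    ``sites`` are (chain_id, res_seq) pairs; every site must exist in the
    structure. Values can modestly exceed 100% for fully extended exposed
    residues because the normalization table and the numerical SASA use
    different radii conventions.
    """
    if cfg is None:
        cfg = SASAConfig()
    max_asa = load_max_asa()
    _, areas = sasa(s, cfg)
    out = []
    for chain_id, res_seq in sites:
        idx = s.residue_atoms(chain_id, res_seq)   # raises if absent
        res_name = s.atoms[idx[0]].res_name
        if res_name not in max_asa:
            raise KeyError(f"no maxASA entry for residue type {res_name}")
        out.append(100.0 * float(areas[idx].sum()) / max_asa[res_name])
    return out


def annotate_sites(seq: str, aln: Alignment, structure: ParamStructure | None,
                   motif: MotifMatrix, sites: list[int],
                   chain_id: str = "A",
                   sasa_cfg: SASAConfig | None = None) -> list[SiteAnnotation]:
    """One annotation record per 1-based site position in ``seq``.

    The alignment's reference row must match ``seq`` (gaps removed).
    Missing data is reported as None with an explanatory flag rather than
    an error: a site absent from the structure loses RSA; a site mapping to
    an all-gap column loses conservation.
    """
    ref_ungapped = aln.reference_row.replace("-", "").replace(".", "")
    if ref_ungapped != seq.upper():
        raise ValueError("alignment reference sequence does not match seq")
    profiles = column_profiles(aln)
    out = []
    for pos in sites:
        if not (1 <= pos <= len(seq)):
            raise IndexError(f"site {pos} out of range 1..{len(seq)}")
        flags: list[str] = []
        col = aln.column_of_reference_position(pos)
        profile = profiles[col]
        if profile.frequencies:
            cons = conservation_score(profile)
            if profile.low_confidence:
                flags.append("gappy_column")
        else:
            cons = None
            flags.append("all_gap_column")
        rsa = None
        if structure is not None:
            try:
                rsa = relative_accessibility(structure, [(chain_id, pos)],
                                             sasa_cfg)[0]
            except KeyError:
                flags.append("absent_from_structure")
        else:
            flags.append("no_structure")
        ms = score_site(seq, pos, motif)
        out.append(SiteAnnotation(position=pos, residue=seq[pos - 1].upper(),
                                  conservation=cons, rsa_percent=rsa,
                                  motif_score_bits=ms, flags=flags))
    return out
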