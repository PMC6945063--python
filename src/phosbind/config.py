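"""Structured run configuration.

A single YAML file carries every tunable parameter of the pipeline (grid
spacings, dielectrics, ionic strength, probe radius, surface tension,
contact cutoff, dwell filter, window size is fixed at 15) so the analysis
contract is visible and overridable in one place. Lengths accept explicit
unit keys: plain numbers are angstroms; a mapping ``{value: 0.6, unit: nm}``
is converted on load.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import SALT_BRIDGE_CUTOFF
from .pb import PBConfig
from .sasa import SASAConfig

__all__ = ["RunConfig", "ValidationError", "default_config_yaml", "load_config"]

_LENGTH_UNITS = {"angstrom": 1.0, "a": 1.0, "ang": 1.0, "nm": 10.0}


class ValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


def _length(value, default: float) -> float:
    if value is None:
        return default
    if isinstance(value, dict):
        try:
            unit = str(value["unit"]).lower()
            scale = _LENGTH_UNITS[unit]
        except KeyError:
            raise ValidationError(f"unknown length unit in {value!r}") from None
        return float(value["value"]) * scale
    return float(value)


@dataclass
class SaltbridgeInput:
    topology: str
    coords: str
    label: str = ""


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "phosbind_out"
    stages: list[str] = field(default_factory=lambda: [
        "saltbridge", "mmpbsa", "conservation", "motif", "annotate"])
    # inputs
    complex_pqr: str | None = None
    complex_pqr_alt: str | None = None     # optional second state for ddG
    trajectories: list[SaltbridgeInput] = field(default_factory=list)
    pair_res_a: tuple[str, int] = ("A", 2)
    pair_res_b: tuple[str, int] = ("B", 2)
    alignment: str | None = None
    alignment_reference: str | None = None
    substrates: str | None = None
    structure_pdb: str | None = None
    structure_chain: str = "A"
    sites: list[int] = field(default_factory=list)
    # analysis parameters
    cutoff: float = SALT_BRIDGE_CUTOFF
    dwell_min: int = 1
    chain_a: str = "A"
    chain_b: str = "B"
    frame_interval_ps: float = 0.0
    include_polar: bool = True
    lj_epsilon_default: float | None = None   # fill-in for PQR inputs (no LJ columns)
    lj_sigma_default: float | None = None
    motif_alpha: float = 0.01
    pb: PBConfig = field(default_factory=PBConfig)
    sasa: SASAConfig = field(default_factory=SASAConfig)

    def validate(self) -> None:
        known = {"saltbridge", "mmpbsa", "conservation", "motif", "annotate"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        needed: list[str] = []
        if "saltbridge" in self.stages:
            if not self.trajectories:
                raise ValidationError("saltbridge stage needs trajectories")
            for t in self.trajectories:
                needed += [t.topology, t.coords]
        if "mmpbsa" in self.stages:
            if not self.complex_pqr:
                raise ValidationError("mmpbsa stage needs complex_pqr")
            needed.append(self.complex_pqr)
            if self.complex_pqr_alt:
                needed.append(self.complex_pqr_alt)
        if "conservation" in self.stages or "annotate" in self.stages:
            if not self.alignment:
                raise ValidationError("conservation/annotate stages need alignment")
            needed.append(self.alignment)
        if "motif" in self.stages or "annotate" in self.stages:
            if not self.substrates:
                raise ValidationError("motif/annotate stages need substrates")
            needed.append(self.substrates)
        if self.structure_pdb:
            needed.append(self.structure_pdb)
        missing = [p for p in needed if not Path(p).exists()]
        if missing:
            raise ValidationError("missing input files: " + ", ".join(missing))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
    cfg.stages = list(raw.get("stages", cfg.stages))
    inp = raw.get("inputs", {})
    cfg.complex_pqr = inp.get("complex_pqr")
    cfg.complex_pqr_alt = inp.get("complex_pqr_alt")
    cfg.trajectories = [SaltbridgeInput(topology=t["topology"], coords=t["coords"],
                                        label=t.get("label", f"rep{i + 1}"))
                        for i, t in enumerate(inp.get("trajectories", []))]
    if "pair" in inp:
        cfg.pair_res_a = (str(inp["pair"]["resA"][0]), int(inp["pair"]["resA"][1]))
        cfg.pair_res_b = (str(inp["pair"]["resB"][0]), int(inp["pair"]["resB"][1]))
    cfg.alignment = inp.get("alignment")
    cfg.alignment_reference = inp.get("alignment_reference")
    cfg.substrates = inp.get("substrates")
    cfg.structure_pdb = inp.get("structure_pdb")
    cfg.structure_chain = str(inp.get("structure_chain", "A"))
    cfg.sites = [int(s) for s in inp.get("sites", [])]
    sb = raw.get("saltbridge", {})
    cfg.cutoff = _length(sb.get("cutoff"), cfg.cutoff)
    cfg.dwell_min = int(sb.get("dwell_min", cfg.dwell_min))
    mm = raw.get("mmpbsa", {})
    cfg.chain_a = str(mm.get("chain_a", cfg.chain_a))
    cfg.chain_b = str(mm.get("chain_b", cfg.chain_b))
    cfg.frame_interval_ps = float(mm.get("frame_interval_ps", cfg.frame_interval_ps))
    cfg.include_polar = bool(mm.get("include_polar", cfg.include_polar))
    lj = mm.get("lj_defaults")
    if lj:
        cfg.lj_epsilon_default = float(lj["epsilon"])
        cfg.lj_sigma_default = float(lj["sigma"])
    cfg.motif_alpha = float(raw.get("motif", {}).get("alpha", cfg.motif_alpha))
    pb_raw = dict(raw.get("pb", {}))
    for key in ("fine_spacing", "stern_layer", "fine_margin", "coarse_pad"):
        if key in pb_raw:
            pb_raw[key] = _length(pb_raw[key], getattr(PBConfig(), key))
    cfg.pb = PBConfig(**pb_raw)
    sasa_raw = dict(raw.get("sasa", {}))
    if "probe_radius" in sasa_raw:
        sasa_raw["probe_radius"] = _length(sasa_raw["probe_radius"],
                                           SASAConfig().probe_radius)
    cfg.sasa = SASAConfig(**sasa_raw)
    return cfg


def default_config_yaml() -> str:
    """YAML text with every parameter at its default, ready to edit."""
    pb = PBConfig()
    sasa = SASAConfig()
    return f"""\
# phosbind run configuration — all defaults shown explicitly.
# Plain lengths are angstroms; any length also accepts {{value: .., unit: nm}}.
seed: 0
output_dir: phosbind_out
stages: [saltbridge, mmpbsa, conservation, motif, annotate]

inputs:
  complex_pqr: null          # two-chain complex with charges/radii (PQR)
  complex_pqr_alt: null      # optional second state; enables the ddG row
  trajectories: []           # [{{topology: top.pqr, coords: rep1.tsv, label: rep1}}]
  pair: {{resA: [A, 2], resB: [B, 2]}}
  alignment: null            # aligned FASTA/Stockholm, reference first
  alignment_reference: null
  substrates: null           # TSV: sequence <tab> site_position (1-based)
  structure_pdb: null        # structure for solvent accessibility
  structure_chain: A
  sites: []                  # 1-based positions in the reference sequence

saltbridge:
  cutoff: {SALT_BRIDGE_CUTOFF}                # A (= 0.6 nm), stable-contact threshold
  dwell_min: 1               # frames; 10 recommended for noisy data

mmpbsa:
  chain_a: A
  chain_b: B
  # lj_defaults: {{epsilon: 0.45, sigma: 3.4}}   # PQR files carry no LJ terms
  frame_interval_ps: 0.0     # 0 = every frame; 10000 = the conventional 10 ns
  include_polar: true

pb:
  eps_solute: {pb.eps_solute}
  eps_solvent: {pb.eps_solvent}
  ionic_strength: {pb.ionic_strength}        # mol/L
  temperature: {pb.temperature}          # K
  fine_spacing: {pb.fine_spacing}           # A
  coarse_factor: {pb.coarse_factor}          # x solute long axis
  stern_layer: {pb.stern_layer}            # A
  solver_tol: {pb.solver_tol}
  max_iter: {pb.max_iter}
  omega: {pb.omega}                 # SOR relaxation

sasa:
  probe_radius: {sasa.probe_radius}          # A
  gamma: {sasa.gamma}              # kJ/mol/A^2
  offset_b: {sasa.offset_b}             # kJ/mol
  n_sphere_points: {sasa.n_sphere_points}

motif:
  alpha: 0.01                # pseudocount; window is 15 residues, site at 8
"""
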