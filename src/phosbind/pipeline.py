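"""Pipeline orchestration: stages, manifest, and report.

Stages run in dependency order; the three analysis branches (salt-bridge
dynamics, MM-PBSA energetics, conservation/motif/annotation) are
independent, so a failure in one branch skips only its own downstream
stages. Output tables are written with a fixed 6-significant-digit float
format so that identical configurations produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, ValidationError
from .energetics import (EnergyBreakdown, binding_energy, compare_states,
                         residue_decomposition)
from .msa import column_profiles, conservation_score, read_alignment
from .motif import build_motif
from .saltbridge import ContactSeries, count_formation_events, \
    min_sidechain_distance, summarize_replicas
from .sites import annotate_sites
from .structures import read_pdb, read_pqr, read_trajectory, write_bfactor_map

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "StageFailure", "run_pipeline", "make_report", "fmt"]


def fmt(x) -> str:
    """Fixed 6-significant-digit float format (deterministic outputs)."""
    if x is None:
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


class StageFailure(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, str] = field(default_factory=dict)   # name -> ok/failed/skipped
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.stages.values())

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        payload = {"version": self.version, "config": self.config,
                   "stages": self.stages, "outputs": self.outputs,
                   "errors": self.errors}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def _stage_saltbridge(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    series_list = []
    for t in cfg.trajectories:
        top = read_pqr(t.topology) if t.topology.endswith(".pqr") \
            else read_pdb(t.topology)
        traj = read_trajectory(t.coords, top)
        series = min_sidechain_distance(traj, cfg.pair_res_a, cfg.pair_res_b,
                                        cutoff=cfg.cutoff, dwell_min=cfg.dwell_min)
        series_list.append((t.label, series))
        p = outdir / f"saltbridge_{t.label}_distance.tsv"
        with open(p, "w") as fh:
            fh.write("time_ps\tdistance_A\tin_contact\n")
            for tt, d, c in zip(series.times, series.distances, series.in_contact):
                fh.write(f"{fmt(tt)}\t{fmt(d)}\t{int(c)}\n")
        manifest.register(p)
        p = outdir / f"saltbridge_{t.label}_events.tsv"
        with open(p, "w") as fh:
            fh.write("start_frame\tend_frame\tdwell\tinitial_contact\n")
            for ev in count_formation_events(series):
                fh.write(f"{ev.start_frame}\t{ev.end_frame}\t{ev.dwell}\t"
                         f"{int(ev.initial_contact)}\n")
        manifest.register(p)
    summary = summarize_replicas([s for _, s in series_list])
    p = outdir / "saltbridge_summary.tsv"
    with open(p, "w") as fh:
        fh.write("replica\tformation_events\tcontact_fraction\n")
        for (label, _), cnt, frac in zip(series_list, summary.per_replica_counts,
                                         summary.contact_fractions):
            fh.write(f"{label}\t{cnt}\t{fmt(frac)}\n")
        fh.write(f"pooled\t{summary.pooled_events}\t"
                 f"{fmt(float(np.mean(summary.contact_fractions)))}\n")
    manifest.register(p)


def _write_breakdown(b: EnergyBreakdown, outdir: Path, tag: str,
                     manifest: RunManifest) -> None:
    p = outdir / f"mmpbsa_{tag}_frames.tsv"
    with open(p, "w") as fh:
        fh.write("frame\te_vdw\te_elec\tg_polar\tg_nonpolar\ttotal\n")
        for i in range(b.n_frames):
            fh.write(f"{i}\t{fmt(b.e_vdw[i])}\t{fmt(b.e_elec[i])}\t"
                     f"{fmt(b.g_polar[i])}\t{fmt(b.g_nonpolar[i])}\t"
                     f"{fmt(b.total[i])}\n")
    manifest.register(p)
    p = outdir / f"mmpbsa_{tag}_summary.tsv"
    with open(p, "w") as fh:
        fh.write("term\tmean_kJ_mol\tsd_kJ_mol\n")
        for label, mean, sd in b.summary_rows():
            fh.write(f"{label}\t{fmt(mean)}\t{fmt(sd)}\n")
    manifest.register(p)


def _apply_lj_defaults(s, cfg: RunConfig):
    if cfg.lj_epsilon_default is None:
        return s
    for a in s.atoms:
        if a.lj_sigma == 0.0 and a.is_heavy:
            a.lj_epsilon = cfg.lj_epsilon_default
            a.lj_sigma = cfg.lj_sigma_default
    return s


def _stage_mmpbsa(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    s = _apply_lj_defaults(read_pqr(cfg.complex_pqr), cfg)
    b1 = binding_energy(s, cfg.chain_a, cfg.chain_b, pb=cfg.pb,
                        sasa_cfg=cfg.sasa,
                        frame_interval_ps=cfg.frame_interval_ps,
                        include_polar=cfg.include_polar)
    _write_breakdown(b1, outdir, "state1", manifest)
    rmap = residue_decomposition(s, cfg.chain_a, cfg.chain_b, pb=cfg.pb,
                                 sasa_cfg=cfg.sasa,
                                 include_polar=cfg.include_polar)
    p = outdir / "mmpbsa_residues.tsv"
    with open(p, "w") as fh:
        fh.write("chain\tres_seq\te_vdw\te_elec\tg_polar\tg_nonpolar\ttotal\n")
        for (c, r), vals in sorted(rmap.components.items()):
            fh.write(f"{c}\t{r}\t" + "\t".join(
                fmt(vals[k]) for k in
                ("e_vdw", "e_elec", "g_polar", "g_nonpolar", "total")) + "\n")
    manifest.register(p)
    p = outdir / "mmpbsa_residues_bfactor.pdb"
    write_bfactor_map(s, rmap.as_bfactor_values("total"), p)
    manifest.register(p)
    if cfg.complex_pqr_alt:
        s2 = _apply_lj_defaults(read_pqr(cfg.complex_pqr_alt), cfg)
        b2 = binding_energy(s2, cfg.chain_a, cfg.chain_b, pb=cfg.pb,
                            sasa_cfg=cfg.sasa,
                            frame_interval_ps=cfg.frame_interval_ps,
                            include_polar=cfg.include_polar)
        _write_breakdown(b2, outdir, "state2", manifest)
        dd = compare_states(b1, b2, allow_unequal_n=True)
        p = outdir / "mmpbsa_ddG.tsv"
        with open(p, "w") as fh:
            fh.write("term\tddG_kJ_mol\tsd_kJ_mol\n")
            labels = {"e_vdw": "van der Waals", "e_elec": "Electrostatic",
                      "g_polar": "Polar solvation", "g_nonpolar": "SASA",
                      "total": "ddG"}
            for key, label in labels.items():
                d, sd = dd[key]
                fh.write(f"{label}\t{fmt(d)}\t{fmt(sd)}\n")
        manifest.register(p)


def _stage_conservation(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    aln = read_alignment(cfg.alignment, reference=cfg.alignment_reference)
    profiles = column_profiles(aln)
    refmap = {v: k for k, v in aln.reference_position_map().items()}
    p = outdir / "conservation.tsv"
    with open(p, "w") as fh:
        fh.write("column\tref_position\tconsensus\tgap_fraction\t"
                 "max_frequency\tconservation_score\tlow_confidence\n")
        for col, prof in enumerate(profiles):
            score = conservation_score(prof) if prof.frequencies else None
            maxf = max((f for a, f in prof.frequencies.items() if a != "X"),
                       default=None)
            fh.write(f"{col}\t{refmap.get(col, 'NA')}\t{prof.consensus or 'NA'}\t"
                     f"{fmt(prof.gap_fraction)}\t{fmt(maxf)}\t"
                     f"{score if score is not None else 'NA'}\t"
                     f"{int(prof.low_confidence)}\n")
    manifest.register(p)


def _read_substrates(path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seq, pos = line.split()[:2]
            out.append((seq, int(pos)))
    return out


def _stage_motif(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    subs = _read_substrates(cfg.substrates)
    motif = build_motif(subs, alpha=cfg.motif_alpha)
    p = outdir / "motif_counts.tsv"
    motif.to_counts_tsv(p)
    manifest.register(p)
    p = outdir / "motif.meme"
    motif.to_meme(p, name="kinase_substrate")
    manifest.register(p)


def _stage_annotate(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    aln = read_alignment(cfg.alignment, reference=cfg.alignment_reference)
    seq = aln.reference_row.replace("-", "").replace(".", "")
    subs = _read_substrates(cfg.substrates)
    motif = build_motif(subs, alpha=cfg.motif_alpha)
    structure = read_pdb(cfg.structure_pdb) if cfg.structure_pdb else None
    if structure is not None and cfg.structure_pdb.endswith(".pqr"):
        structure = read_pqr(cfg.structure_pdb)
    annos = annotate_sites(seq, aln, structure, motif, cfg.sites,
                           chain_id=cfg.structure_chain, sasa_cfg=cfg.sasa)
    p = outdir / "site_annotations.tsv"
    with open(p, "w") as fh:
        fh.write("position\tresidue\tconservation_score\trsa_percent\t"
                 "motif_score_bits\tflags\n")
        for a in annos:
            fh.write(f"{a.position}\t{a.residue}\t"
                     f"{a.conservation if a.conservation is not None else 'NA'}\t"
                     f"{fmt(a.rsa_percent)}\t{fmt(a.motif_score_bits)}\t"
                     f"{','.join(a.flags) or '-'}\n")
    manifest.register(p)


_STAGES = {
    "saltbridge": _stage_saltbridge,
    "mmpbsa": _stage_mmpbsa,
    "conservation": _stage_conservation,
    "motif": _stage_motif,
    "annotate": _stage_annotate,
}
# annotation combines conservation + motif inputs; run it after both
_ORDER = ["saltbridge", "mmpbsa", "conservation", "motif", "annotate"]
_DEPENDS = {"annotate": {"conservation", "motif"}}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Validate, run the selected stages, and write the run manifest.

    Raises :class:`ValidationError` before any stage runs if inputs are
    missing. Stage failures are recorded; stages depending on a failed one
    are skipped. The manifest is always written.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(cfg), version=__version__)
    failed: set[str] = set()
    for name in _ORDER:
        if name not in cfg.stages:
            continue
        deps = _DEPENDS.get(name, set()) & set(cfg.stages)
        if deps & failed:
            manifest.stages[name] = "skipped"
            continue
        t0 = time.time()
        try:
            _STAGES[name](cfg, outdir, manifest)
            manifest.stages[name] = "ok"
            logger.info("stage %s done in %.1f s", name, time.time() - t0)
        except Exception as exc:   # recorded, not raised: manifest must be written
            manifest.stages[name] = "failed"
            manifest.errors[name] = f"{type(exc).__name__}: {exc}"
            failed.add(name)
            logger.error("stage %s failed: %s", name, exc)
    manifest.write(outdir / "manifest.json")
    return manifest


def _config_snapshot(cfg: RunConfig) -> dict:
    snap = dataclasses.asdict(cfg)
    snap["pb"] = dataclasses.asdict(cfg.pb)
    snap["sasa"] = dataclasses.asdict(cfg.sasa)
    return snap


def make_report(manifest: RunManifest, outdir: Path) -> Path:
    """Human-readable Markdown report embedding the stage summary tables."""
    if not manifest.stages:
        raise ValueError("empty manifest: no stages were run")
    missing = [p for p in manifest.outputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError("missing outputs: " + ", ".join(missing))
    lines = ["# phosbind run report", ""]
    lines.append("| stage | status |")
    lines.append("|-------|--------|")
    for name, status in manifest.stages.items():
        lines.append(f"| {name} | {status} |")
    lines.append("")

    def embed(path: Path, title: str):
        if not path.exists():
            return
        lines.append(f"## {title}\n")
        rows = path.read_text().strip().split("\n")
        header = rows[0].split("\t")
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))
        for row in rows[1:]:
            lines.append("| " + " | ".join(row.split("\t")) + " |")
        lines.append("")

    embed(outdir / "mmpbsa_state1_summary.tsv", "Binding energy terms (state 1)")
    embed(outdir / "mmpbsa_state2_summary.tsv", "Binding energy terms (state 2)")
    embed(outdir / "mmpbsa_ddG.tsv", "ddG (state 2 - state 1)")
    embed(outdir / "saltbridge_summary.tsv", "Salt-bridge formation events")
    embed(outdir / "site_annotations.tsv", "Phosphosite annotations")
    bf = outdir / "mmpbsa_residues_bfactor.pdb"
    if bf.exists():
        lines.append(f"Per-residue binding-energy map (B-factor column): `{bf}`\n")
    p = outdir / "report.md"
    p.write_text("\n".join(lines) + "\n")
    return p
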