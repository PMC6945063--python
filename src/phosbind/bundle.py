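"""Self-contained synthetic fixture bundles.

``write_fixture_bundle`` materializes one directory containing everything
the pipeline stages consume — PQR structures, contact-trajectory coordinate
tables for two systems (a never-binding control and a binding system, six
replicas each), an ortholog-like alignment, and substrate windows — plus a
JSON manifest recording the specs, derived seeds, and ground truths.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .motif import CENTER
from .structures import write_pqr, write_trajectory_tsv
from .synthetic import (AlignmentSpec, TelegraphSpec, ToyComplexSpec,
                        default_motif_ppm, gen_alignment, gen_born_system,
                        gen_contact_trajectory, gen_substrate_windows,
                        gen_toy_complex, stream_seed)

__all__ = ["write_fixture_bundle"]

N_REPLICAS = 6


def write_fixture_bundle(outdir, seed: int = 0, n_frames: int = 2000,
                         n_sequences: int = 500, n_windows: int = 100) -> dict:
    """Write the full fixture bundle; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "ground_truth": {}, "specs": {}, "files": {}}

    born = gen_born_system(1.0, 2.0)
    p = outdir / "born_ion.pqr"
    write_pqr(born.structure, p)
    manifest["files"]["born_ion"] = p.name
    manifest["ground_truth"]["born_energy_eps_2_80"] = born.analytic_energy(2.0, 80.0)

    spec1 = ToyComplexSpec(charge_pattern="opposite", seed=seed)
    complex1, ref1 = gen_toy_complex(spec1)
    p = outdir / "toy_complex_bound.pqr"
    write_pqr(complex1, p)
    manifest["files"]["complex_state1"] = p.name
    manifest["specs"]["complex_state1"] = asdict(spec1)
    manifest["ground_truth"]["complex_state1_vacuum_mm"] = ref1

    spec2 = ToyComplexSpec(charge_pattern="dipole", seed=seed)
    complex2, ref2 = gen_toy_complex(spec2)
    p = outdir / "toy_complex_weak.pqr"
    write_pqr(complex2, p)
    manifest["files"]["complex_state2"] = p.name
    manifest["specs"]["complex_state2"] = asdict(spec2)
    manifest["ground_truth"]["complex_state2_vacuum_mm"] = ref2

    traj_entries = []
    truths = {}
    for system, k_on in (("control", 0.0), ("binding", 0.01)):
        for rep in range(N_REPLICAS):
            rep_seed = stream_seed(f"{system}_rep{rep}", seed)
            tspec = TelegraphSpec(k_on=k_on, n_frames=n_frames, seed=rep_seed)
            traj, _states, events = gen_contact_trajectory(tspec)
            label = f"{system}_rep{rep + 1}"
            top_path = outdir / "contact_topology.pqr"
            if not top_path.exists():
                write_pqr(traj.topology, top_path)
            coords_path = outdir / f"contact_{label}.tsv"
            write_trajectory_tsv(traj, coords_path)
            traj_entries.append({"topology": top_path.name,
                                 "coords": coords_path.name, "label": label})
            truths[label] = {"true_formation_frames": events,
                             "spec": asdict(tspec)}
    manifest["files"]["trajectories"] = traj_entries
    manifest["ground_truth"]["contact_events"] = truths

    aspec = AlignmentSpec(n_sequences=n_sequences, seed=seed)
    aln = gen_alignment(aspec)
    p = outdir / "alignment.fasta"
    with open(p, "w") as fh:
        for sid, s in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{s}\n")
    manifest["files"]["alignment"] = p.name
    manifest["specs"]["alignment"] = {
        "n_sequences": aspec.n_sequences, "n_columns": aspec.n_columns,
        "seed": aspec.seed}
    manifest["ground_truth"]["alignment_conservation"] = \
        [float(v) for v in aspec.conservation]

    ppm = default_motif_ppm()
    windows = gen_substrate_windows(ppm, n_windows, seed=seed)
    p = outdir / "substrates.tsv"
    with open(p, "w") as fh:
        fh.write("# sequence\tsite_position (1-based)\n")
        for w in windows:
            fh.write(f"{w}\t{CENTER}\n")
    manifest["files"]["substrates"] = p.name
    manifest["ground_truth"]["motif_ppm"] = [[float(v) for v in row]
                                             for row in ppm]

    (outdir / "bundle_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
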