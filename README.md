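# phosbind

Computational analysis of how phosphorylation of surface serines reshapes a
protein–protein interface, built for the LC3C–ATG4B system (and its
GABARAP-L2 counterpart) in autophagy: the kinase TBK1 phosphorylates the
autophagy modifier LC3C on two surface-exposed serines (S93/S96) next to the
interface with the processing protease ATG4B, and the question is whether —
and through which interactions — the added negative charge destabilizes the
complex and restructures the free protein's C-terminal tail.

The package provides four analysis branches, each testable end to end on
synthetic fixtures with known ground truth, so no external structures,
trajectories, or alignments are required:

1. **MM-PBSA binding free energies** of two-chain complexes over trajectory
   frames, with residue-wise decomposition. In the single-trajectory scheme
   the per-frame binding energy is

       ΔG_bind = ΔE_vdW + ΔE_elec + ΔΔG_polar + ΔΔG_nonpolar

   where the molecular-mechanics terms are all-pair inter-chain
   Lennard-Jones and vacuum Coulomb sums (bonded terms cancel identically),
   ΔΔG_polar = G_PB(AB) − G_PB(A) − G_PB(B) comes from a finite-difference
   **linearized Poisson–Boltzmann** solver written for this package
   (7-point stencil, face-smoothed dielectric boundary, Debye–Hückel
   screening outside a Stern layer, two-level focusing, red-black SOR), and
   ΔΔG_nonpolar = γ·(SASA_AB − SASA_A − SASA_B) is the SASA model with a
   deterministic Shrake–Rupley surface. The configurational-entropy term
   −TΔS is not evaluated and is reported as absent, never folded into
   totals. Defaults follow the conventional continuum setup: ε_solute = 2,
   ε_solvent = 80, 150 mM ionic strength, 0.5 Å fine grid, coarse grid 1.5×
   the solute long axis, probe 1.4 Å, γ = 0.0226 kJ/mol/Å²,
   offset 3.84 kJ/mol.

2. **Salt-bridge formation dynamics**: per-frame minimum distance between
   side-chain heavy atoms of a residue pair (e.g. R134 against a
   phosphoserine), contact classification at the 6.0 Å (0.6 nm) cutoff, and
   deterministic counting of *formation events* — maximal in-contact runs
   entered by a downward crossing, with a dwell filter for noisy data and
   runs already bound at frame 0 flagged separately — pooled over replica
   simulations.

3. **Phosphoserine building**: SER → SEP with ideal phosphate geometry
   (P–OG 1.61 Å, tetrahedral oxygens), a 10°-step torsion scan that picks
   the least-clashing rotamer, and re-parameterization to the fully
   deprotonated −2 e state.

4. **Phosphosite annotation**: per-column conservation of ortholog
   alignments (entropy-based 0–9 score), a kinase-substrate motif built
   from 15-residue windows (position probability matrix, information
   content in bits, log-odds site scoring), and relative solvent
   accessibility (residue SASA / theoretical maximum, in %).

A `synthetic` module generates every fixture class with known ground truth
— Born ions and two-chain toy charge complexes with closed-form energies,
two-state telegraph contact trajectories, alignments with controlled
per-column conservation, substrate windows drawn from a known motif — and
the `phosbind` command line orchestrates the stages behind a structured
YAML configuration.

## Worked example

Binding energy of a synthetic two-chain complex (four +1 e atoms against
four −1 e atoms, 10 Å apart — the generator also returns the closed-form
vacuum interaction for cross-checking):

```python
from phosbind import binding_energy, PBConfig
from phosbind.synthetic import ToyComplexSpec, gen_toy_complex

complex_, vacuum_ref = gen_toy_complex(ToyComplexSpec(seed=3))
b = binding_energy(complex_, "A", "B", pb=PBConfig(temperature=298.0))
for label, mean, sd in b.summary_rows():
    print(f"{label:22s} {mean:10.1f} +/- {sd:.1f} kJ/mol")
```

```
van der Waals                -0.0 +/- 0.0 kJ/mol
Electrostatic             -1944.0 +/- 0.0 kJ/mol
Polar solvation             964.9 +/- 0.0 kJ/mol
SASA                          0.0 +/- 0.0 kJ/mol
Total binding energy       -979.2 +/- 0.0 kJ/mol
```

The electrostatic attraction of the opposite-charged chains (−1944 kJ/mol,
matching the generator's closed form to nine digits) is roughly half
compensated by the polar-solvation penalty of desolvating them — the same
cancellation pattern that governs real interface energetics. Salt-bridge
event detection on a telegraph trajectory recovers the generator's
switching ground truth exactly:

```python
from phosbind import count_formation_events, min_sidechain_distance
from phosbind.synthetic import TelegraphSpec, gen_contact_trajectory

traj, states, true_frames = gen_contact_trajectory(TelegraphSpec(seed=4))
series = min_sidechain_distance(traj, ("A", 2), ("B", 2), dwell_min=10)
events = [e for e in count_formation_events(series) if not e.initial_contact]
print(true_frames)                                   # [44, 384, 896, 1356, 1716, 1807]
print([e.start_frame for e in events])               # [44, 384, 896, 1356, 1716, 1807]
```

The full pipeline runs from the shell:

```sh
phosbind simulate --seed 1 -o fixtures      # synthetic bundle + ground truth
phosbind config init -o run.yaml            # every parameter, explicit
phosbind run -c run.yaml                    # stages + manifest.json
phosbind report -m out/manifest.json        # Markdown summary tables
```

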