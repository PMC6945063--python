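# Methods

## Scope and model

The package analyses how phosphorylation of surface serines changes the
stability of a two-chain protein complex and the conformational behaviour
of the free protein. Its quantitative core is the single-trajectory MM-PBSA
estimate of the binding free energy,

    ΔG_bind = ΔE_MM + ΔG_solv,      ΔE_MM = ΔE_vdW + ΔE_elec,
    ΔG_solv = ΔΔG_polar + ΔΔG_nonpolar,

evaluated per frame on complex conformations whose receptor and ligand
coordinates are taken from the same frame (rigid split). Under that scheme
the intramolecular bonded terms cancel identically and are not computed.
The configurational-entropy contribution −TΔS is deliberately not
evaluated: quasi-harmonic or normal-mode entropies on desk-scale fixtures
would be noise, so the term is reported as absent and never added to
totals. Binding energies from this class of model rank states and localize
interactions; they are not dissociation constants.

### Molecular-mechanics terms

Inter-chain electrostatics is the all-pair vacuum Coulomb sum
f·q_i·q_j/(ε·r_ij) with f = 1389.35458 kJ·mol⁻¹·Å·e⁻² and ε = 1; van der
Waals is the all-pair 12-6 Lennard-Jones sum under Lorentz–Berthelot
combination. No distance cutoff is applied: these are post-processing
energies of finite systems, not dynamics, and a cutoff would introduce a
free parameter with no benefit.

### Polar solvation: finite-difference linearized Poisson–Boltzmann

The solver discretizes ∇·(ε∇u) − ε_s κ² m(r) u = −4π ρ on a regular grid,
with the potential u in units of e/Å so that the energy of charge q at
potential u is f·q·u.

- **Dielectric map.** ε = ε_solute inside the inflated van der Waals volume
  of the solute, ε_solvent outside, sampled on the three staggered
  face-midpoint grids. The boundary is smoothed over one grid spacing by
  harmonic interpolation in the signed distance to the surface. The
  smoothing is what makes the computed energy converge smoothly (and, on
  the Born ion, monotonically) under grid refinement; a hard staircase
  boundary makes the energy oscillate with grid alignment. A molecular
  (probe-rolled) surface is out of scope; the vdW boundary is the simplest
  definition consistent with a 0.5 Å grid.
- **Screening.** κ² = 8π f I N_A/(10²⁷ ε_s R T) (1:1 electrolyte, I in
  mol/L, lengths in Å), active only outside the solute inflated by a
  2.0 Å Stern layer. At 150 mM and 298 K this gives a Debye length of
  7.85 Å (ε = 78.54).
- **Charges** are spread to the eight surrounding nodes by trilinear
  interpolation; the same weights are reused to read the potential back,
  which makes per-atom energies sum exactly to the total.
- **Focusing.** A coarse solve (box = 1.5× the solute long axis, at least
  the fine box plus 12 Å padding) with analytic Debye–Hückel boundary
  values supplies, by trilinear interpolation, both the Dirichlet boundary
  and the initial guess of the fine solve (0.5 Å default spacing, solute
  plus a 4 Å margin).
- **Reaction-field energy.** G_polar = (f/2) Σ q_node [u − u_ref] with
  u_ref from a same-grid, same-spreading solve at ε = ε_solute everywhere
  and κ = 0 (analytic Coulomb boundary, exact for a homogeneous medium).
  Identical grids and spreading make the singular grid self-energy cancel
  exactly, which is why the Born ion converges to 0.2 % at 0.25 Å.
- **Linear solver.** Damped red-black successive over-relaxation
  (ω = 1.8), deterministic, relative residual ‖Au − b‖/‖b‖ ≤ 1e-6,
  residual checked every 20 sweeps. Uncharged species short-circuit to
  exactly zero.

Binding uses ΔΔG_polar = G(AB) − G(A) − G(B) with all three species solved
on the identical complex-derived grids and identical charge mapping, so
grid artefacts largely cancel. One physical subtlety worth recording: this
difference tends to zero at large separation only for **net-neutral**
chains. For two net charges it tends to −f q₁q₂/(ε_in r) — the reference
solve retains the solute-dielectric Coulomb cross term — and cancels the
vacuum MM Coulomb term only when ε_in = 1. The test suite pins both
limits; the non-interacting-limit validation therefore uses net-neutral
(dipolar) chains, the physically long-range-silent case.

The PB temperature defaults to 310 K, the conventional physiological
production temperature; 298 K is available in the configuration (closed-
form comparisons in the tests use 298 K).

### Nonpolar solvation

ΔG_nonpolar = γ·SASA + b per species, with γ = 0.0226 kJ/mol/Å² and
b = 3.84 kJ/mol. In binding differences the per-species constant b cancels
by construction (it counts species, not surface), so
ΔΔG_nonpolar = γ·(SASA_AB − SASA_A − SASA_B). SASA is Shrake–Rupley with a
deterministic Fibonacci point set (960 points/atom by default, probe
1.4 Å); hydrogens carry no surface. The quadrature is exact for an
isolated sphere and rotation-noise is below 0.5 % at the default point
count.

### Residue decomposition

Pairwise MM energies are split half to each partner atom; polar per-atom
values are (f/2)·q_i·Δu(r_i) differences between complex and species
solves; nonpolar per-atom values are γ times the per-atom area change.
Summing any component over residues reproduces the complex-level value to
floating-point round-off — an exact bookkeeping identity, enforced by
tests, that makes the per-residue map trustworthy for localizing interface
hot spots. Values are exported as TSV and as a PDB whose B-factor column
carries the per-residue total (clamped to the column's format range).

## Salt-bridge formation events

The contact coordinate is the per-frame minimum distance between the
side-chain heavy atoms of a residue pair (side chain = everything but
N/CA/C/O and their hydrogens); glycine has no side chain and is rejected.
Contact means distance ≤ 6.0 Å (0.6 nm), with the boundary closed so tests
can be bit-exact. A **formation event** is a maximal in-contact run of at
least `dwell_min` frames that is *entered by a crossing* (previous frame
above the cutoff); a run already in contact at frame 0 is flagged as an
initial contact and excluded from the formation count, since no formation
was observed. This makes counting deterministic and gives a
never-crossing control trajectory a count of exactly zero. `dwell_min`
defaults to 1; 10 frames is the recommended setting for noisy data and is
what the detector-calibration fixtures use. No periodic-boundary handling
is attempted — inputs are assumed whole/unwrapped, and a distance beyond a
sanity bound (500 Å) raises rather than silently mis-measuring a wrapped
trajectory.

## Phosphoserine construction

The builder requires an intact SER with CB and OG, removes the hydroxyl
hydrogen if present, renames the residue SEP, and places P at 1.61 Å from
OG (CB–OG–P ≈ 119°) with three phosphate oxygens at 1.48 Å in tetrahedral
geometry. The torsion of the whole group about CB–OG is scanned in 10°
steps and the rotamer maximizing the minimum non-bonded heavy-atom
distance is kept — a deterministic, clash-aware placement that needs no
minimizer. The residue is re-parameterized to a net charge of −2 e (fully
deprotonated phosphate, the physiological-pH convention; the protonation
state is configurable through a custom parameter table since experimental
patching protocols do not always state it). Exactly one residue changes;
every other atom is bitwise untouched.

## Conservation, motif, accessibility

- **Conservation.** Column frequencies are computed over non-gap symbols
  (X counted, never consensus; consensus ties break alphabetically), and
  the 0–9 score is floor(9·(1 − H/log₂20)) with H the Shannon column
  entropy. This is a deliberate, clearly-labelled surrogate for
  phylogenetic rate-based scores (ConSurf-style scales): it is
  deterministic and dependency-free but treats sequences as independent
  draws, so densely sampled clades inflate apparent conservation.
  Columns with gap fraction > 0.5 are flagged low-confidence.
- **Motif.** Substrate windows are 15-mers centred on the phosphosite
  (position 8), X-padded at sequence ends with X excluded from counts. The
  position probability matrix uses pseudocount α
  ((count + α)/(n_eff + 20α)); information content is log₂20 − H per
  position, and site scoring is the summed log₂(PPM/background) with X
  contributing zero. α = 0 keeps a fully conserved column at exactly
  log₂20 bits; α = 0.01 is the scoring default so unseen residues stay
  finite.
- **Accessibility.** RSA % = residue SASA / theoretical maximum ASA for
  the residue type (bundled table of published theoretical maxima; the SEP
  entry is an in-house approximation, marked as such in the file). Because
  the numerical surface and the normalization table use different radii
  conventions, fully extended residues can modestly exceed 100 %.

## Synthetic data: what it emulates and what it does not

All generators are deterministic given (spec, seed); a single global seed
fans out to independent streams via SHA-256 of the generator name.

- **Born ion / toy complexes** carry closed-form reference energies
  (computed by plain-Python double loops, independent of the vectorized
  path). The toy complex places two clash-guarded random clusters at a
  controlled separation with opposite, dipolar (net-neutral), or zero
  charge patterns.
- **Telegraph trajectories** model the contact coordinate as a two-state
  Markov chain (bound 4.5 Å / unbound 9.0 Å, Gaussian noise σ = 0.3 Å)
  with per-frame switch probabilities k_on = 0.01, k_off = 0.002 over 2000
  frames, starting unbound. These defaults give a handful of
  multi-hundred-frame bound episodes per trajectory — the regime the
  dwell-filtered detector is designed for, mimicking formation events that
  persist once formed. The noise is uncorrelated frame to frame, so the
  fixtures do not probe autocorrelated distance fluctuations of real MD;
  the brute-force-equivalence property test covers arbitrary series
  instead.
- **Alignments** draw each column independently: consensus residue with
  probability p, else uniform over the remaining 19. Per-column p defaults
  to Uniform(0.4, 1.0) — the mostly-conserved regime of ortholog sets —
  and carries no phylogeny, indels, or covariation.
- **Substrate windows** are i.i.d. draws from a known PPM. The default
  generating motif is informative (favoured residue p = 0.7, secondary
  0.2, uniform remainder; the position after the phosphosite is
  leucine-dominated, as in serine/threonine kinase substrate preferences,
  and the centre is fixed serine). The informativeness is a condition, not
  a tuning: recovering a near-uniform PPM to 0.05 total variation from
  1000 windows is statistically impossible (binomial error alone exceeds
  the bound), so the recovery guarantee is stated — and holds — for
  informative motifs.

Passing tests on these fixtures demonstrates correctness of the
*computational machinery* — solvers, detectors, estimators, bookkeeping —
not the accuracy of continuum electrostatics or reduced charge sets for
real proteins.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| ε_solute / ε_solvent | 2 / 80 | – | dielectric contrast of the PB model |
| ionic strength | 0.150 | mol/L | Debye screening (λ_D ≈ 7.9 Å at 298 K) |
| PB temperature | 310 | K | enters κ² only; 298 K for closed-form checks |
| fine grid spacing | 0.5 | Å | PB discretization; 0.25 for validation solves |
| coarse box factor | 1.5 | × long axis | focusing outer box |
| Stern layer | 2.0 | Å | ion-exclusion shell |
| SOR ω / tolerance | 1.8 / 1e-6 | – | iteration damping / relative residual |
| probe radius | 1.4 | Å | solvent probe for SASA |
| γ / b | 0.0226 / 3.84 | kJ/mol/Å², kJ/mol | SASA model coefficients |
| contact cutoff | 6.0 | Å | salt-bridge classification (0.6 nm) |
| dwell_min | 1 (10 for noisy data) | frames | event persistence filter |
| frame interval | 0 (= every frame) | ps | subsampling; 10 ns conventional for long MD |
| motif window / α | 15, site at 8 / 0.01 | – | PPM construction and scoring |

All lengths are angstroms internally; configuration values may be given in
nm with an explicit unit key. The bundled parameter set is a minimal
heavy-atom fixed-point-charge table (integer residue sums, element-based
radii and LJ parameters) written for this package so that every energy is
reproducible from the repository alone; it is not a port of a production
force field, and absolute energies computed with it are fixture-scale
quantities, not predictions for real proteins.

## Numerical choices and degenerate inputs

- Contact at exactly the cutoff counts as contact; consensus ties break
  alphabetically; SOR is deterministic (no random initialization); TSV
  floats are written at 6 significant digits so identical runs are
  byte-identical.
- All-gap alignment columns, sites missing from structures, and windows
  truncated by termini degrade to flagged partial annotations, not errors;
  genuinely malformed inputs (wrong atom counts, non-numeric coordinates,
  unknown parameters) raise with the offending line/frame/atom named.
- Validation problem sizes: Born ion at 1.0/0.5/0.25 Å spacings;
  non-interacting limit at 80 Å separation (net-neutral chains); 100
  random 10⁴-frame series and 100 telegraph trajectories of 2000 frames
  for the detector; 1000 windows / 500 sequences for the estimators. These
  are the sizes at which the stated tolerances are comfortably resolved on
  a single CPU.

## Known limitations

- Linearized PB only, vdW dielectric boundary, no nonlinear or
  molecular-surface options; no PME/periodic electrostatics.
- Single-trajectory MM-PBSA only (no separate receptor/ligand ensembles);
  no entropy term.
- The conservation score is not a phylogenetic rate; densely sampled
  clades bias it.
- The bundled charge set is reduced; results on real structures are
  qualitative (ranking/localization), and a full force field would be
  needed for production numbers.
- Binary trajectory formats are supported only through an optional
  MDAnalysis adapter; the text formats (multi-model PDB, coordinate TSV)
  are the tested path.
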