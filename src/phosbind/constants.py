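"""Physical constants and unit conventions.

All lengths are in angstroms (A), energies in kJ/mol, charges in elementary
charges (e), times in picoseconds. Inputs given in nanometres are converted
at the boundary (see :mod:`phosbind.config`).
"""

#: Coulomb constant e^2/(4 pi eps0) * N_A, in kJ mol^-1 A e^-2.
COULOMB_KJ = 1389.35458

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.31446261815324e-3

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Default salt-bridge distance cutoff (A); 0.6 nm.
SALT_BRIDGE_CUTOFF = 6.0

#: Backbone atom names; everything else on a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "HA1", "HA2",
                            "HN", "H1", "H2", "H3", "OXT"})
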