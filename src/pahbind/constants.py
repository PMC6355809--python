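"""Physical constants and package-wide defaults.

All core computations use a fixed unit system: concentrations in mol/L,
energies in kJ/mol, temperatures in K, lengths in nm.  Unit conversion
happens only at the I/O boundary (see :mod:`pahbind.io`).
"""

#: Molar gas constant, kJ/(mol K).
R_KJ_PER_MOL_K = 8.31446e-3

#: Standard-state volume per molecule at 1 M, nm^3 (1 molecule / 1.660 nm^3).
V0_NM3 = 1.660

#: Default temperature for K_d -> Gibbs energy conversion, K.
T_KD_DEFAULT = 297.0

#: Default temperature for free-energy cycle arithmetic, K.
T_CYCLE_DEFAULT = 300.0

#: Binding sites per RHCC-NT tetramer (the two equivalent interior cavities).
SITES_PER_TETRAMER_DEFAULT = 2

#: Molar mass of the RHCC-NT homotetramer, kg/mol.
TETRAMER_MOLAR_MASS_DEFAULT = 23.6
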