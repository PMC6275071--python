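"""Physical constants and unit conventions.

The package uses AMBER-style units throughout: lengths in Å, energies in
kcal/mol, masses in amu, times in ps, charges in elementary charge units.
No unit auto-detection is performed anywhere.
"""

#: Boltzmann constant, kcal/(mol K) (AMBER convention).
KB = 0.0019872041

#: Coulomb constant k_c, kcal Å / (mol e^2) (AMBER convention).
COULOMB_CONSTANT = 332.0636

#: 1 kcal/mol expressed in amu Å^2 / ps^2.  Converts a force in
#: kcal/(mol Å) divided by a mass in amu into an acceleration in Å/ps^2.
KCAL_PER_MOL_IN_AMU_A2_PS2 = 418.4

#: Default water-probe radius for solvent-accessible surface area, Å.
DEFAULT_PROBE_RADIUS = 1.4
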