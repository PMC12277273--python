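"""Internal unit system and conversion constants.

The simulator works in "real"-style units throughout: kcal/mol for energy,
Å for length, fs for time, Da (g/mol) for mass, degrees Kelvin for
temperature.  Velocities are Å/fs and forces kcal/mol/Å.  Two derived
constants glue these together:

* ``ACCEL`` converts force/mass into Å/fs²
  (1 kcal/mol/Å / Da = 4.184e3 J·mol⁻¹·m⁻¹·kg⁻¹·mol · 1e-3 ... = 4.1839e-4 Å/fs²).
* ``MVV2E`` is its inverse and converts m·v² into kcal/mol.

Stress: 1 kcal/mol/Å³ = 6.9477 GPa (4184 J / 6.02214e23 / 1e-30 m³).
"""

# kcal/mol/Å per Da -> Å/fs²
ACCEL = 4.1839e-4
# Da·(Å/fs)² -> kcal/mol
MVV2E = 1.0 / ACCEL
# Boltzmann constant, kcal/mol/K
KB = 0.0019872041
# kcal/mol/Å³ -> GPa
KCAL_PER_A3_TO_GPA = 6.9477
# kcal/mol/Å³ -> MPa
KCAL_PER_A3_TO_MPA = 6947.7
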