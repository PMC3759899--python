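"""Physical constants and the package-wide unit system.

Units everywhere: lengths in Angstrom (Å), energies in kcal/mol, masses in
atomic mass units (amu), time in femtoseconds (fs), temperatures in Kelvin.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: kcal/mol per amu·Å²/fs².
#:
#: 1 amu·Å²/fs² per particle is 1e-3 kg/mol · 1e10 m²/s² = 1e7 J/mol, and
#: 1 kcal = 4184 J, so the factor is exactly 1e7/4184.
KCAL_PER_AMU_A2_FS2 = 1.0e7 / 4184.0  # ≈ 2390.0574

#: fs per ps, used to convert Langevin damping constants quoted in ps⁻¹.
FS_PER_PS = 1000.0
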