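"""Physical constants and unit conversions.

Internal unit system: length Å, energy kcal·mol⁻¹, mass amu, time fs
(friction given in ps⁻¹, timestep in fs, temperatures in K).
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹
KB = 1.987204259e-3

#: Acceleration conversion: (kcal·mol⁻¹·Å⁻¹ / amu) -> Å·fs⁻²
#: 1 kcal/mol = 4184 J/mol; 1 amu = 1 g/mol; lengths in Å, time in fs.
ACCEL = 4.184e-4

#: Debye–Waller prefactor: B = (8 π² / 3) ⟨Δr²⟩ for isotropic displacement.
import math

B_FACTOR_PREFACTOR = 8.0 * math.pi ** 2 / 3.0

FS_PER_PS = 1000.0
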