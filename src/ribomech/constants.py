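"""Physical constants and unit conventions.

Energies are kcal·mol⁻¹, distances Å, angles degrees, temperatures K and
rate constants min⁻¹ throughout the package.
"""

import math

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL: float = 1.987204e-3

#: Boltzmann constant, J·K⁻¹ (SI, used only in the Eyring prefactor).
KB_J: float = 1.380649e-23

#: Planck constant, J·s.
H_J: float = 6.62607015e-34

#: Default temperature, K.
DEFAULT_TEMPERATURE: float = 298.15

LN10: float = math.log(10.0)


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/RT in mol·kcal⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_KCAL * temperature)


def rt_ln10(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT·ln(10) in kcal·mol⁻¹, the conversion between ΔG and pKa units."""
    return R_KCAL * temperature * LN10
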