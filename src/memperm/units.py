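"""Unit conventions shared by every analysis.

All lengths are in angstrom (Å), times in picoseconds (ps), energies in
kcal/mol and temperatures in kelvin.  Derived quantities inherit these:
diffusion coefficients are Å²/ps, spring constants kcal/mol/Å², and the
permeability P = 1/R comes out in Å/ps (1 Å/ps = 10⁴ cm/s).
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol K).
K_B = 1.987204259e-3

#: Conversion factor from Å/ps to cm/s.
ANGSTROM_PER_PS_TO_CM_PER_S = 1.0e4

#: Default simulation temperature (K), the liquid-crystalline regime of a
#: POPC/cholesterol bilayer.
DEFAULT_TEMPERATURE = 310.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kcal.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K; must be positive.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (K_B * temperature)
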