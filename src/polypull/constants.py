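"""Physical constants and thermal state shared across the package.

Units follow AFM force-spectroscopy convention: lengths in nm, forces in pN,
energies in pN·nm (single molecule) or kcal/mol (molar), temperatures in K.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K).
BOLTZMANN_PN_NM = 1.380649e-2

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 1.98720425e-3

#: 1 kcal/mol expressed in joules per molecule.
KCAL_PER_MOL_IN_J = 6.9477e-21

#: Contour length gained per residue when a folded chain is fully stretched, nm.
RISE_PER_RESIDUE_NM = 0.36

ROOM_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class Thermal:
    """Temperature and derived thermal-energy scales.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    """

    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in pN·nm (4.114 pN·nm at 298 K)."""
        return BOLTZMANN_PN_NM * self.temperature

    @property
    def RT(self) -> float:
        """Molar thermal energy R·T in kcal/mol (0.592 kcal/mol at 298 K)."""
        return GAS_CONSTANT_KCAL * self.temperature


ROOM = Thermal()
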