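"""Potency and binding-affinity unit conversions.

pEC50 is defined on the molar scale: for an EC50 given in nanomolar,
``pEC50 = -log10(EC50 [mol/L]) = 9 - log10(EC50 [nM])``.  Binding free
energy follows from an inhibition constant via ``dG = R*T*ln(Ki [mol/L])``
with R in kcal/(mol*K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidValueError

#: gas constant, kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987e-3
#: standard temperature, K
STANDARD_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class ThermoConstants:
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = STANDARD_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidValueError(f"temperature must be positive, got {self.temperature}")


def ec50_to_pec50(ec50_nM: float) -> float:
    """Convert an EC50 in nM to pEC50 (molar scale)."""
    if not ec50_nM > 0:
        raise InvalidValueError(f"EC50 must be positive, got {ec50_nM}")
    return 9.0 - math.log10(ec50_nM)


def pec50_to_ec50(pec50: float) -> float:
    """Inverse of :func:`ec50_to_pec50`: pEC50 back to EC50 in nM."""
    return 10.0 ** (9.0 - pec50)


def ki_to_deltaG(ki_nM: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant in nM.

    Negative for sub-molar Ki; zero at Ki = 1 mol/L.
    """
    if not ki_nM > 0:
        raise InvalidValueError(f"Ki must be positive, got {ki_nM}")
    ki_molar = ki_nM * 1e-9
    return constants.gas_constant * constants.temperature * math.log(ki_molar)
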