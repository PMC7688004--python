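"""Thermodynamic conversion between binding free energy and dissociation constant.

The binding free energy of a complex relates to its dissociation constant by
``dG = R*T*ln(Kd)`` with the gas constant ``R`` in kcal/(mol*K).  Tighter
binders have more negative ``dG`` and smaller ``Kd``; ``dG = 0`` corresponds to
``Kd = 1`` M.
"""

from __future__ import annotations

import math

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Standard-condition temperature (K) used when none is given.
STANDARD_TEMPERATURE: float = 298.15


def _check(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def delta_g_to_kd(delta_g: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Dissociation constant (molar) from binding free energy (kcal/mol)."""
    delta_g = _check(delta_g, "delta_g")
    temperature = _check(temperature, "temperature")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp(delta_g / (R_KCAL * temperature))


def kd_to_delta_g(kd: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from dissociation constant (molar)."""
    kd = _check(kd, "kd")
    temperature = _check(temperature, "temperature")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    return R_KCAL * temperature * math.log(kd)
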