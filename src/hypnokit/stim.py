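"""Charge-density estimation for deep-brain-stimulation settings.

The charge density delivered per pulse at the electrode surface is

    charge density (uC/mm^2) = (voltage / impedance) * pulse_width / area

with voltage in volts, impedance in ohms, pulse width in microseconds and
contact area in mm^2; amperes times microseconds gives microcoulombs, so no
extra unit factor is needed. Current is derived from voltage and the
measured contact impedance rather than supplied directly, matching how DBS
settings are recorded in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class StimulationSettings:
    """Electrical stimulation settings for one animal/condition."""

    voltage_v: float
    impedance_ohm: float
    pulse_width_us: float
    contact_area_mm2: float
    frequency_hz: Optional[float] = None  # metadata only; not in the formula

    def __post_init__(self) -> None:
        if self.impedance_ohm <= 0:
            raise ValueError("impedance must be positive")
        if self.contact_area_mm2 <= 0:
            raise ValueError("contact area must be positive")
        if self.pulse_width_us <= 0:
            raise ValueError("pulse width must be positive")
        if self.voltage_v < 0:
            raise ValueError("voltage must be non-negative")


def charge_density(settings: StimulationSettings, decimals: int = 2) -> float:
    """Charge density in uC/mm^2, rounded to ``decimals`` (default 2)."""
    current_a = settings.voltage_v / settings.impedance_ohm
    charge_uc = current_a * settings.pulse_width_us  # A * us = uC
    return round(charge_uc / settings.contact_area_mm2, decimals)
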