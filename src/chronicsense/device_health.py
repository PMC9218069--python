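"""Electrode impedance computation and longitudinal trending.

The implanted device delivers a constant-current test pulse (100 Hz,
80 us) and reports the scalar magnitude |Z| = |V/I|.  Trending looks for
the initial stabilization point, the long-term level, the stimulated vs
sense-only level ratio, and breakage signatures (open circuit or an abrupt
step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImpedanceMeasurement",
    "ContactTrend",
    "TrendSummary",
    "impedance_from_waveform",
    "impedance_trend",
]

TEST_RATE_HZ = 100.0
TEST_PULSE_WIDTH_US = 80.0
OPEN_CIRCUIT_CEILING_OHM = 50_000.0
STEP_CHANGE_FACTOR = 5.0
STABLE_REL_CHANGE = 0.10


@dataclass
class ImpedanceMeasurement:
    """One |Z| reading for a contact at a follow-up time (months)."""

    contact: str
    month: float
    current_ma: float
    voltage_v: float
    rate_hz: float = TEST_RATE_HZ
    pulse_width_us: float = TEST_PULSE_WIDTH_US

    @property
    def impedance_ohm(self) -> float:
        return impedance_from_waveform(self.current_ma, self.voltage_v)

    @property
    def open_circuit(self) -> bool:
        return self.impedance_ohm > OPEN_CIRCUIT_CEILING_OHM


def impedance_from_waveform(current_ma: float, voltage_v: float) -> float:
    """|Z| in ohms from delivered current (mA) and measured voltage (V).

    Homogeneous of degree zero: scaling V and I together leaves |Z|
    unchanged.  Zero current is rejected.
    """
    if current_ma == 0:
        raise ValueError("current must be non-zero")
    return abs(voltage_v / (current_ma * 1e-3))


@dataclass
class ContactTrend:
    contact: str
    usage: str                       # "stimulated" | "sense_only"
    stabilization_month: float | None
    long_term_level_ohm: float | None
    breakage_month: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class TrendSummary:
    contacts: dict[str, ContactTrend]
    sense_stim_ratio: float | None   # long-term sense-only / stimulated level


def _contact_trend(contact: str, months: np.ndarray, z: np.ndarray,
                   usage: str) -> ContactTrend:
    if np.any(np.diff(months) <= 0):
        raise ValueError(f"{contact}: timestamps must be strictly increasing")
    if months.size < 3:
        raise ValueError(f"{contact}: need >= 3 time points")

    flags: list[str] = []
    breakage_month = None
    over = np.flatnonzero(z > OPEN_CIRCUIT_CEILING_OHM)
    ratio = z[1:] / z[:-1]
    steps = np.flatnonzero((ratio > STEP_CHANGE_FACTOR) | (ratio < 1 / STEP_CHANGE_FACTOR)) + 1
    candidates = []
    if over.size:
        candidates.append(months[over[0]])
        flags.append("open_circuit")
    if steps.size:
        candidates.append(months[steps[0]])
        flags.append("step_change")
    if candidates:
        breakage_month = float(min(candidates))

    # restrict stabilization/level analysis to the pre-breakage span
    good = months < breakage_month if breakage_month is not None else np.ones_like(z, bool)
    zg, mg = z[good], months[good]
    stabilization = None
    if zg.size >= 3:
        rel = np.abs(np.diff(zg)) / zg[:-1]
        # first month after which every subsequent relative change is small
        stable_from = None
        for i in range(rel.size):
            if np.all(rel[i:] < STABLE_REL_CHANGE):
                stable_from = i
                break
        if stable_from is not None:
            stabilization = float(mg[stable_from])
    level = float(np.median(zg[mg >= stabilization])) if stabilization is not None else None
    return ContactTrend(contact, usage, stabilization, level, breakage_month, flags)


def impedance_trend(
    series: list[ImpedanceMeasurement],
    usage: dict[str, str],
) -> TrendSummary:
    """Per-contact trend summary plus the sense-only/stimulated level ratio.

    ``usage`` maps contact -> "stimulated" or "sense_only".  Each contact
    needs at least 3 strictly increasing time points.
    """
    by_contact: dict[str, list[ImpedanceMeasurement]] = {}
    for m in series:
        by_contact.setdefault(m.contact, []).append(m)

    contacts: dict[str, ContactTrend] = {}
    for contact, ms in by_contact.items():
        months = np.array([m.month for m in ms], dtype=float)
        z = np.array([m.impedance_ohm for m in ms], dtype=float)
        contacts[contact] = _contact_trend(
            contact, months, z, usage.get(contact, "sense_only"))

    stim_levels = [t.long_term_level_ohm for t in contacts.values()
                   if t.usage == "stimulated" and t.long_term_level_ohm]
    sense_levels = [t.long_term_level_ohm for t in contacts.values()
                    if t.usage == "sense_only" and t.long_term_level_ohm]
    ratio = None
    if stim_levels and sense_levels:
        ratio = float(np.mean(sense_levels) / np.mean(stim_levels))
    return TrendSummary(contacts=contacts, sense_stim_ratio=ratio)
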