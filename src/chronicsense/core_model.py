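"""Domain types shared by every analysis stage.

The model is deliberately small: lead geometries (which contacts exist and
where they sit), bipolar sense pairs, multichannel recordings in microvolts,
and stimulation settings/events.  Time is always seconds from session start,
sample indices are 0-based, and epoch windows are half-open ``[start, end)``.

Channel labels follow the ``"LEAD_Ex-Ey"`` dialect, e.g. ``"HC_E0-E3"`` or
``"HC_L_E1a-E2a"``.  Lead identifiers come from
``{"AN", "HC", "FX_L", "FX_R", "HC_L", "HC_R", "AN_L", "AN_R"}``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "LEAD_IDS",
    "LeadGeometry",
    "BipolarPair",
    "Channel",
    "Recording",
    "StimSetting",
    "StimEvent",
    "build_lead",
]

#: Lead identifiers accepted in channel labels.
LEAD_IDS = ("AN", "HC", "FX_L", "FX_R", "HC_L", "HC_R", "AN_L", "AN_R")

_CONTACT_RE = re.compile(r"^E[0-3][abc]?$")
_LABEL_RE = re.compile(
    r"^(?P<lead>" + "|".join(LEAD_IDS) + r")_(?P<a>E[0-3][abc]?)-(?P<b>E[0-3][abc]?|C)$"
)

RING = "ring"


class UnsupportedLeadError(ValueError):
    """Raised when a lead code is not one of the supported geometries."""


@dataclass(frozen=True)
class LeadGeometry:
    """Contact layout of a DBS lead.

    Parameters
    ----------
    lead_code
        Commercial-style code, e.g. ``"3389"`` or ``"1-3-3-1"``.
    contacts
        Ordered contact names, most distal first.
    levels
        Contact name -> axial level index (0 = most distal).
    segment_angle
        Contact name -> angular sector index (0, 1, 2) or ``"ring"``.
    """

    lead_code: str
    contacts: tuple[str, ...]
    levels: dict[str, int]
    segment_angle: dict[str, int | str]

    def __post_init__(self) -> None:
        if len(set(self.contacts)) != len(self.contacts):
            raise ValueError("duplicate contact names")
        for c in self.contacts:
            if not _CONTACT_RE.match(c):
                raise ValueError(f"malformed contact name {c!r}")
            if c not in self.levels or c not in self.segment_angle:
                raise ValueError(f"contact {c!r} missing level or angle")
        lv = sorted(set(self.levels.values()))
        if lv != list(range(len(lv))):
            raise ValueError("level indices must be contiguous from 0")

    @property
    def is_directional(self) -> bool:
        return any(a != RING for a in self.segment_angle.values())

    @property
    def segmented_contacts(self) -> tuple[str, ...]:
        """Contacts sitting on an angular segment (not full rings)."""
        return tuple(c for c in self.contacts if self.segment_angle[c] != RING)

    def to_dict(self) -> dict:
        return {
            "lead_code": self.lead_code,
            "contacts": list(self.contacts),
            "levels": dict(self.levels),
            "segment_angle": dict(self.segment_angle),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LeadGeometry":
        return cls(
            lead_code=d["lead_code"],
            contacts=tuple(d["contacts"]),
            levels={k: int(v) for k, v in d["levels"].items()},
            segment_angle={
                k: (v if v == RING else int(v)) for k, v in d["segment_angle"].items()
            },
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "LeadGeometry":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class BipolarPair:
    """A differential sense pair between two contacts of one lead."""

    anode_contact: str
    cathode_contact: str

    def __post_init__(self) -> None:
        if self.anode_contact == self.cathode_contact:
            raise ValueError("bipolar pair contacts must differ")

    @property
    def label(self) -> str:
        return f"{self.anode_contact}-{self.cathode_contact}"

    @property
    def contacts(self) -> frozenset[str]:
        return frozenset((self.anode_contact, self.cathode_contact))

    def on_lead(self, lead: LeadGeometry) -> bool:
        return self.contacts <= set(lead.contacts)


@dataclass
class Channel:
    """One recorded channel: a bipolar pair on a named lead."""

    lead_id: str
    pair: BipolarPair
    valid: bool = True

    def __post_init__(self) -> None:
        if self.lead_id not in LEAD_IDS:
            raise ValueError(f"unknown lead id {self.lead_id!r}")

    @property
    def label(self) -> str:
        return f"{self.lead_id}_{self.pair.label}"


def parse_channel_label(label: str) -> Channel:
    """Parse a ``"LEAD_Ex-Ey"`` label into a :class:`Channel`.

    Raises ``ValueError`` naming the label if it does not match the dialect.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"channel label {label!r} does not match 'LEAD_Ex-Ey' dialect")
    if m.group("b") == "C":
        raise ValueError(f"channel label {label!r}: sense pairs cannot reference case")
    return Channel(m.group("lead"), BipolarPair(m.group("a"), m.group("b")))


@dataclass
class StimSetting:
    """Stimulation parameters for one protocol block.

    ``amplitude_mode`` is carried explicitly ("V" or "mA"); the pipeline
    never converts between voltage and current modes.  An amplitude of 0 is
    allowed and means sham (no pulses delivered).
    """

    cathode_contact: str
    anode: str  # contact name or "case"
    amplitude: float
    amplitude_mode: str  # "V" or "mA"
    rate_hz: float
    pulse_width_us: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_mode not in ("V", "mA"):
            raise ValueError("amplitude_mode must be 'V' or 'mA'")
        if self.rate_hz <= 0 or self.duration_s <= 0 or self.pulse_width_us <= 0:
            raise ValueError("rate, pulse width and duration must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimSetting":
        return cls(**d)


@dataclass
class StimEvent:
    """A stimulation span within a recording, in seconds from start."""

    setting: StimSetting
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset_s < self.offset_s:
            raise ValueError("require 0 <= onset < offset")

    def to_dict(self) -> dict:
        return {
            "setting": self.setting.to_dict(),
            "onset_s": self.onset_s,
            "offset_s": self.offset_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimEvent":
        return cls(StimSetting.from_dict(d["setting"]), d["onset_s"], d["offset_s"])


@dataclass
class Recording:
    """Multichannel microvolt time series plus acquisition metadata.

    ``samples`` is a ``(n_channels, n_samples)`` float array in microvolts.
    All channels share ``fs`` and length.  ``events`` carries the
    stimulation log when one exists.
    """

    fs: float
    channels: list[Channel]
    samples: np.ndarray
    t0: str = "1970-01-01T00:00:00"
    hp_cutoff: float = 0.5
    lp_cutoff: float = 100.0
    condition: str = "sling"  # or "free_roaming"
    events: list[StimEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError("samples must be (n_channels, n_samples)")
        if not 200 <= self.fs <= 800:
            raise ValueError("fs must lie in [200, 800] Hz")
        if not self.hp_cutoff < self.lp_cutoff:
            raise ValueError("hp_cutoff must be below lp_cutoff")
        if self.condition not in ("sling", "free_roaming"):
            raise ValueError("condition must be 'sling' or 'free_roaming'")
        for ev in self.events:
            if ev.offset_s > self.duration_s + 1e-9:
                raise ValueError("stim event extends past end of recording")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.labels}") from None

    def get(self, label: str) -> np.ndarray:
        """Signal of one channel by ``"LEAD_Ex-Ey"`` label."""
        return self.samples[self.channel_index(label)]


# ---------------------------------------------------------------------------
# Lead geometry construction

_SUPPORTED_RING_CODES = ("3387", "3389")
_DIRECTIONAL_CODE = "1-3-3-1"


def build_lead(lead_code: str) -> LeadGeometry:
    """Build the geometry for a supported lead code.

    Supported codes: ``"3387"`` and ``"3389"`` (4 ring contacts E0..E3) and
    ``"1-3-3-1"`` (8 contacts: distal ring E0, two levels of three angular
    segments E1a..E1c / E2a..E2c, proximal ring E3).

    Raises
    ------
    UnsupportedLeadError
        For any other code.
    """
    if lead_code in _SUPPORTED_RING_CODES:
        contacts = ("E0", "E1", "E2", "E3")
        return LeadGeometry(
            lead_code=lead_code,
            contacts=contacts,
            levels={c: i for i, c in enumerate(contacts)},
            segment_angle={c: RING for c in contacts},
        )
    if lead_code == _DIRECTIONAL_CODE:
        contacts = ("E0", "E1a", "E1b", "E1c", "E2a", "E2b", "E2c", "E3")
        levels = {"E0": 0, "E1a": 1, "E1b": 1, "E1c": 1,
                  "E2a": 2, "E2b": 2, "E2c": 2, "E3": 3}
        angle: dict[str, int | str] = {"E0": RING, "E3": RING}
        for lvl in ("E1", "E2"):
            for i, s in enumerate("abc"):
                angle[lvl + s] = i
        return LeadGeometry(_DIRECTIONAL_CODE, contacts, levels, angle)
    raise UnsupportedLeadError(f"unsupported lead code {lead_code!r}")
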