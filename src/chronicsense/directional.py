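"""Directional-lead analyses: montage enumeration, radial spectra, segment
power ranking over sessions, post-stimulation suppression profiling, and
rank concordance.

Per-segment power attribution: the power of a segmented contact is the mean
band power over all montage pairs containing it (each segment is covered by
exactly four of the fifteen pairs).  Ranks are descending (1 = highest
power); ties break by contact name order and are flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_model import BipolarPair, LeadGeometry, Recording, StimEvent
from .spectral import SpectralEstimate, band_power, power_spectral_density

__all__ = [
    "SegmentRanking",
    "SuppressionProfile",
    "enumerate_montage",
    "montage_groups",
    "radial_spectra",
    "rank_segments",
    "suppression_response",
    "rank_concordance",
]

DEFAULT_BAND = (3.0, 8.0)
BASELINE_S = 20.0
SUBWINDOW_S = 2.0


@dataclass
class SegmentRanking:
    """Band power per segmented contact and the resulting rank order."""

    session_id: str
    band: tuple[float, float]
    powers: dict[str, float]
    ranks: dict[str, int] = field(default_factory=dict)
    tied: bool = False

    def __post_init__(self) -> None:
        if not self.ranks:
            ordered = sorted(self.powers, key=lambda c: (-self.powers[c], c))
            self.ranks = {c: i + 1 for i, c in enumerate(ordered)}
            vals = sorted(self.powers.values())
            self.tied = any(a == b for a, b in zip(vals, vals[1:]))
        if sorted(self.ranks.values()) != list(range(1, len(self.powers) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    @property
    def top_contact(self) -> str:
        return min(self.ranks, key=self.ranks.get)


@dataclass
class SuppressionProfile:
    """Baseline-normalized per-minute LFP power after one stimulation."""

    stimulated_contact: str
    baseline_power: float
    minute_power: list[float]
    dispersion: list[float]

    def __post_init__(self) -> None:
        if self.baseline_power <= 0:
            raise ValueError("baseline power must be > 0")
        if len(self.minute_power) > 10:
            raise ValueError("at most 10 post-stimulation minutes are profiled")

    @property
    def normalized(self) -> list[float]:
        return [p / self.baseline_power for p in self.minute_power]

    @property
    def depth(self) -> float:
        """Deepest normalized suppression (minimum over minutes)."""
        return min(self.normalized)


def enumerate_montage(lead: LeadGeometry) -> list[BipolarPair]:
    """The sense montage for a lead.

    For 1-3-3-1 directional leads: the 15 pairs formed by distal ring to
    each lower segment (3), within-level angular pairs (6), corresponding
    segments across levels (3), and each upper segment to the proximal ring
    (3).  For 4-contact leads: all 6 unordered pairs.
    """
    if lead.is_directional:
        pairs = [BipolarPair("E0", c) for c in ("E1a", "E1b", "E1c")]
        for lvl in ("E1", "E2"):
            for a, b in itertools.combinations("abc", 2):
                pairs.append(BipolarPair(lvl + a, lvl + b))
        pairs += [BipolarPair("E1" + s, "E2" + s) for s in "abc"]
        pairs += [BipolarPair("E2" + s, "E3") for s in "abc"]
    elif len(lead.contacts) == 4:
        pairs = [BipolarPair(a, b) for a, b in itertools.combinations(lead.contacts, 2)]
    else:
        raise ValueError(f"unsupported lead geometry {lead.lead_code!r}")
    for p in pairs:
        assert p.on_lead(lead)
    return pairs


def montage_groups(lead: LeadGeometry, n_groups: int = 3,
                   group_s: float = 40.0) -> tuple[list[list[BipolarPair]], float]:
    """Partition the montage into recording groups; returns (groups, total s)."""
    pairs = enumerate_montage(lead)
    if len(pairs) % n_groups:
        raise ValueError("montage does not split evenly")
    size = len(pairs) // n_groups
    groups = [pairs[i * size:(i + 1) * size] for i in range(n_groups)]
    return groups, n_groups * group_s


def radial_spectra(
    rec: Recording, lead_id: str, lead: LeadGeometry,
    segment_s: float = 4.0, overlap: float = 0.5,
) -> dict[str, SpectralEstimate]:
    """One PSD per radial direction from its corresponding-segment pair.

    Directions whose pair channel is absent or flagged invalid (broken
    contact) are omitted; if all three are missing a ``KeyError`` names the
    first missing pair.
    """
    if not lead.is_directional:
        raise ValueError("radial spectra require a directional lead")
    out: dict[str, SpectralEstimate] = {}
    missing = []
    for s in "abc":
        label = f"{lead_id}_E1{s}-E2{s}"
        try:
            i = rec.channel_index(label)
        except KeyError:
            missing.append(label)
            continue
        if not rec.channels[i].valid:
            continue
        out[s] = power_spectral_density(rec, label, segment_s, overlap)
    if not out:
        raise KeyError(f"no usable radial pairs; first missing: {missing[0]}")
    return out


def rank_segments(
    recs: list[Recording], lead_id: str, lead: LeadGeometry,
    band: tuple[float, float] = DEFAULT_BAND,
    segment_s: float = 4.0, overlap: float = 0.5,
) -> list[SegmentRanking]:
    """Per-session ranking of segmented contacts by attributed band power."""
    montage = enumerate_montage(lead)
    rankings = []
    for k, rec in enumerate(recs):
        powers: dict[str, float] = {}
        for contact in lead.segmented_contacts:
            cover = [p for p in montage if contact in p.contacts]
            vals = []
            for p in cover:
                label = f"{lead_id}_{p.label}"
                try:
                    i = rec.channel_index(label)
                except KeyError:
                    continue
                if not rec.channels[i].valid:
                    continue
                est = power_spectral_density(rec, label, segment_s, overlap)
                vals.append(band_power(est, band))
            if not vals:
                raise ValueError(f"segment {contact} has no covering pairs in session {k}")
            powers[contact] = float(np.mean(vals))
        rankings.append(SegmentRanking(session_id=f"session{k}", band=band, powers=powers))
    return rankings


def _subwindow_powers(x: np.ndarray, fs: float, band: tuple[float, float],
                      sub_s: float) -> np.ndarray:
    n_sub = int(round(sub_s * fs))
    n_win = x.size // n_sub
    out = np.empty(n_win)
    for i in range(n_win):
        seg = x[i * n_sub:(i + 1) * n_sub]
        freqs, pxx = sps.periodogram(seg, fs=fs, window="hann", detrend="constant")
        sel = (freqs >= band[0]) & (freqs <= band[1])
        out[i] = np.trapezoid(pxx[sel], freqs[sel])
    return out


def suppression_response(
    rec: Recording,
    event: StimEvent,
    band: tuple[float, float] = DEFAULT_BAND,
    channel: str | None = None,
    max_minutes: int = 10,
    guard_s: float = 0.5,
) -> SuppressionProfile:
    """Per-minute post-stimulation band power, normalized to baseline.

    Baseline is the median band power over 2 s sub-windows of the 20 s
    pre-stimulus window; each complete post minute is the median over its
    own 2 s sub-windows, with dispersion the s.d. over those sub-windows.
    Requires a full 20 s stimulation-free baseline and at least one
    complete post minute.
    """
    if channel is None:
        channel = rec.labels[0]
    x = rec.get(channel)
    fs = rec.fs
    i_on = int(round(event.onset_s * fs))
    i_off = int(round((event.offset_s + guard_s) * fs))
    base_n = int(round(BASELINE_S * fs))
    if i_on < base_n:
        raise ValueError(f"need >= {BASELINE_S:g}s pre-stimulus baseline")
    for other in rec.events:
        if other is event:
            continue
        if other.offset_s > event.onset_s - BASELINE_S and other.onset_s < event.onset_s:
            raise ValueError("baseline window contaminated by another stimulation")

    base = _subwindow_powers(x[i_on - base_n:i_on], fs, band, SUBWINDOW_S)
    baseline = float(np.median(base))

    minute_n = int(round(60.0 * fs))
    post = x[i_off:]
    # truncate at the next stimulation onset if any
    nxt = [int(round(e.onset_s * fs)) - i_off for e in rec.events
           if e.onset_s * fs > i_off]
    if nxt:
        post = post[: max(min(nxt), 0)]
    n_minutes = min(post.size // minute_n, max_minutes)
    if n_minutes < 1:
        raise ValueError("need at least one complete post-stimulation minute")
    minute_power, dispersion = [], []
    for m in range(n_minutes):
        sub = _subwindow_powers(post[m * minute_n:(m + 1) * minute_n], fs, band,
                                SUBWINDOW_S)
        minute_power.append(float(np.median(sub)))
        dispersion.append(float(np.std(sub)))
    return SuppressionProfile(
        stimulated_contact=event.setting.cathode_contact,
        baseline_power=baseline,
        minute_power=minute_power,
        dispersion=dispersion,
    )


def rank_concordance(ranks_a: dict[str, int], ranks_b: dict[str, int]) -> tuple[float, float]:
    """(R^2, signed r) between two rankings of the same contacts.

    R^2 is the squared Pearson correlation of the rank vectors (equal to
    squared Spearman when there are no ties); because R^2 is direction
    blind, the signed correlation is returned alongside.  Requires
    identical contact sets of size >= 3.
    """
    if set(ranks_a) != set(ranks_b):
        raise ValueError("rankings cover different contact sets")
    if len(ranks_a) < 3:
        raise ValueError("need at least 3 contacts")
    contacts = sorted(ranks_a)
    a = np.array([ranks_a[c] for c in contacts], dtype=float)
    b = np.array([ranks_b[c] for c in contacts], dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r, r
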