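"""Seeded synthetic cohort generator.

Produces multichannel recordings with the statistical structure the analysis
stages assume: theta-dominant hippocampal LFP with a 4-5 Hz spectral peak,
sharp-wave "output" states that propagate to the thalamic lead with a
30-40 ms lag, sleep-state K-complexes appearing near-simultaneously as small
far-field events at the hippocampal site, stimulus-artifact + evoked-potential
trains, amplitude-dependent post-burst suppression and after-discharge, gain
asymmetry across directional segments, and a longitudinal impedance model
with scheduled lead breakages.

Everything is driven by ``numpy.random.Generator`` seeded from
:class:`GeneratorParams.seed`; identical parameters yield bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Optional

import numpy as np

from .core_model import (
    BipolarPair,
    Channel,
    LeadGeometry,
    Recording,
    StimEvent,
    StimSetting,
    build_lead,
)
from .directional import enumerate_montage

__all__ = [
    "GeneratorParams",
    "generate_lfp",
    "generate_stim_session",
    "generate_cohort_timeline",
    "CohortSession",
]

STATES = ("theta", "sharp_wave", "sleep")

_DEF_GAINS = {c: 1.0 for c in ("E1a", "E1b", "E1c", "E2a", "E2b", "E2c")}


@dataclass
class GeneratorParams:
    """All knobs of the synthetic signal model.

    Amplitudes are microvolts, times seconds unless suffixed.  Invariants:
    ``theta_f0`` in [4, 5] Hz, ``net_lag_ms`` in [30, 40], suppression
    threshold strictly below after-discharge threshold, all segment gains
    positive.
    """

    seed: int = 0
    theta_f0: float = 4.5
    theta_amp: float = 25.0
    noise_sd: float = 8.0
    one_over_f_exponent: float = 1.0
    state_dwell: dict = field(
        default_factory=lambda: {"theta": 20.0, "sharp_wave": 20.0, "sleep": 20.0}
    )
    sw_rate: float = 0.5          # sharp-wave events per second within state
    sw_amp: float = 150.0
    kc_rate: float = 0.15         # K-complexes per second within sleep state
    kc_amp: float = 200.0
    ep_latency_ms: float = 37.0
    ep_amp_max: float = 40.0
    ep_threshold_v: float = 2.0   # stim amplitude of half-max EP
    net_lag_ms: float = 36.0
    propagated_ratio: float = 0.6
    farfield_ratio: float = 0.15
    theta_supp_v: float = 0.6     # inhibitory (suppression) threshold
    theta_ad_v: float = 1.0       # after-discharge threshold
    supp_power_floor: float = 0.25
    ad_duration_s: float = 4.0
    artifact_gain: float = 10.0   # artifact amplitude = gain * theta_amp
    segment_gains: dict = field(default_factory=lambda: dict(_DEF_GAINS))
    impedance_base_ohm: float = 1200.0
    breakage_schedule: list = field(default_factory=list)  # [(contact, month)]

    def __post_init__(self) -> None:
        if not 4.0 <= self.theta_f0 <= 5.0:
            raise ValueError("theta_f0 must lie in [4, 5] Hz")
        if not 30.0 <= self.net_lag_ms <= 40.0:
            raise ValueError("net_lag_ms must lie in [30, 40] ms")
        if not self.theta_supp_v < self.theta_ad_v:
            raise ValueError("suppression threshold must be below after-discharge")
        if any(g <= 0 for g in self.segment_gains.values()):
            raise ValueError("segment gains must be > 0")
        if not 0 < self.farfield_ratio < 1:
            raise ValueError("farfield_ratio must lie in (0, 1)")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Deterministic per-purpose generator derived from ``seed``."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=spawn_key))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(**d)


# ---------------------------------------------------------------------------
# signal primitives


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      sd: float, alpha: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^alpha, RMS-normalized to sd.

    Shaping happens in the frequency domain; power below 0.5 Hz is held flat
    to mimic the hardware high-pass and keep the series stationary.
    """
    white = rng.standard_normal(n)
    if alpha == 0 or n < 8:
        return sd * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    f_ref = np.maximum(freqs, 0.5)
    spec *= f_ref ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n=n)
    rms = float(np.sqrt(np.mean(x**2)))
    return sd * x / rms if rms > 0 else x


def _biexp_kernel(fs: float, rise_ms: float = 5.0, decay_ms: float = 40.0) -> np.ndarray:
    """Unit-peak biexponential transient (sharp-wave shape)."""
    t = np.arange(0.0, 6.0 * decay_ms / 1000.0, 1.0 / fs)
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    k = (1 - np.exp(-t / tr)) * np.exp(-t / td)
    return k / k.max()


def _kcomplex_kernel(fs: float, width_s: float = 0.7) -> np.ndarray:
    """Unit-peak biphasic slow transient (~one windowed sine cycle)."""
    n = max(int(round(width_s * fs)), 8)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    k = np.sin(2 * np.pi * t) * np.hanning(n)
    return k / np.abs(k).max()


def _ep_kernel(fs: float, latency_ms: float) -> np.ndarray:
    """Unit-amplitude EP template: small early trough, Gaussian main peak.

    The main (positive) peak sits exactly at ``latency_ms`` after the
    trigger; total span is latency + 4 sigma.
    """
    sigma_ms = 8.0
    t_ms = np.arange(0.0, latency_ms + 4 * sigma_ms, 1000.0 / fs)
    main = np.exp(-0.5 * ((t_ms - latency_ms) / sigma_ms) ** 2)
    trough = -0.3 * np.exp(-0.5 * ((t_ms - latency_ms / 2.0) / (sigma_ms / 1.5)) ** 2)
    return main + trough


def _add_at(signal: np.ndarray, kernel: np.ndarray, idx: int, amp: float) -> None:
    """Add ``amp * kernel`` into ``signal`` starting at sample ``idx`` (clipped)."""
    if idx >= signal.size:
        return
    start = max(idx, 0)
    k0 = start - idx
    stop = min(idx + kernel.size, signal.size)
    if stop > start:
        signal[start:stop] += amp * kernel[k0:k0 + (stop - start)]


def _state_sequence(rng: np.random.Generator, duration: float,
                    dwell: dict) -> list[tuple[str, float, float]]:
    """Two/three-state alternating dwell process covering [0, duration).

    Dwell times are exponential with the per-state means; a state with
    infinite mean dwell captures the whole session (and is used as the
    initial state).
    """
    states = [s for s in STATES if dwell.get(s, 0) > 0]
    if not states:
        raise ValueError("at least one state must have positive dwell")
    inf_states = [s for s in states if math.isinf(dwell[s])]
    if inf_states:
        return [(inf_states[0], 0.0, duration)]
    seq = []
    t = 0.0
    state = states[int(rng.integers(len(states)))]
    while t < duration:
        d = float(rng.exponential(dwell[state]))
        d = max(d, 1.0 / 4.0)  # avoid zero-length segments
        seq.append((state, t, min(t + d, duration)))
        t += d
        others = [s for s in states if s != state]
        state = others[int(rng.integers(len(others)))] if others else state
    return seq


def _theta_component(rng: np.random.Generator, t: np.ndarray,
                     params: GeneratorParams) -> np.ndarray:
    """Amplitude-modulated theta oscillation (modulation depth 0.3)."""
    phi0 = rng.uniform(0, 2 * np.pi)
    phi1 = rng.uniform(0, 2 * np.pi)
    env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.8 * t + phi1)
    return params.theta_amp * env * np.sin(2 * np.pi * params.theta_f0 * t + phi0)


def _mask_from_windows(t: np.ndarray, windows: Iterable[tuple[float, float]],
                       fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Soft 0/1 mask active inside the windows, cosine-ramped at edges."""
    mask = np.zeros_like(t)
    for a, b in windows:
        mask[(t >= a) & (t < b)] = 1.0
    if ramp_s > 0:
        n = max(int(ramp_s * fs), 1)
        kernel = np.hanning(2 * n + 1)
        kernel /= kernel.sum()
        mask = np.convolve(mask, kernel, mode="same")
    return np.clip(mask, 0.0, 1.0)


# ---------------------------------------------------------------------------
# lead/channel plumbing


def _default_channels(lead_id: str, lead: LeadGeometry,
                      full_montage: bool = False) -> list[Channel]:
    """Sense channels for a lead: wideband E0-E3 for ring leads (all 6
    pairs when ``full_montage``), the full 15-pair montage for directional
    leads."""
    if lead.is_directional:
        return [Channel(lead_id, p) for p in enumerate_montage(lead)]
    if full_montage:
        return [Channel(lead_id, p) for p in enumerate_montage(lead)]
    return [Channel(lead_id, BipolarPair("E0", "E3"))]


def _pair_gain(pair: BipolarPair, params: GeneratorParams) -> float:
    """Channel gain = mean of its contacts' segment gains (rings gain 1)."""
    g = [params.segment_gains.get(c, 1.0) for c in (pair.anode_contact, pair.cathode_contact)]
    return float(np.mean(g))


def _lead_region(lead_id: str) -> str:
    return lead_id.split("_")[0]  # "HC_L" -> "HC"


# ---------------------------------------------------------------------------
# public generators


def generate_lfp(
    params: GeneratorParams,
    duration_s: float,
    fs: float = 250.0,
    leads: Optional[dict[str, LeadGeometry]] = None,
    condition: str = "sling",
    full_montage: bool = False,
) -> Recording:
    """Generate a spontaneous multichannel LFP recording.

    ``leads`` maps lead id -> geometry; default is a hippocampal and a
    thalamic 4-contact lead (``{"HC": 3387, "AN": 3389}``).  Hippocampal
    channels alternate between a theta state (narrowband oscillation over a
    1/f background) and a sharp-wave state (biexponential transients at
    ``sw_rate``); thalamic channels carry the background plus coupled
    activity: each hippocampal sharp wave reappears ``net_lag_ms`` later at
    ``propagated_ratio`` amplitude, and sleep-state K-complexes are thalamic
    events mirrored at zero lag on the hippocampal lead at
    ``farfield_ratio``.  Directional channels are scaled by the mean
    segment gain of their contacts.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and fs must be > 0")
    if leads is None:
        leads = {"HC": build_lead("3387"), "AN": build_lead("3389")}

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = params.rng(0)

    seq = _state_sequence(rng, duration_s, params.state_dwell)
    theta_win = [(a, b) for s, a, b in seq if s == "theta"]
    sw_win = [(a, b) for s, a, b in seq if s == "sharp_wave"]
    sleep_win = [(a, b) for s, a, b in seq if s == "sleep"]

    theta_mask = _mask_from_windows(t, theta_win, fs)
    hc_base = _theta_component(rng, t, params) * theta_mask

    # sharp waves on HC, propagated copies on AN
    sw_kernel = _biexp_kernel(fs)
    hc_sw = np.zeros(n)
    an_sw = np.zeros(n)
    lag_n = int(round(params.net_lag_ms / 1000.0 * fs))
    for a, b in sw_win:
        n_ev = rng.poisson(params.sw_rate * (b - a))
        times = np.sort(rng.uniform(a, b, n_ev))
        amps = params.sw_amp * rng.lognormal(mean=0.0, sigma=0.3, size=n_ev)
        for tt, amp in zip(times, amps):
            idx = int(round(tt * fs))
            _add_at(hc_sw, sw_kernel, idx, amp)
            _add_at(an_sw, sw_kernel, idx + lag_n, params.propagated_ratio * amp)

    # K-complexes on AN, zero-lag far-field copies on HC
    kc_kernel = _kcomplex_kernel(fs)
    an_kc = np.zeros(n)
    for a, b in sleep_win:
        n_ev = rng.poisson(params.kc_rate * (b - a))
        times = np.sort(rng.uniform(a, b, n_ev))
        amps = params.kc_amp * rng.lognormal(mean=0.0, sigma=0.2, size=n_ev)
        for tt, amp in zip(times, amps):
            _add_at(an_kc, kc_kernel, int(round(tt * fs)), amp)
    hc_kc = params.farfield_ratio * an_kc

    region_base = {
        "HC": hc_base + hc_sw + hc_kc,
        "AN": 0.3 * params.theta_amp * theta_mask
        * np.sin(2 * np.pi * params.theta_f0 * t + rng.uniform(0, 2 * np.pi))
        + an_sw + an_kc,
    }
    # fornix leads carry theta-dominant activity like HC, without sharp waves
    region_base["FX"] = hc_base * 0.8

    channels: list[Channel] = []
    rows: list[np.ndarray] = []
    noise_rng = params.rng(1)
    for lead_id, lead in leads.items():
        base = region_base.get(_lead_region(lead_id), hc_base)
        for ch in _default_channels(lead_id, lead, full_montage):
            g = _pair_gain(ch.pair, params)
            noise = _one_over_f_noise(noise_rng, n, fs, params.noise_sd,
                                      params.one_over_f_exponent)
            rows.append(g * base + noise)
            channels.append(ch)

    return Recording(fs=fs, channels=channels, samples=np.vstack(rows),
                     condition=condition)


def _insert_pulse_train(sig: np.ndarray, fs: float, onset_s: float,
                        duration_s: float, rate_hz: float, amp: float) -> list[int]:
    """Insert 1-sample biphasic artifacts at each pulse; return pulse indices."""
    n_pulses = int(round(rate_hz * duration_s))
    idxs = []
    for k in range(n_pulses):
        idx = int(round((onset_s + k / rate_hz) * fs))
        if idx + 1 < sig.size:
            sig[idx] += amp
            sig[idx + 1] -= amp
            idxs.append(idx)
    return idxs


def _ad_kernel(rng: np.random.Generator, fs: float, duration_s: float) -> np.ndarray:
    """After-discharge: large 2-8 Hz transient with a tapered envelope."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f_sweep = np.linspace(6.0, 2.5, n)  # stays inside 2-8 Hz
    phase = 2 * np.pi * np.cumsum(f_sweep) / fs
    env = np.sin(np.pi * np.clip(t / duration_s, 0, 1)) ** 0.5
    return env * np.sin(phase + rng.uniform(0, 2 * np.pi))


def generate_stim_session(
    params: GeneratorParams,
    setting: StimSetting,
    protocol: str,
    fs: float = 250.0,
    amplitudes: Optional[list[float]] = None,
    post_s: float = 60.0,
    leads: Optional[dict[str, LeadGeometry]] = None,
) -> tuple[Recording, list[StimEvent]]:
    """Generate a stimulation session for one of the three protocols.

    ``ep_train``
        A pulse train (``setting.rate_hz`` x ``setting.duration_s``) with a
        2 s lead-in: every pulse inserts a 1-sample biphasic artifact
        (amplitude ``artifact_gain * theta_amp``) and an EP template on the
        hippocampal channel whose main peak falls ``ep_latency_ms`` after
        the pulse; EP amplitude is sigmoidal in the stimulation voltage with
        half-max at ``ep_threshold_v``.  Amplitude 0 delivers nothing.
    ``burst_ramp``
        One 10 s ramped burst per entry of ``amplitudes`` (default
        ``setting.amplitude`` only), 20 s apart.  Bursts at or above the
        suppression threshold attenuate post-burst LFP power to
        ``supp_power_floor`` for a span growing with amplitude; at or above
        the after-discharge threshold a large 2-8 Hz transient
        (``ad_duration_s``) follows the burst.
    ``directional_sweep``
        Monopolar stimulation of every segmented contact in seeded random
        order: 20 s baseline, 10 s stimulation, ``post_s`` follow-up per
        contact.  Post-stimulation LFP power on the lead is suppressed to a
        floor of ``1 - 0.75 * gain(contact)``, so higher-gain contacts
        produce deeper suppression.

    Returns the recording plus the stimulation event list (also attached to
    ``recording.events``).
    """
    if protocol == "ep_train":
        return _ep_train_session(params, setting, fs, leads)
    if protocol == "burst_ramp":
        amps = list(amplitudes) if amplitudes is not None else [setting.amplitude]
        return _burst_ramp_session(params, setting, amps, fs, leads)
    if protocol == "directional_sweep":
        return _directional_sweep_session(params, setting, fs, post_s, leads)
    raise ValueError(f"unknown protocol {protocol!r}")


def _ep_train_session(params, setting, fs, leads):
    lead_in = 2.0
    tail = 1.0
    duration = lead_in + setting.duration_s + tail
    # EP sessions are awake/sling recordings: theta background, no sharp
    # waves (whose fast rise would fire the artifact detector)
    p = replace(params, state_dwell={"theta": math.inf})
    rec = generate_lfp(p, duration, fs=fs, leads=leads)

    events: list[StimEvent] = []
    if setting.amplitude > 0:
        art_amp = params.artifact_gain * params.theta_amp
        ep_amp = params.ep_amp_max / (
            1.0 + math.exp(-(setting.amplitude - params.ep_threshold_v) / 0.8)
        )
        ep_kernel = _ep_kernel(fs, params.ep_latency_ms)
        hc_rows = [i for i, ch in enumerate(rec.channels)
                   if _lead_region(ch.lead_id) == "HC"]
        n_pulses = int(round(setting.rate_hz * setting.duration_s))
        for k in range(n_pulses):
            t_pulse = lead_in + k / setting.rate_hz
            idx = int(round(t_pulse * fs))
            for i in hc_rows:
                rec.samples[i, idx] += art_amp
                if idx + 1 < rec.n_samples:
                    rec.samples[i, idx + 1] -= art_amp
                _add_at(rec.samples[i], ep_kernel, idx, ep_amp)
            events.append(StimEvent(setting, t_pulse, t_pulse + 1.0 / fs))
    rec.events = events
    return rec, events


def _burst_ramp_session(params, setting, amplitudes, fs, leads):
    burst_s, gap_s = setting.duration_s, 20.0
    lead_in = 10.0
    duration = lead_in + len(amplitudes) * (burst_s + gap_s)
    # bursts ride on an always-on theta background so suppression is visible
    p = replace(params, state_dwell={"theta": math.inf})
    rec = generate_lfp(p, duration, fs=fs, leads=leads)
    rng = params.rng(2)

    ad_kernel_cache = _ad_kernel(rng, fs, params.ad_duration_s)
    envelope = np.ones(rec.n_samples)
    t = rec.times()
    events: list[StimEvent] = []
    art_amp = params.artifact_gain * params.theta_amp
    for j, amp in enumerate(amplitudes):
        onset = lead_in + j * (burst_s + gap_s)
        offset = onset + burst_s
        burst_setting = replace(setting, amplitude=float(amp))
        events.append(StimEvent(burst_setting, onset, offset))
        if amp <= 0:
            continue
        for i in range(rec.samples.shape[0]):
            _insert_pulse_train(rec.samples[i], fs, onset, burst_s,
                                setting.rate_hz, art_amp * min(amp, 2.0))
        if amp >= params.theta_supp_v:
            supp_dur = 6.0 + 4.0 * (amp - params.theta_supp_v)
            sel = (t >= offset) & (t < offset + supp_dur)
            envelope[sel] = np.minimum(envelope[sel],
                                       math.sqrt(params.supp_power_floor))
    rec.samples *= envelope  # power scaled by envelope^2
    for ev, amp in zip(events, amplitudes):
        if amp >= params.theta_ad_v:
            ad_amp = 8.0 * params.theta_amp
            idx = int(round((ev.offset_s + 0.3) * fs))
            for i in range(rec.samples.shape[0]):
                _add_at(rec.samples[i], ad_kernel_cache, idx, ad_amp)
    rec.events = events
    return rec, events


def _directional_sweep_session(params, setting, fs, post_s, leads):
    if leads is None:
        leads = {"HC": build_lead("1-3-3-1")}
    lead_id, lead = next(iter(leads.items()))
    if not lead.is_directional:
        raise ValueError("directional_sweep requires a directional lead")
    order_rng = params.rng(3)
    contacts = list(lead.segmented_contacts)
    order = [contacts[i] for i in order_rng.permutation(len(contacts))]

    base_s, stim_s = 20.0, setting.duration_s
    block_s = base_s + stim_s + post_s
    duration = block_s * len(order) + 5.0
    p = replace(params, state_dwell={"theta": math.inf})
    rec = generate_lfp(p, duration, fs=fs, leads=leads)

    t = rec.times()
    envelope = np.ones(rec.n_samples)
    hold_s = min(180.0, 0.6 * post_s)
    ramp_s = min(60.0, 0.2 * post_s)
    art_amp = params.artifact_gain * params.theta_amp
    events: list[StimEvent] = []
    for j, contact in enumerate(order):
        onset = j * block_s + base_s
        offset = onset + stim_s
        ev_setting = replace(setting, cathode_contact=contact, anode="case")
        events.append(StimEvent(ev_setting, onset, offset))
        if setting.amplitude <= 0:
            continue
        for i in range(rec.samples.shape[0]):
            _insert_pulse_train(rec.samples[i], fs, onset, stim_s,
                                setting.rate_hz, art_amp)
        gain = params.segment_gains.get(contact, 1.0)
        floor = float(np.clip(1.0 - 0.75 * gain, 0.05, 1.0))  # power floor
        seg = np.ones_like(t)
        rel = t - offset
        in_hold = (rel >= 0) & (rel < hold_s)
        in_ramp = (rel >= hold_s) & (rel < hold_s + ramp_s)
        seg[in_hold] = floor
        seg[in_ramp] = floor + (1.0 - floor) * (rel[in_ramp] - hold_s) / ramp_s
        envelope = np.minimum(envelope, np.sqrt(seg))
    rec.samples *= envelope
    rec.events = events
    return rec, events


# ---------------------------------------------------------------------------
# longitudinal cohort timeline


@dataclass
class CohortSession:
    """One monthly follow-up: metadata, recording, per-contact impedances."""

    month: int
    condition: str
    recording: Recording
    impedance_ohm: dict[str, float]        # (lead_id, contact) key "HC:E1"
    invalid_channels: list[str]


OPEN_CIRCUIT_OHM = 1.0e6
STABILIZATION_TAU_MONTHS = 1.5  # ~6 weeks


def _impedance_at(month: float, plateau: float, rng: np.random.Generator) -> float:
    start = 2.2 * plateau
    z = plateau + (start - plateau) * math.exp(-month / STABILIZATION_TAU_MONTHS)
    return z * rng.lognormal(mean=0.0, sigma=0.02)


def generate_cohort_timeline(
    params: GeneratorParams,
    months: int,
    leads: Optional[dict[str, LeadGeometry]] = None,
    stimulated_contacts: Optional[set[str]] = None,
    session_s: float = 30.0,
    fs: float = 250.0,
) -> list[CohortSession]:
    """Emit one session per month with signals and an impedance table.

    Impedances follow an exponential post-implant stabilization (~6 weeks)
    toward a contact-specific plateau with lognormal measurement noise;
    contacts in ``stimulated_contacts`` plateau 2.5x lower.  From a
    scheduled breakage month on, the broken contact reads open-circuit and
    every channel containing it is flagged invalid and replaced by flat
    amplifier noise.  The session schedule (months, conditions) is
    deterministic; only the signals depend on the seed.
    """
    if months < 1:
        raise ValueError("months must be >= 1")
    if leads is None:
        leads = {"HC": build_lead("3387"), "AN": build_lead("3389")}
    stimulated_contacts = stimulated_contacts or set()

    all_contacts = {(lid, c) for lid, lead in leads.items() for c in lead.contacts}
    breakages: dict[tuple[str, str], int] = {}
    for item in params.breakage_schedule:
        if len(item) == 3:
            lid, contact, month = item
        else:
            contact, month = item
            lid = next((l for l, lead in leads.items() if contact in lead.contacts), None)
        if (lid, contact) not in all_contacts:
            raise ValueError(f"breakage contact {contact!r} not on any lead")
        breakages[(lid, contact)] = int(month)

    imp_rng = params.rng(4)
    sessions: list[CohortSession] = []
    for month in range(1, months + 1):
        # per-month signal seed derived deterministically from the base seed
        rec = generate_lfp(replace(params, seed=params.seed * 10_000 + month),
                           session_s, fs=fs, leads=leads,
                           condition="sling" if month % 2 else "free_roaming",
                           full_montage=True)

        impedances: dict[str, float] = {}
        broken_now = {k for k, m in breakages.items() if month >= m}
        for lid, lead in leads.items():
            for c in lead.contacts:
                if (lid, c) in broken_now:
                    z = OPEN_CIRCUIT_OHM
                else:
                    plateau = params.impedance_base_ohm
                    if c in stimulated_contacts:
                        plateau /= 2.5
                    z = _impedance_at(month, plateau, imp_rng)
                impedances[f"{lid}:{c}"] = z

        invalid = []
        for i, ch in enumerate(rec.channels):
            if any(ch.lead_id == lid and c in ch.pair.contacts
                   for lid, c in broken_now):
                ch.valid = False
                rec.samples[i] = 2.0 * np.random.default_rng(
                    params.seed * 10_000 + month + 7919 + i
                ).standard_normal(rec.n_samples)
                invalid.append(ch.label)
        sessions.append(CohortSession(month, rec.condition, rec, impedances, invalid))
    return sessions
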