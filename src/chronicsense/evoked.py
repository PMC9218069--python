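"""Stimulus-artifact detection, epoch averaging, EP metrics, burst response.

Artifacts are found as robust threshold crossings of the differentiated
signal (|dx| > 8 MAD, 50 ms refractory).  Epochs default to -10..+100 ms
around the trigger with the 0-5 ms artifact span blanked by linear
interpolation before averaging.  Burst responses are labeled by comparing
band power in matched 5 s windows before and after each burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_model import Recording, StimEvent

__all__ = [
    "EvokedPotential",
    "BurstResponse",
    "detect_stim_artifacts",
    "average_epochs",
    "ep_metrics",
    "classify_burst_responses",
]

MAD_K = 8.0
REFRACTORY_S = 0.050
BLANK_MS = (0.0, 5.0)
DEFAULT_WINDOW_MS = (-10.0, 100.0)
R_SUPP = 0.7
R_AD = 3.0
AD_BAND = (2.0, 8.0)


@dataclass
class EvokedPotential:
    """Averaged stimulus-locked waveform with its main-peak metrics."""

    window_ms: tuple[float, float]
    waveform: np.ndarray
    fs: float
    n_epochs: int
    latency_ms: float = float("nan")
    amplitude_uv: float = float("nan")
    polarity: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")

    def times_ms(self) -> np.ndarray:
        n = self.waveform.size
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.fs


@dataclass
class BurstResponse:
    """Post/pre power outcome of one stimulus burst."""

    burst_amplitude: float
    label: str  # "none" | "suppression" | "after_discharge"
    post_pre_power_ratio: float

    def __post_init__(self) -> None:
        if self.post_pre_power_ratio <= 0:
            raise ValueError("power ratio must be > 0")
        if self.label not in ("none", "suppression", "after_discharge"):
            raise ValueError(f"unknown label {self.label!r}")


def detect_stim_artifacts(rec: Recording, channel: str,
                          k: float = MAD_K,
                          refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Trigger times (s) of stimulus artifacts on one channel.

    Threshold is ``k`` times the MAD of the first difference; crossings
    within ``refractory_s`` of the previous trigger are discarded (two
    pulses closer than the refractory period yield one trigger).  An empty
    array is returned for stimulation-free recordings.
    """
    x = rec.get(channel)
    dx = np.abs(np.diff(x))
    # MAD scaled to sigma-equivalent for the usual k*sigma interpretation
    mad = 1.4826 * float(np.median(np.abs(dx - np.median(dx))))
    thresh = k * max(mad, 1e-12)
    above = np.flatnonzero(dx > thresh)
    refrac_n = int(round(refractory_s * rec.fs))
    triggers = []
    last = -refrac_n - 1
    for i in above:
        if i - last > refrac_n:
            # dx[i] spans samples i -> i+1; the artifact sample is i+1
            triggers.append(i + 1)
            last = i
    return np.asarray(triggers, dtype=float) / rec.fs


def average_epochs(
    rec: Recording,
    channel: str,
    triggers: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    align_to_peak: bool = False,
    blank_ms: tuple[float, float] = BLANK_MS,
    max_shift_ms: float = 5.0,
) -> EvokedPotential:
    """Artifact-triggered epoch average with blanking and optional alignment.

    Epochs whose window is clipped by the recording bounds are dropped (and
    excluded from ``n_epochs``).  The 0-5 ms artifact span is replaced by
    linear interpolation per epoch.  With ``align_to_peak``, each epoch may
    be shifted by up to +-5 ms to maximize correlation with the plain
    average before the final mean is taken.
    """
    x = rec.get(channel)
    fs = rec.fs
    pre_n = int(round(-window_ms[0] / 1000.0 * fs))
    post_n = int(round(window_ms[1] / 1000.0 * fs))
    n_win = pre_n + post_n
    # snap the reported window to the sample grid so latencies are unbiased
    window_ms = (-pre_n * 1000.0 / fs, post_n * 1000.0 / fs)

    b0 = pre_n + int(round(blank_ms[0] / 1000.0 * fs))
    b1 = pre_n + int(round(blank_ms[1] / 1000.0 * fs))

    epochs = []
    for t in np.atleast_1d(triggers):
        i = int(round(t * fs))
        lo, hi = i - pre_n, i + post_n
        if lo < 0 or hi > x.size:
            continue
        ep = x[lo:hi].copy()
        if b1 > b0 and b1 < n_win and b0 >= 1:
            ep[b0:b1] = np.linspace(ep[b0 - 1], ep[b1], b1 - b0, endpoint=False)
        epochs.append(ep)
    if not epochs:
        raise ValueError("no usable epochs: every trigger window is clipped")
    E = np.vstack(epochs)

    avg = E.mean(axis=0)
    if align_to_peak and len(epochs) > 1:
        max_shift = int(round(max_shift_ms / 1000.0 * fs))
        shifted = np.empty_like(E)
        for r in range(E.shape[0]):
            best, best_score = 0, -np.inf
            for s in range(-max_shift, max_shift + 1):
                rolled = np.roll(E[r], s)
                score = float(np.dot(rolled, avg))
                if score > best_score:
                    best_score, best = score, s
            shifted[r] = np.roll(E[r], best)
        avg = shifted.mean(axis=0)

    ep = EvokedPotential(window_ms=window_ms, waveform=avg, fs=fs,
                         n_epochs=E.shape[0])
    lat, amp, pol = ep_metrics(ep)
    ep.latency_ms, ep.amplitude_uv, ep.polarity = lat, amp, pol
    return ep


def ep_metrics(
    ep: EvokedPotential,
    search_window_ms: tuple[float, float] = (8.0, 90.0),
) -> tuple[float, float, int]:
    """(latency ms, amplitude uV, polarity) of the main peak.

    The main peak is the extremum of largest absolute value inside the
    search window (which must exclude the blanked artifact span); latency is
    refined by quadratic interpolation around the peak sample so it is not
    limited to the sample grid.  Latency is invariant to gain scaling.
    """
    t = ep.times_ms()
    sel = (t >= search_window_ms[0]) & (t <= search_window_ms[1])
    if not np.any(sel):
        raise ValueError("search window contains no samples")
    idx_local = int(np.argmax(np.abs(ep.waveform[sel])))
    idx = np.flatnonzero(sel)[idx_local]
    y = ep.waveform
    lat = t[idx]
    # parabolic refinement on |peak| neighborhood
    if 0 < idx < y.size - 1:
        y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-12:
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                lat = lat + delta * 1000.0 / ep.fs
    amp = float(abs(y[idx]))
    pol = int(np.sign(y[idx])) or 1
    return float(lat), amp, pol


def _window_band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Hann-window periodogram power (uV^2) of one window over a band."""
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(pxx[sel], freqs[sel]))


def classify_burst_responses(
    rec: Recording,
    bursts: list[StimEvent],
    band: tuple[float, float] = (2.0, 30.0),
    channel: str | None = None,
    window_s: float = 5.0,
    guard_s: float = 0.4,
    r_supp: float = R_SUPP,
    r_ad: float = R_AD,
) -> tuple[list[BurstResponse], float | None, float | None]:
    """Label each burst and estimate the two response thresholds.

    For every burst, band power in the ``window_s`` window after the burst
    (offset + guard) is compared with the window before its onset.  A 2-8 Hz
    excursion exceeding ``r_ad`` times baseline labels after_discharge
    (takes precedence); a post/pre ratio strictly below ``r_supp`` labels
    suppression; otherwise none.  Threshold estimates are the lowest burst
    amplitudes attaining each label (None if never attained).

    Bursts must be spaced so the pre window of one does not overlap the post
    window of the previous.
    """
    if channel is None:
        channel = rec.labels[0]
    x = rec.get(channel)
    fs = rec.fs
    w_n = int(round(window_s * fs))
    g_n = int(round(guard_s * fs))

    spans = []
    for ev in bursts:
        i_on, i_off = int(ev.onset_s * fs), int(ev.offset_s * fs)
        pre = (i_on - w_n, i_on)
        post = (i_off + g_n, i_off + g_n + w_n)
        if pre[0] < 0 or post[1] > x.size:
            raise ValueError(f"burst at {ev.onset_s:g}s lacks {window_s:g}s clean windows")
        spans.append((ev, pre, post))
    for (_, _, post_a), (_, pre_b, _) in zip(spans, spans[1:]):
        if pre_b[0] < post_a[1]:
            raise ValueError(
                f"bursts too close: need >= {2 * window_s + guard_s:g}s spacing"
            )

    responses = []
    for ev, pre, post in spans:
        p_pre = _window_band_power(x[pre[0]:pre[1]], fs, band)
        p_post = _window_band_power(x[post[0]:post[1]], fs, band)
        ratio = p_post / max(p_pre, 1e-12)
        ad_pre = _window_band_power(x[pre[0]:pre[1]], fs, AD_BAND)
        ad_post = _window_band_power(x[post[0]:post[1]], fs, AD_BAND)
        if ad_post > r_ad * ad_pre:
            label = "after_discharge"
        elif ratio < r_supp:
            label = "suppression"
        else:
            label = "none"
        responses.append(BurstResponse(ev.setting.amplitude, label, max(ratio, 1e-12)))

    def _lowest(lbl: str) -> float | None:
        amps = [r.burst_amplitude for r in responses
                if r.label == lbl or (lbl == "suppression" and r.label == "after_discharge")]
        return min(amps) if amps else None

    theta_inh = _lowest("suppression")
    theta_ad = _lowest("after_discharge")
    return responses, theta_inh, theta_ad
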