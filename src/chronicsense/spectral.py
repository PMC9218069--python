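"""PSD, spectrogram, band power and peak frequency.

Conventions: Welch averaging with a Hann window (default 4 s segments, 50 %
overlap, so df = 0.25 Hz resolves a 4-5 Hz peak), amplitude spectral density
in microvolt per root-hertz as the canonical stored quantity, spectrogram
values in dB re 1 uV^2/Hz with a 40 dB display dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_model import Recording

__all__ = [
    "SpectralEstimate",
    "Spectrogram",
    "power_spectral_density",
    "spectrogram",
    "band_power",
    "peak_frequency",
]

DB_REF = 1.0  # uV^2/Hz


@dataclass
class SpectralEstimate:
    """Amplitude spectral density on a uniform frequency grid."""

    freqs: np.ndarray          # Hz, 0 .. fs/2
    density: np.ndarray        # uV/sqrt(Hz)
    df: float
    window: str = "hann"
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.shape != self.density.shape:
            raise ValueError("freqs and density must align")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def power(self) -> np.ndarray:
        """Power spectral density, uV^2/Hz."""
        return self.density**2


@dataclass
class Spectrogram:
    """Short-time power in dB with a display dynamic range."""

    times: np.ndarray
    freqs: np.ndarray
    values_db: np.ndarray      # freqs x times
    dynamic_range_db: float = 40.0

    def clipped(self) -> np.ndarray:
        """dB matrix clipped to [max - dynamic_range, max] for display."""
        top = float(np.max(self.values_db))
        return np.clip(self.values_db, top - self.dynamic_range_db, top)


def _segment_params(rec: Recording, segment_s: float, overlap: float):
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    nperseg = int(round(segment_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording too short: need >= {segment_s:g} s "
            f"({nperseg} samples), have {rec.n_samples}"
        )
    return nperseg, int(round(nperseg * overlap))


def power_spectral_density(
    rec: Recording, channel: str, segment_s: float = 4.0, overlap: float = 0.5
) -> SpectralEstimate:
    """Welch-averaged amplitude spectral density of one channel.

    Hann window, mean averaging; the returned density is the square root of
    the Welch power density, in uV/sqrt(Hz).
    """
    x = rec.get(channel)
    nperseg, noverlap = _segment_params(rec, segment_s, overlap)
    freqs, pxx = sps.welch(
        x, fs=rec.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", average="mean",
    )
    step = nperseg - noverlap
    n_segments = 1 + (rec.n_samples - nperseg) // step
    return SpectralEstimate(
        freqs=freqs, density=np.sqrt(pxx), df=float(freqs[1] - freqs[0]),
        window="hann", n_segments=int(n_segments),
    )


def spectrogram(
    rec: Recording, channel: str, segment_s: float = 1.0, overlap: float = 0.5,
    dynamic_range_db: float = 40.0,
) -> Spectrogram:
    """Short-time Hann spectrogram in dB re 1 uV^2/Hz.

    A floor of -120 dB is applied so silent input stays finite.
    """
    x = rec.get(channel)
    nperseg, noverlap = _segment_params(rec, segment_s, overlap)
    freqs, times, pxx = sps.spectrogram(
        x, fs=rec.fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", mode="psd",
    )
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(pxx / DB_REF)
    db = np.maximum(db, -120.0)
    return Spectrogram(times=times, freqs=freqs, values_db=db,
                       dynamic_range_db=dynamic_range_db)


def band_power(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """Integrated power (uV^2) of the density over ``band`` (trapezoidal)."""
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi <= est.freqs[-1] + est.df / 2:
        raise ValueError(f"band {band} invalid for grid ending at {est.freqs[-1]:g} Hz")
    sel = (est.freqs >= f_lo) & (est.freqs <= f_hi)
    if sel.sum() < 2:
        raise ValueError("band covers fewer than two frequency bins")
    return float(np.trapezoid(est.power[sel], est.freqs[sel]))


def peak_frequency(est: SpectralEstimate, search_band: tuple[float, float]) -> float:
    """Frequency of maximum density inside ``search_band``.

    Ties are broken toward the lower frequency (argmax picks the first of
    equal maxima on an ascending grid).
    """
    f_lo, f_hi = search_band
    sel = (est.freqs >= f_lo) & (est.freqs <= f_hi)
    if not np.any(sel):
        raise ValueError(f"search band {search_band} contains no grid points")
    f_sub = est.freqs[sel]
    d_sub = est.density[sel]
    return float(f_sub[int(np.argmax(d_sub))])
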