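"""Welch power spectra and the oscillation-presence gate.

Raw-signal shape metrics are only meaningful when a dominant rhythm exists
in the band of interest, so before cycle analysis each channel's Welch PSD
(Hamming window, 256-sample segments, 128-sample overlap, 450-point
transform at 512 Hz) is screened for a spectral peak rising above the 1/f
aperiodic background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .exceptions import ParameterError

DEFAULT_WINDOW = 256
DEFAULT_OVERLAP = 128
DEFAULT_NFFT = 450


@dataclass(frozen=True)
class PsdResult:
    freqs: np.ndarray
    power: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if (np.diff(self.freqs) <= 0).any():
            raise ParameterError("frequency grid must be strictly increasing")
        if (self.power < 0).any():
            raise ParameterError("spectral power must be nonnegative")

    def peak_frequency(self, f_lo: float = 0.0, f_hi: float = np.inf) -> float:
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return float(self.freqs[sel][np.argmax(self.power[sel])])


def welch_psd(
    signal: np.ndarray,
    fs: float,
    window: int = DEFAULT_WINDOW,
    overlap: int = DEFAULT_OVERLAP,
    nfft: int = DEFAULT_NFFT,
) -> PsdResult:
    """Hamming-tapered averaged periodogram (one-sided, constant detrend)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < window:
        raise ParameterError(
            f"signal ({signal.size} samples) shorter than window ({window})"
        )
    freqs, power = welch(signal, fs=fs, window="hamming", nperseg=window,
                         noverlap=overlap, nfft=nfft, detrend="constant")
    return PsdResult(freqs=freqs, power=power,
                     params={"window": window, "overlap": overlap, "nfft": nfft})


def oscillation_present(
    psd: PsdResult,
    f_lo: float,
    f_hi: float,
    threshold: float = 2.0,
    fit_range: tuple[float, float] = (2.0, 100.0),
) -> bool:
    """True when the PSD has a local maximum inside [f_lo, f_hi] exceeding an
    interpolated log-log aperiodic fit by ``threshold``.

    The aperiodic background is a straight line fitted to log power vs log
    frequency over ``fit_range`` excluding the candidate band, mimicking the
    visual check a practitioner performs on the spectrum.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    f, p = psd.freqs, psd.power
    in_band = (f >= f_lo) & (f <= f_hi)
    if not in_band.any():
        return False
    fit_sel = (f >= fit_range[0]) & (f <= fit_range[1]) & ~in_band & (p > 0)
    if fit_sel.sum() < 3:
        raise ParameterError("too few points outside the band to fit background")
    coeffs = np.polyfit(np.log10(f[fit_sel]), np.log10(p[fit_sel]), 1)

    # local maxima strictly inside the band
    band_idx = np.flatnonzero(in_band)
    for i in band_idx:
        if 0 < i < f.size - 1 and p[i] >= p[i - 1] and p[i] >= p[i + 1]:
            background = 10 ** np.polyval(coeffs, np.log10(f[i]))
            if p[i] > threshold * background:
                return True
    return False


def psd_table(psds: dict[str, PsdResult]) -> pd.DataFrame:
    """Tidy frequency x channel power table for writing to CSV/TSV."""
    first = next(iter(psds.values()))
    out = {"frequency_hz": first.freqs}
    for ch, psd in psds.items():
        out[ch] = psd.power
    return pd.DataFrame(out)
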