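"""Beta-phase / gamma-amplitude coupling via the normalized modulation index.

The low-frequency phase (beta, 13-30 Hz, FIR order 231 ms) and the
high-frequency amplitude (broad gamma, 50-150 Hz, order 240 ms) are taken
from the angle and magnitude of the Hilbert analytic signal of the two
band-passed copies.  Amplitude is then averaged in equal-width phase bins
over (-pi, pi]; the modulation index is the Kullback-Leibler divergence of
the normalized binned distribution from uniform, divided by ln(n_bins), so
it lies in [0, 1] with 0 for no coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .cycles import BETA_BAND, GAMMA_BAND, BandSpec, design_bandpass
from .exceptions import (
    FilteringError,
    InsufficientDataError,
    ParameterError,
    UndefinedMetricError,
)
from .preprocess import artifact_mask

DEFAULT_N_BINS = 18


@dataclass(frozen=True)
class PacResult:
    """Normalized modulation index plus the settings that produced it."""

    mi: float
    phase_band: BandSpec
    amp_band: BandSpec
    n_bins: int
    n_samples_used: int

    def as_dict(self) -> dict:
        return {
            "mi": self.mi,
            "phase_band": [self.phase_band.f_lo, self.phase_band.f_hi],
            "amp_band": [self.amp_band.f_lo, self.amp_band.f_hi],
            "n_bins": self.n_bins,
            "n_samples_used": self.n_samples_used,
        }


# ---------------------------------------------------------------------------
# Phase / amplitude extraction
# ---------------------------------------------------------------------------

def _filter_and_analytic(signal: np.ndarray, fs: float, band: BandSpec):
    signal = np.asarray(signal, dtype=float)
    signal = signal - signal.mean()  # DC is out of band; remove it exactly
    h = design_bandpass(band, fs)
    if signal.size <= 3 * h.size:
        raise FilteringError(
            f"signal ({signal.size}) shorter than 3x filter length ({h.size})"
        )
    filtered = fftconvolve(signal, h, mode="same")
    analytic = hilbert(filtered)
    usable = np.ones(signal.size, dtype=bool)
    usable[:h.size] = False
    usable[-h.size:] = False
    return analytic, usable


def extract_phase(
    signal: np.ndarray, fs: float, band: BandSpec = BETA_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase in (-pi, pi] of the band-passed signal, plus a
    usable-sample mask (one filter length at each end is unusable)."""
    analytic, usable = _filter_and_analytic(signal, fs, band)
    # a (near-)zero analytic signal has no meaningful angle
    usable &= np.abs(analytic) > 1e-12 * max(1.0, np.abs(analytic).max())
    return np.angle(analytic), usable


def extract_amplitude(
    signal: np.ndarray, fs: float, band: BandSpec = GAMMA_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous amplitude (>= 0) of the band-passed signal, plus the
    usable-sample mask."""
    analytic, usable = _filter_and_analytic(signal, fs, band)
    return np.abs(analytic), usable


# ---------------------------------------------------------------------------
# Modulation index
# ---------------------------------------------------------------------------

def phase_bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over (-pi, pi], right-closed."""
    width = 2 * np.pi / n_bins
    idx = np.ceil((np.asarray(phase) + np.pi) / width).astype(int) - 1
    return np.clip(idx, 0, n_bins - 1)


def modulation_index(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    mask: np.ndarray | None = None,
    phase_band: BandSpec = BETA_BAND,
    amp_band: BandSpec = GAMMA_BAND,
) -> PacResult:
    """KL-based normalized modulation index of a phase/amplitude pair.

    Mean amplitude per phase bin is normalized to a distribution P;
    mi = KL(P || uniform) / ln(n_bins), which is 0 for a perfectly uniform
    amplitude profile and 1 when all amplitude mass falls in one bin.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ParameterError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    if mask is not None:
        phase = phase[mask]
        amplitude = amplitude[mask]
    if phase.size == 0:
        raise InsufficientDataError("no usable samples")

    idx = phase_bin_indices(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise InsufficientDataError(
            f"{int((counts == 0).sum())} of {n_bins} phase bins received no samples"
        )
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = sums / counts
    total = means.sum()
    if total <= 0:
        raise UndefinedMetricError("all-zero amplitude: modulation index undefined")
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    return PacResult(
        mi=kl / np.log(n_bins),
        phase_band=phase_band,
        amp_band=amp_band,
        n_bins=n_bins,
        n_samples_used=int(phase.size),
    )


# ---------------------------------------------------------------------------
# Full chain on one channel
# ---------------------------------------------------------------------------

def compute_pac(
    signal: np.ndarray,
    fs: float,
    phase_band: BandSpec = BETA_BAND,
    amp_band: BandSpec = GAMMA_BAND,
    n_bins: int = DEFAULT_N_BINS,
    artifact_intervals: Iterable[Sequence[int]] = (),
    order: str = "remove_before_hilbert",
) -> PacResult:
    """Band-pass, artifact removal and Hilbert transform in one call.

    ``order='remove_before_hilbert'`` filters the continuous signal, deletes
    the artifact-flagged samples, and takes the Hilbert transform of the
    concatenated remainder (one filter length is then trimmed at each end).
    ``order='hilbert_before_remove'`` transforms first and masks afterwards,
    additionally discarding one filter length around every artifact gap so
    transform edge effects never enter the binning.
    """
    signal = np.asarray(signal, dtype=float)
    signal = signal - signal.mean()
    h_phase = design_bandpass(phase_band, fs)
    h_amp = design_bandpass(amp_band, fs)
    edge = max(h_phase.size, h_amp.size)
    if signal.size <= 3 * edge:
        raise FilteringError("signal shorter than 3x the longer filter")
    bad = artifact_mask(artifact_intervals, signal.size)

    if order == "remove_before_hilbert":
        fp = fftconvolve(signal, h_phase, mode="same")[~bad]
        fa = fftconvolve(signal, h_amp, mode="same")[~bad]
        phase = np.angle(hilbert(fp))
        amplitude = np.abs(hilbert(fa))
        usable = np.ones(phase.size, dtype=bool)
        usable[:edge] = False
        usable[-edge:] = False
    elif order == "hilbert_before_remove":
        phase, up = extract_phase(signal, fs, phase_band)
        amplitude, ua = extract_amplitude(signal, fs, amp_band)
        usable = up & ua & ~bad
        # widen every excluded region by one filter length on each side
        grow = np.flatnonzero(bad)
        if grow.size:
            for i in grow[np.r_[True, np.diff(grow) > 1]]:
                usable[max(0, i - edge):i] = False
            for i in grow[np.r_[np.diff(grow) > 1, True]]:
                usable[i:i + edge + 1] = False
    else:
        raise ParameterError(f"unknown order {order!r}")

    return modulation_index(phase, amplitude, n_bins=n_bins, mask=usable,
                            phase_band=phase_band, amp_band=amp_band)
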