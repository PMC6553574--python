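"""Cycle-by-cycle waveform-shape features and the four shape ratios.

Cycles are delimited by zerocrossings of a narrow-band (beta, 13-30 Hz)
filtered copy of the signal, but every feature is measured on the RAW
signal: the peak is the raw maximum between a rising and the next falling
zerocrossing, the trough the raw minimum between that falling crossing and
the next rising one.  Peak sharpness is the mean voltage drop from the
extremum to the samples ``width`` points before and after it; rise/decay
steepness is the largest one-sample slope between consecutive extrema.

Channel-level ratios are natural logs of mean-feature quotients:

    peak_trough_ratio  PTR = ln(mean peak sharpness / mean trough sharpness)
    rise_fall_ratio    RTF = ln(mean rise steepness  / mean decay steepness)

with sharpness_ratio = |PTR| and steepness_ratio = |RTF|.  The sign pair
(PTR, RTF) places a channel in one of four shape quadrants; Q4 (sharper
peaks, steeper decays: PTR > 0, RTF < 0) is the canonical sensorimotor
shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .exceptions import FilteringError, ParameterError, UndefinedMetricError
from .preprocess import artifact_mask

DEFAULT_SHARPNESS_WIDTH = 3
DEFAULT_MIN_CYCLES = 5


# ---------------------------------------------------------------------------
# Band definition and zero-lag FIR band-pass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """Frequency band plus FIR order expressed in milliseconds."""

    f_lo: float
    f_hi: float
    order_ms: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ParameterError(f"need 0 < f_lo < f_hi, got {self}")

    def n_taps(self, fs: float) -> int:
        """round(order_ms * fs / 1000), forced odd."""
        taps = round(self.order_ms * fs / 1000.0)
        return taps + 1 if taps % 2 == 0 else taps


BETA_BAND = BandSpec(13.0, 30.0, 231.0)
MU_ALPHA_BAND = BandSpec(8.0, 12.0, 231.0)
GAMMA_BAND = BandSpec(50.0, 150.0, 240.0)


def design_bandpass(band: BandSpec, fs: float) -> np.ndarray:
    """Hamming-window FIR band-pass coefficients (odd length, linear phase)."""
    if band.f_hi >= fs / 2:
        raise ParameterError(f"band {band} exceeds Nyquist for fs={fs}")
    return firwin(band.n_taps(fs), [band.f_lo, band.f_hi],
                  pass_zero=False, fs=fs, window="hamming")


def bandpass_fir(signal: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """One-pass linear-phase band-pass with the group delay compensated, so
    filtered and raw samples are index-aligned."""
    signal = np.asarray(signal, dtype=float)
    h = design_bandpass(band, fs)
    if signal.size <= 3 * h.size:
        raise FilteringError(
            f"signal ({signal.size}) shorter than 3x filter length ({h.size})"
        )
    # odd-length kernel + mode='same' centres the output: exact delay removal
    return fftconvolve(signal, h, mode="same")


# ---------------------------------------------------------------------------
# Zerocrossings and extrema
# ---------------------------------------------------------------------------

def find_zerocrossings(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rising crossings at i where x[i] < 0 <= x[i+1]; falling where
    x[i] >= 0 > x[i+1].  A sample exactly at 0 counts as nonnegative."""
    x = np.asarray(filtered, dtype=float)
    neg = x[:-1] < 0
    nonneg_next = x[1:] >= 0
    rising = np.flatnonzero(neg & nonneg_next)
    falling = np.flatnonzero(~neg & ~nonneg_next)
    return rising, falling


def _cycle_bounds(
    rising: np.ndarray, falling: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aligned (rise_zc, fall_zc, next_rise_zc) triples for complete cycles.

    Crossings of a band-limited signal strictly alternate, so after dropping
    falling crossings that precede the first rising one, falling[k] bounds
    the positive half of cycle k."""
    rising = np.asarray(rising, int)
    falling = np.asarray(falling, int)
    if rising.size < 2:
        empty = np.array([], int)
        return empty, empty, empty
    falling = falling[falling > rising[0]]
    n = min(rising.size - 1, falling.size)
    return rising[:n], falling[:n], rising[1:n + 1]


def _segment_argmax(raw: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """First index of the maximum of raw over each [start, end) segment,
    vectorized over segments (segments must be nonempty)."""
    lmax = int((ends - starts).max())
    idx = starts[:, None] + np.arange(lmax)[None, :]
    pad = idx >= ends[:, None]
    vals = raw[np.minimum(idx, raw.size - 1)]
    vals[pad] = -np.inf
    return starts + np.argmax(vals, axis=1)


def locate_extrema(
    raw: np.ndarray,
    rising: np.ndarray,
    falling: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-signal extrema between alternating crossings: the peak is the raw
    argmax over [rise_zc, fall_zc), the trough the raw argmin over
    [fall_zc, next rise_zc).  First index wins on ties.  Returns index arrays
    of equal length (one per complete cycle)."""
    raw = np.asarray(raw, dtype=float)
    r, f, r_next = _cycle_bounds(rising, falling)
    if r.size == 0:
        return np.array([], int), np.array([], int)
    peaks = _segment_argmax(raw, r, f)
    troughs = _segment_argmax(-raw, f, r_next)
    return peaks, troughs


def extrema_sharpness(
    raw: np.ndarray,
    indices: np.ndarray,
    width: int = DEFAULT_SHARPNESS_WIDTH,
    kind: str = "peak",
) -> np.ndarray:
    """Sharpness at each extremum: the mean voltage difference between the
    extremum and the samples ``width`` points before and after it (sign such
    that true local extrema give nonnegative values).  Extrema closer than
    ``width`` to either end yield NaN."""
    if width < 1:
        raise ParameterError("width must be >= 1")
    raw = np.asarray(raw, dtype=float)
    idx = np.asarray(indices, int)
    out = np.full(idx.shape, np.nan)
    ok = (idx >= width) & (idx < raw.size - width)
    i = idx[ok]
    if kind == "peak":
        out[ok] = ((raw[i] - raw[i - width]) + (raw[i] - raw[i + width])) / 2.0
    elif kind == "trough":
        out[ok] = ((raw[i - width] - raw[i]) + (raw[i + width] - raw[i])) / 2.0
    else:
        raise ParameterError(f"kind must be 'peak' or 'trough', got {kind!r}")
    return out


def segment_steepness(
    raw: np.ndarray,
    peaks: np.ndarray,
    troughs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle steepness from one-sample forward differences.

    rise_steep[i]  = max slope over [trough[i-1], peak[i])   (NaN for i=0)
    decay_steep[i] = max |slope| over [peak[i], trough[i])

    Empty segments (adjacent equal indices) yield NaN.
    """
    raw = np.asarray(raw, dtype=float)
    peaks = np.asarray(peaks, int)
    troughs = np.asarray(troughs, int)
    diff = np.diff(raw)
    n = peaks.size
    rise = np.full(n, np.nan)
    decay = np.full(n, np.nan)
    if n == 0:
        return rise, decay
    bounds = np.empty(2 * n, dtype=int)
    bounds[0::2] = peaks
    bounds[1::2] = troughs
    if (np.diff(bounds) > 0).all() and bounds[-1] < diff.size:
        # strict peak/trough interleave: one reduceat covers all segments
        decay = np.maximum.reduceat(np.abs(diff), bounds)[0::2]
        rise[1:] = np.maximum.reduceat(diff, bounds)[1::2][:n - 1]
    else:
        for i in range(n):
            if i > 0 and peaks[i] > troughs[i - 1]:
                rise[i] = diff[troughs[i - 1]:peaks[i]].max()
            if troughs[i] > peaks[i]:
                decay[i] = np.abs(diff[peaks[i]:troughs[i]]).max()
    return rise, decay


# ---------------------------------------------------------------------------
# Cycle table
# ---------------------------------------------------------------------------

def detect_cycles(
    raw: np.ndarray,
    fs: float,
    band: BandSpec = BETA_BAND,
    width: int = DEFAULT_SHARPNESS_WIDTH,
    artifact_intervals: Iterable[Sequence[int]] = (),
) -> pd.DataFrame:
    """Run the full per-channel cycle decomposition.

    Returns a DataFrame with one row per complete cycle: zerocrossing and
    extremum indices, sharpness and steepness features, and a ``valid`` flag.
    A cycle is invalid when its extremum lies in an artifact interval, when a
    steepness segment overlaps one, when the extremum is within ``width``
    samples of the recording boundary, or when a segment is degenerate.
    """
    raw = np.asarray(raw, dtype=float)
    filtered = bandpass_fir(raw, fs, band)
    rising, falling = find_zerocrossings(filtered)
    rise_zc, fall_zc, _ = _cycle_bounds(rising, falling)
    peaks, troughs = locate_extrema(raw, rising, falling)
    n = peaks.size
    if n == 0:
        return pd.DataFrame(columns=[
            "rise_zc", "fall_zc", "peak_idx", "trough_idx", "peak_sharp",
            "trough_sharp", "rise_steep", "decay_steep", "valid"])

    peak_sharp = extrema_sharpness(raw, peaks, width, "peak")
    trough_sharp = extrema_sharpness(raw, troughs, width, "trough")
    rise_steep, decay_steep = segment_steepness(raw, peaks, troughs)

    mask = artifact_mask(artifact_intervals, raw.size)
    feats = np.column_stack([peak_sharp, trough_sharp, rise_steep, decay_steep])
    valid = ~np.isnan(feats).any(axis=1)
    valid &= ~mask[peaks] & ~mask[troughs]
    near_edge = ((peaks < width) | (peaks >= raw.size - width)
                 | (troughs < width) | (troughs >= raw.size - width))
    valid &= ~near_edge
    cum = np.concatenate([[0], np.cumsum(mask)])
    valid &= cum[troughs] - cum[peaks] == 0          # decay segment clean
    rise_hit = np.zeros(n, dtype=bool)
    rise_hit[1:] = cum[peaks[1:]] - cum[troughs[:-1]] > 0
    valid &= ~rise_hit

    return pd.DataFrame({
        "rise_zc": rise_zc,
        "fall_zc": fall_zc,
        "peak_idx": peaks,
        "trough_idx": troughs,
        "peak_sharp": peak_sharp,
        "trough_sharp": trough_sharp,
        "rise_steep": rise_steep,
        "decay_steep": decay_steep,
        "valid": valid,
    })


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeMetrics:
    """Channel-level waveform-shape summary; see module docstring for the
    ratio definitions and the quadrant convention."""

    sharpness_ratio: float
    steepness_ratio: float
    peak_trough_ratio: float
    rise_fall_ratio: float
    quadrant: str
    n_valid_cycles: int

    def as_dict(self) -> dict:
        return {
            "sharpness_ratio": self.sharpness_ratio,
            "steepness_ratio": self.steepness_ratio,
            "peak_trough_ratio": self.peak_trough_ratio,
            "rise_fall_ratio": self.rise_fall_ratio,
            "quadrant": self.quadrant,
            "n_valid_cycles": self.n_valid_cycles,
        }


def _quadrant(ptr: float, rtf: float) -> str:
    if ptr == 0 or rtf == 0:
        return "boundary"
    if ptr > 0:
        return "Q4" if rtf < 0 else "Q1"
    return "Q3" if rtf < 0 else "Q2"


def shape_metrics(
    cycle_table: pd.DataFrame,
    min_cycles: int = DEFAULT_MIN_CYCLES,
) -> ShapeMetrics:
    """Collapse a cycle table to the four shape ratios and quadrant label.

    Means are taken over valid cycles only; fewer than ``min_cycles`` valid
    cycles, or a nonpositive mean feature, leaves the metric undefined.
    """
    valid = cycle_table[cycle_table["valid"]]
    n = len(valid)
    if n < min_cycles:
        raise UndefinedMetricError(
            f"only {n} valid cycles (< {min_cycles}); metric undefined"
        )
    mp = valid["peak_sharp"].mean()
    mt = valid["trough_sharp"].mean()
    mr = valid["rise_steep"].mean()
    md = valid["decay_steep"].mean()
    if min(mp, mt, mr, md) <= 0:
        raise UndefinedMetricError("nonpositive mean cycle feature")
    ptr = float(np.log(mp / mt))
    rtf = float(np.log(mr / md))
    return ShapeMetrics(
        sharpness_ratio=abs(ptr),
        steepness_ratio=abs(rtf),
        peak_trough_ratio=ptr,
        rise_fall_ratio=rtf,
        quadrant=_quadrant(ptr, rtf),
        n_valid_cycles=n,
    )


def channel_shape_metrics(
    raw: np.ndarray,
    fs: float,
    band: BandSpec = BETA_BAND,
    width: int = DEFAULT_SHARPNESS_WIDTH,
    min_cycles: int = DEFAULT_MIN_CYCLES,
    artifact_intervals: Iterable[Sequence[int]] = (),
) -> ShapeMetrics:
    """Convenience: detect_cycles + shape_metrics on one raw trace."""
    table = detect_cycles(raw, fs, band=band, width=width,
                          artifact_intervals=artifact_intervals)
    return shape_metrics(table, min_cycles=min_cycles)


# ---------------------------------------------------------------------------
# Small utilities and writers
# ---------------------------------------------------------------------------

def samples_to_ms(n_samples: float, fs: float) -> float:
    """Duration of ``n_samples`` at rate ``fs``, in milliseconds (the
    default sharpness width of 3 samples at 512 Hz spans ~5.9 ms)."""
    return 1000.0 * n_samples / fs


def write_cycle_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def write_shape_metrics(
    metrics: dict[str, ShapeMetrics],
    path: str | Path,
    band: BandSpec = BETA_BAND,
    width: int = DEFAULT_SHARPNESS_WIDTH,
) -> None:
    """Per-channel metrics JSON, annotated with the band and width used."""
    payload = {
        "band": {"f_lo": band.f_lo, "f_hi": band.f_hi, "order_ms": band.order_ms},
        "sharpness_width_samples": width,
        "channels": {ch: m.as_dict() for ch, m in metrics.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))
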