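"""Recording container, referencing, high-pass filtering, artifact bookkeeping.

The preprocessing chain mirrors standard resting-EEG practice: per-channel
demeaning, then a common average reference over the good channels (or a
bipolar derivation such as C3-CP1/C4-CP2), then a zero-phase FIR high-pass
at 0.5 Hz to remove slow drift.  Artifact spans are carried along as
half-open, 0-based sample intervals and are excluded *after* filtering, so
the filters never run across concatenation discontinuities.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import filtfilt, firwin

from .exceptions import (
    ChannelLookupError,
    FilteringError,
    IntervalError,
    ParameterError,
    ReferencingError,
    UndefinedMetricError,
)

Interval = tuple[int, int]

DEFAULT_HIGHPASS_HZ = 0.5


# ---------------------------------------------------------------------------
# Artifact intervals
# ---------------------------------------------------------------------------

def normalize_artifact_intervals(
    intervals: Iterable[Sequence[int]],
    n_samples: int | None = None,
) -> list[Interval]:
    """Sort, merge, clip and de-duplicate half-open sample intervals.

    Empty intervals (start == end) are dropped.  The operation is idempotent
    and invariant to input order.  With ``n_samples`` given, intervals are
    clipped to ``[0, n_samples)``.
    """
    cleaned: list[Interval] = []
    for iv in intervals:
        start, end = int(iv[0]), int(iv[1])
        if start > end:
            raise IntervalError(f"interval start {start} > end {end}")
        if n_samples is not None:
            start = max(start, 0)
            end = min(end, n_samples)
        if end <= start:
            continue
        cleaned.append((start, end))
    cleaned.sort()
    merged: list[Interval] = []
    for start, end in cleaned:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def seconds_to_sample_intervals(
    intervals_s: Iterable[Sequence[float]], fs: float
) -> list[Interval]:
    """Convert annotation spans in seconds to conservative sample intervals
    (floor the start, ceil the end)."""
    return normalize_artifact_intervals(
        [(math.floor(a * fs), math.ceil(b * fs)) for a, b in intervals_s]
    )


def artifact_mask(intervals: Iterable[Sequence[int]], n_samples: int) -> np.ndarray:
    """Boolean mask, True where a sample falls inside an artifact interval."""
    mask = np.zeros(n_samples, dtype=bool)
    for start, end in normalize_artifact_intervals(intervals, n_samples):
        mask[start:end] = True
    return mask


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in volts or arbitrary units.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names (10-20 convention where applicable), unique.
    artifact_intervals : list of (start, end)
        Half-open, 0-based sample intervals flagged for rejection.
    bad_channels : list of str
        Channels excluded from referencing and analysis.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    artifact_intervals: list[Interval] = field(default_factory=list)
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("channel labels must be unique")
        if self.data.shape[0] != len(self.labels):
            raise ParameterError(
                f"{self.data.shape[0]} data rows for {len(self.labels)} labels"
            )
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        unknown = set(self.bad_channels) - set(self.labels)
        if unknown:
            raise ChannelLookupError(f"bad_channels not in labels: {sorted(unknown)}")
        self.artifact_intervals = normalize_artifact_intervals(
            self.artifact_intervals, self.n_samples
        )

    # -- basic accessors ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def good_labels(self) -> list[str]:
        return [lb for lb in self.labels if lb not in self.bad_channels]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise ChannelLookupError(label) from None

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       labels=list(self.labels),
                       artifact_intervals=list(self.artifact_intervals),
                       bad_channels=list(self.bad_channels))


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------

def demean_and_average_reference(rec: Recording) -> Recording:
    """Remove each good channel's mean, then subtract the instantaneous mean
    across good channels (common average reference).

    Bad channels are excluded from the average and passed through unchanged.
    Idempotent on good channels up to numerical precision.
    """
    good = [i for i, lb in enumerate(rec.labels) if lb not in rec.bad_channels]
    if len(good) < 2:
        raise ReferencingError(
            f"average reference needs >=2 good channels, have {len(good)}"
        )
    out = rec.copy()
    sub = out.data[good]
    sub = sub - sub.mean(axis=1, keepdims=True)
    sub = sub - sub.mean(axis=0, keepdims=True)
    out.data[good] = sub
    return out


def bipolar_reference(
    rec: Recording, pairs: Sequence[tuple[str, str]]
) -> Recording:
    """Derive one channel per (anode, cathode) pair, data = anode - cathode,
    labelled ``"A-C"``.  Both members must be present and good."""
    rows, labels = [], []
    for anode, cathode in pairs:
        for lb in (anode, cathode):
            if lb in rec.bad_channels:
                raise ChannelLookupError(f"channel {lb!r} is marked bad")
        rows.append(rec.channel(anode) - rec.channel(cathode))
        labels.append(f"{anode}-{cathode}")
    return Recording(
        data=np.array(rows),
        fs=rec.fs,
        labels=labels,
        artifact_intervals=list(rec.artifact_intervals),
    )


# ---------------------------------------------------------------------------
# High-pass filtering
# ---------------------------------------------------------------------------

def highpass_taps(fs: float, cutoff: float, n_samples: int) -> int:
    """Filter length heuristic: 3 cycles of the cutoff frequency, forced odd,
    capped at a third of the signal length (with a warning)."""
    taps = 3 * round(fs / cutoff)
    cap = n_samples // 3
    if taps > cap:
        warnings.warn(
            f"high-pass filter length {taps} capped at n_samples/3 = {cap}",
            stacklevel=2,
        )
        taps = cap
    if taps % 2 == 0:
        taps -= 1
    if taps < 3:
        raise FilteringError("signal too short to design a high-pass filter")
    return taps


def highpass_filter(rec: Recording, cutoff: float = DEFAULT_HIGHPASS_HZ) -> Recording:
    """Zero-phase (two-way) FIR high-pass of every channel.

    The linear-phase FIR is applied forward and backward so the net phase
    shift is zero; the DC component of the output is ~0.
    """
    if not 0 < cutoff < rec.fs / 2:
        raise ParameterError(f"cutoff {cutoff} outside (0, fs/2)")
    taps = highpass_taps(rec.fs, cutoff, rec.n_samples)
    if rec.n_samples <= 3 * taps:
        raise FilteringError(
            f"signal ({rec.n_samples} samples) shorter than 3x filter length ({taps})"
        )
    h = firwin(taps, cutoff, pass_zero=False, fs=rec.fs)
    out = rec.copy()
    # remove the channel means exactly; the FIR handles sub-cutoff drift
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    out.data = filtfilt(h, [1.0], out.data, axis=1, padlen=taps)
    return out


# ---------------------------------------------------------------------------
# Composite (per-subject) metric
# ---------------------------------------------------------------------------

def composite_channels(
    values: Mapping[str, float], group: Sequence[str]
) -> float:
    """Average a per-channel metric over a channel group (e.g. C3 and C4).

    Channels missing from ``values`` or holding NaN are skipped; with a
    single available channel its own value is returned.  With none, the
    metric is undefined.
    """
    avail = [values[lb] for lb in group
             if lb in values and values[lb] is not None
             and not np.isnan(values[lb])]
    if not avail:
        raise UndefinedMetricError(f"no defined value among channels {list(group)}")
    return float(np.mean(avail))


# ---------------------------------------------------------------------------
# I/O — plain matrix + JSON sidecar, and EDF/BDF via mne
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as ``<path>.tsv`` (samples x channels, headered)
    plus ``<path>.json`` sidecar with fs, labels, artifact intervals."""
    path = Path(path)
    header = "\t".join(rec.labels)
    np.savetxt(path.with_suffix(".tsv"), rec.data.T, delimiter="\t",
               header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "labels": rec.labels,
        "artifact_intervals": [list(iv) for iv in rec.artifact_intervals],
        "bad_channels": rec.bad_channels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording.  ``.edf``/``.bdf`` go through mne; anything else is
    the plain TSV + JSON-sidecar pair written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix.lower() in {".edf", ".bdf"}:
        return _read_edf(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t", skiprows=1).T
    return Recording(
        data=np.atleast_2d(data),
        fs=sidecar["fs"],
        labels=sidecar["labels"],
        artifact_intervals=[tuple(iv) for iv in sidecar.get("artifact_intervals", [])],
        bad_channels=sidecar.get("bad_channels", []),
    )


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: optional dependency

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    intervals_s = [
        (ann["onset"], ann["onset"] + ann["duration"])
        for ann in raw.annotations
        if str(ann["description"]).lower().startswith(("bad", "artifact"))
    ]
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        artifact_intervals=seconds_to_sample_intervals(intervals_s, raw.info["sfreq"]),
        bad_channels=list(raw.info["bads"]),
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Export to EDF through mne (requires the ``edfio`` backend)."""
    import mne

    info = mne.create_info(rec.labels, rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data, info, verbose="error")
    if rec.artifact_intervals:
        onsets = [a / rec.fs for a, _ in rec.artifact_intervals]
        durs = [(b - a) / rec.fs for a, b in rec.artifact_intervals]
        raw.set_annotations(mne.Annotations(onsets, durs, ["BAD_artifact"] * len(onsets)))
    try:
        mne.export.export_raw(str(path), raw, fmt="edf", verbose="error")
    except (ImportError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise RuntimeError(
            "EDF export needs the 'edfio' backend; use write_recording() for "
            "the plain TSV+JSON format instead"
        ) from exc
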