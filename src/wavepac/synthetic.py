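"""Synthetic sensorimotor EEG with controllable waveform shape and coupling.

The generator builds a non-sinusoidal oscillation from half-cosine arcs whose
rise and decay durations and peak/trough curvature are tuned independently,
adds a 1/f^chi aperiodic background, and optionally a gamma carrier whose
amplitude is locked to the oscillation's phase.  Paired two-state cohorts
(e.g. off/on medication) share per-subject shape parameters except for a
specified state effect, so ground truth for every downstream metric is known.

Waveform model.  Within each cycle the phase theta advances linearly from
-pi to 0 over the rise (a fraction ``rdsym`` of the period) and from 0 to pi
over the decay.  The base waveform is cos(theta); the positive half is raised
to ``peak_exp`` and the negative half (of its magnitude) to ``trough_exp``,
which sharpens the corresponding extremum while preserving its value of +-1,
so amplitude and sharpness stay decoupled.  With rdsym=0.5 and unit
exponents the output is exactly a cosine at ``osc_freq``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ParameterError, WavepacError
from .preprocess import Interval, Recording, normalize_artifact_intervals

DEFAULT_CHANNELS = ("C3", "C4")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic recording.

    duration/fs in seconds/Hz; ``rdsym`` is the fraction of each cycle spent
    rising (0.5 = symmetric); ``peak_exp``/``trough_exp`` >= 1 sharpen the
    respective extremum (1 = sinusoidal curvature); ``aperiodic_exp`` is the
    1/f^chi exponent of the background whose amplitude is ``noise_amp``;
    ``pac_depth`` is the modulation fraction m in [0, 1] applied to a gamma
    carrier of amplitude ``gamma_amp`` at ``gamma_freq``.
    """

    duration: float = 180.0
    fs: float = 512.0
    osc_freq: float = 20.0
    rdsym: float = 0.5
    peak_exp: float = 1.0
    trough_exp: float = 1.0
    osc_amp: float = 1.0
    aperiodic_exp: float = 2.0
    noise_amp: float = 0.5
    pac_depth: float = 0.0
    gamma_freq: float = 100.0
    gamma_amp: float = 0.1
    artifact_intervals: tuple[Interval, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rdsym < 1:
            raise ParameterError(f"rdsym must be in (0,1), got {self.rdsym}")
        if not 0 <= self.pac_depth <= 1:
            raise ParameterError(f"pac_depth must be in [0,1], got {self.pac_depth}")
        if self.peak_exp < 1 or self.trough_exp < 1:
            raise ParameterError("sharpening exponents must be >= 1")
        if self.aperiodic_exp < 0:
            raise ParameterError("aperiodic_exp must be >= 0")
        if self.fs <= 2 * self.gamma_freq:
            raise ParameterError("fs must exceed 2 x gamma_freq")
        if self.duration <= 0 or self.osc_freq <= 0:
            raise ParameterError("duration and osc_freq must be positive")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


@dataclass(frozen=True)
class CohortSpec:
    """Paired two-state cohort: every subject is simulated under both
    conditions, sharing per-subject shape offsets drawn once with spread
    ``between_subject_sd`` (applied to rdsym additively and to the sharpening
    exponents multiplicatively on the log scale)."""

    n_subjects: int = 15
    channels: Sequence[str] = DEFAULT_CHANNELS
    state_params: Mapping[str, SynthParams] = field(
        default_factory=lambda: {"off": SynthParams(), "on": SynthParams()}
    )
    between_subject_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if len(self.state_params) < 2:
            raise WavepacError(
                "state_params must define both conditions of the paired design"
            )


# ---------------------------------------------------------------------------
# Oscillation
# ---------------------------------------------------------------------------

def oscillation_phase(params: SynthParams) -> np.ndarray:
    """Asymmetric cycle phase in (-pi, pi]: -pi..0 over the rise (fraction
    rdsym of the period), 0..pi over the decay."""
    t = np.arange(params.n_samples) / params.fs
    frac = (t * params.osc_freq) % 1.0
    rising = frac < params.rdsym
    theta = np.empty_like(frac)
    theta[rising] = -np.pi + np.pi * frac[rising] / params.rdsym
    theta[~rising] = np.pi * (frac[~rising] - params.rdsym) / (1 - params.rdsym)
    return theta


def simulate_asymmetric_oscillation(params: SynthParams) -> np.ndarray:
    """Noiseless shaped oscillation: half-cosine arcs with independently
    controlled rise/decay durations and peak/trough sharpness; zero mean
    over whole cycles; extrema at +-osc_amp."""
    base = np.cos(oscillation_phase(params))
    mag = np.abs(base)
    x = np.where(base >= 0, mag ** params.peak_exp, -(mag ** params.trough_exp))
    # remove the mean computed over an integer number of cycles
    n_whole = int(np.floor(params.duration * params.osc_freq)
                  / params.osc_freq * params.fs)
    if n_whole >= 1:
        x = x - x[:n_whole].mean()
    return params.osc_amp * x


# ---------------------------------------------------------------------------
# Aperiodic background
# ---------------------------------------------------------------------------

def simulate_aperiodic(
    exponent: float,
    n: int,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian noise spectrally shaped so power ~ 1/f^exponent; zero mean,
    unit variance.  The DC bin is zeroed.  exponent=0 gives white noise."""
    if n <= 1:
        raise ParameterError("n must be > 1")
    if exponent < 0:
        raise ParameterError("exponent must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


# ---------------------------------------------------------------------------
# Phase-amplitude coupling
# ---------------------------------------------------------------------------

def inject_pac(
    beta_phase: np.ndarray,
    gamma_freq: float,
    depth: float,
    fs: float,
    amp: float = 1.0,
    return_envelope: bool = False,
):
    """Gamma carrier with instantaneous amplitude amp * (1 + depth *
    cos(beta_phase)).  depth=0 gives a constant-amplitude carrier; the
    envelope's min/max ratio is (1-depth)/(1+depth)."""
    if not 0 <= depth <= 1:
        raise ParameterError(f"depth must be in [0,1], got {depth}")
    beta_phase = np.asarray(beta_phase, dtype=float)
    t = np.arange(beta_phase.size) / fs
    envelope = amp * (1.0 + depth * np.cos(beta_phase))
    signal = envelope * np.cos(2 * np.pi * gamma_freq * t)
    if return_envelope:
        return signal, envelope
    return signal


# ---------------------------------------------------------------------------
# Full recordings and cohorts
# ---------------------------------------------------------------------------

ARTIFACT_BURST_GAIN = 10.0  # burst amplitude relative to osc_amp


def simulate_recording(
    params: SynthParams,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> Recording:
    """One multichannel recording: each channel holds the shaped oscillation
    plus independent 1/f background and (if gamma_amp > 0) a phase-locked
    gamma component.  Declared artifact intervals are overwritten with
    high-amplitude broadband bursts and carried on the Recording."""
    n = params.n_samples
    rng = np.random.default_rng(params.seed)
    osc = simulate_asymmetric_oscillation(params)
    theta = oscillation_phase(params)
    rows = []
    for _ in channels:
        x = osc.copy()
        if params.noise_amp > 0:
            x = x + params.noise_amp * simulate_aperiodic(
                params.aperiodic_exp, n, params.fs, rng
            )
        if params.gamma_amp > 0:
            x = x + inject_pac(theta, params.gamma_freq, params.pac_depth,
                               params.fs, amp=params.gamma_amp)
        rows.append(x)
    data = np.array(rows)
    intervals = normalize_artifact_intervals(params.artifact_intervals, n)
    for start, end in intervals:
        data[:, start:end] += (
            ARTIFACT_BURST_GAIN * params.osc_amp
            * rng.standard_normal((data.shape[0], end - start))
        )
    return Recording(data=data, fs=params.fs, labels=list(channels),
                     artifact_intervals=intervals)


def simulate_cohort(spec: CohortSpec) -> dict[str, list[Recording]]:
    """Paired cohort: returns {condition: [Recording per subject]}.

    Per-subject offsets are drawn once and applied to every condition, so
    the two states differ only by the offsets' carrier (the state_params)
    plus independent noise realizations — a genuinely paired design.
    """
    conditions = list(spec.state_params)
    rng = np.random.default_rng(spec.seed)
    d_rdsym = rng.normal(0.0, spec.between_subject_sd, spec.n_subjects)
    d_logexp = rng.normal(0.0, spec.between_subject_sd, spec.n_subjects)
    # one sub-seed per subject x condition, below 2**31
    seeds = rng.integers(0, 2**31 - 1, size=(spec.n_subjects, len(conditions)))
    out: dict[str, list[Recording]] = {c: [] for c in conditions}
    for i in range(spec.n_subjects):
        for j, cond in enumerate(conditions):
            base = spec.state_params[cond]
            params = replace(
                base,
                rdsym=float(np.clip(base.rdsym + d_rdsym[i], 0.05, 0.95)),
                peak_exp=max(1.0, base.peak_exp * float(np.exp(d_logexp[i]))),
                trough_exp=max(1.0, base.trough_exp * float(np.exp(d_logexp[i]))),
                seed=int(seeds[i, j]),
            )
            out[cond].append(simulate_recording(params, spec.channels))
    return out


# ---------------------------------------------------------------------------
# Config mapping (YAML)
# ---------------------------------------------------------------------------

def params_from_dict(d: Mapping) -> SynthParams:
    d = dict(d)
    if "artifact_intervals" in d:
        d["artifact_intervals"] = tuple(tuple(iv) for iv in d["artifact_intervals"])
    return SynthParams(**d)


def cohort_from_dict(d: Mapping) -> CohortSpec:
    d = dict(d)
    d["state_params"] = {
        cond: params_from_dict(p) for cond, p in d["state_params"].items()
    }
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return CohortSpec(**d)


def load_config(path) -> SynthParams | CohortSpec:
    """Read a YAML config that maps 1:1 onto SynthParams (key ``params``) or
    CohortSpec (key ``cohort``)."""
    import yaml

    cfg = yaml.safe_load(open(path))
    if "cohort" in cfg:
        return cohort_from_dict(cfg["cohort"])
    if "params" in cfg:
        return params_from_dict(cfg["params"])
    raise ParameterError("config must contain a 'params' or 'cohort' block")
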