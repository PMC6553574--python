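"""Group-level statistics: paired/unpaired nonparametric tests, FDR,
effect sizes, the Q4 inclusion rule, topographic statistic maps, and the
cohort pipeline that strings the per-channel metrics into them.

Conventions follow the clinical-EEG literature this package targets: the
paired test is the Wilcoxon signed-rank (statistic reported as the smaller
of the positive/negative rank sums, exact null for n <= 25), the unpaired
test a tie-corrected rank-sum z, multiplicity handled by Benjamini-Hochberg
step-up FDR within a table-sized family, and effect size as Cohen's d with
pooled unbiased SD (modulation-index values are natural-log scaled first).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import cycles as _cycles
from . import pac as _pac
from .cycles import BETA_BAND, BandSpec, ShapeMetrics
from .exceptions import ParameterError, UndefinedMetricError, WavepacError
from .preprocess import Recording, composite_channels

DEFAULT_SENSORIMOTOR = ("C3", "C4")
DEFAULT_CONTROL_ELECTRODES = ("F7", "F8")


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def signed_rank_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; ties get averaged ranks.  The statistic is
    the smaller of the positive/negative rank sums.  The exact (sign-flip
    permutation) null distribution is used for n <= 25, otherwise a
    continuity-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedMetricError("all paired differences are zero")
    if d.size < 5:
        raise ParameterError(f"need >=5 nonzero differences, have {d.size}")
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, tie-corrected normal approximation.

    Returns the z statistic for the first sample's rank sum (so swapping the
    samples negates z) and the two-sided p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4 or y.size < 4:
        raise ParameterError("each group needs n >= 4")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise UndefinedMetricError("all observations tied; rank-sum z undefined")
    z = (r1 - mu) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p (n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ParameterError("vectors must have equal length")
    if x.size < 5:
        raise ParameterError("need n >= 5")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedMetricError("constant vector: correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def fdr_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(a: Sequence[float], b: Sequence[float], log_scale: bool = False) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD, with
    unbiased variances; ``log_scale`` natural-logs both vectors first (used
    for modulation-index values, which are right-skewed)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs n >= 2")
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ParameterError("log scaling requires strictly positive values")
        a, b = np.log(a), np.log(b)
    pooled = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                     / (a.size + b.size - 2))
    if pooled == 0:
        raise UndefinedMetricError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# Comparison containers
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One row of a results table: a metric compared between two conditions."""

    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    paired: bool
    statistic: float
    p_raw: float
    cohens_d: float
    n: int
    p_fdr: float = np.nan

    def as_row(self) -> dict:
        return {
            "metric": self.metric,
            "paired": self.paired,
            "n": self.n,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "cohens_d": self.cohens_d,
        }


def compare_conditions(
    values: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    paired: bool = True,
    log_scale_metrics: Iterable[str] = ("pac",),
) -> list[GroupComparison]:
    """Run the appropriate two-sample test per metric and BH-adjust the raw
    p-values across the whole family (all metrics passed in one call)."""
    log_scale_metrics = set(log_scale_metrics)
    comps = []
    for metric, (a, b) in values.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if paired:
            statistic, p = signed_rank_test(a, b)
        else:
            statistic, p = rank_sum_test(a, b)
        d = cohens_d(a, b, log_scale=metric in log_scale_metrics)
        comps.append(GroupComparison(
            metric=metric, values_a=a, values_b=b, paired=paired,
            statistic=statistic, p_raw=p, cohens_d=d, n=int(a.size)))
    adj = fdr_adjust([c.p_raw for c in comps])
    for c, q in zip(comps, adj):
        c.p_fdr = float(q)
    return comps


def comparisons_table(comps: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in comps])


# ---------------------------------------------------------------------------
# Q4 inclusion
# ---------------------------------------------------------------------------

def q4_inclusion(
    metrics: Mapping[int, Mapping[str, Mapping[str, ShapeMetrics]]],
    quadrant: str = "Q4",
) -> dict[int, list[str]]:
    """Retention rule for the canonical-shape analysis.

    ``metrics[subject][channel][condition]`` holds a ShapeMetrics.  A channel
    is retained iff its quadrant equals ``quadrant`` in BOTH conditions; a
    subject is retained iff at least one channel is.  Returns
    {subject: [retained channels]} for retained subjects only.
    """
    retained: dict[int, list[str]] = {}
    for subject, per_channel in metrics.items():
        chans = []
        for channel, per_cond in per_channel.items():
            if per_cond and all(m.quadrant == quadrant for m in per_cond.values()):
                chans.append(channel)
        if chans:
            retained[subject] = chans
    return retained


def q4_composite(
    metrics: Mapping[int, Mapping[str, Mapping[str, ShapeMetrics]]],
    metric_name: str,
    condition: str,
    retained: Mapping[int, Sequence[str]],
) -> dict[int, float]:
    """Per-subject composite of one metric over the retained channels only
    (a single retained channel contributes its own value)."""
    out = {}
    for subject, chans in retained.items():
        vals = {ch: getattr(metrics[subject][ch][condition], metric_name)
                for ch in chans}
        out[subject] = composite_channels(vals, list(chans))
    return out


# ---------------------------------------------------------------------------
# Topographic statistic map
# ---------------------------------------------------------------------------

def topo_stat_map(
    statistics: Mapping[str, float],
    critical: float,
    smaller_is_significant: bool = True,
) -> dict[str, float]:
    """Rescale per-electrode test statistics for a topographic map.

    Non-significant electrodes are set to 0; significant ones are rescaled
    to the percentage of the most significant statistic, so the most
    significant electrode maps to 100.  For signed-rank statistics smaller
    values are more significant (significant iff stat < critical); pass
    ``smaller_is_significant=False`` for z-like statistics.
    """
    if not statistics:
        raise ParameterError("need at least one electrode")
    out = {}
    if smaller_is_significant:
        scores = {e: critical - s for e, s in statistics.items() if s < critical}
    else:
        scores = {e: s - critical for e, s in statistics.items() if s > critical}
    best = max(scores.values()) if scores else None
    for e, s in statistics.items():
        out[e] = 100.0 * scores[e] / best if e in scores else 0.0
    return out


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------

SHAPE_METRIC_NAMES = ("sharpness_ratio", "steepness_ratio")


def subject_metrics(
    rec: Recording,
    channels: Sequence[str] = DEFAULT_SENSORIMOTOR,
    band: BandSpec = BETA_BAND,
    include_pac: bool = True,
    min_cycles: int = _cycles.DEFAULT_MIN_CYCLES,
) -> dict[str, float]:
    """Composite (channel-averaged) metrics for one recording.

    Each metric is computed per channel on the raw trace (artifact intervals
    respected) and averaged over the channels present; a channel whose
    metric is undefined is skipped.
    """
    per_channel: dict[str, dict[str, float]] = {m: {} for m in SHAPE_METRIC_NAMES}
    if include_pac:
        per_channel["pac"] = {}
    for ch in channels:
        if ch not in rec.labels or ch in rec.bad_channels:
            continue
        x = rec.channel(ch)
        try:
            sm = _cycles.channel_shape_metrics(
                x, rec.fs, band=band, min_cycles=min_cycles,
                artifact_intervals=rec.artifact_intervals)
        except UndefinedMetricError:
            sm = None
        if sm is not None:
            for m in SHAPE_METRIC_NAMES:
                per_channel[m][ch] = getattr(sm, m)
        if include_pac:
            try:
                per_channel["pac"][ch] = _pac.compute_pac(
                    x, rec.fs, phase_band=band,
                    artifact_intervals=rec.artifact_intervals).mi
            except WavepacError:
                pass
    out = {}
    for m, vals in per_channel.items():
        out[m] = composite_channels(vals, list(channels)) if vals else np.nan
    return out


def analyze_cohort(
    cohort: Mapping[str, Sequence[Recording]],
    conditions: tuple[str, str] = ("off", "on"),
    channels: Sequence[str] = DEFAULT_SENSORIMOTOR,
    band: BandSpec = BETA_BAND,
    include_pac: bool = True,
    demean: bool = True,
) -> pd.DataFrame:
    """Per-subject composite metric table for a paired cohort.

    Returns a tidy DataFrame (subject, condition, metric, value).  Synthetic
    recordings are drift-free and carry only the channels of interest, so by
    default channels are only demeaned — the common-average/bipolar
    re-referencing and 0.5 Hz high-pass of the preprocess module are applied
    upstream when analyzing real multichannel EEG.
    """
    rows = []
    for cond in conditions:
        for subject, rec in enumerate(cohort[cond]):
            if demean:
                rec = rec.copy()
                rec.data = rec.data - rec.data.mean(axis=1, keepdims=True)
            vals = subject_metrics(rec, channels=channels, band=band,
                                   include_pac=include_pac)
            for metric, value in vals.items():
                rows.append({"subject": subject, "condition": cond,
                             "metric": metric, "value": value})
    return pd.DataFrame(rows)


def compare_cohort(
    metric_table: pd.DataFrame,
    conditions: tuple[str, str] = ("off", "on"),
) -> list[GroupComparison]:
    """Paired condition comparison of every metric in an analyze_cohort
    table, FDR-corrected as one family (subjects with a missing value for a
    metric are dropped pairwise for that metric)."""
    values = {}
    for metric, sub in metric_table.groupby("metric", sort=False):
        wide = sub.pivot(index="subject", columns="condition", values="value")
        wide = wide.dropna()
        values[metric] = (wide[conditions[0]].to_numpy(),
                          wide[conditions[1]].to_numpy())
    return compare_conditions(values, paired=True)
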