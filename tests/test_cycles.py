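"""Cycle decomposition, the four shape ratios, and their invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wavepac import (
    BETA_BAND,
    BandSpec,
    SynthParams,
    UndefinedMetricError,
    bandpass_fir,
    channel_shape_metrics,
    detect_cycles,
    extrema_sharpness,
    find_zerocrossings,
    locate_extrema,
    samples_to_ms,
    segment_steepness,
    shape_metrics,
    simulate_asymmetric_oscillation,
)
from wavepac.exceptions import ParameterError

from naive_reference import naive_cycle_table

FS = 512.0


class TestBandpass:
    def test_tap_counts_from_order_ms(self):
        assert BETA_BAND.n_taps(FS) == 119       # round(118.272) -> odd
        assert BandSpec(50, 150, 240).n_taps(FS) == 123

    def test_passband_amplitude_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        y = bandpass_fir(np.sin(2 * np.pi * 20 * t), FS, BETA_BAND)
        mid = y[1024:-1024]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_amplitude_suppressed(self):
        t = np.arange(int(10 * FS)) / FS
        y = bandpass_fir(np.sin(2 * np.pi * 5 * t), FS, BETA_BAND)
        assert np.abs(y[1024:-1024]).max() < 0.05

    def test_group_delay_compensated(self):
        # a filtered pure in-band sine stays sample-aligned with the input
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 20 * t)
        y = bandpass_fir(x, FS, BETA_BAND)
        mid = slice(1024, -1024)
        lag = np.argmax(np.correlate(y[mid][:2048], x[mid][:2048], "full")) - 2047
        assert lag == 0

    def test_band_outside_nyquist(self):
        with pytest.raises(ParameterError):
            bandpass_fir(np.zeros(4096), FS, BandSpec(50, 400, 240))


class TestZerocrossings:
    @pytest.mark.parametrize("x, rising, falling", [
        ([-1, 1, -1], [0], [1]),
        ([1, 1, 1], [], []),
        ([-1, 0, -1], [0], [1]),  # exact zero counts as nonnegative
    ])
    def test_examples(self, x, rising, falling):
        r, f = find_zerocrossings(np.asarray(x, float))
        assert r.tolist() == rising
        assert f.tolist() == falling

    def test_single_sine_cycle(self):
        # one full cycle entering the positive half once and leaving it once
        x = -np.sin(2 * np.pi * np.arange(64) / 64)
        r, f = find_zerocrossings(x)
        assert len(r) == 1 and len(f) == 1


class TestExtrema:
    def test_peak_between_crossings(self):
        raw = np.array([0.0, 1.0, 3.0, 1.0, 0.0, -2.0, 0.0, 1.0])
        peaks, troughs = locate_extrema(raw, rising=[0, 6], falling=[3])
        assert peaks.tolist() == [2]
        assert troughs.tolist() == [5]

    def test_plateau_tie_takes_first_index(self):
        raw = np.array([0.0, 2.0, 2.0, 0.0, -1.0, -1.0, 0.0, 1.0])
        peaks, troughs = locate_extrema(raw, rising=[0, 6], falling=[3])
        assert peaks.tolist() == [1]
        assert troughs.tolist() == [4]

    def test_cycle_count_on_noiseless_sine(self):
        t = np.arange(int(10 * FS)) / FS
        table = detect_cycles(np.sin(2 * np.pi * 20 * t), FS)
        assert abs(len(table) - 200) <= 1


class TestSharpness:
    def test_triangle_peak(self):
        raw = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        assert extrema_sharpness(raw, [3], width=3, kind="peak")[0] == 3.0

    def test_triangle_trough_by_symmetry(self):
        raw = -np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        assert extrema_sharpness(raw, [3], width=3, kind="trough")[0] == 3.0

    def test_boundary_extremum_is_nan(self):
        raw = np.arange(10.0)
        assert np.isnan(extrema_sharpness(raw, [1], width=3, kind="peak")[0])

    def test_default_width_duration(self):
        assert samples_to_ms(3, 512) == pytest.approx(5.86, abs=0.005)


class TestSteepness:
    def test_rise_and_decay_examples(self):
        # trough at 0, peak at 3, next trough at 5: values 0,1,3,4,1,0
        raw = np.array([0.0, 1.0, 3.0, 4.0, 1.0, 0.0])
        rise, decay = segment_steepness(raw, peaks=[3], troughs=[5])
        assert decay[0] == 3.0          # |4 -> 1|
        rise, decay = segment_steepness(raw, peaks=[0, 3], troughs=[1, 5])
        assert rise[1] == 2.0           # 1 -> 3 between trough 1 and peak 3

    def test_linear_ramp_slope_recovered(self):
        raw = np.concatenate([np.linspace(-1, 1, 11), np.linspace(1, -2, 7)[1:]])
        rise, decay = segment_steepness(raw, peaks=[0, 10], troughs=[4, 16])
        assert rise[1] == pytest.approx(0.2, abs=1e-12)
        assert decay[1] == pytest.approx(0.5, abs=1e-12)


class TestShapeMetrics:
    @staticmethod
    def table(mp, mt, mr, md, n=10):
        return pd.DataFrame({
            "peak_sharp": [mp] * n, "trough_sharp": [mt] * n,
            "rise_steep": [mr] * n, "decay_steep": [md] * n,
            "valid": [True] * n,
        })

    def test_log_ratio_arithmetic(self):
        m = shape_metrics(self.table(2.0, 1.0, 1.0, 1.0))
        assert m.peak_trough_ratio == pytest.approx(np.log(2), abs=1e-12)
        assert m.sharpness_ratio == pytest.approx(np.log(2), abs=1e-12)
        assert m.rise_fall_ratio == 0.0
        assert m.steepness_ratio == 0.0
        assert m.quadrant == "boundary"

    @pytest.mark.parametrize("mp,mt,mr,md,quadrant", [
        (2, 1, 2, 1, "Q1"), (1, 2, 2, 1, "Q2"),
        (1, 2, 1, 2, "Q3"), (2, 1, 1, 2, "Q4"),
    ])
    def test_quadrants(self, mp, mt, mr, md, quadrant):
        assert shape_metrics(self.table(mp, mt, mr, md)).quadrant == quadrant

    def test_too_few_cycles_undefined(self):
        with pytest.raises(UndefinedMetricError):
            shape_metrics(self.table(1, 1, 1, 1, n=3))

    def test_nonpositive_mean_undefined(self):
        with pytest.raises(UndefinedMetricError):
            shape_metrics(self.table(-1, 1, 1, 1))

    def test_symmetric_sine_ratios_near_zero(self, symmetric_sine):
        m = channel_shape_metrics(symmetric_sine, FS)
        for v in (m.sharpness_ratio, m.steepness_ratio,
                  abs(m.peak_trough_ratio), abs(m.rise_fall_ratio)):
            assert v < 0.02


@pytest.fixture(scope="module")
def clean():
    """Integer samples-per-cycle oscillation, so boundary cycles carry
    identical features and the invariances below hold to rounding error."""
    p = SynthParams(duration=10, fs=FS, osc_freq=16, rdsym=0.6,
                    peak_exp=2.0, noise_amp=0.0, gamma_amp=0.0)
    return simulate_asymmetric_oscillation(p)


class TestInvariances:
    """Antisymmetry/invariance of the four shape ratios."""

    def test_negation_flips_ptr_and_rtf(self, clean):
        m = channel_shape_metrics(clean, FS)
        mn = channel_shape_metrics(-clean, FS)
        assert abs(mn.peak_trough_ratio + m.peak_trough_ratio) < 1e-9
        assert abs(mn.rise_fall_ratio + m.rise_fall_ratio) < 1e-9
        assert abs(mn.sharpness_ratio - m.sharpness_ratio) < 1e-9
        assert abs(mn.steepness_ratio - m.steepness_ratio) < 1e-9

    def test_time_reversal_flips_rtf_only(self, clean):
        m = channel_shape_metrics(clean, FS)
        mr = channel_shape_metrics(clean[::-1], FS)
        assert abs(mr.rise_fall_ratio + m.rise_fall_ratio) < 1e-9
        assert abs(mr.peak_trough_ratio - m.peak_trough_ratio) < 1e-9

    def test_amplitude_invariance(self, clean):
        m = channel_shape_metrics(clean, FS)
        ms = channel_shape_metrics(7.3 * clean, FS)
        assert abs(ms.peak_trough_ratio - m.peak_trough_ratio) < 1e-9
        assert abs(ms.rise_fall_ratio - m.rise_fall_ratio) < 1e-9


class TestOracleEquivalence:
    def test_pipeline_matches_naive_reference(self, noisy_asymmetric_signal):
        table = detect_cycles(noisy_asymmetric_signal, FS)
        ref = naive_cycle_table(noisy_asymmetric_signal, FS)
        assert len(table) == len(ref)
        for col in ("rise_zc", "fall_zc", "peak_idx", "trough_idx"):
            assert table[col].tolist() == [r[col] for r in ref]
        for col in ("peak_sharp", "trough_sharp", "rise_steep", "decay_steep"):
            got = table[col].to_numpy()
            want = np.array([r[col] for r in ref])
            both = ~np.isnan(want)
            assert np.isnan(got[~both]).all()
            assert np.abs(got[both] - want[both]).max() < 1e-12


class TestArtifactsAndWidths:
    def test_cycles_touching_artifacts_invalidated(self, asymmetric_signal):
        clean = detect_cycles(asymmetric_signal, FS)
        flagged = detect_cycles(asymmetric_signal, FS,
                                artifact_intervals=[(1000, 1500)])
        assert len(clean) == len(flagged)
        hit = (flagged["peak_idx"] >= 990) & (flagged["peak_idx"] < 1510)
        assert not flagged.loc[hit, "valid"].any()
        assert flagged["valid"].sum() < clean["valid"].sum()

    def test_sharpness_ratio_rank_stable_across_widths(self):
        exps = [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        ratios = {w: [] for w in (2, 3, 4)}
        for e in exps:
            p = SynthParams(duration=20, fs=FS, osc_freq=20, peak_exp=e,
                            noise_amp=0.0, gamma_amp=0.0)
            x = simulate_asymmetric_oscillation(p)
            for w in ratios:
                ratios[w].append(channel_shape_metrics(x, FS, width=w).sharpness_ratio)
        assert stats.spearmanr(ratios[2], ratios[3])[0] > 0.9
        assert stats.spearmanr(ratios[3], ratios[4])[0] > 0.9
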