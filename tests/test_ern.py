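import numpy as np
import pytest

from mstate import synth
from mstate.core import Recording
from mstate.ern import (
    ErnScore,
    ErpAverage,
    average_condition,
    difference_wave,
    filter_trials,
    grand_average,
    identify_error_microstate,
    residualize_ern,
    score_ern,
    segment_grand_average,
)


def epoched(data, sr=250.0, time_zero=125):
    return Recording(data=data, sr=sr, kind="epoched", time_zero=time_zero)


class TestFilterTrials:
    def test_rule_applied_literally(self, rng):
        rec = epoched(rng.standard_normal((4, 3, 326)))
        out = filter_trials(rec, [50, 150, 2500, 900])
        assert out.n_trials == 2
        np.testing.assert_array_equal(out.data, rec.data[[1, 3]])

    def test_all_in_range_identity(self, rng):
        rec = epoched(rng.standard_normal((3, 3, 326)))
        out = filter_trials(rec, [400, 500, 600])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_boundaries_inclusive(self, rng):
        rec = epoched(rng.standard_normal((2, 3, 326)))
        out = filter_trials(rec, [100, 2000])
        assert out.n_trials == 2

    def test_length_mismatch_errors(self, rng):
        rec = epoched(rng.standard_normal((2, 3, 326)))
        with pytest.raises(ValueError):
            filter_trials(rec, [500])


class TestAverageCondition:
    def test_identical_trials(self, rng):
        trial = rng.standard_normal((3, 326))
        rec = epoched(np.tile(trial, (10, 1, 1)))
        avg = average_condition(rec, "nogo_error")
        bmask = avg.baseline_mask()
        expected = trial - trial[:, bmask].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(avg.data, expected, atol=1e-12)

    def test_baseline_mean_is_zero(self, rng):
        rec = epoched(rng.standard_normal((8, 4, 326)))
        avg = average_condition(rec, "nogo_error")
        bmask = avg.baseline_mask()
        np.testing.assert_allclose(avg.data[:, bmask].mean(axis=1), 0.0, atol=1e-9)

    def test_noise_shrinks_with_n(self, rng):
        signal = rng.standard_normal((2, 326))
        errs = []
        for n in (8, 128):
            data = signal[None] + rng.standard_normal((n, 2, 326))
            avg = average_condition(epoched(data), "nogo_error")
            ref = average_condition(epoched(signal[None].repeat(6, 0)), "nogo_error")
            errs.append(np.sqrt(np.mean((avg.data - ref.data) ** 2)))
        assert errs[1] < errs[0] / 2.0  # ~ sqrt(16) expected

    def test_trial_gate(self, rng):
        rec = epoched(rng.standard_normal((5, 3, 326)))
        with pytest.raises(ValueError, match="gate"):
            average_condition(rec, "nogo_error")
        with pytest.raises(ValueError, match="gate"):
            average_condition(epoched(rng.standard_normal((20, 3, 326))), "go_correct")


class TestDifferenceWave:
    def _avg(self, data):
        times = (np.arange(data.shape[1]) - 125) * 4.0
        return ErpAverage("nogo_error", data, times, n_trials=10)

    def test_identical_inputs_zero(self, rng):
        a = self._avg(rng.standard_normal((3, 326)))
        d = difference_wave(a, a)
        np.testing.assert_allclose(d.data, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 3, 326))
        d1 = difference_wave(self._avg(x), self._avg(y))
        d2 = difference_wave(self._avg(2 * x), self._avg(2 * y))
        np.testing.assert_allclose(d2.data, 2 * d1.data, atol=1e-12)

    def test_axis_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            difference_wave(self._avg(rng.standard_normal((3, 326))),
                            self._avg(rng.standard_normal((4, 326))))

    def test_planted_component_visible(self, gonogo_data):
        epochs, _, gt = gonogo_data
        avg_go = average_condition(epochs.go, "go_correct")
        avg_nogo = average_condition(epochs.nogo, "nogo_error")
        diff = difference_wave(avg_nogo, avg_go)
        tmask = (diff.times >= gt.ern_window_ms[0]) & (diff.times <= gt.ern_window_ms[1])
        observed = diff.data[np.ix_(gt.ern_roi, np.flatnonzero(tmask))].mean()
        assert observed == pytest.approx(gt.ern_amplitude_uv, abs=1.0)


@pytest.fixture(scope="module")
def segmented(gonogo_data):
    epochs, _, gt = gonogo_data
    avg_go = average_condition(epochs.go, "go_correct")
    avg_nogo = average_condition(epochs.nogo, "nogo_error")
    diff = difference_wave(avg_nogo, avg_go)
    states, seg = segment_grand_average(diff, k_range=(1, 8), restarts=30, seed=3)
    return diff, states, seg, gt, avg_go, avg_nogo


class TestSegmentationAndIdentification:
    def test_every_nonbaseline_sample_labeled(self, segmented):
        diff, _, seg, _, _, _ = segmented
        analyzed = diff.times > diff.baseline[1]
        assert np.all(seg.labels[analyzed] >= 0)
        assert np.all(seg.labels[~analyzed] == -1)

    def test_seed_repeatability(self, gonogo_data):
        epochs, _, _ = gonogo_data
        avg_go = average_condition(epochs.go, "go_correct")
        avg_nogo = average_condition(epochs.nogo, "nogo_error")
        diff = difference_wave(avg_nogo, avg_go)
        s1, g1 = segment_grand_average(diff, k_range=(1, 6), restarts=10, seed=9)
        s2, g2 = segment_grand_average(diff, k_range=(1, 6), restarts=10, seed=9)
        np.testing.assert_array_equal(s1.maps, s2.maps)
        np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_window_and_roi_recovered(self, segmented):
        diff, _, seg, gt, _, _ = segmented
        _, window, roi = identify_error_microstate(seg, diff.times)
        assert window[0] <= 0 <= window[1]
        assert abs(window[0] - gt.ern_window_ms[0]) <= 24.0
        assert abs(window[1] - gt.ern_window_ms[1]) <= 24.0
        peak = int(np.argmin(np.array(gt.extra["ern_map"])))
        assert peak in roi

    def test_score_recovers_planted_amplitude(self, segmented):
        diff, _, seg, gt, avg_go, avg_nogo = segmented
        _, window, roi = identify_error_microstate(seg, diff.times)
        score = score_ern(avg_go, avg_nogo, window, roi)
        assert score.nogo_mean - score.go_mean == pytest.approx(
            gt.ern_amplitude_uv, abs=1.0
        )

    def test_no_run_at_zero_errors(self):
        from mstate.backfitting import Segmentation

        labels = np.full(326, -1)
        seg = Segmentation(
            labels=labels,
            corr_matrix=np.zeros((326, 2)),
            gfp_trace=np.ones(326),
            sr=250.0,
        )
        times = (np.arange(326) - 125) * 4.0
        with pytest.raises(ValueError, match="manually"):
            identify_error_microstate(seg, times)


class TestScoreErn:
    def _avg(self, data, condition="go_correct"):
        times = (np.arange(data.shape[1]) - 125) * 4.0
        return ErpAverage(condition, data, times, n_trials=25)

    def test_constant_wave(self):
        data = np.full((4, 326), -5.0)
        a = self._avg(data)
        s = score_ern(a, a, (-64, 108), [1, 2])
        assert s.go_mean == pytest.approx(-5.0)

    def test_single_sample_single_channel(self, rng):
        data = rng.standard_normal((4, 326))
        a = self._avg(data)
        t_idx = 150
        t_ms = (t_idx - 125) * 4.0
        s = score_ern(a, a, (t_ms, t_ms), [2])
        assert s.go_mean == pytest.approx(data[2, t_idx])

    def test_linear_in_input(self, rng):
        data = rng.standard_normal((4, 326))
        s1 = score_ern(self._avg(data), self._avg(data), (-64, 108), [0, 1])
        s2 = score_ern(self._avg(3 * data), self._avg(3 * data), (-64, 108), [0, 1])
        assert s2.go_mean == pytest.approx(3 * s1.go_mean)

    def test_out_of_range_errors(self, rng):
        a = self._avg(rng.standard_normal((4, 326)))
        with pytest.raises(ValueError):
            score_ern(a, a, (-64, 108), [7])
        with pytest.raises(ValueError):
            score_ern(a, a, (900, 1000), [0])
        with pytest.raises(ValueError):
            score_ern(a, a, (-64, 108), [])


class TestResidualizeErn:
    @staticmethod
    def scores(go, nogo):
        return [
            ErnScore(participant=str(i), go_mean=float(g), nogo_mean=float(n))
            for i, (g, n) in enumerate(zip(go, nogo))
        ]

    def test_perfect_fit_zero_residuals(self, rng):
        go = rng.standard_normal(10)
        out = residualize_ern(self.scores(go, go))
        for s in out:
            assert s.residualized == pytest.approx(0.0, abs=1e-9)

    def test_residuals_orthogonal_to_go(self, rng):
        go = rng.standard_normal(200)
        nogo = 2 * go + rng.standard_normal(200)
        out = residualize_ern(self.scores(go, nogo))
        resid = np.array([s.residualized for s in out])
        assert abs(np.corrcoef(resid, go)[0, 1]) < 1e-9

    def test_residual_mean_zero(self, rng):
        go, nogo = rng.standard_normal((2, 30))
        out = residualize_ern(self.scores(go, nogo))
        assert np.mean([s.residualized for s in out]) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            residualize_ern(self.scores([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError):
            residualize_ern(self.scores([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestGrandAverage:
    def test_mean_across_participants(self, rng):
        times = (np.arange(326) - 125) * 4.0
        waves = [
            ErpAverage("difference", rng.standard_normal((3, 326)), times, 1)
            for _ in range(5)
        ]
        g = grand_average(waves)
        np.testing.assert_allclose(g.data, np.mean([w.data for w in waves], axis=0))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            grand_average([])


def test_end_to_end_amplitude_recovery_correlation(states4):
    """Planted per-participant amplitudes should be recovered monotonically."""
    rng = np.random.default_rng(0)
    amplitudes = rng.uniform(-8.0, -2.0, size=12)
    scores = []
    fixed_window, fixed_roi = None, None
    for i, amp in enumerate(amplitudes):
        epochs, _, gt = synth.simulate_gonogo(
            states4, n_go=40, n_nogo=25, ern_amplitude_uv=float(amp), snr=5.0, seed=500 + i
        )
        avg_go = average_condition(epochs.go, "go_correct")
        avg_nogo = average_condition(epochs.nogo, "nogo_error")
        if fixed_window is None:
            diff = difference_wave(avg_nogo, avg_go)
            _, seg = segment_grand_average(diff, k_range=(1, 8), restarts=20, seed=1)
            _, fixed_window, fixed_roi = identify_error_microstate(seg, diff.times)
        scores.append(score_ern(avg_go, avg_nogo, fixed_window, fixed_roi, participant=str(i)))
    resid = np.array([s.residualized for s in residualize_ern(scores)])
    r = np.corrcoef(amplitudes, resid)[0, 1]
    assert r > 0.8
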