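import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mstate import synth
from mstate.backfitting import (
    UNASSIGNED,
    Segmentation,
    backfit,
    enforce_min_segment,
    normalize_gfp_median,
    runs_of,
    smooth_labels,
    temporal_stats,
)
from mstate.clustering import MicrostateSet
from mstate.core import Recording, gfp_series


def make_segmentation(labels, k=3, sr=250.0, fits=None, polarity="invariant"):
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if fits is None:
        # strong fit for the given label, weak elsewhere
        C = np.full((n, k), 0.3)
        mask = labels != UNASSIGNED
        C[np.flatnonzero(mask), labels[mask]] = 0.9
    else:
        C = np.asarray(fits, dtype=float)
    return Segmentation(
        labels=labels,
        corr_matrix=C,
        gfp_trace=np.ones(n),
        sr=sr,
        polarity_mode=polarity,
    )


class TestNormalizeGfpMedian:
    def test_constant_gfp_halved(self):
        data = np.array([[2.0, 2.0, 2.0], [-2.0, -2.0, -2.0]])
        rec = Recording(data=data, sr=250.0)
        out = normalize_gfp_median(rec)
        np.testing.assert_allclose(out.data, data / 2.0)

    def test_idempotent(self, rng):
        rec = Recording(data=rng.standard_normal((8, 100)), sr=250.0)
        once = normalize_gfp_median(rec)
        twice = normalize_gfp_median(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_output_median_is_one(self, rng):
        rec = Recording(data=rng.standard_normal((8, 101)) * 37.0, sr=250.0)
        out = normalize_gfp_median(rec)
        assert np.median(gfp_series(out.data)) == pytest.approx(1.0, abs=1e-9)

    def test_zero_median_errors(self):
        rec = Recording(data=np.zeros((4, 10)), sr=250.0)
        with pytest.raises(ValueError):
            normalize_gfp_median(rec)


class TestBackfit:
    def test_exact_template_match(self, states4):
        data = np.tile(states4.maps[2][:, None] * 5.0, (1, 10))
        rec = Recording(data=data, sr=250.0)
        seg = backfit(rec, states4, min_corr=0.5)
        assert np.all(seg.labels == 2)
        np.testing.assert_allclose(np.abs(seg.corr), 1.0, atol=1e-9)

    def test_orthogonal_sample_unassigned(self, states4, rng):
        # build a map orthogonal to every template
        v = rng.standard_normal(32)
        v -= v.mean()
        for m in states4.maps:
            v -= (v @ m) * m
        data = np.tile(v[:, None], (1, 5))
        rec = Recording(data=data, sr=250.0)
        seg = backfit(rec, states4, min_corr=0.5)
        assert np.all(seg.labels == UNASSIGNED)

    def test_window_restriction(self, states4):
        data = np.tile(states4.maps[0][:, None], (1, 100))
        rec = Recording(data=data, sr=250.0)
        seg = backfit(rec, states4, min_corr=0.5, window=(100.0, 200.0))
        times = rec.times_ms()
        inside = (times >= 100) & (times <= 200)
        assert np.all(seg.labels[inside] == 0)
        assert np.all(seg.labels[~inside] == UNASSIGNED)

    def test_empty_window_errors(self, states4):
        rec = Recording(data=np.tile(states4.maps[0][:, None], (1, 10)), sr=250.0)
        with pytest.raises(ValueError):
            backfit(rec, states4, window=(5000.0, 6000.0))

    def test_bad_min_corr_errors(self, states4):
        rec = Recording(data=np.tile(states4.maps[0][:, None], (1, 10)), sr=250.0)
        with pytest.raises(ValueError):
            backfit(rec, states4, min_corr=1.5)

    def test_variant_gate_is_signed(self, states4):
        variant = MicrostateSet(maps=states4.maps.copy(), polarity_mode="variant")
        data = np.tile(-states4.maps[1][:, None], (1, 5))
        rec = Recording(data=data, sr=250.0)
        seg = backfit(rec, variant, min_corr=0.25, polarity_mode="variant")
        # anti-correlated with its own template: winner must be another map or gate out
        assert np.all(seg.labels != 1)


class TestSmoothLabels:
    def test_besag_zero_is_identity(self, rng):
        labels = rng.integers(0, 3, size=50)
        seg = make_segmentation(labels)
        out = smooth_labels(seg, 32.0, besag=0.0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_island_absorbed(self):
        # 17 samples: state 0 everywhere, single-sample island of state 1 with
        # a near-tied fit; the neighbor bonus flips it
        labels = np.array([0] * 8 + [1] + [0] * 8)
        C = np.full((17, 2), 0.1)
        C[:, 0] = 0.80
        C[8, 0] = 0.79
        C[8, 1] = 0.81
        seg = make_segmentation(labels, k=2, fits=C)
        out = smooth_labels(seg, 32.0, besag=10.0)
        assert np.all(out.labels == 0)

    def test_fixed_point(self, rng):
        labels = rng.integers(0, 3, size=120)
        C = rng.uniform(0.3, 0.9, size=(120, 3))
        seg = make_segmentation(labels, k=3, fits=C)
        once = smooth_labels(seg, 32.0, besag=10.0)
        twice = smooth_labels(once, 32.0, besag=10.0)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_unassigned_frozen(self, rng):
        labels = rng.integers(0, 3, size=60)
        labels[10:20] = UNASSIGNED
        seg = make_segmentation(labels)
        out = smooth_labels(seg, 32.0, besag=10.0)
        assert np.all(out.labels[10:20] == UNASSIGNED)
        assert not np.any((out.labels == UNASSIGNED) & (labels != UNASSIGNED))

    def test_sub_sample_window_errors(self):
        seg = make_segmentation([0, 1, 0])
        with pytest.raises(ValueError):
            smooth_labels(seg, 1.0, besag=10.0)


class TestEnforceMinSegment:
    def test_even_split(self):
        labels = [0] * 20 + [1] * 6 + [2] * 20  # 6 samples = 24 ms < 32 ms
        out = enforce_min_segment(make_segmentation(labels), 32.0)
        expected = [0] * 23 + [2] * 23
        np.testing.assert_array_equal(out.labels, expected)

    def test_odd_split_floors_to_preceding(self):
        labels = [0] * 20 + [1] * 5 + [2] * 20
        out = enforce_min_segment(make_segmentation(labels), 32.0)
        expected = [0] * 22 + [2] * 23
        np.testing.assert_array_equal(out.labels, expected)

    def test_no_short_runs_is_identity(self):
        labels = [0] * 20 + [1] * 20 + [0] * 20
        out = enforce_min_segment(make_segmentation(labels), 32.0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_edge_runs_merge_into_single_neighbor(self):
        labels = [1] * 3 + [0] * 30 + [2] * 2
        out = enforce_min_segment(make_segmentation(labels), 32.0)
        np.testing.assert_array_equal(out.labels, [0] * 35)

    @given(st.lists(st.integers(min_value=-1, max_value=3), min_size=1, max_size=120))
    @settings(max_examples=100, deadline=None)
    def test_no_interior_short_run_for_any_label_sequence(self, labels):
        out = enforce_min_segment(make_segmentation(labels, k=4), 32.0)
        runs = runs_of(out.labels)
        min_samples = int(np.ceil(32.0 * 250.0 / 1000.0))
        for i, (_, start, stop) in enumerate(runs):
            if 0 < i < len(runs) - 1:
                assert stop - start >= min_samples
        # sample count conserved
        assert len(out.labels) == len(labels)

    def test_no_interior_short_run_remains(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 4, size=200)
            out = enforce_min_segment(make_segmentation(labels, k=4), 32.0)
            runs = runs_of(out.labels)
            min_samples = int(np.ceil(32.0 * 250.0 / 1000.0))
            for i, (_, start, stop) in enumerate(runs):
                if 0 < i < len(runs) - 1:
                    assert stop - start >= min_samples


class TestTemporalStats:
    def test_arithmetic_from_definitions(self):
        # 1000 samples at 250 Hz; state 0 occupies 10 interior runs of 50
        labels = np.full(1000, 1)
        starts = np.linspace(30, 900, 10).astype(int)
        for s in starts:
            labels[s : s + 50] = 0
        seg = make_segmentation(labels, k=2)
        st = temporal_stats(seg)
        assert st.coverage[0] == pytest.approx(0.5)
        assert st.occurrence[0] == pytest.approx(2.5)
        assert st.mean_duration[0] == pytest.approx(200.0)

    def test_perfect_fit_gev_one(self, states4):
        data = np.tile(states4.maps[0][:, None] * 3.0, (1, 200))
        rec = Recording(data=data, sr=250.0)
        seg = backfit(rec, states4, min_corr=0.5)
        st = temporal_stats(seg)
        assert st.gev[0] == pytest.approx(1.0, abs=1e-9)
        for s in (1, 2, 3):
            assert st.gev[s] == pytest.approx(0.0, abs=1e-12)

    def test_gev_matches_brute_force(self, resting_rec, states4):
        rec, _ = resting_rec
        seg = backfit(rec, states4, min_corr=0.5)
        st = temporal_stats(seg)
        g = gfp_series(rec.data)
        denom = np.sum(g**2)
        X = rec.data.T
        Xc = X - X.mean(axis=1, keepdims=True)
        for state in range(4):
            acc = 0.0
            for t in range(rec.n_samples):
                if seg.labels[t] == state:
                    c = (Xc[t] @ states4.maps[state]) / np.linalg.norm(Xc[t])
                    acc += (g[t] * c) ** 2
            assert st.gev[state] == pytest.approx(acc / denom, rel=1e-9)

    def test_gev_sums_below_one(self, resting_rec, states4):
        rec, _ = resting_rec
        seg = backfit(rec, states4, min_corr=0.5)
        st = temporal_stats(seg)
        assert sum(st.gev.values()) <= 1.0 + 1e-12

    def test_coverage_plus_unassigned_is_one(self, resting_rec, states4):
        rec, _ = resting_rec
        seg = backfit(rec, states4, min_corr=0.9)
        st = temporal_stats(seg)
        total = sum(st.coverage.values()) + st.unassigned_fraction
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_analyzed_samples_errors(self):
        seg = make_segmentation([0, 0, 0])
        seg.analyzed = np.zeros(3, dtype=bool)
        with pytest.raises(ValueError):
            temporal_stats(seg)


class TestPipelineProperties:
    def test_polarity_flip_invariance(self, resting_rec, states4):
        rec, _ = resting_rec
        flipped = rec.copy(data=-rec.data)

        def run(r):
            seg = backfit(r, states4, min_corr=0.5)
            seg = smooth_labels(seg, 32.0, 10.0)
            return enforce_min_segment(seg, 32.0)

        np.testing.assert_array_equal(run(rec).labels, run(flipped).labels)

    def test_coverage_recovery_across_seeds(self, states4):
        planted = np.array([0.4, 0.3, 0.2, 0.1])
        errors = []
        for seed in range(5):
            rec, gt = synth.simulate_resting(
                states4, duration_s=60.0, snr=10.0, seed=100 + seed, coverages=planted
            )
            seg = backfit(rec, states4, min_corr=0.5)
            seg = smooth_labels(seg, 32.0, 10.0)
            seg = enforce_min_segment(seg, 32.0)
            st = temporal_stats(seg)
            est = np.array([st.coverage[i] for i in range(4)])
            errors.append(np.abs(est - planted).max())
        assert np.mean(errors) < 0.05
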