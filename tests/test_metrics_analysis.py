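"""Entropy, centre-of-activity, DCT modes, correlations, session splits."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.fft import dctn

from neuropong import metrics_analysis as ma
from neuropong.game_world import GameEvent, RallyRecord
from neuropong.motor_decoding import GRID_SIZE, N_CHANNELS
from neuropong.sensory_coding import SAMPLE_RATE
from neuropong.signal_chain import SpikeEvent


def events_from(channels, samples, amp=-10.0):
    return (np.asarray(channels), np.asarray(samples),
            np.full(len(channels), amp))


class TestBinaryEntropy:
    @pytest.mark.parametrize("p,h", [(0.0, 0.0), (1.0, 0.0), (0.5, 1.0)])
    def test_known_values(self, p, h):
        assert ma.binary_entropy(p) == pytest.approx(h)

    def test_direct_evaluation_oracle(self):
        expected = -0.25 * np.log2(0.25) - 0.75 * np.log2(0.75)
        assert ma.binary_entropy(0.25) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=1))
    @settings(deadline=None)
    def test_symmetry_and_bounds(self, p):
        h = ma.binary_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(ma.binary_entropy(1 - p), abs=1e-12)
        assert h <= ma.binary_entropy(0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ma.binary_entropy(1.5)


class TestClusteredEntropy:
    def test_scheme_structure(self):
        scheme = ma.default_cluster_scheme()
        assert len(scheme) == 18
        sizes = {len(c) for c in scheme}
        assert sizes == {50}
        flat = np.concatenate(scheme)
        assert len(np.unique(flat)) == 900  # disjoint

    def test_no_spikes_zero_entropy(self):
        series = ma.clustered_entropy(events_from([], []),
                                      duration_samples=SAMPLE_RATE)
        assert series.mean == 0.0

    def test_saturated_raster_zero_entropy(self):
        # every electrode fires in every window: p = 1 everywhere
        scheme = ma.default_cluster_scheme()
        chans, samps = [], []
        for w in range(5):
            for c in np.concatenate(scheme):
                chans.append(c)
                samps.append(w * 2000 + 10)
        series = ma.clustered_entropy(events_from(chans, samps),
                                      duration_samples=5 * 2000)
        assert series.mean == pytest.approx(0.0)

    def test_half_active_gives_unit_entropy(self):
        # exactly 25 of 50 electrodes firing per cluster and window
        scheme = ma.default_cluster_scheme()
        chans = np.concatenate([c[:25] for c in scheme])
        series = ma.clustered_entropy(events_from(chans, np.full(len(chans), 5)),
                                      duration_samples=2000)
        assert series.mean == pytest.approx(1.0)

    def test_hand_computed_mixed_raster(self):
        # one window: cluster 0 has 10/50 active, others silent
        scheme = ma.default_cluster_scheme()
        chans = scheme[0][:10]
        series = ma.clustered_entropy(events_from(chans, np.full(10, 100)),
                                      duration_samples=2000)
        expected = ma.binary_entropy(0.2) / 18
        assert series.mean == pytest.approx(expected)

    def test_relabelling_within_cluster_invariant(self, rng):
        scheme = ma.default_cluster_scheme()
        chans = rng.choice(scheme[4], size=30, replace=True)
        samps = rng.integers(0, 20_000, size=30)
        a = ma.clustered_entropy(events_from(chans, samps),
                                 duration_samples=20_000).mean
        perm = rng.permutation(scheme[4])
        remap = dict(zip(scheme[4], perm))
        b = ma.clustered_entropy(
            events_from([remap[c] for c in chans], samps),
            duration_samples=20_000).mean
        assert a == pytest.approx(b)


class TestNormalizedEntropy:
    def test_zero_entropy_stays_zero(self):
        assert ma.normalized_entropy(0.0, 500.0) == 0.0

    def test_scaling(self):
        assert ma.normalized_entropy(0.8, 400.0) == pytest.approx(0.002)
        assert ma.normalized_entropy(0.8, 800.0) == pytest.approx(0.001)

    def test_zero_count_convention(self):
        out = ma.normalized_entropy(np.array([0.5, 0.5]), np.array([10.0, 0.0]))
        assert out[1] == 0.0

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            ma.normalized_entropy(np.zeros(3), np.zeros(4))


class TestPrePostEntropy:
    def test_no_feedback_events_empty_result(self):
        out = ma.pre_post_feedback_entropy(events_from([], []), [],
                                           duration_samples=10 * SAMPLE_RATE)
        assert len(out["pre"]) == 0

    def test_edge_events_skipped(self):
        out = ma.pre_post_feedback_entropy(
            events_from([0], [100]), [SAMPLE_RATE],  # 1 s in: no 4 s pre
            duration_samples=20 * SAMPLE_RATE)
        assert len(out["pre"]) == 0

    def test_activity_increase_raises_post_entropy(self, rng):
        # sparse pre-window activity, denser post-window activity
        # (p rising toward 0.5 -> entropy rises)
        scheme = ma.default_cluster_scheme()
        onset = 5 * SAMPLE_RATE
        chans, samps = [], []
        for w in range(40):  # pre: 2 electrodes per cluster window
            for cl in scheme:
                chans.extend(cl[:2])
                samps.extend([onset - 4 * SAMPLE_RATE + w * 2000 + 7] * 2)
        for w in range(40):  # post: 10 electrodes
            for cl in scheme:
                chans.extend(cl[:10])
                samps.extend([onset + w * 2000 + 7] * 10)
        out = ma.pre_post_feedback_entropy(events_from(chans, samps), [onset],
                                           duration_samples=10 * SAMPLE_RATE)
        assert out["post"][0] > out["pre"][0]


class TestCenterOfActivity:
    def test_single_electrode(self):
        assert ma.center_of_activity([5.0], [6.0], [2.0]) == (6.0, 2.0)

    def test_hand_evaluation(self):
        counts = [4.0, 1.0]
        assert ma.center_of_activity(counts, [1.0, 6.0], [1.0, 1.0]) == \
            (2.0, 1.0)

    def test_uniform_counts_centroid(self):
        x, y = np.meshgrid(np.arange(5.0), np.arange(5.0))
        ca = ma.center_of_activity(np.ones(25), x.ravel(), y.ravel())
        assert ca == (2.0, 2.0)

    def test_reference_translation_covariance(self, rng):
        counts = rng.uniform(0, 5, 20)
        x, y = rng.uniform(0, 30, 20), rng.uniform(0, 30, 20)
        ca0 = ma.center_of_activity(counts, x, y)
        ca1 = ma.center_of_activity(counts, x, y, ref=(3.0, -2.0))
        assert ca1[0] == pytest.approx(ca0[0] - 3.0)
        assert ca1[1] == pytest.approx(ca0[1] + 2.0)

    def test_permutation_invariance(self, rng):
        counts = rng.uniform(0, 5, 20)
        x, y = rng.uniform(0, 30, 20), rng.uniform(0, 30, 20)
        perm = rng.permutation(20)
        a = ma.center_of_activity(counts, x, y)
        b = ma.center_of_activity(counts[perm], x[perm], y[perm])
        assert a == pytest.approx(b)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError):
            ma.center_of_activity([0.0, 0.0], [1.0, 2.0], [1.0, 2.0])


class TestPlasticityScore:
    def _stationary_ca(self, rng, n_bins, spread=2.0):
        return rng.normal([10.0, 12.0], spread, size=(n_bins, 2))

    def test_identical_cas_zero_scores(self):
        ca = np.tile([5.0, 5.0], (1200, 1))
        res = ma.plasticity_score(ca, ca)
        assert res.gameplay_score == pytest.approx(0.0)
        assert res.rest_score == pytest.approx(0.0)

    def test_duration_requirement(self, rng):
        short = self._stationary_ca(rng, 300)
        with pytest.raises(ValueError):
            ma.plasticity_score(short, self._stationary_ca(rng, 1200))

    def test_shifted_activity_raises_gameplay_score(self, rng):
        rest = self._stationary_ca(rng, 1200)
        shifted = rest + np.array([6.0, 0.0])  # CA displaced toward motor side
        res = ma.plasticity_score(shifted, rest)
        assert res.gameplay_score > res.rest_score

    def test_null_calibration_over_seeds(self):
        # swapping which stationary draw plays the "gameplay" role leaves
        # the score's expectation unchanged: no spurious plasticity when
        # gameplay and rest come from the same process
        diffs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            a = self._stationary_ca(r, 1200)
            b = self._stationary_ca(r, 1200)
            c = self._stationary_ca(r, 1200)
            diffs.append(ma.plasticity_score(a, b).gameplay_score
                         - ma.plasticity_score(c, b).gameplay_score)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-3


class TestDctModes:
    def test_uniform_image_no_asymmetry(self):
        modes = ma.dct_modes(np.full((8, 8), 3.0))
        for (u, v) in ma.ASYMMETRY_MODES:
            assert modes[(u, v)] == pytest.approx(0.0, abs=1e-12)

    def test_separable_gradient(self):
        img = np.tile(np.linspace(1, 5, 8), (8, 1))  # varies along columns
        modes = ma.dct_modes(img)
        assert modes[(0, 1)] > 1e-3      # horizontal-axis asymmetry
        assert modes[(1, 0)] == pytest.approx(0.0, abs=1e-9)

    def test_brute_force_dct_oracle(self, rng):
        img = rng.uniform(1, 4, size=(6, 6))
        modes = ma.dct_modes(img)
        # direct basis-function summation (orthonormal type-II DCT)
        n = 6
        for (u, v) in [(0, 1), (2, 0), (1, 1)]:
            basis_u = np.cos(np.pi * u * (2 * np.arange(n) + 1) / (2 * n))
            basis_v = np.cos(np.pi * v * (2 * np.arange(n) + 1) / (2 * n))
            cu = np.sqrt((1 if u == 0 else 2) / n)
            cv = np.sqrt((1 if v == 0 else 2) / n)
            coef = cu * cv * basis_u @ img @ basis_v
            assert modes[(u, v)] == pytest.approx(abs(coef) / img.mean(),
                                                  rel=1e-9)

    def test_scale_invariance(self, rng):
        img = rng.uniform(1, 4, size=(8, 8))
        a, b = ma.dct_modes(img), ma.dct_modes(img * 17.0)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ma.dct_modes(np.zeros((4, 4)))


class TestLaggedCrossCorrelation:
    def test_exact_shift_gives_unity(self, rng):
        a = rng.poisson(5, size=500).astype(float)
        b = np.roll(a, 1)
        assert ma.lagged_cross_correlation(a[:-1], b[:-1]) == pytest.approx(1.0)

    def test_negated_shift(self, rng):
        a = rng.poisson(5, size=500).astype(float)
        b = np.roll(-a, 1)
        assert ma.lagged_cross_correlation(a[:-1], b[:-1]) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        n = 4000
        a, b = rng.poisson(5, n).astype(float), rng.poisson(5, n).astype(float)
        assert abs(ma.lagged_cross_correlation(a, b)) < 3 / np.sqrt(n)

    def test_constant_series_flagged(self):
        with pytest.raises(ValueError):
            ma.lagged_cross_correlation(np.ones(100), np.arange(100.0))

    def test_spearman_variant(self, rng):
        a = rng.poisson(5, 500).astype(float)
        r = ma.lagged_cross_correlation(a, np.roll(a, 1), method="spearman")
        assert r == pytest.approx(1.0, abs=0.02)


class TestExclusiveMotorEvents:
    def test_alternating_regions_fraction_one(self, layout):
        chans, samps = [], []
        for b in range(10):
            src = layout.motor1_channels if b % 2 else layout.motor2_channels
            chans.append(src[0])
            samps.append(b * SAMPLE_RATE + 50)
        frac = ma.exclusive_motor_events(events_from(chans, samps), layout,
                                         duration_samples=10 * SAMPLE_RATE)
        assert frac == 1.0

    def test_both_regions_every_bin_zero(self, layout):
        chans, samps = [], []
        for b in range(10):
            chans += [layout.motor1_channels[0], layout.motor2_channels[0]]
            samps += [b * SAMPLE_RATE + 50] * 2
        frac = ma.exclusive_motor_events(events_from(chans, samps), layout,
                                         duration_samples=10 * SAMPLE_RATE)
        assert frac == 0.0

    def test_constructed_fraction(self, layout):
        # 30 exclusive bins out of 100
        chans, samps = [], []
        for b in range(30):
            chans.append(layout.motor1_channels[0])
            samps.append(b * SAMPLE_RATE + 5)
        frac = ma.exclusive_motor_events(events_from(chans, samps), layout,
                                         duration_samples=100 * SAMPLE_RATE)
        assert frac == pytest.approx(0.30)

    def test_above_noise_criterion(self, layout):
        # small-amplitude events (>-5 uV) do not qualify
        evs = events_from([layout.motor1_channels[0]], [50], amp=-3.0)
        frac = ma.exclusive_motor_events(evs, layout,
                                         duration_samples=SAMPLE_RATE)
        assert frac == 0.0


class TestSymmetryDeviation:
    def test_z_score_identities(self):
        assert ma.symmetry_deviation(5.0, 5.0, 0.0, 1.0) == 0.0
        assert ma.symmetry_deviation(8.0, 5.0, 3.0, 1.0) == 0.0
        assert ma.symmetry_deviation(9.0, 5.0, 3.0, 1.0) == 1.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            ma.symmetry_deviation(1.0, 2.0, 0.0, 0.0)


class TestSplitTimepoints:
    def _records(self, end_minutes):
        return [RallyRecord(i, 1, 0, int(m * 60 * 100))
                for i, m in enumerate(end_minutes)]

    def test_assignment(self):
        recs = self._records([3.0, 5.5, 12.0, 19.9])
        t1, t2 = ma.split_timepoints(recs, 20 * 60 * 100)
        assert [r.rally_index for r in t1] == [0]
        assert [r.rally_index for r in t2] == [2, 3]  # 5.5 min in the gap

    def test_short_session_scales_with_warning(self):
        recs = self._records([1.0, 8.0])
        with pytest.warns(UserWarning):
            t1, t2 = ma.split_timepoints(recs, 10 * 60 * 100)
        assert [r.rally_index for r in t1] == [0]
        assert [r.rally_index for r in t2] == [1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ma.split_timepoints([], 1000)


class TestEventRallyRecords:
    def test_open_loop_stream_split_at_misses(self):
        events = [GameEvent("serve", 0), GameEvent("paddle_hit", 50),
                  GameEvent("paddle_hit", 150), GameEvent("miss", 250),
                  GameEvent("miss", 400), GameEvent("paddle_hit", 500)]
        recs = ma.event_rally_records(events)
        assert [r.hits for r in recs] == [2, 0]
        assert [r.end_tick for r in recs] == [250, 400]


class TestOutlierFilter:
    def test_extreme_value_dropped(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 500), [50.0]])
        kept = ma.filter_outliers(vals)
        assert 50.0 not in kept
        assert len(kept) >= 498
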