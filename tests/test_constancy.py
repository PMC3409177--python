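"""Content-constancy statistics: smoothing, range over mean, SI, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from hypothesis.extra import numpy as st_np

from synaptenacity import (
    GeneratorParams,
    PunctumTrace,
    compare_distributions,
    compare_si_curves,
    loss_rate,
    normalized_si_curve,
    range_over_mean,
    shuffled_si_floor,
    si_endpoint,
    similarity_index,
    simulate_trace_population,
    smooth,
    smooth_trace,
)
from synaptenacity.datatypes import TraceStatus
from synaptenacity.errors import InsufficientDataError, ParameterError
from tests.conftest import make_record

positive_vectors = st_np.arrays(
    np.float64,
    st_hyp.integers(min_value=2, max_value=30),
    elements=st_hyp.floats(min_value=0.01, max_value=1e4),
)


class TestSmooth:
    def test_constant_trace_unchanged(self):
        assert np.allclose(smooth(np.full(9, 3.5), 5), 3.5)

    def test_impulse_window_means_including_boundaries(self):
        x = np.array([0, 0, 0, 0, 5, 0, 0, 0, 0], dtype=float)
        out = smooth(x, 5)
        # center: full 5-point window; neighbours: symmetric truncated windows
        assert out[4] == pytest.approx(1.0)
        assert out[3] == pytest.approx(1.0)  # window [1..5]
        assert out[5] == pytest.approx(1.0)  # window [3..7]
        assert out[2] == pytest.approx(1.0)  # window [0..4]
        assert out[1] == pytest.approx(0.0)  # window [0..2]
        assert out[0] == pytest.approx(0.0)  # window [0]

    def test_ramp_boundary_windows_hand_computed(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        out = smooth(x, 5)
        assert np.allclose(out, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_width_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(smooth(x, 1), x)

    def test_even_width_rejected(self):
        with pytest.raises(ParameterError):
            smooth(np.ones(10), 4)

    def test_smooth_trace_preserves_metadata(self, wt_record):
        tr = wt_record.traces[0]
        out = smooth_trace(tr, 5)
        assert out.punctum_id == tr.punctum_id
        assert out.status == tr.status
        assert np.array_equal(out.t, tr.t)


class TestRangeOverMean:
    def test_constant_trace_is_zero(self):
        assert range_over_mean(np.full(20, 7.0)).value == 0.0

    def test_hand_computed_example(self):
        # smoothed series [8, 10, 12] -> (12-8)/10
        assert range_over_mean(np.array([8.0, 10.0, 12.0]), width=1).value == pytest.approx(0.4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(positive_vectors, st_hyp.floats(min_value=0.01, max_value=100.0))
    def test_scale_and_reversal_invariance(self, values, k):
        base = range_over_mean(values).value
        assert range_over_mean(values * k).value == pytest.approx(base, rel=1e-9)
        assert range_over_mean(values[::-1]).value == pytest.approx(base, rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(InsufficientDataError):
            range_over_mean(np.zeros(10))


class TestSimilarityIndex:
    def test_identical_vectors(self):
        g = np.array([1.0, 2.0, 3.0])
        assert similarity_index(g, g) == pytest.approx(1.0)

    def test_positive_scalar_invariance_machine_precision(self):
        g = np.array([1.0, 2.0, 3.0, 0.5])
        for c in (0.5, 2.0, 1e-3, 1e4):
            assert similarity_index(g, c * g) == pytest.approx(1.0, abs=1e-14)

    def test_orthogonal_vectors(self):
        assert similarity_index(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(positive_vectors.filter(lambda v: v.size >= 2))
    def test_symmetry_and_range_for_positive_data(self, g):
        rng = np.random.default_rng(0)
        h = g * np.exp(rng.normal(0, 0.5, g.size))
        si = similarity_index(g, h)
        assert si == pytest.approx(similarity_index(h, g), abs=1e-14)
        assert 0.0 < si <= 1.0 + 1e-12

    def test_shared_bleach_factor_leaves_si_unchanged(self):
        rng = np.random.default_rng(2)
        M = np.exp(rng.normal(np.log(100), 0.6, (12, 20)))
        t = np.arange(20.0)
        bleached = M * np.exp(-0.01 * t)[None, :]
        for k in range(20):
            assert similarity_index(M[:, 0], M[:, k]) == pytest.approx(
                similarity_index(bleached[:, 0], bleached[:, k]), abs=1e-12
            )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(np.zeros(3), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(np.ones(3), np.ones(4))


class TestShuffledFloor:
    def test_rotation_invariant_vector(self):
        g0 = np.array([1.0, 5.0, 2.0, 4.0])
        flat = np.full(4, 3.0)
        expected = similarity_index(g0, np.ones(4))
        assert shuffled_si_floor(g0, flat) == pytest.approx(expected, abs=1e-14)

    def test_length_three_exhaustive_hand_value(self):
        g = np.array([1.0, 2.0, 3.0])
        # both nonzero rotations give SI = 11/14
        assert shuffled_si_floor(g, g) == pytest.approx(11.0 / 14.0)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_over_all_rotations(self, n):
        rng = np.random.default_rng(n)
        g0 = np.exp(rng.normal(0, 0.7, n))
        g_last = np.exp(rng.normal(0, 0.7, n))
        brute = np.mean(
            [similarity_index(g0, np.roll(g_last, k)) for k in range(1, n)]
        )
        assert shuffled_si_floor(g0, g_last, n_shuffles=10) == pytest.approx(brute, abs=1e-14)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(3, 30)
            g0 = np.exp(rng.normal(0, 1.0, n))
            gl = np.exp(rng.normal(0, 1.0, n))
            assert shuffled_si_floor(g0, gl, seed=int(rng.integers(1e6))) <= 1.0 + 1e-12

    def test_subsampled_offsets_are_seeded(self):
        rng = np.random.default_rng(4)
        g0 = np.exp(rng.normal(0, 1.0, 40))
        gl = np.exp(rng.normal(0, 1.0, 40))
        a = shuffled_si_floor(g0, gl, n_shuffles=10, seed=5)
        b = shuffled_si_floor(g0, gl, n_shuffles=10, seed=5)
        c = shuffled_si_floor(g0, gl, n_shuffles=10, seed=6)
        assert a == b
        assert a != c

    def test_aligned_complementary_offset_equals_raw_si(self):
        # circular autocorrelation is symmetric (R(k) = R(n-k)); when g_last is
        # g0 rotated by 1, the single offset n-2 rotates it to lag -1, whose SI
        # equals the raw SI at lag 1 -> a floor exactly equal to raw SI.
        rng = np.random.default_rng(12)
        g0 = np.exp(rng.normal(0, 0.8, 5))
        g_last = np.roll(g0, 1)
        raw = similarity_index(g0, g_last)
        floor = shuffled_si_floor(g0, g_last, offsets=[3])  # 1 + 3 = 4 = -1 mod 5
        assert floor == pytest.approx(raw, abs=1e-14)

    def test_too_short_vectors_rejected(self):
        with pytest.raises(InsufficientDataError):
            shuffled_si_floor(np.ones(2), np.ones(2))


class TestNormalizedSICurve:
    def test_starts_at_one(self, wt_record):
        curve = normalized_si_curve(wt_record)
        assert curve.si_raw[0] == pytest.approx(1.0)
        assert curve.si_norm[0] == pytest.approx(1.0)

    def test_zero_fluctuation_record_stays_at_one(self):
        params = GeneratorParams(
            n_puncta=10,
            n_timepoints=15,
            fluctuation_sd=0.0,
            reconfiguration_sd=0.0,
            bleach_rate=2e-3,
            loss_prob=0.0,
            measurement_noise_sd=0.0,
            seed=1,
        )
        records, _ = simulate_trace_population(params, "wt")
        curve = normalized_si_curve(records[0])
        assert np.allclose(curve.si_raw, 1.0, atol=1e-12)
        assert np.allclose(curve.si_norm, 1.0, atol=1e-9)

    def test_rotated_final_vector_with_exhaustive_floor(self):
        # length-3 identity: floor = (raw + 1)/2, so the normalized endpoint is
        # exactly -1 whenever the final vector is a nonzero rotation of g0.
        rng = np.random.default_rng(3)
        g0 = np.exp(rng.normal(np.log(100), 0.5, 3))
        M = np.linspace(g0, np.roll(g0, 1), 6).T  # (3 puncta, 6 time points)
        curve = normalized_si_curve(make_record(M))
        raw_end = similarity_index(g0, np.roll(g0, 1))
        assert curve.si_shuffled == pytest.approx((raw_end + 1.0) / 2.0, abs=1e-12)
        assert curve.si_norm[-1] == pytest.approx(-1.0, abs=1e-9)

    def test_heavy_reconfiguration_endpoint_near_floor(self):
        endpoints = []
        for seed in range(5):
            params = GeneratorParams(
                n_puncta=60,
                n_timepoints=40,
                reconfiguration_sd=0.25,
                fluctuation_sd=0.02,
                loss_prob=0.0,
                measurement_noise_sd=0.0,
                seed=seed,
            )
            records, _ = simulate_trace_population(params, "wt")
            endpoints.append(si_endpoint(normalized_si_curve(records[0])))
        assert abs(float(np.mean(endpoints))) < 0.3

    def test_si_decay_monotone_in_reconfiguration_sd(self):
        means = []
        for rc in (0.0, 0.02, 0.06, 0.15):
            endpoints = []
            for seed in range(4):
                params = GeneratorParams(
                    n_puncta=50,
                    n_timepoints=40,
                    reconfiguration_sd=rc,
                    fluctuation_sd=0.02,
                    loss_prob=0.0,
                    measurement_noise_sd=0.0,
                    seed=seed,
                )
                records, _ = simulate_trace_population(params, "wt")
                endpoints.append(si_endpoint(normalized_si_curve(records[0])))
            means.append(float(np.mean(endpoints)))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_excludes_lost_puncta_and_requires_three_tracked(self):
        M = np.exp(np.random.default_rng(0).normal(np.log(50), 0.4, (4, 8)))
        rec = make_record(M)
        rec.traces[0].status = TraceStatus.LOST
        rec.traces[0].loss_time = 30.0
        rec.traces[1].status = TraceStatus.REJECTED_SPLIT_MERGE
        with pytest.raises(InsufficientDataError):
            normalized_si_curve(rec)
        rec.traces[1].status = TraceStatus.TRACKED
        curve = normalized_si_curve(rec)
        assert curve.n_puncta == 3


class TestLossRate:
    def test_no_losses(self, wt_record):
        for tr in wt_record.traces:
            tr.status = TraceStatus.TRACKED
            tr.loss_time = None
        assert loss_rate(wt_record) == 0.0

    def test_one_in_ten_with_rejections_excluded(self):
        M = np.full((12, 5), 50.0)
        rec = make_record(M)
        rec.traces[0].status = TraceStatus.LOST
        rec.traces[0].loss_time = 20.0
        rec.traces[10].status = TraceStatus.REJECTED_SPLIT_MERGE
        rec.traces[11].status = TraceStatus.REJECTED_SPLIT_MERGE
        assert loss_rate(rec) == pytest.approx(0.1)

    def test_consistent_with_generator_truth(self):
        params = GeneratorParams(n_puncta=800, n_timepoints=10, loss_prob=0.09, seed=21)
        records, _ = simulate_trace_population(params, "wt")
        sd = np.sqrt(0.09 * 0.91 / 800)
        assert abs(loss_rate(records[0]) - 0.09) <= 3 * sd

    def test_empty_record_rejected(self):
        rec = make_record(np.full((2, 5), 50.0))
        for tr in rec.traces:
            tr.status = TraceStatus.REJECTED_SPLIT_MERGE
        with pytest.raises(InsufficientDataError):
            loss_rate(rec)


class TestComparisons:
    def test_identical_samples_statistic_zero(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        res = compare_distributions(a, a)
        assert res.statistic == 0.0

    def test_disjoint_supports_statistic_one(self):
        res = compare_distributions(np.linspace(0.1, 0.3, 10), np.linspace(5.0, 7.0, 10))
        assert res.statistic == 1.0
        assert res.pvalue < 0.05

    def test_half_shifted_uniforms_statistic_near_half(self):
        # true sup-CDF gap is 0.5; the empirical sup has a small positive bias
        rng = np.random.default_rng(8)
        a = rng.uniform(0.0, 1.0, 1000)
        b = rng.uniform(0.5, 1.5, 1000)
        res = compare_distributions(a, b)
        assert 0.5 - 0.05 <= res.statistic <= 0.5 + 0.1

    def test_group_summaries_reported(self):
        res = compare_distributions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        assert res.mean_a == pytest.approx(2.0)
        assert res.mean_b == pytest.approx(5.5)
        assert res.sd_a == pytest.approx(1.0)
        assert res.n_a == 3 and res.n_b == 4

    def test_si_curves_self_comparison(self):
        params = GeneratorParams(n_puncta=20, n_timepoints=15, seed=2, loss_prob=0.0)
        records, _ = simulate_trace_population(params, "wt", n_neurons=3)
        curves = [normalized_si_curve(r) for r in records]
        res = compare_si_curves(curves, curves)
        assert res.statistic == 0.0

    def test_insufficient_curves_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_distributions([1.0], [1.0, 2.0])
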