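import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pihi.cohort_io import VitalSequence
from pihi.icv import (CVMatrix, NormalizationBounds, assign_binary, assign_class,
                      compute_cv, compute_cv_matrix, entropy_weights, fit_bounds,
                      integrate_icv, normalize_icv)


def _seq(pid, channel, values, cadence=10.0):
    k = len(values)
    half = k // 2
    times = np.concatenate([-cadence * np.arange(half, 0, -1),
                            cadence * np.arange(1, k - half + 1)])
    return VitalSequence(pid, channel, times, np.asarray(values, dtype=float))


class TestComputeCV:
    def test_constant_sequence_is_zero(self):
        assert compute_cv([80.0] * 60) == 0.0

    def test_population_divisor(self):
        # population std sqrt(200/3) over mean 110
        expected = math.sqrt(200.0 / 3.0) / 110.0
        assert compute_cv([100.0, 110.0, 120.0]) == pytest.approx(expected, abs=1e-12)

    def test_accepts_vital_sequence(self):
        seq = _seq("P0", "SP", [100.0, 110.0, 120.0, 110.0])
        assert compute_cv(seq) == pytest.approx(compute_cv(seq.values))

    @given(hnp.arrays(np.float64, st.integers(2, 50),
                      elements=st.floats(1.0, 500.0)),
           st.floats(0.01, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, values, c):
        assert compute_cv(c * values) == pytest.approx(compute_cv(values), abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError, match="2 points"):
            compute_cv([100.0])

    def test_nonpositive_mean(self):
        with pytest.raises(ValueError, match="positive"):
            compute_cv(np.array([-1.0, 1.0]))


class TestComputeCVMatrix:
    def test_matrix_matches_per_sequence_calls(self):
        rng = np.random.default_rng(4)
        seqs = [_seq(p, c, 100 + 10 * rng.random(60))
                for p in ("A", "B") for c in ("SP", "DP", "HR")]
        cv, excluded = compute_cv_matrix(seqs)
        assert cv.values.shape == (2, 3) and not excluded
        for i, pid in enumerate(cv.patient_ids):
            for s, channel in enumerate(cv.channels):
                ref = next(q for q in seqs if q.patient_id == pid and q.channel == channel)
                assert cv.values[i, s] == pytest.approx(compute_cv(ref), abs=1e-15)

    def test_short_channel_excludes_patient(self):
        rng = np.random.default_rng(5)
        seqs = [_seq("A", c, 100 + rng.random(60)) for c in ("SP", "DP", "HR")]
        seqs += [_seq("B", c, 100 + rng.random(10 if c == "HR" else 60))
                 for c in ("SP", "DP", "HR")]
        cv, excluded = compute_cv_matrix(seqs, min_points=54)
        assert cv.patient_ids == ["A"]
        assert excluded[0][0] == "B" and "HR" in excluded[0][1]

    def test_missing_channel_fatal_policy(self):
        seqs = [_seq("A", c, 100 + np.arange(60)) for c in ("SP", "DP")]
        with pytest.raises(ValueError, match="missing channel"):
            compute_cv_matrix(seqs, on_incomplete="fatal")

    def test_window_restriction(self):
        # points outside +/- 100 s must not contribute
        values = 100.0 + np.arange(60.0)
        seqs_full = [_seq("A", c, values) for c in ("SP", "DP", "HR")]
        cv, _ = compute_cv_matrix(seqs_full, window_s=100.0, min_points=2)
        inside = [v for t, v in zip(seqs_full[0].times, values) if abs(t) <= 100]
        assert cv.values[0, 0] == pytest.approx(compute_cv(inside), abs=1e-15)


class TestEntropyWeights:
    def test_homogeneous_column_gets_zero_weight(self):
        y = np.column_stack([np.full(10, 0.25),
                             np.linspace(0.1, 0.5, 10),
                             np.linspace(0.2, 0.3, 10)])
        w = entropy_weights(CVMatrix(y, [f"P{i}" for i in range(10)]))
        assert w.raw[0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_share_equally(self):
        col = np.linspace(0.1, 0.6, 8)
        y = np.column_stack([col, col, col])
        w = entropy_weights(CVMatrix(y, [f"P{i}" for i in range(8)]))
        np.testing.assert_allclose(w.normalized, [1 / 3] * 3, atol=1e-12)

    def test_two_patient_hand_value(self):
        y = np.array([[0.1, 0.3], [0.3, 0.3]])
        w = entropy_weights(CVMatrix(y, ["A", "B"], ("SP", "DP")))
        expected = 1.0 + (0.25 * math.log(0.25) + 0.75 * math.log(0.75)) / math.log(2)
        assert w.raw[0] == pytest.approx(expected, abs=1e-12)
        assert w.raw[1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_column_warns_and_gets_zero(self):
        y = np.column_stack([np.zeros(5), np.linspace(0.1, 0.5, 5)])
        with pytest.warns(UserWarning, match="all-zero"):
            w = entropy_weights(CVMatrix(y, list("abcde"), ("SP", "DP")))
        assert w.raw[0] == 0.0

    def test_all_zero_fatal(self):
        y = np.zeros((5, 3))
        with pytest.raises(ValueError, match="undefined"):
            entropy_weights(CVMatrix(y, list("abcde")))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_raw_in_unit_interval_and_normalized_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random((rng.integers(2, 30), 3)) * 0.5 + 1e-6
        w = entropy_weights(CVMatrix(y, [f"P{i}" for i in range(len(y))]))
        assert np.all(w.raw >= -1e-12) and np.all(w.raw <= 1 + 1e-12)
        assert w.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_log_base_independence(self):
        # the 1/log(N) prefactor cancels the base when applied consistently
        rng = np.random.default_rng(3)
        y = rng.random((12, 3)) + 0.01
        w_e = entropy_weights(CVMatrix(y, [f"P{i}" for i in range(12)]))
        p = y / y.sum(axis=0)
        w_10 = 1 + np.sum(p * np.log10(p), axis=0) / np.log10(12)
        np.testing.assert_allclose(w_e.raw, w_10, atol=1e-12)

    def test_shrinking_dispersion_shrinks_weight(self):
        base = np.linspace(0.1, 0.5, 10)
        other = np.linspace(0.2, 0.4, 10)
        weights = []
        for eps in (1.0, 0.5, 0.25, 0.1, 0.01, 0.0):
            col = 0.3 + eps * (base - 0.3)
            y = np.column_stack([col, other, other[::-1]])
            w = entropy_weights(CVMatrix(y, [f"P{i}" for i in range(10)]))
            weights.append(w.raw[0])
        assert all(a > b for a, b in zip(weights, weights[1:]))
        assert weights[-1] == pytest.approx(0.0, abs=1e-12)


class TestIntegrateICV:
    def test_constant_row_is_fixed_point(self):
        y = np.array([[0.3, 0.3, 0.3]])
        w = entropy_weights(CVMatrix(np.random.default_rng(0).random((5, 3)) + 0.01,
                                     [f"P{i}" for i in range(5)]))
        cv = CVMatrix(y, ["A"])
        assert integrate_icv(cv, w)[0] == pytest.approx(0.3, abs=1e-12)

    def test_degenerate_weight_selects_channel(self):
        from pihi.icv import WeightVector
        cv = CVMatrix(np.array([[0.1, 0.5, 0.9]]), ["A"])
        w = WeightVector(raw=np.array([1.0, 0, 0]), normalized=np.array([1.0, 0, 0]))
        assert integrate_icv(cv, w)[0] == 0.1

    def test_dot_product_with_published_style_weights(self):
        from pihi.icv import WeightVector
        cv = CVMatrix(np.array([[0.1, 0.2, 0.3]]), ["A"])
        w = WeightVector(raw=None, normalized=np.array([0.342, 0.355, 0.303]))
        assert integrate_icv(cv, w)[0] == pytest.approx(0.1961, abs=1e-10)

    def test_dimension_mismatch_fatal(self):
        from pihi.icv import WeightVector
        cv = CVMatrix(np.array([[0.1, 0.2, 0.3]]), ["A"])
        w = WeightVector(raw=None, normalized=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="does not match"):
            integrate_icv(cv, w)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_convexity_bound(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random((rng.integers(2, 20), 3)) + 1e-6
        cv = CVMatrix(y, [f"P{i}" for i in range(len(y))])
        z = integrate_icv(cv, entropy_weights(cv))
        assert np.all(z >= y.min(axis=1) - 1e-15)
        assert np.all(z <= y.max(axis=1) + 1e-15)


class TestNormalization:
    def test_bounds_from_values(self):
        b = fit_bounds([0.0055, 0.2, 0.6746])
        assert (b.icv_min, b.icv_max) == (0.0055, 0.6746)
        assert fit_bounds([0.0, 1.0]) == NormalizationBounds(0.0, 1.0)

    def test_bounds_match_scan(self):
        vals = np.random.default_rng(9).random(1000)
        b = fit_bounds(vals)
        lo = hi = vals[0]
        for v in vals[1:]:
            lo, hi = min(lo, v), max(hi, v)
        assert (b.icv_min, b.icv_max) == (lo, hi)

    def test_degenerate_bounds_fatal(self):
        with pytest.raises(ValueError, match="identical"):
            fit_bounds([0.3, 0.3, 0.3])

    def test_endpoints_and_midpoint(self):
        b = NormalizationBounds(0.0055, 0.6746)
        assert normalize_icv(0.0055, b) == 0.0
        assert normalize_icv(0.6746, b) == 1.0
        mid = (0.0055 + 0.6746) / 2
        assert normalize_icv(mid, b) == pytest.approx(0.5, abs=1e-12)

    def test_out_of_range_clipped_with_warning(self):
        b = NormalizationBounds(0.0, 1.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert normalize_icv(1.5, b) == 1.0
        with pytest.warns(UserWarning, match="clipped"):
            assert normalize_icv(-0.1, b) == 0.0

    def test_bounds_round_trip_json(self, tmp_path):
        b = NormalizationBounds(0.0055, 0.6746)
        b.to_json(tmp_path / "b.json")
        assert NormalizationBounds.from_json(tmp_path / "b.json") == b


class TestClassesAndThreshold:
    @pytest.mark.parametrize("norm,expected", [
        (0.0, 1), (0.19999, 1), (0.2, 2), (0.39999, 2), (0.4, 3),
        (0.6, 4), (0.79999, 4), (0.8, 5), (1.0, 5),
    ])
    def test_bin_edges(self, norm, expected):
        assert assign_class(norm) == expected

    def test_out_of_range_invalid(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                assign_class(bad)

    @pytest.mark.parametrize("norm,expected", [
        (0.3, "instable"), (0.29, "stable"), (0.0, "stable"), (1.0, "instable"),
    ])
    def test_binary_threshold(self, norm, expected):
        assert assign_binary(norm) == expected

    def test_vectorised_consistency(self):
        norms = np.linspace(0, 1, 101)
        classes = assign_class(norms)
        assert all(assign_class(float(v)) == c for v, c in zip(norms, classes))


class TestMonotoneResponse:
    def test_post_intubation_step_increases_index(self):
        """A growing post-intubation excursion in one channel must raise the
        raw index strictly."""
        from pihi.icv import WeightVector
        times = np.concatenate([-10.0 * np.arange(30, 0, -1), 10.0 * np.arange(1, 31)])
        post = times > 0
        raws = []
        for step in (0.0, 5.0, 10.0, 20.0, 40.0):
            values_sp = np.full(60, 120.0)
            values_sp[post] += step
            cvs = np.array([[compute_cv(values_sp),
                             compute_cv(np.full(60, 75.0) + 0.001 * np.arange(60)),
                             compute_cv(np.full(60, 80.0) + 0.001 * np.arange(60))]])
            cv = CVMatrix(cvs, ["A"])
            w = WeightVector(raw=None, normalized=np.array([1 / 3] * 3))
            raws.append(integrate_icv(cv, w)[0])
        assert all(a < b for a, b in zip(raws, raws[1:]))
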