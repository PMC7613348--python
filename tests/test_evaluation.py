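"""Goodness-of-fit statistics: closed forms, oracles, report consistency."""

import numpy as np
import pytest

from sifemu import (
    SpectralMatrix,
    absolute_error_map,
    error_summary,
    evaluate_pairs,
    make_band_grid,
    nrmse,
    r_squared,
    rmse_per_band,
)
from sifemu.errors import ArgumentError, ShapeError


def _mat(values, grid=None):
    values = np.atleast_2d(values)
    grid = grid or make_band_grid(751.0, 751.0 + values.shape[1] - 1, values.shape[1])
    return SpectralMatrix(values, grid)


class TestRMSE:
    def test_perfect_agreement_is_zero(self, rng):
        X = _mat(rng.normal(size=(6, 4)))
        assert np.all(rmse_per_band(X, X) == 0.0)

    def test_closed_form_single_band(self):
        from sifemu import BandGrid
        grid = BandGrid(np.array([760.0]))
        ref = _mat(np.array([[0.0], [2.0]]), grid)
        est = _mat(np.array([[1.0], [3.0]]), grid)
        assert rmse_per_band(ref, est)[0] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        r = rng.normal(size=(7, 5))
        e = rng.normal(size=(7, 5))
        result = rmse_per_band(r, e)
        for b in range(5):
            acc = 0.0
            for i in range(7):
                acc += (e[i, b] - r[i, b]) ** 2
            assert result[b] == pytest.approx(np.sqrt(acc / 7), abs=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            rmse_per_band(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))


class TestNRMSE:
    def test_uniform_error_half_range(self):
        ref = np.array([[0.0, 2.0], [0.0, 2.0]])
        est = ref + 1.0
        overall, per_band = nrmse(ref, est)
        assert overall == pytest.approx(50.0)
        np.testing.assert_allclose(per_band, 50.0)

    def test_perfect_is_zero(self, rng):
        X = rng.normal(size=(5, 3))
        assert nrmse(X, X)[0] == 0.0

    def test_scale_invariance(self, rng):
        r = rng.normal(size=(6, 4))
        e = r + rng.normal(size=(6, 4))
        assert nrmse(r, e)[0] == pytest.approx(nrmse(10 * r, 10 * e)[0], rel=1e-12)

    def test_denominator_is_global_not_per_band(self):
        # band 0 spans [0, 10], band 1 spans [4, 6]; same error in both bands
        # must give the same NRMSE_lambda because one global range is used
        ref = np.array([[0.0, 4.0], [10.0, 6.0]])
        est = ref + 1.0
        _, per_band = nrmse(ref, est)
        assert per_band[0] == pytest.approx(per_band[1])

    def test_zero_range_rejected(self):
        with pytest.raises(ArgumentError):
            nrmse(np.ones((3, 2)), np.zeros((3, 2)))


class TestRSquared:
    def test_perfect_is_one(self, rng):
        x = rng.normal(size=20)
        assert r_squared(x, x) == 1.0

    def test_mean_predictor_is_zero(self, rng):
        x = rng.normal(size=50)
        assert r_squared(x, np.full(50, x.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_can_be_negative(self, rng):
        x = rng.normal(size=30)
        assert r_squared(x, -5 * x) < 0

    def test_matches_ss_oracle_on_random_vectors(self, rng):
        for _ in range(10):
            ref = rng.normal(size=25)
            est = rng.normal(size=25)
            ss_res = sum((r - e) ** 2 for r, e in zip(ref, est))
            ss_tot = sum((r - ref.mean()) ** 2 for r in ref)
            assert r_squared(ref, est) == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ArgumentError):
            r_squared(np.ones(5), np.zeros(5))


class TestEvaluatePairs:
    def test_perfect_report(self, rng):
        X = _mat(rng.normal(size=(8, 5)))
        report = evaluate_pairs(X, X)
        assert report.rmse == 0.0 and report.nrmse_pct == 0.0
        assert report.r2 == 1.0 and report.r2_at_760nm == 1.0
        assert report.n == 8

    def test_report_reproduces_components(self, rng):
        grid = make_band_grid(751.0, 777.0, 27)
        ref = _mat(rng.normal(size=(40, 27)), grid)
        est = _mat(ref.values + rng.normal(scale=0.2, size=(40, 27)), grid)
        report = evaluate_pairs(ref, est)
        overall, per_band = nrmse(ref, est)
        assert report.nrmse_pct == overall
        np.testing.assert_array_equal(report.rmse_per_band, rmse_per_band(ref, est))
        assert report.r2 == r_squared(ref.values, est.values)
        b760 = grid.index_nearest(760.0)
        assert report.r2_at_760nm == r_squared(ref.values[:, b760], est.values[:, b760])

    def test_permutation_invariance(self, rng):
        grid = make_band_grid(751.0, 777.0, 27)
        ref = rng.normal(size=(15, 27))
        est = ref + rng.normal(size=(15, 27))
        perm = rng.permutation(15)
        a = evaluate_pairs(_mat(ref, grid), _mat(est, grid))
        b = evaluate_pairs(_mat(ref[perm], grid), _mat(est[perm], grid))
        assert a.nrmse_pct == pytest.approx(b.nrmse_pct, rel=1e-12)
        assert a.r2 == pytest.approx(b.r2, rel=1e-12)


class TestErrorMaps:
    def test_identical_cubes_zero_summary(self, sif_pair, rng):
        vals = rng.normal(size=(4, 4, 5)).astype(np.float32)
        ref, est = sif_pair(vals, vals)
        err = absolute_error_map(ref, est, 760.0)
        assert np.all(err == 0.0)
        s = error_summary(err)
        assert (s.median, s.p02, s.p98) == (0.0, 0.0, 0.0)

    def test_constant_offset(self, sif_pair, rng):
        vals = rng.normal(size=(3, 3, 5)).astype(np.float32)
        ref, est = sif_pair(vals, vals + 0.5)
        s = error_summary(absolute_error_map(ref, est, 755.0))
        for v in (s.median, s.p25, s.p75, s.p02, s.p98):
            assert v == pytest.approx(0.5, abs=1e-6)

    def test_spot_check_pixels(self, sif_pair, rng):
        ref_vals = rng.normal(size=(5, 5, 5)).astype(np.float32)
        est_vals = rng.normal(size=(5, 5, 5)).astype(np.float32)
        ref, est = sif_pair(ref_vals, est_vals)
        band = ref.grid.index_nearest(758.0)
        err = absolute_error_map(ref, est, 758.0)
        for r, c in [(0, 0), (2, 4), (4, 1)]:
            assert err[r, c] == pytest.approx(
                float(est_vals[r, c, band]) - float(ref_vals[r, c, band]), abs=1e-7)

    def test_band_outside_grid_raises(self, sif_pair, rng):
        vals = rng.normal(size=(2, 2, 5)).astype(np.float32)
        ref, est = sif_pair(vals, vals)
        with pytest.raises(ArgumentError):
            absolute_error_map(ref, est, 900.0)

    def test_percentiles_ordered(self, rng):
        s = error_summary(rng.normal(size=(20, 20)))
        assert s.p02 <= s.p25 <= s.median <= s.p75 <= s.p98
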