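"""Construction of the six confidence intervals."""

import numpy as np
import pytest
from scipy import stats

import mataboot as mb
from mataboot.boot import BootstrapTails
from mataboot.intervals import _endpoints_vectorized
from mataboot.lognormal import LOG_SCALE_MEAN


def oracle_t_tails(nu, B=20_000):
    """BootstrapTails built from exact t quantiles at plotting positions."""
    q = stats.t.ppf(np.arange(1, B + 1) / (B + 1), df=nu)
    return BootstrapTails(q, B, f"t{nu}")


def grid_scan_limit(estimates, weights, alpha, side, kernel, lo, hi, n=400_001):
    """Independent dense-grid root of the weighted tail equation."""
    grid = np.linspace(lo, hi, n)
    vals = np.array(
        [mb.mata_tail_equation(t, estimates, weights, side, kernel) for t in grid[:: n // 2001]]
    )
    coarse = grid[:: n // 2001]
    # locate sign change on the coarse grid, then refine linearly
    idx = np.argmin(np.abs(vals - alpha))
    lo2, hi2 = coarse[max(idx - 1, 0)], coarse[min(idx + 1, len(coarse) - 1)]
    fine = np.linspace(lo2, hi2, 20001)
    fvals = np.array(
        [mb.mata_tail_equation(t, estimates, weights, side, kernel) for t in fine]
    )
    return fine[np.argmin(np.abs(fvals - alpha))]


class TestFullWald:
    def test_t_quantile_oracle(self):
        iv = mb.full_wald(mb.ModelEstimate(0.0, 1.0, 10), 0.025)
        assert iv.lower == pytest.approx(-2.2281388520, abs=1e-6)
        assert iv.upper == pytest.approx(2.2281388520, abs=1e-6)

    def test_width_vanishes_at_alpha_half(self):
        iv = mb.full_wald(mb.ModelEstimate(1.0, 4.0, 12), 0.499999)
        assert iv.width == pytest.approx(0.0, abs=1e-3)

    def test_large_nu_matches_z_interval(self):
        iv = mb.full_wald(mb.ModelEstimate(0.0, 1.0, 10**6), 0.025)
        assert iv.upper == pytest.approx(1.959964, abs=1e-4)


class TestMaWald:
    def test_single_model_large_nu_is_z_interval(self):
        e = mb.ModelEstimate(2.0, 1.0, 10**6)
        iv = mb.ma_wald([e], mb.WeightVector(np.array([1.0])), 0.025)
        assert iv.lower == pytest.approx(2.0 - 1.959964, abs=1e-4)
        assert iv.upper == pytest.approx(2.0 + 1.959964, abs=1e-4)

    def test_two_model_hand_value(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 10**6), mb.ModelEstimate(2.0, 1.0, 10**6)]
        w = mb.WeightVector(np.array([0.5, 0.5]))
        iv = mb.ma_wald(ests, w, 0.025)
        assert (iv.lower + iv.upper) / 2 == pytest.approx(1.0, abs=1e-9)
        assert iv.width / 2 == pytest.approx(1.959964 * np.sqrt(2.0), rel=1e-3)

    def test_disagreeing_second_model_never_narrows(self):
        e1 = mb.ModelEstimate(0.0, 1.0, 30)
        solo = mb.ma_wald([e1], mb.WeightVector(np.array([1.0])), 0.025)
        for shift in (0.5, 1.0, 3.0):
            pair = [e1, mb.ModelEstimate(shift, 1.0, 30)]
            both = mb.ma_wald(pair, mb.WeightVector(np.array([0.6, 0.4])), 0.025)
            assert both.width >= solo.width - 1e-12


class TestTailEquation:
    def test_centered_single_model_is_half(self):
        e = mb.ModelEstimate(1.3, 0.49, 20)
        w = mb.WeightVector(np.array([1.0]))
        assert mb.mata_tail_equation(1.3, [e], w, "upper", "z") == pytest.approx(0.5)

    def test_upper_equation_strictly_decreasing(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 8), mb.ModelEstimate(1.0, 0.25, 30)]
        w = mb.WeightVector(np.array([0.3, 0.7]))
        grid = np.linspace(-5, 5, 101)
        for kernel in ("z", "t"):
            vals = [mb.mata_tail_equation(t, ests, w, "upper", kernel) for t in grid]
            assert np.all(np.diff(vals) < 0)

    def test_zero_weight_model_irrelevant(self):
        e1 = mb.ModelEstimate(0.0, 1.0, 10)
        e2a = mb.ModelEstimate(5.0, 2.0, 3)
        e2b = mb.ModelEstimate(-7.0, 0.1, 50)
        w = mb.WeightVector(np.array([1.0, 0.0]))
        va = mb.mata_tail_equation(0.7, [e1, e2a], w, "lower", "t")
        vb = mb.mata_tail_equation(0.7, [e1, e2b], w, "lower", "t")
        assert va == pytest.approx(vb, abs=1e-15)


class TestMataWald:
    def test_single_model_t_reduces_to_classical(self):
        e = mb.ModelEstimate(0.0, 1.0, 10)
        w = mb.WeightVector(np.array([1.0]))
        iv = mb.mata_wald([e], w, 0.025, "t")
        assert iv.lower == pytest.approx(-2.2281388520, abs=1e-8)
        assert iv.upper == pytest.approx(2.2281388520, abs=1e-8)

    def test_single_model_z_reduces_to_normal(self):
        e = mb.ModelEstimate(0.0, 1.0, 10)
        w = mb.WeightVector(np.array([1.0]))
        iv = mb.mata_wald([e], w, 0.025, "z")
        assert iv.lower == pytest.approx(-1.9599640, abs=1e-6)
        assert iv.upper == pytest.approx(1.9599640, abs=1e-6)

    def test_degenerate_weights_reduce_to_full_wald(self):
        ests = [mb.ModelEstimate(1.2, 0.36, 14), mb.ModelEstimate(9.9, 1.0, 3)]
        w = mb.WeightVector(np.array([1.0, 0.0]))
        iv = mb.mata_wald(ests, w, 0.025, "t")
        ref = mb.full_wald(ests[0], 0.025)
        assert iv.lower == pytest.approx(ref.lower, abs=1e-8)
        assert iv.upper == pytest.approx(ref.upper, abs=1e-8)

    def test_two_model_grid_scan_oracle(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 8), mb.ModelEstimate(0.8, 0.5, 25)]
        w = mb.WeightVector(np.array([0.45, 0.55]))
        iv = mb.mata_wald(ests, w, 0.025, "t")
        up = grid_scan_limit(ests, w, 0.025, "upper", "t", iv.upper - 0.01, iv.upper + 0.01)
        lo = grid_scan_limit(ests, w, 0.025, "lower", "t", iv.lower - 0.01, iv.lower + 0.01)
        assert iv.upper == pytest.approx(up, abs=1e-6)
        assert iv.lower == pytest.approx(lo, abs=1e-6)

    def test_t_interval_contains_z_interval(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 8), mb.ModelEstimate(0.8, 0.5, 25)]
        w = mb.WeightVector(np.array([0.45, 0.55]))
        t_iv = mb.mata_wald(ests, w, 0.025, "t")
        z_iv = mb.mata_wald(ests, w, 0.025, "z")
        assert t_iv.lower < z_iv.lower
        assert t_iv.upper > z_iv.upper

    def test_solution_satisfies_tail_equation(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            ests = [
                mb.ModelEstimate(rng.normal(), rng.uniform(0.1, 2.0), int(rng.integers(3, 60)))
                for _ in range(4)
            ]
            raw = rng.uniform(0.1, 1.0, 4)
            w = mb.WeightVector(raw / raw.sum())
            iv = mb.mata_wald(ests, w, 0.025, "t")
            assert mb.mata_tail_equation(iv.upper, ests, w, "upper", "t") == pytest.approx(
                0.025, abs=1e-8
            )
            assert mb.mata_tail_equation(iv.lower, ests, w, "lower", "t") == pytest.approx(
                0.025, abs=1e-8
            )


class TestMataSBoot:
    def test_oracle_t_tails_match_mata_wald_t(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 8), mb.ModelEstimate(0.8, 0.5, 25)]
        w = mb.WeightVector(np.array([0.45, 0.55]))
        tails = [oracle_t_tails(8), oracle_t_tails(25)]
        boot_iv = mb.mata_sboot(ests, w, tails, 0.025)
        t_iv = mb.mata_wald(ests, w, 0.025, "t")
        assert boot_iv.lower == pytest.approx(t_iv.lower, rel=5e-3)
        assert boot_iv.upper == pytest.approx(t_iv.upper, rel=5e-3)

    def test_symmetric_tails_give_symmetric_interval(self):
        e = mb.ModelEstimate(2.0, 1.0, 10)
        w = mb.WeightVector(np.array([1.0]))
        iv = mb.mata_sboot([e], w, [oracle_t_tails(10)], 0.025)
        assert (iv.upper - 2.0) == pytest.approx(2.0 - iv.lower, abs=1e-3)

    def test_negatively_skewed_tails_raise_upper_limit(self):
        # shifted-negated chi2 statistics: heavy lower tail for T*
        B = 20_000
        nu = 10
        q = stats.chi2.ppf(np.arange(1, B + 1) / (B + 1), df=4)
        skewed = np.sort(-(q - 4) / np.sqrt(8))  # mean 0, var 1, negative skew
        e = mb.ModelEstimate(0.0, 1.0, nu)
        w = mb.WeightVector(np.array([1.0]))
        iv_skew = mb.mata_sboot([e], w, [BootstrapTails(skewed, B, "sk")], 0.025)
        iv_t = mb.mata_wald([e], w, 0.025, "t")
        assert iv_skew.upper > iv_t.upper

    def test_alpha_below_resolution_rejected(self):
        e = mb.ModelEstimate(0.0, 1.0, 10)
        w = mb.WeightVector(np.array([1.0]))
        tails = oracle_t_tails(10, B=39)
        with pytest.raises(ValueError, match="B >="):
            mb.mata_sboot([e], w, [tails], 0.01)

    def test_solution_satisfies_tail_equation(self):
        ests = [mb.ModelEstimate(0.0, 1.0, 8), mb.ModelEstimate(0.8, 0.5, 25)]
        w = mb.WeightVector(np.array([0.45, 0.55]))
        tails = [oracle_t_tails(8, 999), oracle_t_tails(25, 999)]
        iv = mb.mata_sboot(ests, w, tails, 0.025)
        assert mb.mata_tail_equation(iv.upper, ests, w, "upper", tails) == pytest.approx(
            0.025, abs=1e-8
        )
        assert mb.mata_tail_equation(iv.lower, ests, w, "lower", tails) == pytest.approx(
            0.025, abs=1e-8
        )


class TestVectorizedSolver:
    def test_matches_scalar_solver(self):
        rng = np.random.default_rng(15)
        M, C = 4, 3
        eta = rng.normal(size=(M, C))
        se = rng.uniform(0.2, 1.0, M)
        nu = rng.integers(4, 40, M).astype(float)
        raw = rng.uniform(0.2, 1.0, M)
        w = raw / raw.sum()
        lo, up = _endpoints_vectorized(eta, se, nu, w, 0.025, "t")
        for c in range(C):
            ests = [
                mb.ModelEstimate(eta[m, c], se[m] ** 2, int(nu[m])) for m in range(M)
            ]
            iv = mb.mata_wald(ests, mb.WeightVector(w), 0.025, "t")
            assert lo[c] == pytest.approx(iv.lower, abs=1e-9)
            assert up[c] == pytest.approx(iv.upper, abs=1e-9)

    def test_boot_kernel_matches_scalar_solver(self):
        rng = np.random.default_rng(16)
        M, B, C = 3, 501, 2
        eta = rng.normal(size=(M, C))
        se = rng.uniform(0.3, 1.0, M)
        nu = np.array([8.0, 15.0, 30.0])
        w = np.array([0.2, 0.5, 0.3])
        tails = np.sort(rng.standard_t(10, size=(M, B, C)), axis=1)
        lo, up = _endpoints_vectorized(eta, se, nu, w, 0.025, "boot", tails=tails)
        for c in range(C):
            ests = [
                mb.ModelEstimate(eta[m, c], se[m] ** 2, int(nu[m])) for m in range(M)
            ]
            tl = [BootstrapTails(tails[m, :, c], B, "x") for m in range(M)]
            iv = mb.mata_sboot(ests, mb.WeightVector(w), tl, 0.025)
            assert lo[c] == pytest.approx(iv.lower, abs=1e-9)
            assert up[c] == pytest.approx(iv.upper, abs=1e-9)


class TestPercentileBootstrap:
    def test_order_statistic_positions(self):
        # B = 39, alpha = 0.025 -> 1st and 39th order statistics
        import math

        assert math.ceil(0.025 * 40) == 1
        assert math.ceil(0.975 * 40) == 39

    def test_interval_from_synthetic_data(self, design3, dataset3, models3):
        rng = np.random.default_rng(23)
        iv = mb.percentile_bootstrap(
            dataset3, design3, models3, mb.CellTarget((1, 1, 1)), 999, 0.025, rng
        )
        assert iv.method == "pb"
        assert iv.lower < iv.upper
        # quantile oracle: recompute from the recorded estimates
        from mataboot.intervals import _pb_eta_stars

        full_fit = mb.fit_model(
            models3[-1], design3, np.log(dataset3["response"].to_numpy()), dataset3
        )
        stars = np.sort(
            _pb_eta_stars(full_fit, 999, np.random.default_rng(23))[:, 0]
        )
        assert iv.lower == pytest.approx(stars[int(np.ceil(0.025 * 1000)) - 1])
        assert iv.upper == pytest.approx(stars[int(np.ceil(0.975 * 1000)) - 1])

    def test_deterministic_given_seed(self, design3, dataset3, models3):
        args = (dataset3, design3, models3, mb.CellTarget((2, 2, 2)), 199, 0.025)
        iv1 = mb.percentile_bootstrap(*args, np.random.default_rng(3))
        iv2 = mb.percentile_bootstrap(*args, np.random.default_rng(3))
        assert (iv1.lower, iv1.upper) == (iv2.lower, iv2.upper)

    def test_small_B_rejected(self, design3, dataset3, models3):
        with pytest.raises(ValueError):
            mb.percentile_bootstrap(
                dataset3, design3, models3, mb.CellTarget((1, 1, 1)), 20, 0.025,
                np.random.default_rng(0),
            )


class TestBackTransformOrdering:
    def test_method_endpoint_order_preserved(self, design3, dataset3, fits3):
        w = mb.aic_weights([f.aic for f in fits3])
        target = mb.CellTarget((1, 2, 1))
        ests = mb.cell_estimates(fits3, target)
        iv_t = mb.mata_wald(ests, w, 0.025, "t")
        iv_z = mb.mata_wald(ests, w, 0.025, "z")
        bt_t, bt_z = mb.back_transform(iv_t), mb.back_transform(iv_z)
        assert bt_t.lower < bt_z.lower and bt_z.upper < bt_t.upper
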