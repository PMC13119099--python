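import numpy as np
import pytest

from devkinetics import (
    aic_from_sse,
    breakpoint_from_lines,
    compare_linear_bilinear,
    fit_bilinear,
    fit_linear,
    residual_bootstrap_bilinear,
)
from devkinetics._exceptions import ParallelLinesError

from conftest import CONC_GRID, fixture_row

GRID = np.asarray(CONC_GRID, dtype=float)


def brute_force_bilinear(x, y):
    """Independent exhaustive-enumeration oracle: plain loops + polyfit.

    Fits every admissible two-block split and returns the global SSE
    minimizer (None when no split is admissible).
    """
    order = np.argsort(x)
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    best = None
    for i in range(2, x.size - 1):
        a1, b1 = np.polyfit(x[:i], y[:i], 1)
        a2, b2 = np.polyfit(x[i:], y[i:], 1)
        if a1 == a2:
            continue
        xc = (b2 - b1) / (a1 - a2)
        if not (x[i - 1] <= xc < x[i]):
            continue
        pred = np.where(x <= xc, a1 * x + b1, a2 * x + b2)
        sse = float(np.sum((y - pred) ** 2))
        if best is None or sse < best["sse"]:
            best = {"a1": a1, "b1": b1, "a2": a2, "b2": b2, "x_c": xc, "sse": sse}
    return best


class TestFitLinear:
    def test_hand_computed_ols(self):
        res = fit_linear([0, 1, 2], [1, 2, 4])
        assert res.coef["a"] == pytest.approx(1.5)
        assert res.coef["b"] == pytest.approx(0.8333, abs=1e-4)

    def test_exact_line_has_zero_sse(self):
        x = np.arange(5.0)
        res = fit_linear(x, 2 * x + 1)
        assert res.coef["a"] == pytest.approx(2.0)
        assert res.sse == pytest.approx(0.0, abs=1e-20)

    def test_constant_response_gives_flat_line(self):
        res = fit_linear([0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert res.coef["a"] == pytest.approx(0.0)
        assert res.coef["b"] == pytest.approx(3.0)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBreakpointFromLines:
    def test_unit_example(self):
        assert breakpoint_from_lines(1, 0, 0, 1) == pytest.approx(1.0)

    def test_stress_threshold_from_published_segments(self):
        xc = breakpoint_from_lines(-0.0466, 0.0427, -0.0053, 0.018704)
        assert xc == pytest.approx(0.581, abs=1e-3)

    def test_symmetric_under_line_exchange(self):
        a = breakpoint_from_lines(-0.05, 0.04, -0.005, 0.0187)
        b = breakpoint_from_lines(-0.005, 0.0187, -0.05, 0.04)
        assert a == pytest.approx(b)

    def test_parallel_lines_error(self):
        with pytest.raises(ParallelLinesError):
            breakpoint_from_lines(1.0, 0.0, 1.0, 5.0)

    @pytest.mark.parametrize("scale,shift", [(2.0, 0.0), (0.5, 1.0), (3.0, -2.0)])
    def test_equivariant_under_affine_rescaling_of_x(self, scale, shift):
        # lines y = a*x + b in rescaled u = scale*x + shift coordinates
        a1, b1, a2, b2 = -0.05, 0.04, -0.005, 0.0187
        xc = breakpoint_from_lines(a1, b1, a2, b2)
        uc = breakpoint_from_lines(
            a1 / scale, b1 - a1 * shift / scale, a2 / scale, b2 - a2 * shift / scale
        )
        assert uc == pytest.approx(scale * xc + shift)


class TestAicFromSse:
    def test_unit_sse_per_point(self):
        assert aic_from_sse(11.0, 11, 2) == pytest.approx(4.0)

    def test_direct_evaluation(self):
        # 11*ln(1e-4/11) + 8
        assert aic_from_sse(1e-4, 11, 4) == pytest.approx(-119.69, abs=0.01)

    def test_strictly_increasing_in_sse(self):
        vals = [aic_from_sse(s, 11, 4) for s in (1e-6, 1e-4, 1e-2, 1.0)]
        assert np.all(np.diff(vals) > 0)

    def test_zero_sse_is_minus_inf_with_warning(self):
        with pytest.warns(UserWarning, match="perfect"):
            assert aic_from_sse(0.0, 11, 2) == float("-inf")


class TestFitBilinear:
    def test_exact_piecewise_recovery(self):
        y = np.where(GRID <= 0.6, 0.04 - 0.05 * GRID, 0.013 - 0.005 * GRID)
        res = fit_bilinear(GRID, y)
        assert res.coef["a1"] == pytest.approx(-0.05, abs=1e-12)
        assert res.coef["b1"] == pytest.approx(0.04, abs=1e-12)
        assert res.coef["a2"] == pytest.approx(-0.005, abs=1e-12)
        assert res.coef["b2"] == pytest.approx(0.013, abs=1e-12)
        assert res.coef["x_c"] == pytest.approx(0.6, abs=1e-9)
        assert not res.fallback

    def test_synchrony_fixture_breakpoint(self, sdvp_table):
        x, y = fixture_row(sdvp_table, "gompertz", "s_dvp")
        res = fit_bilinear(x, y)
        assert res.coef["x_c"] == pytest.approx(0.581, abs=0.02)

    def test_matches_enumeration_oracle_on_random_data(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(200):
            y = 0.04 - 0.04 * GRID + rng.normal(0, 0.003, GRID.size)
            oracle = brute_force_bilinear(GRID, y)
            res = fit_bilinear(GRID, y)
            if oracle is None:
                assert res.fallback
                continue
            n_checked += 1
            assert not res.fallback
            for key, val in oracle.items():
                if key == "sse":
                    assert res.sse == pytest.approx(val, rel=1e-12)
                else:
                    assert res.coef[key] == pytest.approx(val, rel=1e-10)
        assert n_checked > 100

    def test_bilinear_sse_never_exceeds_linear(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            y = 0.03 - 0.03 * GRID + rng.normal(0, 0.004, GRID.size)
            res = fit_bilinear(GRID, y)
            if res.fallback:
                continue
            assert res.sse <= fit_linear(GRID, y).sse + 1e-15

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_bilinear([0, 1, 2, 3], [1, 2, 3, 4])


class TestCompareLinearBilinear:
    def test_fixture_synchrony_strongly_favors_bilinear(self, sdvp_table):
        x, y = fixture_row(sdvp_table, "gompertz", "s_dvp")
        _, _, delta = compare_linear_bilinear(x, y)
        assert delta > 2.0

    def test_false_positive_rate_on_linear_truth(self):
        """With a straight-line truth plus noise, the 2k AIC penalty keeps the
        bilinear model from being selected in most replicates (measured
        false-positive rate ~29% at this noise level)."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(500):
            y = 0.04 - 0.02 * GRID + rng.normal(0, 0.0015, GRID.size)
            _, _, delta = compare_linear_bilinear(GRID, y)
            hits += delta > 2
        assert hits / 500 < 0.35

    def test_error_propagates_for_small_designs(self):
        with pytest.raises(ValueError):
            compare_linear_bilinear([0, 0.15, 0.3, 0.45], [1, 2, 3, 4])


class TestResidualBootstrap:
    def test_bit_identical_across_runs_with_same_seed(self, sdvp_table):
        x, y = fixture_row(sdvp_table, "gompertz", "s_dvp")
        a = residual_bootstrap_bilinear(x, y, n_boot=200, seed=11)
        b = residual_bootstrap_bilinear(x, y, n_boot=200, seed=11)
        for k in a:
            assert (a[k].lower, a[k].upper) == (b[k].lower, b[k].upper)

    def test_zero_residual_input_collapses_to_point(self):
        y = np.where(GRID <= 0.6, 0.04 - 0.05 * GRID, 0.013 - 0.005 * GRID)
        cis = residual_bootstrap_bilinear(GRID, y, n_boot=100, seed=0)
        for ci in cis.values():
            assert ci.lower == pytest.approx(ci.point, abs=1e-9)
            assert ci.upper == pytest.approx(ci.point, abs=1e-9)

    def test_interval_brackets_point_estimate(self, sdvp_table):
        x, y = fixture_row(sdvp_table, "gompertz", "s_dvp")
        cis = residual_bootstrap_bilinear(x, y, n_boot=500, seed=2)
        ci = cis["x_c"]
        assert ci.lower <= ci.point <= ci.upper


def test_all_synchrony_breakpoints_in_stress_band(sdvp_table):
    """Secondary breakpoints of all three models' synchrony norms fall in
    the same 0.50-0.65 M band, the signature of a shared stress threshold."""
    for model in ("gompertz", "logit", "dose_response"):
        x, y = fixture_row(sdvp_table, model, "s_dvp")
        xc = fit_bilinear(x, y).coef["x_c"]
        assert 0.50 <= xc <= 0.65, model


from hypothesis import given, settings, strategies as st


@settings(max_examples=100, deadline=None)
@given(
    a1=st.floats(-1, 1), b1=st.floats(-1, 1),
    a2=st.floats(-1, 1), b2=st.floats(-1, 1),
)
def test_breakpoint_exchange_symmetry_property(a1, b1, a2, b2):
    """Swapping the two segments never moves the intersection."""
    if abs(a1 - a2) < 1e-6:
        return
    assert breakpoint_from_lines(a1, b1, a2, b2) == pytest.approx(
        breakpoint_from_lines(a2, b2, a1, b1), rel=1e-9, abs=1e-12
    )
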