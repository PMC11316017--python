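"""Calibration-curve fitting and fit diagnostics."""

import math

import numpy as np
import pytest

from rardose import reference
from rardose.calibration import (
    DosePoint,
    correlation_pvalue,
    fit_exponential,
    fit_family,
    fit_linear,
    fit_quadratic,
    pearson_r,
)
from rardose.exceptions import (
    DegenerateDesignError,
    FitFailureError,
    InvalidInputError,
)

DOSES = (0.0, 5.0, 10.0, 50.0)


def points_from(fn, doses=DOSES):
    return [DosePoint(d, fn(d)) for d in doses]


class TestFitLinear:
    def test_exact_line_recovered(self):
        # the free-radical (EPR) dose response: y = 0.153 x + 45
        model = fit_linear(points_from(lambda x: 0.153 * x + 45.0))
        assert model.constants["a"] == pytest.approx(0.153, rel=1e-12)
        assert model.constants["b"] == pytest.approx(45.0, rel=1e-12)
        assert model.r_value == pytest.approx(1.0)
        assert model.direction == "increasing"

    def test_decreasing_line_has_negative_r(self):
        model = fit_linear(points_from(lambda x: -22e-4 * x + 0.6365))
        assert model.r_value == pytest.approx(-1.0)
        assert model.direction == "decreasing"

    def test_horizontal_line_flagged_zero_variance(self):
        model = fit_linear(points_from(lambda x: 7.0))
        assert model.constants["a"] == pytest.approx(0.0, abs=1e-15)
        assert model.r_value is None
        assert model.fit_status == "zero-variance"

    def test_two_points_interpolate_without_errors(self):
        model = fit_linear([DosePoint(0, 1.0), DosePoint(10, 3.0)])
        assert model.constants["a"] == pytest.approx(0.2)
        assert model.constant_errors is None

    def test_identical_doses_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([DosePoint(5, 1.0), DosePoint(5, 2.0)])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 50, 6)
        y = rng.uniform(0, 10, 6)
        model = fit_linear([DosePoint(xi, yi) for xi, yi in zip(x, y)])
        n = len(x)
        sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
        a = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        b = (sy - a * sx) / n
        assert model.constants["a"] == pytest.approx(a, rel=1e-9)
        assert model.constants["b"] == pytest.approx(b, rel=1e-9)


class TestFitExponential:
    def test_exact_recovery_decaying(self):
        # the catalase dose response: A=6.05e-3, R0=-0.054, y0=88.8e-3
        c = reference.CALIBRATION_CONSTANTS["CAT"]["constants"]
        model = fit_exponential(
            points_from(lambda x: c["A"] * math.exp(c["R0"] * x) + c["y0"])
        )
        for k, v in c.items():
            assert model.constants[k] == pytest.approx(v, rel=1e-6)
        assert model.fit_status == "converged"
        assert model.direction == "decreasing"
        assert model.r_value == pytest.approx(1.0)

    def test_exact_recovery_saturating_increase(self):
        # tail moment: negative amplitude, rises toward its asymptote
        c = reference.CALIBRATION_CONSTANTS["TM"]["constants"]
        model = fit_exponential(
            points_from(lambda x: c["A"] * math.exp(c["R0"] * x) + c["y0"])
        )
        for k, v in c.items():
            assert model.constants[k] == pytest.approx(v, rel=1e-6)
        assert model.direction == "increasing"

    def test_reported_standard_errors_are_calibrated(self):
        """Joint 3-SE coverage over noisy replicates.

        With four points and three constants the error estimate has one
        degree of freedom, so +/-3 SE is roughly an 80% interval per
        constant; simulation puts the joint coverage near 75%.  Anything
        resembling correct error propagation clears 60%; a broken
        covariance computation does not.
        """
        truth = dict(reference.CALIBRATION_CONSTANTS["GSH"]["constants"])
        doses = np.array(DOSES)
        clean = truth["A"] * np.exp(truth["R0"] * doses) + truth["y0"]
        rng = np.random.default_rng(2024)
        hits = []
        for _ in range(200):
            noisy = clean * (1 + 0.03 * rng.standard_normal(4))
            model = fit_exponential(
                [DosePoint(d, v) for d, v in zip(doses, noisy)]
            )
            hits.append(
                all(
                    abs(model.constants[k] - truth[k]) <= 3 * model.constant_errors[k]
                    for k in truth
                )
            )
        assert np.mean(hits) >= 0.6

    def test_flat_responses_unidentifiable(self):
        with pytest.raises(FitFailureError):
            fit_exponential(points_from(lambda x: 3.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_exponential([DosePoint(0, 1.0), DosePoint(5, 2.0)])


class TestFitQuadratic:
    def test_exact_recovery_and_vertex(self):
        # tail length: intercept=6.136, B1=0.1886, B2=-0.0019; vertex ~49.6 mSv
        c = reference.CALIBRATION_CONSTANTS["TL"]["constants"]
        model = fit_quadratic(
            points_from(lambda x: c["intercept"] + c["B1"] * x + c["B2"] * x * x)
        )
        for k, v in c.items():
            assert model.constants[k] == pytest.approx(v, rel=1e-9)
        assert model.vertex == pytest.approx(49.6316, abs=1e-3)
        # rises over the data-bearing branch, flagged because the vertex
        # falls just inside the fitted span
        assert model.direction == "non-monotone"
        lo, hi = model.monotone_branch()
        assert (lo, hi) == pytest.approx((0.0, 49.6316), abs=1e-3)

    def test_three_points_interpolate(self):
        pts = [DosePoint(0, 1.0), DosePoint(5, 4.0), DosePoint(10, 2.0)]
        model = fit_quadratic(pts)
        for p in pts:
            assert model.predict(p.dose) == pytest.approx(p.response, rel=1e-9)

    def test_collinear_points_give_zero_curvature(self):
        model = fit_quadratic(points_from(lambda x: 2.0 * x + 1.0))
        assert model.constants["B2"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_quadratic([DosePoint(0, 1), DosePoint(0, 2), DosePoint(5, 3)])


@pytest.mark.parametrize("marker", ["EPR", "CAT", "TL"])
def test_fitters_reproduce_generating_constants(marker, reference_curves):
    """Noiseless points from each family's own curve are recovered exactly."""
    curve = reference_curves[marker]
    pts = [DosePoint(d, curve.predict(d)) for d in DOSES]
    model = fit_family(curve.family, pts, marker_id=marker)
    for k, v in curve.constants.items():
        tol = 1e-9 if curve.family != "exponential" else 1e-6
        assert model.constants[k] == pytest.approx(v, rel=tol)


class TestPearsonR:
    def test_perfect_correlations(self):
        xs = [0.0, 5.0, 10.0, 50.0]
        assert pearson_r(xs, [2 * x + 1 for x in xs]) == pytest.approx(1.0)
        assert pearson_r(xs, [-2 * x + 1 for x in xs]) == pytest.approx(-1.0)

    def test_matches_summation_oracle(self):
        xs = np.array([0.0, 5.0, 10.0, 50.0])
        ys = np.array([0.64, 0.62, 0.61, 0.52])
        n = len(xs)
        num = n * (xs * ys).sum() - xs.sum() * ys.sum()
        den = math.sqrt(n * (xs**2).sum() - xs.sum() ** 2) * math.sqrt(
            n * (ys**2).sum() - ys.sum() ** 2
        )
        assert pearson_r(xs, ys) == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson_r([1, 2, 3], [5, 5, 5])


class TestCorrelationPvalue:
    def test_reference_sod_entry(self):
        # the published goodness entry for the SOD line: p = 0.006 on 4 points
        assert correlation_pvalue(-0.994, 4) == pytest.approx(0.006, abs=5e-4)

    def test_reference_epr_entry(self):
        assert correlation_pvalue(0.9996, 4) == pytest.approx(4.0e-4, rel=0.05)

    def test_zero_correlation_gives_one(self):
        assert correlation_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_perfect_correlation_gives_zero(self):
        assert correlation_pvalue(1.0, 4) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(InvalidInputError):
            correlation_pvalue(0.5, 2)

    def test_symmetric_in_sign_and_decreasing_in_magnitude(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9, 0.99]
        for r in rs:
            assert correlation_pvalue(r, 6) == pytest.approx(
                correlation_pvalue(-r, 6), rel=1e-12
            )
        ps = [correlation_pvalue(r, 6) for r in rs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
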