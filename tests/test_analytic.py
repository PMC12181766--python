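"""Closed-form partial correlations, derivatives, critical points, shapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import relbias as rb
from relbias.analytic import _constrained_derivative_poly

from conftest import central_difference

loadings = st.floats(-0.95, 0.95).filter(lambda v: abs(v) > 1e-3)
pos_loadings = st.floats(0.05, 0.95)


def _ols_r2_oracle(c: rb.CorrMatrix3) -> float:
    """Independent oracle: R^2 of Y on (exposure, Z') from exact least squares
    on the implied covariance (all variables standardized)."""
    zp, x, y = c.labels
    S = c.to_dataframe()
    Sxx = S.loc[[x, zp], [x, zp]].to_numpy()
    sxy = S.loc[[x, zp], y].to_numpy()
    return float(sxy @ np.linalg.solve(Sxx, sxy))


# ---------------------------------------------------------------------------
# R^2 assembly from correlation matrices
# ---------------------------------------------------------------------------


def test_r2_full_examples_and_oracle():
    c0 = rb.CorrMatrix3(("Z'", "X", "Y"), np.eye(3))
    assert rb.r2_full_from_corr(c0) == 0.0
    c1 = rb.implied_corr_model1(rb.PathModel1(alpha=0.0, beta=0.13, gamma=0.64))
    assert rb.r2_full_from_corr(c1) == pytest.approx(0.00692224, abs=1e-12)
    c2 = rb.implied_corr_model2(rb.PathModel2(0.6, 0.6, beta=0.5, gamma=0.19))
    assert rb.r2_full_from_corr(c2) == pytest.approx(0.0913370, abs=5e-8)
    assert rb.r2_full_from_corr(c2) == pytest.approx(_ols_r2_oracle(c2), abs=1e-12)


def test_r2_reduced_is_squared_marginal_correlation():
    c = rb.implied_corr_model1(rb.PathModel1(alpha=0.5, beta=0.13, gamma=0.64))
    assert rb.r2_reduced_from_corr(c) == pytest.approx((0.5 * 0.13) ** 2, abs=1e-15)
    assert rb.r2_reduced_from_corr(c) == pytest.approx(0.004225, abs=1e-15)


def test_partial_r2_assembly_and_examples():
    # controlling the true confounder removes all spurious association
    c_exact = rb.implied_corr_model1(rb.PathModel1(alpha=1.0, beta=0.3, gamma=0.7))
    assert rb.partial_r2(c_exact).value == pytest.approx(0.0, abs=1e-12)
    # alpha = 0: the formula collapses to the squared marginal correlation
    c0 = rb.implied_corr_model1(rb.PathModel1(alpha=0.0, beta=0.13, gamma=0.64))
    assert rb.partial_r2(c0).value == pytest.approx((0.64 * 0.13) ** 2, abs=1e-12)
    c2 = rb.implied_corr_model2(rb.PathModel2(0.6, 0.6, beta=0.5, gamma=0.19))
    res = rb.partial_r2(c2)
    assert res.value == pytest.approx(0.0014693, abs=5e-8)
    assert res.r2_full >= res.r2_reduced
    assert res.value == pytest.approx(
        (res.r2_full - res.r2_reduced) / (1 - res.r2_reduced), abs=1e-15
    )


def test_singular_denominators_raise():
    vals = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
    with pytest.raises(rb.SingularityError):
        rb.r2_full_from_corr(rb.CorrMatrix3(("Z'", "X", "Y"), vals))
    vals2 = np.array([[1.0, 0.2, 1.0], [0.2, 1.0, 0.2], [1.0, 0.2, 1.0]])
    with pytest.raises(rb.SingularityError):
        rb.partial_r2(rb.CorrMatrix3(("Z'", "X", "Y"), vals2))


# ---------------------------------------------------------------------------
# Closed forms vs the generic assembly
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=200)
@given(a=loadings, b=loadings, g=loadings)
def test_model1_closed_form_matches_generic(a, b, g):
    via_matrix = rb.partial_r2(rb.implied_corr_model1(rb.PathModel1(a, b, g))).value
    assert rb.partial_r2_model1(a, b, g) == pytest.approx(via_matrix, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(ax=loadings, az=loadings, b=loadings, g=loadings)
def test_model2_closed_form_matches_generic(ax, az, b, g):
    via_matrix = rb.partial_r2(rb.implied_corr_model2(rb.PathModel2(ax, az, b, g))).value
    assert rb.partial_r2_model2(ax, az, b, g) == pytest.approx(via_matrix, abs=1e-12)


def test_constrained_form_is_model2_with_tied_loadings():
    for a in (0.0, 0.3, 0.6, 0.9):
        assert rb.partial_r2_model2_constrained(a, 0.5, 0.19) == pytest.approx(
            rb.partial_r2_model2(a, a, 0.5, 0.19), abs=1e-15
        )
    assert rb.partial_r2_model2_constrained(0.0, 0.5, 0.19) == 0.0
    assert rb.partial_r2_model2_constrained(1.0, 0.5, 0.19) == pytest.approx(0.0, abs=1e-12)
    assert rb.partial_r2_model2_constrained(0.6, 0.5, 0.19) == pytest.approx(
        0.0014693, abs=5e-8
    )


@settings(derandomize=True, max_examples=100)
@given(a=pos_loadings, b=pos_loadings, g=pos_loadings)
def test_partial_r2_even_under_sign_flips(a, b, g):
    """R^2 depends on the loadings only through squared products."""
    base = rb.partial_r2_model1(a, b, g)
    assert rb.partial_r2_model1(-a, b, g) == pytest.approx(base, abs=1e-15)
    base2 = rb.partial_r2_model2_constrained(a, b, g)
    assert rb.partial_r2_model2_constrained(-a, b, g) == pytest.approx(base2, abs=1e-15)


# ---------------------------------------------------------------------------
# Linked reliabilities (alpha_x = omega alpha_z + a0)
# ---------------------------------------------------------------------------


def test_omega_reduced_form_matches_substitution(rng):
    for _ in range(300):
        az, b, g = rng.uniform(0.05, 0.95, 3)
        hi = min(1.0 / az, 1.0 / (g * az**2)) * 0.999
        w = rng.uniform(-1.0 / az * 0.999, hi)
        reduced = rb.partial_r2_omega(az, b, g, rb.ReliabilityLink(omega=w))
        substituted = rb.partial_r2_model2(w * az, az, b, g)
        assert reduced == pytest.approx(substituted, abs=1e-12)


def test_omega_special_cases():
    link0 = rb.ReliabilityLink(omega=0.0)
    assert rb.partial_r2_omega(0.7, 0.5, 0.19, link0) == 0.0
    link1 = rb.ReliabilityLink(omega=1.0)
    assert rb.partial_r2_omega(0.6, 0.5, 0.19, link1) == pytest.approx(
        rb.partial_r2_model2_constrained(0.6, 0.5, 0.19), abs=1e-15
    )


def test_omega_half_limit_closed_form():
    """For omega=-1, beta=gamma=1 the curve is alpha_z^2/(1+alpha_z^2) -> 1/2."""
    link = rb.ReliabilityLink(omega=-1.0)
    grid = rb.default_alpha_grid()
    vals = rb.partial_r2_omega(grid, 1.0, 1.0, link)
    assert np.max(np.abs(vals - grid**2 / (1 + grid**2))) < 1e-12
    near_one = rb.partial_r2_omega(1 - 1e-8, 1.0, 1.0, link)
    assert near_one == pytest.approx(0.5, abs=1e-7)


def test_omega_constraint_violation_names_the_bound():
    link = rb.ReliabilityLink(omega=4.0)
    with pytest.raises(rb.DomainError, match=r"1/\(gamma\*alpha_z\^2\)"):
        rb.partial_r2_omega(0.9, 0.5, 0.5, link)


def test_omega_intercept_case_is_monotone():
    """alpha_x = 0.8 alpha_z + 0.2 with beta = gamma = 1 stays monotone."""
    link = rb.ReliabilityLink(omega=0.8, a0=0.2)
    shape = rb.classify_monotonicity(
        lambda a: rb.partial_r2_omega(a, 1.0, 1.0, link), 512
    )
    assert shape == "monotone_nondecreasing"


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------


def test_model1_derivative_matches_numerical(rng):
    for _ in range(200):
        a = rng.uniform(0.02, 0.93)
        b, g = rng.uniform(0.05, 0.95, 2)
        closed = rb.d_partial_r2_model1(a, b, g)
        numeric = central_difference(lambda x: rb.partial_r2_model1(x, b, g), a)
        assert np.isclose(closed, numeric, rtol=1e-6, atol=1e-12)


def test_model2_constrained_derivative_matches_numerical(rng):
    for _ in range(200):
        a = rng.uniform(0.02, 0.93)
        b, g = rng.uniform(0.05, 0.95, 2)
        closed = rb.d_partial_r2_model2_constrained(a, b, g)
        numeric = central_difference(
            lambda x: rb.partial_r2_model2_constrained(x, b, g), a
        )
        assert np.isclose(closed, numeric, rtol=1e-6, atol=1e-12)


def test_model1_derivative_signs_and_oddness():
    assert rb.d_partial_r2_model1(0.0, 0.13, 0.64) == 0.0
    assert rb.d_partial_r2_model1(0.5, 0.13, 0.64) < 0.0
    # even curve, odd derivative
    assert rb.d_partial_r2_model1(-0.5, 0.13, 0.64) == pytest.approx(
        -rb.d_partial_r2_model1(0.5, 0.13, 0.64), abs=1e-15
    )


def test_model2_constrained_derivative_changes_sign_once():
    assert rb.d_partial_r2_model2_constrained(0.0, 0.5, 0.19) == 0.0
    assert rb.d_partial_r2_model2_constrained(0.3, 0.5, 0.19) > 0.0
    assert rb.d_partial_r2_model2_constrained(0.9, 0.5, 0.19) < 0.0


# ---------------------------------------------------------------------------
# Monotonicity and the critical point
# ---------------------------------------------------------------------------


def test_model1_curve_strictly_decreasing_with_known_endpoints(rng):
    grid = rb.default_alpha_grid()
    for _ in range(50):
        b, g = rng.uniform(0.05, 0.95, 2)
        vals = rb.partial_r2_model1(grid, b, g)
        assert np.all(np.diff(vals) < 0.0)
        assert vals[0] == pytest.approx((g * b) ** 2, abs=1e-15)
        assert rb.partial_r2_model1(1.0, b, g) == pytest.approx(0.0, abs=1e-12)


def test_constrained_curve_zero_at_endpoints_positive_inside(rng):
    interior = rb.default_alpha_grid()[1:]
    for _ in range(50):
        b, g = rng.uniform(0.05, 0.95, 2)
        assert rb.partial_r2_model2_constrained(0.0, b, g) == 0.0
        assert rb.partial_r2_model2_constrained(1.0, b, g) == pytest.approx(0.0, abs=1e-12)
        assert np.all(rb.partial_r2_model2_constrained(interior, b, g) > 0.0)


def test_critical_point_location_and_root_quality():
    cp = rb.critical_point(0.5, 0.19)
    assert cp.shape == "unimodal_interior_max"
    assert cp.alpha_star == pytest.approx(0.597, abs=5e-4)
    # the bracketed polynomial vanishes at the root
    assert abs(_constrained_derivative_poly(cp.alpha_star, 0.5, 0.19)) < 1e-10
    assert abs(rb.d_partial_r2_model2_constrained(cp.alpha_star, 0.5, 0.19)) < 1e-8


def test_critical_point_agrees_with_dense_grid_argmax(rng):
    grid = np.linspace(1e-6, 1 - 1e-6, 10_000)
    for b, g in [(0.5, 0.19), (0.3, 0.7), (0.8, 0.4)]:
        cp = rb.critical_point(b, g)
        argmax = grid[np.argmax(rb.partial_r2_model2_constrained(grid, b, g))]
        assert abs(cp.alpha_star - argmax) <= grid[1] - grid[0]


def test_classify_monotonicity_on_the_three_families():
    assert (
        rb.classify_monotonicity(lambda a: rb.partial_r2_model1(a, 0.13, 0.64))
        == "monotone_decreasing"
    )
    assert (
        rb.classify_monotonicity(lambda a: rb.partial_r2_model2_constrained(a, 0.5, 0.19))
        == "unimodal_interior_max"
    )
    link = rb.ReliabilityLink(omega=-1.0)
    assert (
        rb.classify_monotonicity(
            lambda a: rb.partial_r2_omega(np.minimum(a, 0.999), 1.0, 1.0, link)
        )
        == "monotone_nondecreasing"
    )


def test_classify_rejects_multi_modal_curves():
    with pytest.raises(rb.DomainError):
        rb.classify_monotonicity(lambda a: np.sin(6 * np.pi * a), 512)
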