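"""Polynomial trajectory fits, deviance test, FDR mask, turning point."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctshapes import trajectory as T


def test_constant_ct_gives_zero_slope():
    ages = np.linspace(6, 30, 20)
    fit = T.fit_trajectory(ages, np.full(20, 3.0), 1)
    assert abs(fit.shape) < 1e-12
    assert abs(fit.coef[0] - 3.0) < 1e-12


def test_noiseless_linear_recovered_to_machine_precision():
    ages = np.linspace(6, 30, 50)
    fit = T.fit_trajectory(ages, 4 - 0.02 * ages, 1)
    np.testing.assert_allclose(fit.shape, -0.02, atol=1e-14)


def test_noisy_fit_matches_pseudoinverse_oracle(rng):
    ages = rng.uniform(6, 30, 300)
    y = 3.5 - 0.03 * ages + 0.001 * ages**2 + rng.normal(0, 0.1, 300)
    for degree in (1, 2, 3):
        fit = T.fit_trajectory(ages, y, degree)
        X = np.vander(ages, degree + 1, increasing=True)
        oracle = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-8)


def test_all_equal_ages_rejected():
    with pytest.raises(ValueError, match="singular"):
        T.fit_trajectory(np.full(10, 15.0), np.ones(10), 1)


def test_deviance_null_pvalues_uniform():
    # pure-noise data: deviance p-values follow U(0,1)
    rng = np.random.default_rng(42)
    pvals = []
    ages = rng.uniform(6, 30, 200)
    for _ in range(500):
        y = rng.normal(2.5, 0.1, 200)
        fit = T.fit_trajectory(ages, y, 2)
        pvals.append(T.deviance_test(fit))
    _, ks_p = stats.kstest(pvals, "uniform")
    assert ks_p > 0.01


def test_deviance_detects_strong_trend():
    rng = np.random.default_rng(1)
    ages = rng.uniform(6, 30, 200)
    y = 3.0 - 1.0 * (ages - 18) / np.std(ages - 18) * 0.1 * 10 + rng.normal(0, 0.1, 200)
    fit = T.fit_trajectory(ages, y, 1)
    assert T.deviance_test(fit) < 1e-6


def test_deviance_degenerate_cases():
    ages = np.linspace(6, 30, 10)
    # data equal to its own mean: statistic 0, p = 1
    fit = T.fit_trajectory(ages, np.full(10, 2.0), 1)
    assert T.deviance_test(fit) == 1.0
    # perfect polynomial fit with real variance: p = 0 + degeneracy flag
    fit2 = T.fit_trajectory(ages, 3 - 0.05 * ages, 1)
    assert T.deviance_test(fit2) == 0.0
    assert fit2.degenerate
    fit2b = T.fit_trajectory(ages, 3 - 0.05 * ages, 1)
    fit2b.rss = 0.0  # exact zero behaves identically
    assert T.deviance_test(fit2b) == 0.0


def _bh_oracle(pvals, q):
    """Hand-coded Benjamini-Hochberg: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        rejected[order[: kmax + 1]] = True
    return rejected


def test_fdr_mask_hand_example():
    pv = pd.DataFrame(
        {"ASD": [0.01, 0.02, 0.03, 0.04], "TD": [0.01, 0.02, 0.03, 0.04]},
        index=list("abcd"),
    )
    keep = T.fdr_mask(pv, q=0.05)
    assert keep.all()  # largest k with p_(k) <= k q/m is k = 4


def test_fdr_mask_all_ones_empty():
    pv = pd.DataFrame({"ASD": [1.0] * 5, "TD": [1.0] * 5})
    assert not T.fdr_mask(pv).any()


def test_fdr_mask_rule_semantics():
    pv = pd.DataFrame({"ASD": [0.5, 0.001], "TD": [0.001, 0.001]}, index=["r1", "r2"])
    both = T.fdr_mask(pv, rule="both_groups")
    any_ = T.fdr_mask(pv, rule="any_group")
    assert not both["r1"] and both["r2"]
    assert any_["r1"] and any_["r2"]


def test_fdr_mask_matches_bh_oracle_on_random_vectors(rng):
    for _ in range(200):
        m = rng.integers(3, 60)
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3)
        pv = pd.DataFrame({"ASD": p, "TD": p})
        keep = T.fdr_mask(pv, q=0.05).to_numpy()
        np.testing.assert_array_equal(keep, _bh_oracle(p, 0.05))


def _quad_fit(intercept, slope, curvature):
    return T.TrajectoryFit(
        roi="r", group="ASD", degree=2,
        coef=np.array([intercept, slope, curvature]),
        rss=1.0, rss_null=2.0, n=100,
    )


def test_turning_point_is_midpoint():
    fit = _quad_fit(3.0, 0.01, -0.001)
    assert T.turning_point(fit) == pytest.approx(18.0, abs=1e-9)
    assert T.turning_point(fit, 10, 20) == pytest.approx(15.0, abs=1e-9)


def test_turning_point_grid_oracle():
    # numeric maximizer of the vertical chord distance at 0.001-yr resolution
    fit = _quad_fit(3.2, 0.04, -0.0023)
    grid = np.arange(6.0, 30.0 + 1e-9, 0.001)
    f = fit.predict(grid)
    lo, hi = fit.predict(np.array([6.0]))[0], fit.predict(np.array([30.0]))[0]
    chord = lo + (hi - lo) * (grid - 6.0) / 24.0
    numeric = grid[np.argmax(f - chord)]  # concave curve lies above its chord
    assert abs(numeric - T.turning_point(fit)) < 0.001


def test_turning_point_requires_concave_quadratic():
    with pytest.raises(ValueError, match="curvature"):
        T.turning_point(_quad_fit(3.0, 0.0, 0.001))
    bad = T.TrajectoryFit(roi="r", group="ASD", degree=1,
                          coef=np.array([3.0, -0.01]), rss=1, rss_null=2, n=10)
    with pytest.raises(ValueError, match="quadratic"):
        T.turning_point(bad)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    slope=st.floats(-0.1, 0.1),
    curv=st.floats(-0.01, -1e-6),
    const=st.floats(-1.0, 1.0),
)
def test_shape_invariant_to_constant_offset_and_tp_midpoint(slope, curv, const):
    ages = np.linspace(6, 30, 40)
    y = 3.0 + slope * ages + curv * ages**2
    fit = T.fit_trajectory(ages, y, 2)
    fit_shifted = T.fit_trajectory(ages, y + const, 2)
    assert fit_shifted.shape == pytest.approx(fit.shape, abs=1e-10)
    assert T.turning_point(fit) == pytest.approx(18.0, abs=1e-9)


def test_compute_mask_keeps_trending_rois(small_dataset):
    _, cohort, ct = small_dataset
    mask = T.compute_mask({d: ct for d in (1, 2, 3)}, cohort)
    assert len(mask.kept_all_degrees()) == ct.shape[1]  # strong planted trends
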