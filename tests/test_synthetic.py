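"""Generator behavior: determinism, planted structure, moment checks."""

import numpy as np
import pandas as pd
import pytest

import ctshapes as cs
from ctshapes.synthetic import PRESETS, TrajectorySpec


def test_degenerate_group_allowed():
    cohort = cs.generate_cohort(0, 10, [10], seed=1)
    assert len(cohort) == 10
    assert (cohort["group"] == "TD").all()


def test_same_seed_reproduces_tables(paperlike_spec):
    a = cs.generate_cohort(30, 40, [35, 35], seed=5)
    b = cs.generate_cohort(30, 40, [35, 35], seed=5)
    pd.testing.assert_frame_equal(a, b)
    spec = cs.make_spec("paper-like", n_rois=10, centers=2)
    ct_a = cs.generate_ct(a, spec, seed=9)
    ct_b = cs.generate_ct(b, spec, seed=9)
    pd.testing.assert_frame_equal(ct_a, ct_b)
    ados_a = cs.generate_ados(a, spec, seed=3)
    ados_b = cs.generate_ados(b, spec, seed=3)
    pd.testing.assert_frame_equal(ados_a, ados_b)


def test_paper_design_sizes_and_center_structure():
    # 674 ASD / 686 TD across 24 centers, as in the source cohort design
    sizes = [56] * 23 + [72]
    cohort = cs.generate_cohort(674, 686, sizes, seed=2)
    assert (cohort["group"] == "ASD").sum() == 674
    assert (cohort["group"] == "TD").sum() == 686
    assert cohort["center"].nunique() == 24
    assert cohort["age"].between(6, 30).all()


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_asd=10, n_td=10, centers=[10, 0, 10]),
        dict(n_asd=10, n_td=10, centers=[10, 5]),
        dict(n_asd=10, n_td=10, centers=[20], age_range=(4.0, 30.0)),
    ],
)
def test_cohort_rejects_invalid_requests(bad):
    with pytest.raises(ValueError):
        cs.generate_cohort(seed=0, **bad)


def _noiseless_spec(slope=-0.02, offset=0.0, intercept=4.0, centers=("A",)):
    coef = np.array([[intercept, slope, 0.0, 0.0]])
    return TrajectorySpec(
        roi_names=["r1"],
        coefficients={"ASD": coef.copy(), "TD": coef.copy()},
        noise_sd=0.0,
        center_offsets={c: offset for c in centers},
    )


def test_noiseless_ct_evaluates_polynomial_exactly():
    cohort = cs.generate_cohort(0, 5, [5], seed=0, center_names=["A"])
    cohort["age"] = 10.0
    ct = cs.generate_ct(cohort, _noiseless_spec(), seed=1)
    np.testing.assert_allclose(ct["r1"].to_numpy(), 4.0 - 0.2, rtol=0, atol=0)


def test_center_offset_shifts_values_exactly():
    cohort = cs.generate_cohort(0, 8, [4, 4], seed=0, center_names=["A", "B"])
    spec0 = _noiseless_spec(centers=("A", "B"))
    spec = _noiseless_spec(offset=0.0, centers=("A", "B"))
    spec.center_offsets = {"A": 0.0, "B": 0.3}
    base = cs.generate_ct(cohort, spec0, seed=1)
    shifted = cs.generate_ct(cohort, spec, seed=1)
    mask_b = (cohort["center"] == "B").to_numpy()
    np.testing.assert_allclose(
        shifted.to_numpy()[mask_b] - base.to_numpy()[mask_b], 0.3, atol=1e-12
    )
    np.testing.assert_allclose(
        shifted.to_numpy()[~mask_b], base.to_numpy()[~mask_b], atol=0
    )


def test_residual_sd_matches_planted_noise():
    # subtract the planted polynomial; residual SD must be ~noise_sd
    spec = cs.make_spec("null", n_rois=5, centers=1, noise_sd=0.1)
    cohort = cs.generate_cohort(1000, 1000, [2000], seed=3, center_names=["C01"])
    ct = cs.generate_ct(cohort, spec, seed=4)
    age = cohort["age"].to_numpy()
    P = np.column_stack([np.ones_like(age), age, age**2, age**3])
    planted = P @ spec.coefficients["TD"].T + spec.center_offsets["C01"]
    resid = ct.to_numpy() - planted
    sd = resid.std(axis=0)
    np.testing.assert_allclose(sd, 0.1, rtol=0.05)


def test_missing_center_in_spec_names_it():
    cohort = cs.generate_cohort(0, 6, [3, 3], seed=0, center_names=["A", "ZZZ"])
    with pytest.raises(ValueError, match="ZZZ"):
        cs.generate_ct(cohort, _noiseless_spec(centers=("A",)), seed=0)


def test_ados_null_coupling_independent_of_severity():
    spec = cs.make_spec("null", n_rois=10, centers=2)
    cohort = cs.generate_cohort(400, 100, [250, 250], seed=6)
    scored = cs.generate_ados(cohort, spec, seed=7)
    asd = scored[scored["group"] == "ASD"]
    r = np.corrcoef(asd["severity"], asd["ados_comm"])[0, 1]
    assert abs(r) < 0.1


def test_ados_positive_coupling_tracks_severity():
    spec = cs.make_spec("paper-like", n_rois=10, centers=2)
    cohort = cs.generate_cohort(400, 100, [250, 250], seed=6)
    scored = cs.generate_ados(cohort, spec, seed=7)
    asd = scored[scored["group"] == "ASD"]
    for col in ("ados_comm", "ados_social", "ados_stereo"):
        assert np.corrcoef(asd["severity"], asd[col])[0, 1] > 0.2


def test_td_subjects_have_no_ados():
    spec = cs.make_spec("paper-like", n_rois=4, centers=1)
    cohort = cs.generate_cohort(20, 20, [40], seed=1, center_names=["C01"])
    scored = cs.generate_ados(cohort, spec, seed=2)
    td = scored[scored["group"] == "TD"]
    assert td[["ados_comm", "ados_social", "ados_stereo"]].isna().all().all()
    asd = scored[scored["group"] == "ASD"]
    assert (asd[["ados_comm", "ados_social", "ados_stereo"]] >= 0).all().all()


def test_coupling_without_contrast_warns_and_yields_noise():
    spec = cs.make_spec("null", n_rois=4, centers=1)
    spec.ados_coupling = 1.0
    cohort = cs.generate_cohort(50, 10, [60], seed=1, center_names=["C01"])
    with pytest.warns(UserWarning, match="no curvature contrast"):
        cs.generate_ados(cohort, spec, seed=2)


def test_presets_are_finite_and_positive_over_age_range():
    ages = np.linspace(6, 30, 49)
    for preset in PRESETS:
        spec = cs.make_spec(preset, n_rois=40, centers=4)
        P = np.column_stack([np.ones_like(ages), ages, ages**2, ages**3])
        for g in ("ASD", "TD"):
            vals = P @ spec.coefficients[g].T
            assert np.isfinite(vals).all()
            assert (vals > 0.5).all()  # comfortably positive even with noise


def test_invalid_spec_rejected():
    with pytest.raises(ValueError, match="noise_sd"):
        TrajectorySpec(
            roi_names=["r1"],
            coefficients={"ASD": np.zeros((1, 4)), "TD": np.zeros((1, 4))},
            noise_sd=-0.1,
        )
    with pytest.raises(ValueError, match="missing"):
        TrajectorySpec(roi_names=["r1"], coefficients={"ASD": np.zeros((1, 4))})
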