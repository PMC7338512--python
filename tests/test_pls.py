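"""Mean-centered and behavioral PLS: closed forms, oracles, calibration."""

import numpy as np
import pytest

import ctshapes as cs
from ctshapes import pls as P
from ctshapes import subsample as S


def test_identical_group_means_give_zero_singular_value(rng):
    block = rng.normal(size=(4, 6))
    X = np.vstack([block, block])  # rows duplicated across groups
    labels = np.array(["ASD"] * 4 + ["TD"] * 4)
    res = P.mean_centered_pls(X, labels, n_perm=50, n_boot=0, seed=0)
    assert res.singular_values[0] == pytest.approx(0.0, abs=1e-12)


def test_two_group_contrast_closed_form(rng):
    # brain saliences ~ (mean_ASD - mean_TD); design contrast ~ [+1, -1]
    X = rng.normal(size=(6, 4))
    labels = np.array(["ASD", "ASD", "ASD", "TD", "TD", "TD"])
    res = P.mean_centered_pls(X, labels, n_perm=50, n_boot=0, seed=0,
                              groups=["ASD", "TD"])
    diff = X[:3].mean(axis=0) - X[3:].mean(axis=0)
    v1 = res.brain_saliences["LV1"].to_numpy()
    np.testing.assert_allclose(v1, diff / np.linalg.norm(diff), atol=1e-10)
    u1 = res.design_saliences[:, 0]
    np.testing.assert_allclose(u1, [1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-10)
    # sigma_1 from a brute-force SVD of the contrast matrix
    R = np.vstack([diff / 2, -diff / 2])
    s_oracle = np.linalg.svd(R, compute_uv=False)[0]
    assert res.singular_values[0] == pytest.approx(s_oracle, abs=1e-12)
    # rank-one structure
    assert res.singular_values[1] == pytest.approx(0.0, abs=1e-12)


def test_mean_centered_type_one_error_calibrated(rng):
    # i.i.d. rows, shuffled labels: rejection close to nominal
    rejections = 0
    n_rep = 100
    for i in range(n_rep):
        X = rng.normal(size=(30, 10))
        labels = np.array(["ASD"] * 15 + ["TD"] * 15)
        res = P.mean_centered_pls(X, labels, n_perm=200, n_boot=0, seed=i)
        rejections += res.p_perm[0] < 0.05
    assert 0.01 <= rejections / n_rep <= 0.12


def test_tiny_group_rejected():
    X = np.ones((3, 2))
    with pytest.raises(ValueError, match="fewer than 2"):
        P.mean_centered_pls(X, np.array(["ASD", "TD", "TD"]), n_perm=10, n_boot=0)


def test_constant_feature_warns(rng):
    X = rng.normal(size=(8, 3))
    X[:, 1] = 2.0
    labels = np.array(["ASD"] * 4 + ["TD"] * 4)
    with pytest.warns(UserWarning, match="constant feature"):
        P.mean_centered_pls(X, labels, n_perm=10, n_boot=0, seed=0)


def test_singular_value_sum_invariant_under_feature_permutation(rng):
    X = rng.normal(size=(20, 8))
    labels = np.array(["ASD"] * 10 + ["TD"] * 10)
    perm = rng.permutation(8)
    r1 = P.mean_centered_pls(X, labels, n_perm=10, n_boot=0, seed=0)
    r2 = P.mean_centered_pls(X[:, perm], labels, n_perm=10, n_boot=0, seed=0)
    assert np.sum(r1.singular_values**2) == pytest.approx(
        np.sum(r2.singular_values**2), rel=1e-12
    )
    np.testing.assert_allclose(
        r1.brain_saliences.to_numpy()[perm, 0],
        r2.brain_saliences.to_numpy()[:, 0], atol=1e-10,
    )


def test_bootstrap_ratios_large_for_reliable_features(rng):
    # strong separation on feature 0 only
    n = 40
    X = rng.normal(size=(2 * n, 3)) * 0.2
    X[:n, 0] += 2.0
    labels = np.array(["ASD"] * n + ["TD"] * n)
    res = P.mean_centered_pls(X, labels, n_perm=50, n_boot=200, seed=1)
    z = res.bootstrap_ratios["LV1"].to_numpy()
    assert abs(z[0]) > 5
    assert abs(z[0]) > abs(z[1]) and abs(z[0]) > abs(z[2])


def test_behavioral_perfect_correlation(rng):
    X = rng.normal(size=(50, 5))
    Y = X[:, [2]].copy()  # behavior equals one feature
    res = P.behavioral_pls(X, Y, n_perm=50, n_boot=0, seed=0)
    v1 = np.abs(res.brain_saliences["LV1"].to_numpy())
    assert v1.argmax() == 2
    # sigma_1 equals the norm of the correlation row
    r_row = np.array([np.corrcoef(Y[:, 0], X[:, j])[0, 1] for j in range(5)])
    assert res.singular_values[0] == pytest.approx(np.linalg.norm(r_row), rel=1e-10)


def test_behavioral_null_rarely_significant(rng):
    hits = 0
    for i in range(50):
        X = rng.normal(size=(400, 6))
        Y = rng.normal(size=(400, 2))
        res = P.behavioral_pls(X, Y, n_perm=100, n_boot=0, seed=i)
        hits += res.p_perm[0] > 0.05
    assert hits >= 45  # p_perm > 0.05 in >= 90% of replicates


def test_behavioral_constant_behavior_rejected(rng):
    X = rng.normal(size=(10, 3))
    Y = np.ones((10, 1))
    with pytest.raises(ValueError, match="constant behavior"):
        P.behavioral_pls(X, Y, n_perm=10, n_boot=0)


def test_behavioral_correlation_sign_tracks_association(rng):
    # features decrease as the behavior increases -> negative overall r
    n = 200
    latent = rng.normal(size=n)
    X = -np.outer(latent, np.ones(4)) + rng.normal(size=(n, 4)) * 0.5
    Y = np.column_stack([latent + rng.normal(size=n) * 0.5])
    res = P.behavioral_pls(X, Y, n_perm=50, n_boot=0, seed=0)
    assert res.behavior_correlations[0] < -0.5


def _shape_sets_from_preset(preset, seed, n_group=150, n_rois=12, n=35, K=10):
    spec = cs.make_spec(preset, n_rois=n_rois, centers=2)
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    cohort = cs.generate_cohort(n_group, n_group, [n_group] * 2, seed=int(ss[0]))
    ct = cs.generate_ct(cohort, spec, seed=int(ss[1]))
    sets = {}
    for g, sd in (("ASD", ss[2]), ("TD", ss[3])):
        part = cohort[cohort["group"] == g]
        sset = S.draw_and_select(part, n=n, n_candidates=200, K=K, seed=int(sd))
        sets[g] = S.fit_subsamples(sset, ct, cohort, list(ct.columns))
    return spec, sets


def test_group_pls_monotone_in_effect_size():
    # permutation p non-increasing with planted effect, in expectation
    mean_p = {}
    for preset in ("null", "paper-like", "strong"):
        ps = []
        for i in range(20):
            _, sets = _shape_sets_from_preset(preset, seed=100 + i)
            res = P.run_group_pls(sets, n_perm=200, n_boot=0, seed=i)
            ps.append(res.p_perm[0])
        mean_p[preset] = np.mean(ps)
    assert mean_p["null"] >= mean_p["paper-like"] >= mean_p["strong"]
    assert mean_p["strong"] < 0.05


def test_group_pls_k1_rejected(small_dataset):
    _, cohort, ct = small_dataset
    sets = {}
    for g in ("ASD", "TD"):
        part = cohort[cohort["group"] == g]
        sset = S.draw_and_select(part, n=50, n_candidates=5, K=1, seed=0)
        sets[g] = S.fit_subsamples(sset, ct, cohort, list(ct.columns))
    with pytest.raises(ValueError, match="at least 2 subsamples"):
        P.run_group_pls(sets, n_perm=10, n_boot=10, seed=0)


def test_feature_mismatch_rejected(small_dataset):
    _, cohort, ct = small_dataset
    sets = {}
    for g, rois in (("ASD", list(ct.columns[:3])), ("TD", list(ct.columns[:4]))):
        part = cohort[cohort["group"] == g]
        sset = S.draw_and_select(part, n=40, n_candidates=10, K=3, seed=0)
        sets[g] = S.fit_subsamples(sset, ct, cohort, rois)
    with pytest.raises(ValueError, match="feature layout"):
        P.run_group_pls(sets, n_perm=10, n_boot=0, seed=0)


def test_run_behavioral_pls_uses_only_ados_complete(small_dataset):
    _, cohort, ct = small_dataset
    asd = cohort[cohort["group"] == "ASD"]
    sset = S.draw_and_select(asd, n=20, n_candidates=100, K=30, seed=3)
    sset = S.fit_subsamples(sset, ct, cohort, list(ct.columns))
    res = P.run_behavioral_pls(sset, cohort, "curvature",
                               n_perm=100, n_boot=0, seed=4, bonferroni=1)
    assert res.mode == "behavioral"
    assert res.p_corrected[0] == pytest.approx(res.p_perm[0])
    # Bonferroni factor scales the corrected p
    res6 = P.run_behavioral_pls(sset, cohort, "curvature",
                                n_perm=100, n_boot=0, seed=4, bonferroni=6)
    assert res6.p_corrected[0] == pytest.approx(min(1.0, 6 * res.p_perm[0]))
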