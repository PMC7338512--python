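"""Partial Least Squares inference: mean-centered and behavioral variants.

Both variants reduce a cross-block matrix to latent variables (LVs) by
singular value decomposition and attach resampling-based inference:

* **Mean-centered PLS** decomposes the groups x features matrix of column
  means after subtracting the grand mean (the unweighted mean of group
  means). For two groups this is a rank-one contrast: the single LV's brain
  saliences are proportional to the difference of group means, and the design
  saliences express the group contrast (oriented here as first group > second,
  i.e. ASD > TD).
* **Behavioral PLS** decomposes the behaviors x features Pearson correlation
  matrix between an imaging block X and a behavioral block Y, yielding
  overall brain-behavior correlation patterns.

Inference: a permutation test shuffles group labels (mean-centered) or the
X/Y row correspondence (behavioral) and counts permuted singular values at
least as large as the observed ones, with the +1-smoothed estimator
``p = (1 + #{sigma_perm >= sigma})/(1 + n_perm)``. Bootstrap resampling of
observations (within group for mean-centered, paired rows for behavioral)
gives a standard error per salience; the bootstrap ratio
``z = salience / SE`` indexes each feature's reliability. Bootstrap saliences
are sign-aligned to the original ones per LV via their dot product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subsample import SubsampleSet

__all__ = ["PLSResult", "mean_centered_pls", "behavioral_pls", "run_group_pls", "run_behavioral_pls"]


@dataclass
class PLSResult:
    """Latent variables with permutation and bootstrap inference."""

    mode: str                          # "mean_centered" | "behavioral"
    singular_values: np.ndarray        # non-negative, non-increasing
    p_perm: np.ndarray                 # per LV, in (0, 1]
    brain_saliences: pd.DataFrame      # features x LVs, unit-norm columns
    design_saliences: np.ndarray | None = None   # groups/behaviors x LVs
    bootstrap_ratios: pd.DataFrame | None = None # features x LVs
    behavior_correlations: np.ndarray | None = None  # per behavior (LV1)
    behavior_names: list[str] | None = None
    groups: list[str] | None = None
    p_corrected: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)


def _feature_index(X: pd.DataFrame | np.ndarray) -> pd.Index:
    if isinstance(X, pd.DataFrame):
        return X.columns
    return pd.RangeIndex(np.asarray(X).shape[1])


def _contrast_matrix(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Group-mean deviations: group means minus their unweighted mean."""
    M = np.empty((n_groups, X.shape[1]))
    for g in range(n_groups):
        M[g] = X[codes == g].mean(axis=0)
    return M - M.mean(axis=0)


def _oriented_svd(R: np.ndarray, orient: np.ndarray | None = None):
    """SVD with a deterministic sign convention.

    Each LV is flipped so that its design salience has a positive projection
    on ``orient`` (default: the first-group > others contrast direction, i.e.
    the first row of U positive).
    """
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for j in range(len(s)):
        ref = U[0, j] if orient is None else float(orient @ U[:, j])
        if ref < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return U, s, V


def mean_centered_pls(
    X: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    groups: list[str] | None = None,
) -> PLSResult:
    """Mean-centered PLS of observations x features against group labels.

    ``groups`` fixes the row order of the contrast (default: sorted unique
    labels; pass ``["ASD", "TD"]`` for the ASD > TD orientation). Set
    ``n_boot=0`` to skip bootstrap ratios.
    """
    feats = _feature_index(X)
    Xa = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if groups is None:
        groups = sorted(pd.unique(labels))
    codes = np.array([groups.index(l) for l in labels])
    n_groups = len(groups)
    counts = np.bincount(codes, minlength=n_groups)
    if (counts < 2).any():
        small = [groups[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    if not np.isfinite(Xa).all():
        raise ValueError("features must be finite")
    if np.any(Xa.std(axis=0) == 0):
        warnings.warn("constant feature(s) present; their saliences are 0", stacklevel=2)

    R = _contrast_matrix(Xa, codes, n_groups)
    U, s, V = _oriented_svd(R)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(s))
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        s_p = np.linalg.svd(
            _contrast_matrix(Xa, perm, n_groups), compute_uv=False
        )
        exceed += s_p >= s
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    ratios = None
    if n_boot > 0:
        by_group = [np.flatnonzero(codes == g) for g in range(n_groups)]
        boots = np.empty((n_boot, V.shape[0], V.shape[1]))
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(gi, size=len(gi), replace=True) for gi in by_group]
            )
            bcodes = np.concatenate(
                [np.full(len(gi), g) for g, gi in enumerate(by_group)]
            )
            Rb = _contrast_matrix(Xa[idx], bcodes, n_groups)
            _, _, Vb = _oriented_svd(Rb)
            # per-LV sign alignment to the original saliences
            signs = np.sign(np.einsum("fj,fj->j", Vb, V))
            signs[signs == 0] = 1.0
            boots[b] = Vb * signs
        se = boots.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios_arr = np.where(se > 0, V / se, 0.0)
        ratios = pd.DataFrame(ratios_arr, index=feats,
                              columns=[f"LV{j + 1}" for j in range(V.shape[1])])

    return PLSResult(
        mode="mean_centered",
        singular_values=s,
        p_perm=p_perm,
        brain_saliences=pd.DataFrame(
            V, index=feats, columns=[f"LV{j + 1}" for j in range(V.shape[1])]
        ),
        design_saliences=U,
        bootstrap_ratios=ratios,
        groups=list(groups),
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )


def _zscore(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    return (A - A.mean(axis=0)) / sd


def behavioral_pls(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
) -> PLSResult:
    """Behavioral PLS: SVD of the behaviors x features correlation matrix.

    Rows of X (imaging features) and Y (behaviors) must be aligned
    observations. The permutation test shuffles the row correspondence; the
    bootstrap resamples rows jointly. Also reports, for LV1, the overall
    correlation between the LV-projected brain scores and each behavior.
    """
    feats = _feature_index(X)
    bnames = list(_feature_index(Y).astype(str))
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if np.any(Ya.std(axis=0) == 0):
        raise ValueError("constant behavior column(s)")
    n = Xa.shape[0]

    def corr(Xm: np.ndarray, Ym: np.ndarray) -> np.ndarray:
        # constant X columns get zero correlation (their centered values are 0)
        return (_zscore(Ym).T @ _zscore_safe(Xm)) / Xm.shape[0]

    R = corr(Xa, Ya)
    U, s, V = _oriented_svd(R)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(s))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s_p = np.linalg.svd(corr(Xa[perm], Ya), compute_uv=False)
        exceed += s_p >= s
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    ratios = None
    if n_boot > 0:
        boots = np.empty((n_boot, V.shape[0], V.shape[1]))
        for b in range(n_boot):
            idx = rng.choice(n, size=n, replace=True)
            _, _, Vb = _oriented_svd(corr(Xa[idx], Ya[idx]))
            signs = np.sign(np.einsum("fj,fj->j", Vb, V))
            signs[signs == 0] = 1.0
            boots[b] = Vb * signs
        se = boots.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios_arr = np.where(se > 0, V / se, 0.0)
        ratios = pd.DataFrame(ratios_arr, index=feats,
                              columns=[f"LV{j + 1}" for j in range(V.shape[1])])

    # Overall correlation between LV1 brain scores and each behavior.
    # For the correlations the LV is oriented so the mean brain salience is
    # positive; the sign of r then reflects the direction of the raw
    # feature-behavior association (e.g. negative when higher behavior scores
    # go with smaller feature values), independent of the design-side sign
    # convention used for the saliences and bootstrap ratios.
    v1 = V[:, 0] * (1.0 if V[:, 0].mean() >= 0 else -1.0)
    scores = _zscore_safe(Xa) @ v1
    bcorr = np.array(
        [np.corrcoef(scores, Ya[:, j])[0, 1] for j in range(Ya.shape[1])]
    )

    return PLSResult(
        mode="behavioral",
        singular_values=s,
        p_perm=p_perm,
        brain_saliences=pd.DataFrame(
            V, index=feats, columns=[f"LV{j + 1}" for j in range(V.shape[1])]
        ),
        design_saliences=U,
        bootstrap_ratios=ratios,
        behavior_correlations=bcorr,
        behavior_names=bnames,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )


def _zscore_safe(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (A - A.mean(axis=0)) / sd


def run_group_pls(
    shape_sets: dict[str, SubsampleSet],
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    n_parcellations: int = 3,
) -> PLSResult:
    """Group-difference PLS on stacked subsample shape matrices.

    Stacks the per-group K x (ROIs x 3) shape matrices as observations and
    runs mean-centered PLS with the ASD > TD orientation. The reported
    ``p_corrected`` applies a Bonferroni factor for testing several
    parcellations. Asserts the two-group rank-one structure.
    """
    for g, ss in shape_sets.items():
        if ss.shape_matrix is None:
            raise ValueError(f"shape matrix not fitted for group {g}")
        if ss.k < 2:
            raise ValueError("need at least 2 subsamples per group to bootstrap")
    groups = [g for g in ("ASD", "TD") if g in shape_sets] or list(shape_sets)
    mats = [shape_sets[g].shape_matrix for g in groups]
    if not all(mats[0].columns.equals(m.columns) for m in mats[1:]):
        raise ValueError("feature layout differs between groups")
    X = pd.concat(mats, axis=0, ignore_index=True)
    labels = np.concatenate([[g] * shape_sets[g].k for g in groups])

    res = mean_centered_pls(
        X, labels, n_perm=n_perm, n_boot=n_boot, seed=seed, groups=groups
    )
    if len(groups) == 2 and len(res.singular_values) > 1:
        # two-group mean-centered PLS is a rank-one contrast
        assert np.all(
            res.singular_values[1:] <= 1e-8 * max(res.singular_values[0], 1.0)
        ), "two-group contrast should have a single nonzero singular value"
    res.p_corrected = np.minimum(1.0, res.p_perm * n_parcellations)
    return res


def run_behavioral_pls(
    asd_shape_set: SubsampleSet,
    cohort: pd.DataFrame,
    coefficient: str,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    bonferroni: int = 6,
    min_complete: int = 3,
) -> PLSResult:
    """Behavioral PLS of one shape coefficient against subgroup-mean ADOS.

    For every ASD subsample, the three ADOS subscores are averaged over its
    ADOS-complete members (subsamples with fewer than ``min_complete``
    complete members are dropped with a warning). X is the subsamples x ROIs
    matrix of the chosen coefficient (``"slope"``, ``"curvature"`` or
    ``"aberrancy"``); Y is the subsamples x 3 mean-ADOS matrix. The reported
    ``p_corrected`` applies a Bonferroni factor for the family of
    coefficient x parcellation analyses (6 in the full design).
    """
    if asd_shape_set.shape_matrix is None:
        raise ValueError("shape matrix not fitted")
    ados = cohort.set_index("subject_id")[["ados_comm", "ados_social", "ados_stereo"]]
    rows, Y = [], []
    for i, ids in enumerate(asd_shape_set.subsamples):
        sub = ados.loc[ids].dropna()
        if len(sub) < min_complete:
            warnings.warn(
                f"subsample {i}: only {len(sub)} ADOS-complete subjects; dropped",
                stacklevel=2,
            )
            continue
        rows.append(i)
        Y.append(sub.mean(axis=0).to_numpy())
    if len(rows) < 3:
        raise ValueError("too few ADOS-complete subsamples for behavioral PLS")
    sm = asd_shape_set.shape_matrix
    X = sm.loc[rows, sm.columns.get_level_values("coef") == coefficient]
    X.columns = X.columns.get_level_values("roi")
    Ydf = pd.DataFrame(Y, columns=["ados_comm", "ados_social", "ados_stereo"])

    res = behavioral_pls(X, Ydf, n_perm=n_perm, n_boot=n_boot, seed=seed)
    res.p_corrected = np.minimum(1.0, res.p_perm * bonferroni)
    return res
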