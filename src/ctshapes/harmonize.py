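"""Inter-center variance removal for multi-site CT tables.

Scanner and site differences add roughly constant per-center offsets to CT.
They are estimated, per ROI, by an ordinary-least-squares model of CT on
dummy-coded centers alongside the biological terms whose variance must be
preserved — polynomial age terms, a +/-1 diagnostic-group code, and
age^k x group interactions up to the chosen polynomial degree:

    degree 1:  CT ~ 1 + center + age + group + age:group
    degree 2:  ... + age^2 + age^2:group
    degree 3:  ... + age^3 + age^3:group

Only the fitted center effects are then subtracted from the data. Effects are
re-centered to a size-weighted zero mean before subtraction, so each ROI's
grand mean (and the physiological millimeter scale) is preserved regardless
of which center served as the dummy-coding reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["HarmonizationFit", "build_design", "fit_center_model", "remove_center_variance"]

_RCOND = 1e-10


@dataclass
class HarmonizationFit:
    """OLS fit of one ROI's center-adjustment model."""

    roi: str
    degree: int
    params: pd.Series               # coefficient per design column
    center_effects: pd.Series       # per center incl. reference (= 0)
    reference_center: str

    @property
    def intercept(self) -> float:
        return float(self.params["const"])


def _group_code(cohort: pd.DataFrame) -> np.ndarray:
    return np.where(cohort["group"].to_numpy() == "ASD", 1.0, -1.0)


def build_design(cohort: pd.DataFrame, degree: int) -> pd.DataFrame:
    """Design matrix for the center-adjustment model at ``degree`` (1-3).

    Columns: ``const``, one ``center:<name>`` dummy per non-reference center
    (the first center in sorted order is the reference), ``age^k`` for
    k = 1..degree, ``group`` (+1 ASD / -1 TD), and ``age^k:group``
    interactions — ``(n_centers - 1) + 2*degree + 2`` columns in total.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2, or 3")
    age = cohort["age"].to_numpy(dtype=float)
    grp = _group_code(cohort)
    centers = sorted(cohort["center"].unique())
    cols: dict[str, np.ndarray] = {"const": np.ones(len(cohort))}
    for c in centers[1:]:
        cols[f"center:{c}"] = (cohort["center"] == c).to_numpy(dtype=float)
    for k in range(1, degree + 1):
        cols[f"age^{k}" if k > 1 else "age"] = age**k
    cols["group"] = grp
    for k in range(1, degree + 1):
        cols[f"age^{k}:group" if k > 1 else "age:group"] = (age**k) * grp
    return pd.DataFrame(cols, index=cohort.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    _, R = np.linalg.qr(arr)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps * 1e3
    bad = diag < tol
    if bad.any():
        names = [X.columns[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"design matrix is rank deficient; collinear column(s): {names}"
        )


def fit_center_model(
    ct_roi: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    degree: int,
    roi: str = "",
) -> HarmonizationFit:
    """Fit the center-adjustment OLS model for a single ROI."""
    centers = sorted(cohort["center"].unique())
    if len(centers) < 2:
        raise ValueError("need at least 2 centers to estimate center effects")
    X = build_design(cohort, degree)
    _check_rank(X)
    y = np.asarray(ct_roi, dtype=float)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=_RCOND)
    params = pd.Series(beta, index=X.columns)
    effects = pd.Series(0.0, index=pd.Index(centers, name="center"))
    for c in centers[1:]:
        effects[c] = params[f"center:{c}"]
    return HarmonizationFit(
        roi=roi, degree=degree, params=params,
        center_effects=effects, reference_center=centers[0],
    )


def remove_center_variance(
    ct: pd.DataFrame, cohort: pd.DataFrame, degree: int
) -> pd.DataFrame:
    """Subtract estimated center effects from every ROI.

    With a single center the data are returned unchanged. Otherwise, for each
    ROI the fitted per-center effects (reference = 0) are re-centered to a
    size-weighted zero mean and subtracted from that center's subjects; the
    per-ROI grand mean is therefore preserved. Non-positive adjusted values
    are logged, never clipped.
    """
    ct = ct.loc[cohort["subject_id"].to_numpy()]
    centers = sorted(cohort["center"].unique())
    if len(centers) < 2:
        return ct.copy()
    sizes = cohort["center"].value_counts()
    weights = sizes.reindex(centers).to_numpy(dtype=float)
    weights /= weights.sum()

    X = build_design(cohort, degree)
    _check_rank(X)
    # one multi-RHS solve for all ROIs at once
    beta, *_ = np.linalg.lstsq(X.to_numpy(), ct.to_numpy(), rcond=_RCOND)
    params = pd.DataFrame(beta, index=X.columns, columns=ct.columns)
    # per-center effect rows (reference center = 0), ROIs as columns
    effects = pd.DataFrame(0.0, index=centers, columns=ct.columns)
    for c in centers[1:]:
        effects.loc[c] = params.loc[f"center:{c}"]
    effects -= weights @ effects.to_numpy()  # size-weighted re-centering

    per_subject = effects.loc[cohort["center"].to_numpy()].to_numpy()
    adjusted = pd.DataFrame(
        ct.to_numpy() - per_subject, index=ct.index, columns=ct.columns
    )
    n_nonpos = int((adjusted.to_numpy() <= 0).sum())
    if n_nonpos:
        logger.warning("%d adjusted CT value(s) are non-positive", n_nonpos)
    return adjusted
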