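"""Per-group polynomial trajectory models of CT against age.

Each ROI x group is fitted with linear, quadratic, and cubic polynomials of
age. The highest-order coefficient of each model is the "trajectory shape"
parameter: slope (mm/yr) for degree 1, curvature (mm/yr^2) for degree 2,
aberrancy (mm/yr^3) for degree 3. Goodness of fit is assessed with a
likelihood-ratio deviance test against the intercept-only model (Gaussian ML,
chi-squared reference with df = degree), and ROIs failing a Benjamini-Hochberg
FDR screen are masked out of all downstream stages.

For negative-curvature quadratic trajectories, the "turning point" — the age
at which the trajectory is furthest (vertically) from the chord joining its
endpoints — marks the transition from decreased to increased cortical
thinning; for a quadratic it falls analytically at the midpoint of the age
window (18 years on [6, 30]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrajectoryFit",
    "ROIMask",
    "fit_trajectory",
    "fit_many",
    "deviance_test",
    "fdr_mask",
    "compute_mask",
    "turning_point",
    "SHAPE_NAMES",
]

SHAPE_NAMES = {1: "slope", 2: "curvature", 3: "aberrancy"}


@dataclass
class TrajectoryFit:
    """Least-squares polynomial fit of CT against age for one ROI x group."""

    roi: str
    group: str
    degree: int
    coef: np.ndarray          # ascending order, length degree + 1
    rss: float                # residual sum of squares of the full model
    rss_null: float           # RSS of the intercept-only model
    n: int
    degenerate: bool = False  # zero residual variance in the full model

    @property
    def shape(self) -> float:
        """The trajectory-shape parameter: the degree-d coefficient."""
        return float(self.coef[self.degree])

    def predict(self, ages: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ages, float), self.coef)


@dataclass
class ROIMask:
    """Per ROI x degree keep flags from the goodness-of-fit screen."""

    keep: pd.DataFrame        # index: ROI, columns: degrees, bool
    rule: str = "both_groups"
    q: float = 0.05

    def kept(self, degree: int) -> list[str]:
        return list(self.keep.index[self.keep[degree]])

    def kept_all_degrees(self) -> list[str]:
        """ROIs kept at every degree (the combined-feature layout)."""
        return list(self.keep.index[self.keep.all(axis=1)])


def _vander(ages: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(ages, degree + 1, increasing=True)


def fit_trajectory(
    ages: np.ndarray, ct_roi: np.ndarray, degree: int,
    roi: str = "", group: str = "",
) -> TrajectoryFit:
    """Fit a degree-d polynomial of CT on age by least squares.

    Input must be group-pure (one group's subjects only); no group or center
    terms appear in the model.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(ct_roi, dtype=float)
    if len(ages) <= degree + 1:
        raise ValueError(f"need more than {degree + 1} subjects for degree {degree}")
    X = _vander(ages, degree)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("singular design: ages do not span the polynomial basis")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dev_null = y - y.mean()
    return TrajectoryFit(
        roi=roi, group=group, degree=degree, coef=coef,
        rss=rss, rss_null=float(dev_null @ dev_null), n=len(y),
        degenerate=rss == 0.0,
    )


def fit_many(ages: np.ndarray, Y: np.ndarray, degree: int) -> np.ndarray:
    """Vectorized polynomial fit for many ROIs at once.

    Parameters
    ----------
    Y : (n_subjects, n_rois)

    Returns
    -------
    (degree + 1, n_rois) coefficient matrix, ascending order.
    """
    X = _vander(np.asarray(ages, dtype=float), degree)
    coef, *_ = np.linalg.lstsq(X, np.asarray(Y, dtype=float), rcond=None)
    return coef


def deviance_test(fit: TrajectoryFit) -> float:
    """Likelihood-ratio test of the polynomial against the constant model.

    Under Gaussian maximum likelihood the deviance statistic is
    ``n * ln(RSS_null / RSS_full)``, referred to a chi-squared distribution
    with ``degree`` degrees of freedom. A perfect full-model fit (zero
    residual variance) returns p = 0 with the fit flagged degenerate.
    """
    if fit.rss <= 1e-12 * max(fit.rss_null, 1e-300):
        # zero residual variance in the full model (to round-off)
        fit.degenerate = True
        return 0.0 if fit.rss_null > fit.rss else 1.0
    if fit.rss_null <= fit.rss:
        # the polynomial cannot fit worse than the constant up to round-off
        return 1.0
    stat = fit.n * np.log(fit.rss_null / fit.rss)
    return float(stats.chi2.sf(stat, df=fit.degree))


def fdr_mask(
    pvals: pd.DataFrame, q: float = 0.05, rule: str = "both_groups"
) -> pd.Series:
    """Benjamini-Hochberg screen of per-ROI deviance p-values for one degree.

    ``pvals`` has ROIs as index and one column per group; BH runs within each
    group (one family per group x degree x parcellation). An ROI is kept when
    it passes in both groups (``rule="both_groups"``, default) or in at least
    one (``rule="any_group"``).
    """
    if pvals.empty:
        raise ValueError("empty p-value table")
    if rule not in ("both_groups", "any_group"):
        raise ValueError(f"unknown mask rule {rule!r}")
    passed = pd.DataFrame(index=pvals.index, columns=pvals.columns, dtype=bool)
    for col in pvals.columns:
        rej, *_ = multipletests(pvals[col].to_numpy(), alpha=q, method="fdr_bh")
        passed[col] = rej
    return passed.all(axis=1) if rule == "both_groups" else passed.any(axis=1)


def compute_mask(
    ct_by_degree: dict[int, pd.DataFrame],
    cohort: pd.DataFrame,
    degrees: tuple[int, ...] = (1, 2, 3),
    q: float = 0.05,
    rule: str = "both_groups",
) -> ROIMask:
    """Full-sample goodness-of-fit mask across degrees and groups.

    ``ct_by_degree`` maps each degree to the CT table harmonized with that
    degree's adjustment model.
    """
    rois = list(ct_by_degree[degrees[0]].columns)
    keep = pd.DataFrame(index=pd.Index(rois, name="roi"), columns=list(degrees), dtype=bool)
    for d in degrees:
        ct = ct_by_degree[d]
        pv = pd.DataFrame(index=rois, columns=["ASD", "TD"], dtype=float)
        for g in ("ASD", "TD"):
            sel = cohort["group"] == g
            ages = cohort.loc[sel, "age"].to_numpy()
            Y = ct.loc[cohort.loc[sel, "subject_id"].to_numpy()].to_numpy()
            n = len(ages)
            X = _vander(ages, d)
            coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
            rss = ((Y - X @ coef) ** 2).sum(axis=0)
            rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
            with np.errstate(divide="ignore"):
                stat = np.where(rss > 0, n * np.log(np.maximum(rss0, rss) /
                                                    np.where(rss > 0, rss, 1.0)),
                                np.inf)
            pv[g] = stats.chi2.sf(stat, df=d)
        keep[d] = fdr_mask(pv, q=q, rule=rule)
    return ROIMask(keep=keep, rule=rule, q=q)


def turning_point(
    fit: TrajectoryFit, age_lo: float = 6.0, age_hi: float = 30.0
) -> float:
    """Age of maximum vertical distance between a concave quadratic and its chord.

    A straight line is traced between the fitted CT at ``age_lo`` and
    ``age_hi``; the turning point is the age in the window where the quadratic
    trajectory is furthest (vertically) from that line. For a quadratic the
    distance ``f(a) - chord(a) = c (a - lo)(a - hi)`` is itself a parabola,
    so the maximizer is exactly the window midpoint, independent of slope and
    intercept. Requires degree 2 and negative curvature.
    """
    if fit.degree != 2:
        raise ValueError("turning point is defined for quadratic fits only")
    if fit.shape >= 0:
        raise ValueError("turning point requires negative curvature")
    return 0.5 * (age_lo + age_hi)
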