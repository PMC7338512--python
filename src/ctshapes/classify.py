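"""SVM classification of developmental trajectory shapes.

The unit of classification is a *subsample trajectory shape*, not a subject:
the cohort is split in half within two-year age bins (independently per
group), entropy-guided subsampling builds per-group shape matrices on each
half, and a linear-kernel support vector machine (unit box penalty) trained
on the training half's subsample rows predicts group membership of the test
half's rows; features are standardized with the training half's statistics
by default (see :func:`train_eval_svm` for why and how to disable it).
Repeating the whole
split -> subsample -> fit -> evaluate cycle yields distributions of accuracy,
sensitivity (ASD recall), and specificity (TD recall), which are compared
across the three polynomial shape coefficients with independent t-tests under
BH-FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .subsample import SubsampleSet, draw_and_select, fit_subsamples

__all__ = [
    "ClassificationReport",
    "stratified_age_split",
    "train_eval_svm",
    "cross_validate",
    "compare_models",
    "metric_covariate_correlations",
]

METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass
class ClassificationReport:
    """Per-repeat classification metrics and covariates."""

    coefficient: str
    per_repeat: pd.DataFrame   # columns: accuracy/sensitivity/specificity (%),
                               # mean_ados, n_females
    seed: int | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def summary(self) -> pd.DataFrame:
        """Mean, SD, and empirical 5th/95th percentiles per metric."""
        rows = {}
        for m in METRICS:
            v = self.per_repeat[m].to_numpy()
            rows[m] = {
                "mean": v.mean(),
                "std": v.std(ddof=1) if len(v) > 1 else 0.0,
                "ci5": np.percentile(v, 5),
                "ci95": np.percentile(v, 95),
            }
        return pd.DataFrame(rows).T


def stratified_age_split(
    cohort: pd.DataFrame, bin_width: float = 2.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half/half split within group x 2-year age bins.

    Odd bin counts assign the extra subject to train or test with probability
    one half; empty bins are skipped. Deterministic given seed.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    edges = np.arange(6.0, 30.0 + bin_width, bin_width)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for _, gdf in cohort.groupby("group", observed=True):
        bins = np.clip(np.searchsorted(edges, gdf["age"].to_numpy(), side="right") - 1,
                       0, len(edges) - 2)
        for b in np.unique(bins):
            rows = gdf.index.to_numpy()[bins == b]
            rows = rng.permutation(rows)
            half = len(rows) // 2
            if len(rows) % 2 == 1 and rng.uniform() < 0.5:
                half += 1
            train_idx.append(rows[:half])
            test_idx.append(rows[half:])
    train = cohort.loc[np.concatenate(train_idx)].reset_index(drop=True)
    test = cohort.loc[np.concatenate(test_idx)].reset_index(drop=True)
    return train, test


def _coef_block(ss: SubsampleSet, coefficient: str) -> np.ndarray:
    sm = ss.shape_matrix
    if sm is None:
        raise ValueError("shape matrix not fitted")
    block = sm.loc[:, sm.columns.get_level_values("coef") == coefficient]
    return block.to_numpy()


def train_eval_svm(
    train_shapes: dict[str, SubsampleSet],
    test_shapes: dict[str, SubsampleSet],
    coefficient: str,
    standardize: bool = True,
) -> tuple[float, float, float]:
    """Train a linear SVM on training-half subsample shapes, evaluate on test.

    Only the chosen coefficient's ROI columns are used. Returns accuracy,
    sensitivity (ASD recall), and specificity (TD recall) in percent.

    By default features are z-scored with the training half's means and SDs.
    Shape coefficients live on mm/yr^d scales of 1e-3 and below, where a unit
    box penalty leaves the hinge loss essentially unfit (every row inside the
    margin); standardization restores a well-posed margin problem. Pass
    ``standardize=False`` for the raw-scale behavior of common SVM toolbox
    defaults.
    """
    Xtr = np.vstack([_coef_block(train_shapes[g], coefficient) for g in ("ASD", "TD")])
    Xte = np.vstack([_coef_block(test_shapes[g], coefficient) for g in ("ASD", "TD")])
    if Xtr.shape[1] != Xte.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    if standardize:
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    ytr = np.concatenate(
        [np.ones(train_shapes["ASD"].k), np.zeros(train_shapes["TD"].k)]
    )
    yte = np.concatenate(
        [np.ones(test_shapes["ASD"].k), np.zeros(test_shapes["TD"].k)]
    )
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = 100.0 * float((pred == yte).mean())
    sens = 100.0 * float((pred[yte == 1] == 1).mean())
    spec = 100.0 * float((pred[yte == 0] == 0).mean())
    return acc, sens, spec


def cross_validate(
    cohort: pd.DataFrame,
    ct: pd.DataFrame,
    coefficient: str,
    rois: list[str],
    n_repeats: int = 500,
    seed: int = 0,
    n_per_subsample: int = 70,
    n_candidates: int = 2000,
    K: int = 80,
    bin_width: float = 2.0,
    ct_by_degree: dict[int, pd.DataFrame] | None = None,
    standardize: bool = True,
) -> ClassificationReport:
    """Repeat split -> subsample -> fit -> train -> evaluate ``n_repeats`` times.

    Inputs are assumed preprocessed and harmonized. Each repeat draws its
    split and per-group subsample seeds from the master seed; entropy
    selection is re-run within every repeat on each half. Per-repeat
    covariates (mean ADOS over the ASD test half, number of females in the
    test half) are recorded for the covariate-correlation check.
    """
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(5 * n_repeats).reshape(n_repeats, 5) % (2**31)
    records = []
    for r in range(n_repeats):
        s_split, s_a_tr, s_t_tr, s_a_te, s_t_te = (int(x) for x in repeat_seeds[r])
        try:
            train, test = stratified_age_split(cohort, bin_width=bin_width, seed=s_split)
            halves: dict[str, dict[str, SubsampleSet]] = {}
            for name, half, seeds in (
                ("train", train, (s_a_tr, s_t_tr)),
                ("test", test, (s_a_te, s_t_te)),
            ):
                halves[name] = {}
                for g, s_g in zip(("ASD", "TD"), seeds):
                    part = half[half["group"] == g]
                    sset = draw_and_select(
                        part, n=n_per_subsample, n_candidates=n_candidates,
                        K=K, seed=s_g,
                    )
                    halves[name][g] = fit_subsamples(
                        sset, ct, cohort, rois, ct_by_degree=ct_by_degree
                    )
            train_ids = set(train["subject_id"])
            test_ids = set(test["subject_id"])
            assert not train_ids & test_ids, "train/test subjects overlap"
            acc, sens, spec = train_eval_svm(
                halves["train"], halves["test"], coefficient,
                standardize=standardize,
            )
        except ValueError as exc:
            raise RuntimeError(f"cross-validation repeat {r} failed: {exc}") from exc
        test_asd = test[test["group"] == "ASD"]
        mean_ados = test_asd[["ados_comm", "ados_social", "ados_stereo"]].mean(
            axis=1
        ).mean()
        records.append(
            {
                "accuracy": acc, "sensitivity": sens, "specificity": spec,
                "mean_ados": mean_ados,
                "n_females": int((test["sex"] == "F").sum()),
            }
        )
    return ClassificationReport(
        coefficient=coefficient, per_repeat=pd.DataFrame(records), seed=seed
    )


def compare_models(
    reports: dict[str, ClassificationReport], q: float = 0.05
) -> pd.DataFrame:
    """Pairwise independent t-tests between coefficients' metric distributions.

    Returns a tidy table (metric, model_a, model_b, t, p, p_fdr, direction)
    with BH-FDR applied across all pairwise tests of the parcellation.
    ``direction`` is ``">"`` when model_a's mean exceeds model_b's.
    """
    names = list(reports)
    if len(names) < 2:
        raise ValueError("need at least two reports to compare")
    n0 = reports[names[0]].n_repeats
    if any(reports[n].n_repeats != n0 for n in names):
        raise ValueError("reports must have equal n_repeats")
    rows = []
    for m in METRICS:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                va = reports[a].per_repeat[m].to_numpy()
                vb = reports[b].per_repeat[m].to_numpy()
                if np.array_equal(va, vb):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(va, vb)
                rows.append(
                    {
                        "metric": m, "model_a": a, "model_b": b,
                        "t": float(t), "p": float(p),
                        "direction": ">" if va.mean() > vb.mean() else
                                     ("<" if va.mean() < vb.mean() else "="),
                    }
                )
    table = pd.DataFrame(rows)
    rej, p_fdr, *_ = multipletests(table["p"].to_numpy(), alpha=q, method="fdr_bh")
    table["p_fdr"] = p_fdr
    table["significant"] = rej
    return table


def metric_covariate_correlations(report: ClassificationReport) -> pd.DataFrame:
    """Pearson correlation of each metric with each per-repeat covariate."""
    rows = []
    for cov in ("mean_ados", "n_females"):
        x = report.per_repeat[cov].to_numpy(dtype=float)
        for m in METRICS:
            y = report.per_repeat[m].to_numpy()
            if not np.isfinite(x).all() or np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"constant {cov} or {m}; correlation undefined",
                              stacklevel=2)
                rows.append({"metric": m, "covariate": cov,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"metric": m, "covariate": cov,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
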