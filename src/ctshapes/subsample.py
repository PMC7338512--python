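"""Entropy-guided subject subsampling.

The trajectory-shape parameters are constants of a whole sample: a single fit
yields one slope/curvature/aberrancy per ROI. To obtain a *distribution* of
shape estimates within each group, many subject subsets are drawn without
replacement and the polynomial models are refitted on each. Subsets are
screened by the Shannon entropy of their age histogram — the most
uniform-in-age subsets are retained — so every retained subset spans the age
range instead of clustering at the cohort's dense ages.

Defaults follow the full-scale design (70 subjects per subsample, top 80 of
100,000 candidates); tests and fast runs use reduced candidate counts, which
only lowers the entropy ceiling, not the selection logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import SHAPE_NAMES, fit_many

__all__ = ["SubsampleSet", "age_entropy", "default_bin_edges", "draw_and_select", "fit_subsamples"]


def default_bin_edges(age_lo: float = 6.0, age_hi: float = 30.0) -> np.ndarray:
    """One-year histogram bins covering the age window (24 bins on [6, 30])."""
    return np.arange(age_lo, age_hi + 1.0, 1.0)


@dataclass
class SubsampleSet:
    """K selected subject subsets for one group, with their shape matrix."""

    group: str
    n_per_subsample: int
    subsamples: list[np.ndarray]          # K arrays of subject IDs
    entropies: np.ndarray                 # nats, one per selected subsample
    shape_matrix: pd.DataFrame | None = None  # K x (kept ROIs x 3), ROI-major
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.subsamples)


def age_entropy(ages: np.ndarray, bin_edges: np.ndarray | None = None) -> float:
    """Shannon entropy (nats) of the normalized age histogram.

    Empty bins contribute zero; a point mass has entropy 0 and an exactly
    uniform histogram over B bins has entropy ln(B).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("need at least one age")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    if ages.min() < bin_edges[0] or ages.max() > bin_edges[-1]:
        raise ValueError(
            f"ages outside bin coverage [{bin_edges[0]}, {bin_edges[-1]}]"
        )
    counts, _ = np.histogram(ages, bins=bin_edges)
    p = counts[counts > 0] / ages.size
    return float(-(p * np.log(p)).sum())


def _batch_entropy(age_matrix: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Entropy of each row of an (n_candidates, n) age matrix."""
    nc, n = age_matrix.shape
    # np.histogram semantics: last bin closed on the right
    idx = np.searchsorted(bin_edges, age_matrix, side="right") - 1
    idx = np.clip(idx, 0, len(bin_edges) - 2)
    flat = idx + (len(bin_edges) - 1) * np.arange(nc)[:, None]
    counts = np.bincount(flat.ravel(), minlength=nc * (len(bin_edges) - 1))
    counts = counts.reshape(nc, len(bin_edges) - 1)
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def draw_and_select(
    cohort_group: pd.DataFrame,
    n: int = 70,
    n_candidates: int = 2000,
    K: int = 80,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> SubsampleSet:
    """Draw candidate subsamples and keep the K with highest age entropy.

    Each candidate is ``n`` subjects drawn without replacement from the
    group's cohort rows. Ties in entropy are broken by candidate draw order
    (deterministic given seed); duplicate candidate subject sets are allowed.
    """
    ids = cohort_group["subject_id"].to_numpy()
    ages = cohort_group["age"].to_numpy(dtype=float)
    groups = cohort_group["group"].unique()
    group = groups[0] if len(groups) == 1 else "mixed"
    if len(ids) < n:
        raise ValueError(
            f"group has {len(ids)} subjects, fewer than n={n}; "
            f"use a smaller subsample size (e.g. the single-center config uses n=40)"
        )
    if K > n_candidates:
        raise ValueError("K cannot exceed the number of candidates")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    if ages.min() < bin_edges[0] or ages.max() > bin_edges[-1]:
        raise ValueError("cohort ages outside bin coverage")

    rng = np.random.default_rng(seed)
    m = len(ids)
    indices = np.empty((n_candidates, n), dtype=np.int64)
    for i in range(n_candidates):
        indices[i] = rng.choice(m, size=n, replace=False)
    ent = _batch_entropy(ages[indices], bin_edges)
    # top-K, ties broken by draw order (stable sort on negated entropy);
    # selected subsamples are reported in draw order
    top = np.argsort(-ent, kind="stable")[:K]
    sel = np.sort(top)
    return SubsampleSet(
        group=group,
        n_per_subsample=n,
        subsamples=[ids[indices[i]] for i in sel],
        entropies=ent[sel],
        seed=seed,
    )


def fit_subsamples(
    sset: SubsampleSet,
    ct: pd.DataFrame,
    cohort: pd.DataFrame,
    rois: list[str],
    ct_by_degree: dict[int, pd.DataFrame] | None = None,
) -> SubsampleSet:
    """Fill the subsample shape matrix: K rows x (ROIs x 3 coefficients).

    For every subsample, degrees 1-3 are fitted on that subsample's subjects
    and the highest-order coefficient of each model is stored. Columns are
    ROI-major: ``(roi, slope), (roi, curvature), (roi, aberrancy)`` per kept
    ROI. Pass ``ct_by_degree`` to fit each degree on its own (degree-matched
    harmonized) CT table; otherwise ``ct`` is used for all degrees.
    """
    columns = pd.MultiIndex.from_tuples(
        [(roi, SHAPE_NAMES[d]) for roi in rois for d in (1, 2, 3)],
        names=["roi", "coef"],
    )
    # positional lookups once, numpy thereafter (subsamples are many and small)
    tables = {d: (ct if ct_by_degree is None else ct_by_degree[d]) for d in (1, 2, 3)}
    index = tables[1].index
    arrays = {d: t[rois].to_numpy() for d, t in tables.items()}
    ages_aligned = (
        cohort.set_index("subject_id")["age"].reindex(index).to_numpy(dtype=float)
    )
    out = np.empty((sset.k, len(columns)))
    for i, ids in enumerate(sset.subsamples):
        rows = index.get_indexer(ids)
        if (rows < 0).any():
            missing = np.asarray(ids)[rows < 0][:3]
            raise ValueError(f"subsample {i}: subjects missing from CT: {missing}")
        ages = ages_aligned[rows]
        if np.unique(ages).size < 4:
            raise ValueError(f"subsample {i}: ages do not span a cubic basis")
        row = np.empty((len(rois), 3))
        for d in (1, 2, 3):
            coef = fit_many(ages, arrays[d][rows], d)
            row[:, d - 1] = coef[d]
        out[i] = row.ravel()
    sset.shape_matrix = pd.DataFrame(out, columns=columns)
    return sset
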