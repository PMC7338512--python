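"""Cohort filters and CT outlier rejection.

Three screens are applied before any modeling: an age window (closed interval,
default 6-30 years), removal of centers too small to support per-center
statistics (default: fewer than 10 subjects in either diagnostic group), and a
per-center z-score screen that discards subjects whose CT is extreme in any
ROI. All filters are single-pass and idempotent.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["filter_age", "filter_small_centers", "zscore_outlier_filter"]


def filter_age(
    cohort: pd.DataFrame, min_age: float = 6.0, max_age: float = 30.0
) -> pd.DataFrame:
    """Keep subjects with ``min_age <= age <= max_age`` (boundaries retained)."""
    out = cohort[(cohort["age"] >= min_age) & (cohort["age"] <= max_age)]
    if out.empty:
        raise ValueError(f"no subjects remain in age window [{min_age}, {max_age}]")
    return out.reset_index(drop=True)


def filter_small_centers(
    cohort: pd.DataFrame, min_per_group: int = 10
) -> pd.DataFrame:
    """Drop centers with fewer than ``min_per_group`` subjects in either group.

    A center is retained iff it has at least ``min_per_group`` ASD *and*
    ``min_per_group`` TD subjects; all subjects of dropped centers are removed.
    """
    counts = cohort.groupby(["center", "group"], observed=True).size().unstack(
        fill_value=0
    )
    for g in ("ASD", "TD"):
        if g not in counts.columns:
            counts[g] = 0
    keep = counts.index[(counts["ASD"] >= min_per_group) & (counts["TD"] >= min_per_group)]
    if len(keep) == 0:
        raise ValueError(
            f"no center has >= {min_per_group} subjects in both groups"
        )
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("dropping %d small center(s): %s", len(dropped), dropped)
    out = cohort[cohort["center"].isin(keep)]
    return out.reset_index(drop=True)


def zscore_outlier_filter(
    ct: pd.DataFrame,
    cohort: pd.DataFrame,
    threshold: float = 3.0,
    sidecar: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Remove subjects whose CT is a within-center outlier in any ROI.

    For each center and ROI, CT values are z-scored across that center's
    subjects (both groups pooled; SD with one delta degree of freedom). A
    subject is removed if any |z| exceeds ``threshold``. The z-scores are
    computed once on the original data — removed subjects do not trigger a
    re-screen. ROIs with zero within-center SD contribute z = 0 (logged).

    Returns the filtered CT table, the filtered cohort, and the removed IDs
    (optionally also written to a sidecar CSV for audit).
    """
    ct = ct.loc[cohort["subject_id"].to_numpy()]
    removed: list[str] = []
    for center, members in cohort.groupby("center", observed=True):
        ids = members["subject_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(
                f"center {center!r} has fewer than 2 subjects; cannot z-score"
            )
        block = ct.loc[ids].to_numpy()
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.info(
                "center %s: %d ROI(s) with zero SD, z set to 0", center, zero.sum()
            )
        sd = np.where(zero, 1.0, sd)
        z = (block - mean) / sd
        z[:, zero] = 0.0
        bad = np.abs(z).max(axis=1) > threshold
        removed.extend(ids[bad])

    keep = ~cohort["subject_id"].isin(removed)
    out_cohort = cohort[keep].reset_index(drop=True)
    out_ct = ct.loc[out_cohort["subject_id"].to_numpy()]
    if sidecar is not None:
        pd.DataFrame({"subject_id": removed}).to_csv(sidecar, index=False)
    return out_ct, out_cohort, removed
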