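"""End-to-end orchestration with config and seed management.

``run_all`` executes the full analysis in workflow order — preprocessing,
degree-specific harmonization, goodness-of-fit masking, entropy subsampling,
group PLS, behavioral PLS (when ADOS scores are present), the turning-point
statistic, and (optionally) SVM classification — and returns a JSON-ready
results bundle. One master seed spawns a fixed, documented sequence of
per-stage child seeds, so every stage is individually reproducible and a
rerun with the same inputs and config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import classify as _classify
from . import harmonize, preprocess, pls, subsample, trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seeds", "run_all"]

#: fixed order in which child seeds are spawned from the master seed
STAGES = (
    "subsample_asd", "subsample_td", "pls_group", "pls_behavior", "classify",
)


@dataclass
class RunConfig:
    """Tunable parameters of a full run (defaults are the fast test scale)."""

    parcellation: str = "custom"
    degrees: tuple[int, ...] = (1, 2, 3)
    mask_rule: str = "both_groups"
    mask_q: float = 0.05
    # subsampling
    n_per_subsample: int = 70
    n_candidates: int = 2000
    K: int = 80
    # behavioral PLS subgrouping
    ados_n_per_subsample: int = 20
    ados_K: int = 400
    # PLS inference
    n_perm: int = 1000
    n_boot: int = 1000
    bonferroni_parcellations: int = 3
    bonferroni_behavioral: int = 6
    # classification
    classify_repeats: int = 0          # 0 = skip the classification stage
    classify_bin_width: float = 2.0
    # preprocessing
    min_age: float = 6.0
    max_age: float = 30.0
    min_per_group: int = 10
    z_threshold: float = 3.0
    # single-center mode ("" = all centers, harmonized)
    center: str = ""
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "degrees" in d:
            d = {**d, "degrees": tuple(d["degrees"])}
        return cls(**d)

    def digest(self) -> str:
        payload = {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def stage_seeds(master: int) -> dict[str, int]:
    """Per-stage child seeds spawned from the master seed (< 2**31)."""
    state = np.random.SeedSequence(master).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def run_all(
    config: RunConfig, cohort: pd.DataFrame, ct: pd.DataFrame
) -> dict[str, Any]:
    """Execute the full pipeline on in-memory tables; see module docstring."""
    t0 = time.time()
    seeds = stage_seeds(config.seed)
    results: dict[str, Any] = {
        "config": asdict(config) | {"degrees": list(config.degrees)},
        "config_hash": config.digest(),
        "seeds": seeds,
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)
        results["stages"][name] = round(time.time() - t0, 2)

    try:
        stage("preprocess")
        cohort = preprocess.filter_age(cohort, config.min_age, config.max_age)
        if config.center:
            cohort = cohort[cohort["center"] == config.center].reset_index(drop=True)
            if cohort.empty:
                raise ValueError(f"no subjects from center {config.center!r}")
        else:
            cohort = preprocess.filter_small_centers(cohort, config.min_per_group)
        ct, cohort, removed = preprocess.zscore_outlier_filter(
            ct, cohort, config.z_threshold
        )
        results["n_subjects"] = len(cohort)
        results["n_removed_outliers"] = len(removed)

        stage("harmonize")
        if config.center or cohort["center"].nunique() == 1:
            ct_by_degree = {d: ct for d in config.degrees}
        else:
            ct_by_degree = {
                d: harmonize.remove_center_variance(ct, cohort, d)
                for d in config.degrees
            }

        stage("fit")
        mask = trajectory.compute_mask(
            ct_by_degree, cohort, degrees=config.degrees,
            q=config.mask_q, rule=config.mask_rule,
        )
        rois = mask.kept_all_degrees()
        results["n_rois_kept"] = len(rois)
        if not rois:
            raise ValueError("goodness-of-fit mask removed every ROI")

        stage("subsample")
        sets: dict[str, subsample.SubsampleSet] = {}
        for g, s_g in (("ASD", seeds["subsample_asd"]), ("TD", seeds["subsample_td"])):
            part = cohort[cohort["group"] == g]
            sset = subsample.draw_and_select(
                part, n=config.n_per_subsample,
                n_candidates=config.n_candidates, K=config.K, seed=s_g,
            )
            sets[g] = subsample.fit_subsamples(
                sset, ct, cohort, rois, ct_by_degree=ct_by_degree
            )

        stage("pls_group")
        gres = pls.run_group_pls(
            sets, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=seeds["pls_group"],
            n_parcellations=config.bonferroni_parcellations,
        )
        results["group_pls"] = {
            "singular_values": gres.singular_values,
            "p_perm": gres.p_perm,
            "p_corrected": gres.p_corrected,
            "bootstrap_ratios": {
                f"{roi}:{coef}": float(z)
                for (roi, coef), z in gres.bootstrap_ratios["LV1"].items()
            } if gres.bootstrap_ratios is not None else None,
        }

        stage("turning_point")
        tps = []
        asd_ct2 = ct_by_degree[2 if 2 in config.degrees else config.degrees[0]]
        asd = cohort[cohort["group"] == "ASD"]
        for roi in rois:
            fit = trajectory.fit_trajectory(
                asd["age"].to_numpy(),
                asd_ct2.loc[asd["subject_id"].to_numpy(), roi].to_numpy(),
                2, roi=roi, group="ASD",
            )
            if fit.shape < 0:
                tps.append(trajectory.turning_point(fit))
        results["turning_point_mean_years"] = (
            float(np.mean(tps)) if tps else None
        )
        results["n_negative_curvature_rois"] = len(tps)

        has_ados = cohort["ados_comm"].notna().any()
        if has_ados:
            stage("pls_behavior")
            asd_part = cohort[cohort["group"] == "ASD"]
            bset = subsample.draw_and_select(
                asd_part, n=config.ados_n_per_subsample,
                n_candidates=max(config.n_candidates, config.ados_K),
                K=config.ados_K, seed=seeds["pls_behavior"],
            )
            bset = subsample.fit_subsamples(
                bset, ct, cohort, rois, ct_by_degree=ct_by_degree
            )
            results["behavioral_pls"] = {}
            for coef in ("slope", "curvature", "aberrancy"):
                bres = pls.run_behavioral_pls(
                    bset, cohort, coef,
                    n_perm=config.n_perm, n_boot=config.n_boot,
                    seed=seeds["pls_behavior"],
                    bonferroni=config.bonferroni_behavioral,
                )
                results["behavioral_pls"][coef] = {
                    "p_perm": bres.p_perm[0],
                    "p_corrected": bres.p_corrected[0],
                    "behavior_correlations": dict(
                        zip(bres.behavior_names, bres.behavior_correlations)
                    ),
                }

        if config.classify_repeats > 0:
            stage("classify")
            results["classification"] = {}
            reports = {}
            for coef in ("slope", "curvature", "aberrancy"):
                rep = _classify.cross_validate(
                    cohort, ct, coef, rois,
                    n_repeats=config.classify_repeats,
                    seed=seeds["classify"],
                    n_per_subsample=config.n_per_subsample,
                    n_candidates=config.n_candidates, K=config.K,
                    bin_width=config.classify_bin_width,
                    ct_by_degree=ct_by_degree,
                )
                reports[coef] = rep
                results["classification"][coef] = {
                    "summary": rep.summary().to_dict(),
                    "per_repeat": {
                        m: rep.per_repeat[m].tolist() for m in _classify.METRICS
                    },
                }
            comp = _classify.compare_models(reports)
            results["classification"]["model_comparison"] = comp.to_dict("records")
    except Exception as exc:
        failed = list(results["stages"])[-1] if results["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    results["runtime_s"] = round(time.time() - t0, 2)
    return results
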