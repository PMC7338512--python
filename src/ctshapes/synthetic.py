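"""Synthetic cohorts and cortical-thickness tables.

The generator emulates the statistical structure the downstream analysis
assumes for a multi-center developmental MRI study: per-subject ages on
[6, 30] years, unbalanced ASD/TD groups spread over several acquisition
centers, additive per-center offsets on cortical thickness (CT), group-specific
polynomial age trajectories per ROI, i.i.d. Gaussian measurement noise, and
ADOS symptom subscores coupled (negatively) to a planted curvature effect in
the ASD group.

Everything is deterministic given a seed; fixing the seed fixes every
generated value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySpec",
    "make_spec",
    "generate_cohort",
    "generate_ct",
    "generate_ados",
    "PRESETS",
]

AGE_MIN, AGE_MAX = 6.0, 30.0

#: columns of the canonical phenotype table
COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "center",
    "ados_comm", "ados_social", "ados_stereo", "severity",
]


@dataclass
class TrajectorySpec:
    """Generative model for one synthetic dataset.

    Parameters
    ----------
    roi_names
        Labels of the ROIs, one CT column each.
    coefficients
        Mapping ``group -> (n_rois, 4)`` array of polynomial coefficients in
        ascending order: intercept (mm), slope (mm/yr), curvature (mm/yr^2),
        aberrancy (mm/yr^3). Both groups must be present.
    noise_sd
        SD of the additive Gaussian measurement noise, mm.
    center_offsets
        Additive per-center offset, mm. Every center in the cohort must appear.
    ados_coupling
        Dimensionless weight linking a subject's latent severity factor to the
        generated ADOS subscores. Positive coupling plus a nonzero
        ``severity_scale`` plants a negative subgroup-level correlation between
        mean ADOS and fitted curvature.
    severity_scale
        mm/yr^2 of extra (negative) quadratic term per SD of latent severity,
        applied to ``contrast_rois`` of ASD subjects only.
    contrast_rois
        Indices of ROIs carrying the planted group contrast (and the
        severity-driven curvature heterogeneity).
    """

    roi_names: list[str]
    coefficients: dict[str, np.ndarray]
    noise_sd: float = 0.1
    center_offsets: dict[str, float] = field(default_factory=dict)
    ados_coupling: float = 0.0
    severity_scale: float = 0.0
    contrast_rois: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for g in ("ASD", "TD"):
            if g not in self.coefficients:
                raise ValueError(f"coefficients missing for group {g!r}")
            arr = np.asarray(self.coefficients[g], dtype=float)
            if arr.shape != (len(self.roi_names), 4):
                raise ValueError(
                    f"coefficients[{g!r}] must have shape "
                    f"({len(self.roi_names)}, 4), got {arr.shape}"
                )
            self.coefficients[g] = arr
        self.contrast_rois = np.asarray(self.contrast_rois, dtype=int)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


def _default_centers(n_centers: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n_centers)]


def make_spec(
    preset: str = "paper-like",
    n_rois: int = 40,
    centers: list[str] | int = 4,
    noise_sd: float = 0.1,
    contrast_fraction: float = 0.2,
) -> TrajectorySpec:
    """Build a named :class:`TrajectorySpec` preset.

    Presets
    -------
    ``"null"``
        Identical group trajectories; no contrast, no ADOS coupling. Used for
        type-I-error calibration of the whole pipeline.
    ``"paper-like"``
        In the first ``contrast_fraction`` of ROIs (a contiguous, frontal-like
        block) the ASD group has a less-negative slope (+0.012 mm/yr) and a
        negative curvature contrast (-0.002 mm/yr^2) relative to the TD base
        trajectory, plus severity-driven curvature heterogeneity coupled to
        ADOS.
    ``"strong"``
        Same structure with doubled contrasts.

    The TD base is a gently convex thinning trajectory (intercept ~3.55 mm,
    raw slope -0.085 mm/yr, curvature +0.001 mm/yr^2; fitted linear slope
    about -0.05 mm/yr) with small deterministic per-ROI variation. The base
    keeps CT within a physiological 2-3.5 mm band over ages 6-30 and leaves
    the fitted slope clearly negative in both groups even under the doubled
    "strong" contrast (ASD fitted slope ~ -0.025 mm/yr), so planted ROIs
    retain detectable age trends at every polynomial degree.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    slope_delta, curv_delta, coupling, sev_scale = PRESETS[preset]

    if isinstance(centers, int):
        centers = _default_centers(centers)
    roi_names = [f"ROI{i + 1:03d}" for i in range(n_rois)]

    # deterministic per-ROI variation around the base trajectory
    i = np.arange(n_rois)
    intercept = 3.55 + 0.15 * np.sin(2 * np.pi * i / max(n_rois, 1))
    slope = np.full(n_rois, -0.085) + 0.005 * np.cos(2 * np.pi * i / max(n_rois, 1))
    curvature = np.full(n_rois, 0.0010)
    aberrancy = np.zeros(n_rois)
    td = np.column_stack([intercept, slope, curvature, aberrancy])

    asd = td.copy()
    n_contrast = int(round(contrast_fraction * n_rois)) if slope_delta else 0
    contrast = np.arange(n_contrast)
    # plant the contrast centered at age 18 so group trajectories agree
    # mid-range (no overall CT group difference) and stay physiological:
    # add slope_delta*(age-18) + curv_delta*(age-18)^2, expanded into raw
    # polynomial coefficients. The quadratic coefficient still shifts by
    # exactly curv_delta, and (with symmetric ages) the fitted linear slope
    # shifts by slope_delta.
    a0 = 18.0
    asd[contrast, 0] += curv_delta * a0**2 - slope_delta * a0
    asd[contrast, 1] += slope_delta - 2 * a0 * curv_delta
    asd[contrast, 2] += curv_delta

    offsets = {
        c: off
        for c, off in zip(centers, np.linspace(-0.15, 0.15, len(centers)))
    }
    return TrajectorySpec(
        roi_names=roi_names,
        coefficients={"TD": td, "ASD": asd},
        noise_sd=noise_sd,
        center_offsets=offsets,
        ados_coupling=coupling,
        severity_scale=sev_scale,
        contrast_rois=contrast,
    )


#: preset name -> (ASD slope delta mm/yr, ASD curvature delta mm/yr^2,
#:                 ados_coupling, severity_scale mm/yr^2 per SD)
PRESETS: dict[str, tuple[float, float, float, float]] = {
    "null": (0.0, 0.0, 0.0, 0.0),
    "paper-like": (0.012, -0.002, 1.0, 0.0015),
    "strong": (0.024, -0.004, 2.0, 0.003),
}


def generate_cohort(
    n_asd: int,
    n_td: int,
    centers: list[int],
    age_range: tuple[float, float] = (AGE_MIN, AGE_MAX),
    seed: int = 0,
    center_names: list[str] | None = None,
) -> pd.DataFrame:
    """Generate a phenotype table.

    Ages are continuous uniform on ``age_range``; subjects are assigned to
    centers in randomized order so each center gets an ASD/TD mix close to the
    overall proportion. Sex is drawn with ASD/TD female fractions of roughly
    14% / 20%. A latent standard-normal ``severity`` factor is attached to
    every subject; it drives the planted ADOS-curvature coupling downstream.

    Parameters
    ----------
    centers
        Sizes of the acquisition centers; must be positive and sum to
        ``n_asd + n_td``.
    """
    if n_asd < 0 or n_td < 0 or n_asd + n_td == 0:
        raise ValueError("group sizes must be non-negative and not both zero")
    centers = list(centers)
    if any(c <= 0 for c in centers):
        raise ValueError("every center must have a positive size")
    if sum(centers) != n_asd + n_td:
        raise ValueError(
            f"center sizes sum to {sum(centers)}, expected {n_asd + n_td}"
        )
    lo, hi = float(age_range[0]), float(age_range[1])
    if lo < AGE_MIN or hi > AGE_MAX or lo >= hi:
        raise ValueError(f"age_range must be within [{AGE_MIN}, {AGE_MAX}]")
    if center_names is None:
        center_names = _default_centers(len(centers))

    rng = np.random.default_rng(seed)
    n = n_asd + n_td
    group = np.array(["ASD"] * n_asd + ["TD"] * n_td)
    center = np.repeat(center_names, centers)
    # shuffle group labels over the center slots for a realistic mix
    order = rng.permutation(n)
    group = group[order]

    age = rng.uniform(lo, hi, size=n)
    p_female = np.where(group == "ASD", 0.14, 0.20)
    sex = np.where(rng.uniform(size=n) < p_female, "F", "M")
    severity = rng.standard_normal(n)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "center": center,
            "ados_comm": np.nan,
            "ados_social": np.nan,
            "ados_stereo": np.nan,
            "severity": severity,
        }
    )


def _design_poly(age: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(age), age, age**2, age**3])


def generate_ct(
    cohort: pd.DataFrame, spec: TrajectorySpec, seed: int = 0
) -> pd.DataFrame:
    """Generate a subjects x ROIs CT table (mm) under ``spec``.

    ``CT(subject, roi) = poly_group(age) + center_offset + noise`` with
    ``noise ~ N(0, noise_sd)``; ASD subjects additionally carry
    ``-severity_scale * severity * age^2`` on the planted-contrast ROIs.
    Values are checked to be finite and positive after generation.
    """
    missing = set(cohort["center"]) - set(spec.center_offsets)
    if missing:
        raise ValueError(
            f"spec has no center offset for center(s): {sorted(missing)}"
        )
    rng = np.random.default_rng(seed)
    age = cohort["age"].to_numpy(dtype=float)
    P = _design_poly(age)  # n x 4

    values = np.empty((len(cohort), spec.n_rois))
    for g in ("ASD", "TD"):
        m = (cohort["group"] == g).to_numpy()
        if m.any():
            values[m] = P[m] @ spec.coefficients[g].T

    if spec.severity_scale and len(spec.contrast_rois):
        m = (cohort["group"] == "ASD").to_numpy()
        sev = cohort["severity"].to_numpy(dtype=float)
        # curvature perturbation of exactly -severity_scale*severity,
        # anchored at age 18 so CT stays bounded over [6, 30]
        extra = -spec.severity_scale * sev[m, None] * ((age[m, None] - 18.0) ** 2)
        values[np.ix_(m, spec.contrast_rois)] += extra

    offsets = cohort["center"].map(spec.center_offsets).to_numpy(dtype=float)
    values += offsets[:, None]
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(
            "generated CT contains non-finite or non-positive values; "
            "check the trajectory coefficients and noise level"
        )
    return pd.DataFrame(
        values, index=pd.Index(cohort["subject_id"], name="SUB_ID"),
        columns=spec.roi_names,
    )


# plausible ADOS-Generic subscale baselines: (mean, sd of noise, max score)
_ADOS_SCALES = {
    "ados_comm": (3.5, 1.2, 8),
    "ados_social": (4.0, 1.4, 8),
    "ados_stereo": (1.8, 0.9, 4),
}


def generate_ados(
    cohort: pd.DataFrame, spec: TrajectorySpec, seed: int = 0
) -> pd.DataFrame:
    """Fill ADOS subscores for ASD subjects; TD entries stay missing.

    Scores are rounded non-negative integers on plausible subscale ranges
    (0-8 communication/social, 0-4 stereotyped behavior). With
    ``ados_coupling > 0`` each subscore increases with the subject's latent
    severity factor — the same factor that makes the planted curvature more
    negative — so subgroup mean ADOS correlates negatively with fitted
    curvature.
    """
    if not (cohort["group"] == "ASD").any():
        raise ValueError("cohort has no ASD subjects to score")
    if spec.ados_coupling and (spec.severity_scale == 0 or not len(spec.contrast_rois)):
        warnings.warn(
            "ados_coupling requested but no curvature contrast is planted; "
            "ADOS scores will be pure noise",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    m = (out["group"] == "ASD").to_numpy()
    sev = out.loc[m, "severity"].to_numpy(dtype=float)
    planted = bool(spec.severity_scale) and len(spec.contrast_rois) > 0
    effective = spec.ados_coupling if planted else 0.0
    for col, (base, sd, top) in _ADOS_SCALES.items():
        raw = base + effective * sev + rng.normal(0.0, sd, size=m.sum())
        out.loc[m, col] = np.clip(np.round(raw), 0, top)
    return out
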