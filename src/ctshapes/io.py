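"""Readers and writers for phenotype tables, CT tables, results, and config.

The on-disk dialect mirrors ABIDE-style phenotype files: a CSV/TSV with a
``SUB_ID`` column, ``DX_GROUP`` coded either as the strings ``ASD``/``TD`` or
as integers per a configurable mapping (ABIDE convention: 1 = ASD, 2 = TD),
``AGE_AT_SCAN``, ``SEX``, ``SITE_ID`` and optional ``ADOS_COMM``,
``ADOS_SOCIAL``, ``ADOS_STEREO`` columns. CT tables are wide CSV/TSV with
``SUB_ID`` first and one column per ROI label (values in mm).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PARCELLATIONS",
    "read_phenotypes",
    "write_phenotypes",
    "read_ct",
    "write_ct",
    "align_tables",
    "write_results",
    "read_config",
]

#: ROI counts of the supported parcellations
PARCELLATIONS = {"HP": 2, "FSAP": 68, "MMP": 360}

#: ABIDE phenotypic column names <-> canonical in-memory names
_PHENO_COLS = {
    "SUB_ID": "subject_id",
    "DX_GROUP": "group",
    "AGE_AT_SCAN": "age",
    "SEX": "sex",
    "SITE_ID": "center",
    "ADOS_COMM": "ados_comm",
    "ADOS_SOCIAL": "ados_social",
    "ADOS_STEREO": "ados_stereo",
    "SEVERITY": "severity",
}

DEFAULT_DX_MAP = {"1": "ASD", "2": "TD"}
DEFAULT_SEX_MAP = {"1": "M", "2": "F"}

_MISSING_SENTINELS = (-9999, -999)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_phenotypes(
    path: str | Path,
    dx_map: dict[str, str] | None = None,
    sex_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a phenotype CSV/TSV into the canonical cohort table.

    Group and sex codes are remapped through ``dx_map`` / ``sex_map``
    (ABIDE-style integer codes by default); values already equal to the
    canonical labels pass through unchanged. Negative sentinel values in the
    ADOS columns are treated as missing.
    """
    dx_map = dict(DEFAULT_DX_MAP if dx_map is None else dx_map)
    sex_map = dict(DEFAULT_SEX_MAP if sex_map is None else sex_map)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "SUB_ID" not in df.columns:
        raise ValueError(f"{path}: missing required column SUB_ID")
    df = df.rename(columns={k: v for k, v in _PHENO_COLS.items() if k in df.columns})
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate SUB_ID values: {dups[:5]}")

    def remap(col: str, mapping: dict[str, str], valid: set[str]) -> None:
        vals = df[col].astype(str).str.strip()
        mapped = vals.map(lambda v: mapping.get(v, v))
        bad = sorted(set(mapped) - valid)
        if bad:
            raise ValueError(f"{path}: unmapped {col} codes: {bad}")
        df[col] = mapped

    remap("group", dx_map, {"ASD", "TD"})
    if "sex" in df.columns:
        remap("sex", sex_map, {"M", "F"})
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    if not np.isfinite(df["age"]).all():
        raise ValueError(f"{path}: non-finite ages")
    for col in ("ados_comm", "ados_social", "ados_stereo"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df.loc[df[col].isin(_MISSING_SENTINELS) | (df[col] < 0), col] = np.nan
    df["center"] = df["center"].astype(str)
    return df.reset_index(drop=True)


def write_phenotypes(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table using the ABIDE-style column names."""
    inv = {v: k for k, v in _PHENO_COLS.items()}
    out = cohort.rename(columns=inv)
    out.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_ct(path: str | Path, parcellation: str | int = "custom") -> pd.DataFrame:
    """Read a wide CT table (SUB_ID + one column per ROI, mm).

    ``parcellation`` may be one of ``HP``/``FSAP``/``MMP`` (ROI count is
    validated), an integer (expected custom ROI count), or ``"custom"``
    (any count).
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.columns[0] != "SUB_ID":
        raise ValueError(f"{path}: first column must be SUB_ID")
    sub = df["SUB_ID"].astype(str)
    if sub.duplicated().any():
        raise ValueError(f"{path}: duplicate SUB_ID values")
    values = df.drop(columns="SUB_ID")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric CT value at row {row + 2} (subject "
                f"{sub.iloc[row]}), column {col!r}"
            )
        values[col] = numeric.astype(float)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError(f"{path}: non-finite CT values")

    expected: int | None
    if isinstance(parcellation, int):
        expected = parcellation
    else:
        expected = PARCELLATIONS.get(str(parcellation))
    if expected is not None and values.shape[1] != expected:
        raise ValueError(
            f"{path}: parcellation {parcellation!r} expects {expected} ROI "
            f"columns, found {values.shape[1]}"
        )
    values.index = pd.Index(sub, name="SUB_ID")
    return values


def write_ct(ct: pd.DataFrame, path: str | Path) -> None:
    """Write a CT table at full float precision (lossless round-trip)."""
    ct.to_csv(path, sep=_sep_for(path), index=True, float_format="%.17g")


def align_tables(
    cohort: pd.DataFrame, ct: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop (and log) subjects present in only one of the two tables."""
    common = cohort["subject_id"][cohort["subject_id"].isin(ct.index)]
    n_pheno_only = len(cohort) - len(common)
    n_ct_only = len(ct) - len(common)
    if n_pheno_only or n_ct_only:
        logger.warning(
            "dropping unmatched subjects: %d phenotype-only, %d CT-only",
            n_pheno_only, n_ct_only,
        )
    cohort = cohort[cohort["subject_id"].isin(common)].reset_index(drop=True)
    ct = ct.loc[cohort["subject_id"].to_numpy()]
    return cohort, ct


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return {c: obj[c].tolist() for c in obj.columns}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict[str, Any], path: str | Path) -> None:
    """Serialize a (possibly nested) results mapping to JSON."""
    Path(path).write_text(json.dumps(_jsonable(results), indent=2))


def read_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
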