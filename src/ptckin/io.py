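"""Table readers/writers, schemas, and unit normalization.

All tables are long-format CSV (one observation per row).  Internal units
are fixed: concentrations in nM, ensemble rates in min⁻¹, single-molecule
times in s.  Columns declared in μM are converted at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .termination import TitrationPoint, TitrationSeries

__all__ = [
    "SCHEMAS",
    "TableValidationError",
    "read_table",
    "write_table",
    "titrations_from_table",
    "write_json",
]


class TableValidationError(ValueError):
    """Input table failed schema validation; .errors lists row-level issues."""

    def __init__(self, message: str, errors: list[str] | None = None):
        super().__init__(message)
        self.errors = errors or []


#: schema_id -> (required columns, numeric columns, non-negative columns)
SCHEMAS: dict[str, dict] = {
    "trace": {
        "required": ["trace_id", "rfc_total_nM", "p5_total_nM", "ataluren_mM",
                     "time_min", "anisotropy"],
        "numeric": ["rfc_total_nM", "p5_total_nM", "ataluren_mM", "time_min",
                    "anisotropy"],
        "nonneg": ["rfc_total_nM", "p5_total_nM", "ataluren_mM"],
    },
    "titration": {
        "required": ["complex_id", "rfc_total_nM", "k_obs_per_min"],
        "numeric": ["rfc_total_nM", "k_obs_per_min"],
        "nonneg": ["rfc_total_nM", "k_obs_per_min"],
    },
    "readthrough": {
        "required": ["complex_id", "assay", "suppressor", "rfc_present",
                     "ataluren_mM", "g418_uM", "replicate", "signal",
                     "control_signal"],
        "numeric": ["ataluren_mM", "g418_uM", "signal", "control_signal"],
        "nonneg": ["ataluren_mM", "g418_uM", "signal"],
    },
    "panel": {
        "required": ["label", "codon5", "stop", "codon7", "codon8", "codon9",
                     "codon10", "upstream_mode", "model_class", "k_cat_per_min",
                     "K_nM"],
        "numeric": ["k_cat_per_min", "K_nM"],
        "nonneg": ["k_cat_per_min", "K_nM"],
    },
    "fret_trace": {
        "required": ["trace_id", "frame", "time_s", "donor", "acceptor_fret",
                     "acceptor_direct"],
        "numeric": ["frame", "time_s", "donor", "acceptor_fret",
                    "acceptor_direct"],
        "nonneg": ["time_s"],
    },
}

# columns that, when declared in μM, are scaled into the internal nM unit
_UM_TO_NM = 1000.0


def read_table(path, schema_id: str, units: dict[str, str] | None = None
               ) -> pd.DataFrame:
    """Read and validate a long-format CSV against a named schema.

    ``units`` maps column names to "uM" or "nM" for concentration columns
    whose header does not already carry the unit; μM values are multiplied
    into nM.  Raises :class:`TableValidationError` with an itemized report
    on any failure.
    """
    if schema_id not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_id!r}")
    path = Path(path)
    if not path.exists():
        raise TableValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise TableValidationError(f"empty input table: {path}")
    schema = SCHEMAS[schema_id]
    errors: list[str] = []
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing columns {missing}", [f"missing column {c}" for c in missing]
        )
    for col in schema["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            errors.append(f"row {i}: column {col!r} not numeric: {df.loc[i, col]!r}")
        df[col] = coerced
        if df[col].isna().any():
            for i in df.index[df[col].isna()]:
                if i not in bad:
                    errors.append(f"row {i}: column {col!r} missing")
    if not errors:
        for col in schema["nonneg"]:
            for i in df.index[df[col] < 0]:
                errors.append(f"row {i}: column {col!r} negative: {df.loc[i, col]}")
    if errors:
        raise TableValidationError(f"{path}: {len(errors)} validation error(s)", errors)
    for col, unit in (units or {}).items():
        if unit == "uM":
            df[col] = df[col] * _UM_TO_NM
        elif unit != "nM":
            raise TableValidationError(f"unresolvable unit {unit!r} for column {col!r}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def titrations_from_table(df: pd.DataFrame) -> dict[str, TitrationSeries]:
    """Group a titration table into per-complex series.

    Duplicated (complex_id, rfc_total_nM) rows are merged as replicates with
    SE = SD/sqrt(n); a k_obs_se column, if present, is carried through for
    singleton rows.
    """
    out: dict[str, TitrationSeries] = {}
    for cid, sub in df.groupby("complex_id", sort=False):
        pts = []
        for rfc, grp in sub.groupby("rfc_total_nM", sort=True):
            k = grp["k_obs_per_min"].to_numpy(float)
            if len(k) > 1:
                se = float(np.std(k, ddof=1) / np.sqrt(len(k)))
                pts.append(TitrationPoint(float(rfc), float(k.mean()), se))
            else:
                se = float(grp["k_obs_se"].iloc[0]) if "k_obs_se" in grp else float("nan")
                pts.append(TitrationPoint(float(rfc), float(k[0]), se))
        out[str(cid)] = TitrationSeries(complex_id=str(cid), points=tuple(pts))
    return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for valid JSON
        return None
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
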