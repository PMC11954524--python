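"""Rank correlation and linear-trend analysis of ΔRE versus K.

The central empirical claim this analysis supports: the ataluren-induced
gain in readthrough efficiency (ΔRE, percentage points at 1 mM ataluren)
grows with the half-saturation constant K of the release factor complex —
weakly terminating contexts are the ataluren-responsive ones.  The analysis
is run pooled over all complexes and stratified by titration shape
(hyperbolic K_M^RFC versus sigmoidal K_A^RFC), because the sigmoidal class
sits systematically below the hyperbolic trend and dilutes the pooled
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .termination import DETECTION_LIMIT_NM

__all__ = ["PanelRow", "spearman_r", "linear_trend", "correlate_panel"]


@dataclass(frozen=True)
class PanelRow:
    complex_id: str
    model_class: str  # "hyperbolic" | "sigmoidal"
    K: float  # nM
    delta_re: float  # percentage points
    at_detection_limit: bool = False

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.model_class not in ("hyperbolic", "sigmoidal"):
            raise ValueError(f"unknown model_class {self.model_class!r}")


def spearman_r(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: rank correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def linear_trend(x, y) -> dict:
    """Ordinary least squares y ~ x: slope, intercept, r², and slope SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-D, equal length, >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: no spread for regression")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue) ** 2,
        "slope_se": float(res.stderr),
        "n": int(x.size),
    }


def _stratum_stats(df: pd.DataFrame, log_k: bool) -> dict:
    x = np.log10(df["K"].to_numpy()) if log_k else df["K"].to_numpy()
    y = df["delta_re"].to_numpy()
    out: dict = {"n": int(len(df))}
    out["spearman"] = spearman_r(x, y)
    ols = linear_trend(x, y)
    out.update(
        ols_slope=ols["slope"], ols_intercept=ols["intercept"], r2=ols["r2"]
    )
    out["mean_K_nM"] = float(df["K"].mean())
    out["mean_delta_re"] = float(y.mean())
    return out


def correlate_panel(rows, stratify: bool = True,
                    detection_limit_policy: str = "clamp",
                    log_k: bool = False) -> dict:
    """ΔRE-vs-K report: pooled statistics plus per-class strata.

    rows may be PanelRow objects or a DataFrame with columns complex_id,
    model_class, K (or K_nM), delta_re and optionally at_detection_limit.
    Detection-limited rows (fitted K at or below the reporting floor) are,
    by default, included clamped at the 1 nM bound; "drop" excludes them.
    ``log_k=True`` regresses against log10 K instead of K.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
        if "K" not in df.columns and "K_nM" in df.columns:
            df = df.rename(columns={"K_nM": "K"})
    else:
        df = pd.DataFrame([r.__dict__ for r in rows])
    required = {"complex_id", "model_class", "K", "delta_re"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if "at_detection_limit" not in df.columns:
        df["at_detection_limit"] = df["K"] <= DETECTION_LIMIT_NM

    limited = df["at_detection_limit"].astype(bool)
    if detection_limit_policy == "clamp":
        df.loc[limited, "K"] = DETECTION_LIMIT_NM
    elif detection_limit_policy == "drop":
        df = df[~limited]
    else:
        raise ValueError(f"unknown detection_limit_policy {detection_limit_policy!r}")

    report: dict = {
        "log_k": log_k,
        "detection_limit_policy": detection_limit_policy,
        "overall": _stratum_stats(df, log_k),
    }
    if stratify:
        strata = {}
        for cls, sub in df.groupby("model_class"):
            if len(sub) < 3:
                warnings.warn(
                    f"stratum {cls!r} has {len(sub)} rows (<3); omitted",
                    stacklevel=2,
                )
                continue
            strata[cls] = _stratum_stats(sub, log_k)
        report["by_class"] = strata
    return report
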