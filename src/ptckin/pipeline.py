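"""End-to-end closed-loop pipeline over synthetic data.

Stages: generate the 36-context panel → simulate and fit each complex's
depletion-affected titration (with hyperbolic/sigmoidal model selection) →
simulate readthrough ± ataluren and compute ΔRE → classify drug
combinations → correlate ΔRE with K overall and by class → estimate smFRET
dwell rates.  Every stage consumes the previous stage's outputs exactly as
the file-based tools would, and the result bundle records the seed and all
decisions taken so a rerun under the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import correlate_panel
from .io import titrations_from_table, write_json, write_table
from .readthrough import classify_combination, compute_re, delta_re
from .simulate import (
    GeneratorConfig,
    ataluren_ki_for_delta_re,
    calibrate_assoc_rate,
    gen_combination_panel,
    gen_fret_trace,
    gen_panel,
    gen_readthrough_assay,
    gen_titration_series,
)
from .smfret import DwellSet, estimate_rates
from .termination import select_model

log = logging.getLogger("ptckin")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending record."""


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the standard closed loop."""

    seed: int = 0
    outdir: str | None = None
    selection_alpha: float = 0.05
    selection_criterion: str = "f_test"
    z_threshold: float = 2.0
    weighted_fits: bool = True
    n_fret_traces: int = 120
    n_combination_complexes: int = 9
    combination_sd: float = 0.02
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if self.selection_alpha <= 0:
            raise ValueError("selection_alpha must be > 0")

    def asdict(self) -> dict:
        # outdir excluded: the result bundle must be invariant to where it
        # is written (rerun under the same seed is byte-identical)
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("generator", "outdir")}
        d["generator"] = dict(self.generator.__dict__)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("fit_titrations")
def _fit_titrations(panel: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    gen = cfg.generator
    rng = np.random.default_rng(gen.seed + 1)
    rows = []
    for _, row in panel.iterrows():
        series = gen_titration_series(
            row["k_cat_per_min"], row["K_nM"], int(row["n"]),
            cfg=gen, rng=rng, complex_id=row["label"],
        )
        fit = select_model(series, gen.p5_total_nM,
                           criterion=cfg.selection_criterion,
                           alpha=cfg.selection_alpha,
                           weighted=cfg.weighted_fits)
        rows.append(
            {
                "complex_id": fit.complex_id,
                "model_class": fit.model_class,
                "n": fit.n,
                "k_cat": fit.k_cat,
                "k_cat_se": fit.k_cat_se,
                "K_nM": fit.K,
                "K_se": fit.K_se,
                "at_detection_limit": fit.at_detection_limit,
                "rss": fit.rss,
                "true_class": row["model_class"],
                "true_k_cat": row["k_cat_per_min"],
                "true_K_nM": row["K_nM"],
            }
        )
    return pd.DataFrame(rows)


@_stage("readthrough")
def _readthrough(panel: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    gen = cfg.generator
    rng = np.random.default_rng(gen.seed + 2)
    # one global near-cognate TC association rate, calibrated on the
    # reference context (k_cat 0.2 min^-1, K_A 28 nM, n=2, 20% basal RE)
    assoc = calibrate_assoc_rate(0.2, 28.0, 2, gen)
    conditions = [
        {"ataluren_mM": 0.0, "g418_uM": 0.0, "rfc_present": True},
        {"ataluren_mM": 1.0, "g418_uM": 0.0, "rfc_present": True},
    ]
    rows = []
    for _, row in panel.iterrows():
        # per-complex ataluren sensitivity realizing the panel's ΔRE truth
        ki = ataluren_ki_for_delta_re(
            row["k_cat_per_min"], row["K_nM"], int(row["n"]),
            row["delta_re_true"], assoc, cfg=gen,
        )
        tbl = gen_readthrough_assay(
            row["k_cat_per_min"], row["K_nM"], int(row["n"]),
            conditions=conditions, assoc_rate=assoc, Ki_mM=ki,
            complex_id=row["label"], cfg=gen, rng=rng,
        )
        res = {}
        for at, grp in tbl.groupby("ataluren_mM"):
            re_vals = [
                compute_re(r.signal, r.control_signal, r.assay)
                for r in grp.itertuples()
            ]
            res[at] = (float(np.mean(re_vals)),
                       float(np.std(re_vals, ddof=1) / np.sqrt(len(re_vals))))
        dre, dre_sd = delta_re(res[1.0][0], res[0.0][0], res[1.0][1], res[0.0][1])
        rows.append(
            {
                "complex_id": row["label"],
                "model_class": row["model_class"],
                "K_nM": row["K_nM"],
                "at_detection_limit": bool(row["at_detection_limit"]),
                "re_minus": res[0.0][0],
                "re_plus": res[1.0][0],
                "delta_re": dre,
                "delta_re_sd": dre_sd,
                "delta_re_true": row["delta_re_true"],
            }
        )
    return pd.DataFrame(rows)


@_stage("combinations")
def _combinations(cfg: RunConfig) -> list[dict]:
    gen = cfg.generator
    rng = np.random.default_rng(gen.seed + 3)
    tbl = gen_combination_panel(cfg.n_combination_complexes,
                                sd=cfg.combination_sd, cfg=gen, rng=rng)
    out = []
    for r in tbl.itertuples():
        res = classify_combination(
            (r.re_baseline, r.re_baseline_sd),
            (r.re_a, r.re_a_sd),
            (r.re_b, r.re_b_sd),
            (r.re_combo, r.re_combo_sd),
            complex_id=r.complex_id,
            agents=("ataluren", "G418"),
            z_threshold=cfg.z_threshold,
        )
        out.append(
            {
                "complex_id": r.complex_id,
                "re_baseline": res.re_baseline,
                "re_a": res.re_a,
                "re_b": res.re_b,
                "re_combo": res.re_combo,
                "additive_prediction": res.additive_prediction,
                "z": res.z,
                "verdict": res.verdict,
                "true_verdict": r.true_verdict,
            }
        )
    return out


@_stage("smfret")
def _smfret(cfg: RunConfig) -> dict:
    gen = cfg.generator
    rng = np.random.default_rng(gen.seed + 4)
    traces = [gen_fret_trace(gen, rng, trace_id=f"tr-{i:04d}")
              for i in range(cfg.n_fret_traces)]
    ds = DwellSet.from_traces(traces)
    ds = estimate_rates(ds, seed=gen.seed + 5)
    return {
        "n_traces": cfg.n_fret_traces,
        "n_arrivals": len(ds.arrival_waits),
        "k_arrival_app_s": ds.k_arrival_app,
        "k_dis_tRNA_app_s": ds.k_dis_tRNA_app,
        "k_dis_eRF1_app_s": ds.k_dis_eRF1_app,
        "E": ds.E,
        "ci": ds.ci,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns (and optionally writes) the result bundle."""
    logging.basicConfig(level=cfg.log_level)
    gen = cfg.generator
    panel = gen_panel(gen)
    fits = _fit_titrations(panel, cfg)
    rt = _readthrough(panel, cfg)
    combos = _combinations(cfg)
    fret = _smfret(cfg)

    # correlation runs on the *fitted* K joined with the *measured* ΔRE,
    # exactly as the downstream analysis would consume real data
    merged = fits.merge(rt[["complex_id", "delta_re"]], on="complex_id")
    corr = correlate_panel(
        merged[["complex_id", "model_class", "K_nM", "delta_re",
                "at_detection_limit"]],
        stratify=True,
    )

    class_counts = fits["model_class"].value_counts().to_dict()
    accuracy = float((fits["model_class"] == fits["true_class"]).mean())
    combo_accuracy = float(
        np.mean([c["verdict"] == c["true_verdict"] for c in combos])
    )
    bundle = {
        "version": __version__,
        "config": cfg.asdict(),
        "panel_class_counts": {k: int(v) for k, v in class_counts.items()},
        "classification_accuracy": accuracy,
        "fits": fits.to_dict(orient="records"),
        "readthrough": rt.to_dict(orient="records"),
        "combinations": combos,
        "combination_accuracy": combo_accuracy,
        "correlation": corr,
        "smfret": fret,
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        write_table(panel, out / "panel.csv")
        write_table(fits, out / "termination_fits.csv")
        write_table(rt, out / "readthrough.csv")
        write_json(bundle, out / "results.json")
        log.info("wrote results to %s (seed=%d, version=%s)",
                 out, cfg.seed, __version__)
    return bundle
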