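"""Synthetic-data generation with recorded ground truth.

Every input the analysis consumes can be generated here with known truth:
anisotropy decay traces, depletion-affected titration series, readthrough
assays under the shared TC-versus-RFC competition model, Table-1-like
context panels, and two-color single-molecule traces.  The generator
defaults encode the study conditions of the assays they emulate:

* titrations: 50 nM pretermination complex, RFC grid 0-120 nM;
* panel: 36 contexts, 28 hyperbolic / 8 sigmoidal, k_cat ~90% within
  0.1-0.3 min⁻¹, K spread over ≥35-fold with ≥2 contexts at the ≤1 nM
  detection floor; hyperbolic K log-uniform on [1, 35] nM (mean ≈ 9 nM),
  sigmoidal K log-uniform on [15, 50] nM (mean ≈ 29 nM);
* readthrough: 0.2 μM suppressor TC, 50 nM RFC, association rate
  calibrated so the reference context shows 20% basal readthrough;
* smFRET: 35 nM labeled RFC injected 10 s into recording, E = 0.25.

All randomness flows through one integer-seeded numpy Generator, so a fixed
seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import SequenceContext
from .readthrough import partition_probability
from .smfret import FretTrace
from .termination import (
    AnisotropyTrace,
    TitrationPoint,
    TitrationSeries,
    predict_rate,
    solve_bound_complex,
)

__all__ = [
    "GeneratorConfig",
    "gen_decay_trace",
    "gen_titration_series",
    "gen_readthrough_assay",
    "gen_combination_panel",
    "gen_panel",
    "gen_fret_trace",
    "calibrate_assoc_rate",
    "ataluren_ki_for_delta_re",
    "true_partition",
    "REFERENCE_CONTEXT",
]

#: Reference pretermination context: CAA upstream, UGA stop, CUA AUG ACC UUU
#: downstream — chosen to favor readthrough.  Its titration is sigmoidal with
#: K_A ≈ 28 nM and k_cat ≈ 0.2 min⁻¹.
REFERENCE_CONTEXT = SequenceContext(
    label="Reference",
    upstream_codon="CAA",
    stop_codon="UGA",
    downstream_codons=("CUA", "AUG", "ACC", "UUU"),
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in ("UGA", "UAA", "UAG")
)
_STOPS = ("UGA", "UAA", "UAG")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-data generator; defaults are the study conditions."""

    seed: int = 0
    # anisotropy decays
    decay_noise_sd: float = 0.005  # anisotropy units
    decay_time_max_min: float = 30.0
    decay_n_points: int = 61
    # titrations
    p5_total_nM: float = 50.0
    rfc_grid_nM: tuple = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 90.0, 120.0)
    titration_rel_noise: float = 0.10
    # panel composition
    panel_size: int = 36
    n_sigmoidal: int = 8
    n_at_limit: int = 2
    k_cat_log_median: float = 0.173  # min^-1, geometric center of 0.1-0.3
    k_cat_log_sigma: float = 0.335   # ~90% of draws inside [0.1, 0.3]
    K_hyp_range_nM: tuple = (1.0, 35.0)
    K_sig_range_nM: tuple = (15.0, 50.0)
    K_at_limit_nM: float = 0.5
    # ΔRE generative link: delta_re = slope(class)*K + offset(class) + noise,
    # floored at 0; the cooperative class responds less per unit K and sits
    # below the hyperbolic trend throughout
    delta_re_slope_per_nM: float = 0.6
    delta_re_sigmoidal_slope_per_nM: float = 0.15
    delta_re_sigmoidal_offset: float = -1.0
    delta_re_noise_sd: float = 1.5
    delta_re_log_link: bool = False
    # competition / readthrough
    tc_conc_uM: float = 0.2
    rfc_assay_total_nM: float = 50.0
    Ki_mM: float = 0.3
    g418_fmax: float = 25.0
    g418_half_uM: float = 1.0
    basal_re_reference: float = 0.20
    cosed_n_ribosomes: int = 500
    fluor_control_dF: float = 1000.0
    fluor_noise_sd: float = 15.0
    # smFRET
    frame_time_s: float = 0.1
    n_frames: int = 1200
    injection_frame: int = 100
    k_arrival_s: float = 0.10
    k_dis_tRNA_s: float = 0.12
    k_dis_eRF1_s: float = 0.10
    E_true: float = 0.25
    donor_high: float = 100.0
    acceptor_direct_high: float = 100.0
    snr: float = 5.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# decays and titrations
# ---------------------------------------------------------------------------


def gen_decay_trace(k: float, asymptote: float = 0.30, amplitude: float = 0.10,
                    *, k_slow: float | None = None, fast_fraction: float | None = None,
                    noise_sd: float | None = None,
                    cfg: GeneratorConfig | None = None,
                    rng: np.random.Generator | None = None,
                    trace_id: str = "") -> AnisotropyTrace:
    """Anisotropy decay A(t) = asymptote + amplitude·exp(-kt) (+ slow phase)."""
    cfg = cfg or GeneratorConfig()
    rng = rng or cfg.rng()
    if k <= 0:
        raise ValueError("k must be > 0")
    noise = cfg.decay_noise_sd if noise_sd is None else noise_sd
    t = np.linspace(0.0, cfg.decay_time_max_min, cfg.decay_n_points)
    if k_slow is None:
        a = asymptote + amplitude * np.exp(-k * t)
    else:
        f = 0.5 if fast_fraction is None else fast_fraction
        a = asymptote + amplitude * (
            f * np.exp(-k * t) + (1 - f) * np.exp(-k_slow * t)
        )
    if noise > 0:
        a = a + rng.normal(0.0, noise, size=t.size)
    return AnisotropyTrace(time=t, signal=a, trace_id=trace_id)


def gen_titration_series(k_cat: float, K: float, n: int = 1,
                         p5_total: float | None = None,
                         rfc_grid=None, rel_noise: float | None = None,
                         cfg: GeneratorConfig | None = None,
                         rng: np.random.Generator | None = None,
                         complex_id: str = "synthetic") -> TitrationSeries:
    """Titration with ligand depletion: k_obs from the rate law at solved RFC_free."""
    cfg = cfg or GeneratorConfig()
    rng = rng or cfg.rng()
    p5 = cfg.p5_total_nM if p5_total is None else p5_total
    grid = np.asarray(cfg.rfc_grid_nM if rfc_grid is None else rfc_grid, float)
    noise = cfg.titration_rel_noise if rel_noise is None else rel_noise
    pts = []
    for r in grid:
        free = solve_bound_complex(r, p5, K, n).rfc_free
        k = predict_rate(free, k_cat, K, n)
        eps = rng.normal(0.0, noise) if noise > 0 else 0.0
        pts.append(TitrationPoint(rfc_total=float(r),
                                  k_obs=max(k * (1.0 + eps), 0.0),
                                  k_obs_se=max(k * noise, 1e-6)))
    return TitrationSeries(complex_id=complex_id, points=tuple(pts))


# ---------------------------------------------------------------------------
# readthrough under the competition model
# ---------------------------------------------------------------------------


def _g418_factor(g418_uM: float, cfg: GeneratorConfig) -> float:
    return 1.0 + (cfg.g418_fmax - 1.0) * g418_uM / (g418_uM + cfg.g418_half_uM)


def calibrate_assoc_rate(k_cat: float, K: float, n: int,
                         cfg: GeneratorConfig | None = None,
                         target_re: float | None = None) -> float:
    """Association rate (μM⁻¹min⁻¹) giving the target basal readthrough.

    Solves a·[TC]/(a·[TC] + k_term) = target for the no-drug, RFC-present
    condition of the given complex; by default the reference context's 20%
    basal readthrough fixes the near-cognate TC association rate.
    """
    cfg = cfg or GeneratorConfig()
    p = cfg.basal_re_reference if target_re is None else target_re
    if not 0 < p < 1:
        raise ValueError("target RE must be in (0,1)")
    free = solve_bound_complex(cfg.rfc_assay_total_nM, cfg.p5_total_nM, K, n).rfc_free
    k_term = predict_rate(free, k_cat, K, n)
    return k_term * p / (1.0 - p) / cfg.tc_conc_uM


def true_partition(k_cat: float, K: float, n: int, *, assoc_rate: float,
                   ataluren_mM: float = 0.0, g418_uM: float = 0.0,
                   rfc_present: bool = True, Ki_mM: float | None = None,
                   cfg: GeneratorConfig | None = None) -> float:
    """Ground-truth readthrough probability for one condition."""
    cfg = cfg or GeneratorConfig()
    Ki = cfg.Ki_mM if Ki_mM is None else Ki_mM
    if not np.isfinite(Ki):  # ataluren-insensitive complex
        ataluren_mM = 0.0
        Ki = cfg.Ki_mM
    if rfc_present:
        free = solve_bound_complex(
            cfg.rfc_assay_total_nM, cfg.p5_total_nM, K, n
        ).rfc_free
    else:
        free = 0.0
    return partition_probability(
        cfg.tc_conc_uM,
        assoc_rate,
        rfc_free=free,
        k_cat=k_cat,
        K=K,
        n=n,
        ataluren_mM=ataluren_mM,
        Ki_mM=Ki,
        g418_factor=_g418_factor(g418_uM, cfg),
    )


def ataluren_ki_for_delta_re(k_cat: float, K: float, n: int, delta_re_pp: float,
                             assoc_rate: float, ataluren_mM: float = 1.0,
                             cfg: GeneratorConfig | None = None) -> float:
    """Per-complex effective ataluren K_i (mM) realizing a target ΔRE.

    The panel's generative ΔRE-vs-K link (increasing in K, offset down for
    the cooperative class) is the ground truth; this inverts the shared
    competition model so that simulating the assay ± ataluren reproduces
    that ΔRE.  A per-complex K_i absorbs everything the single-site
    competitive-inhibition picture leaves out (notably the ataluren-blind
    second site of cooperative complexes).
    """
    cfg = cfg or GeneratorConfig()
    p0 = true_partition(k_cat, K, n, assoc_rate=assoc_rate, cfg=cfg)
    p1 = min(p0 + delta_re_pp / 100.0, 0.99)
    if p1 <= p0:
        return float("inf")
    free = solve_bound_complex(cfg.rfc_assay_total_nM, cfg.p5_total_nM, K, n).rfc_free
    k_term_target = assoc_rate * cfg.tc_conc_uM * (1.0 - p1) / p1
    k_term_target = min(k_term_target, k_cat * (1.0 - 1e-9))
    K_app = free * ((k_cat / k_term_target) - 1.0) ** (1.0 / n)
    if K_app <= K:
        return float("inf")
    return ataluren_mM / (K_app / K - 1.0)


def gen_readthrough_assay(k_cat: float, K: float, n: int,
                          conditions=None, replicates: int = 3,
                          assay: str = "cosedimentation",
                          assoc_rate: float | None = None,
                          Ki_mM: float | None = None,
                          complex_id: str = "synthetic",
                          cfg: GeneratorConfig | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a readthrough assay table for one complex.

    ``conditions`` is a list of dicts with keys ataluren_mM, g418_uM,
    rfc_present (defaults: the no-drug RFC-present condition).  Returns a
    long-format table with one row per replicate per condition, cognate
    control rows included, plus a ``true_p`` truth column.
    """
    cfg = cfg or GeneratorConfig()
    rng = rng or cfg.rng()
    if assoc_rate is None:
        assoc_rate = calibrate_assoc_rate(k_cat, K, n, cfg)
    if conditions is None:
        conditions = [{"ataluren_mM": 0.0, "g418_uM": 0.0, "rfc_present": True}]
    rows = []
    for cond in conditions:
        at = cond.get("ataluren_mM", 0.0)
        g = cond.get("g418_uM", 0.0)
        rfc = cond.get("rfc_present", True)
        p = true_partition(k_cat, K, n, assoc_rate=assoc_rate, ataluren_mM=at,
                           g418_uM=g, rfc_present=rfc, Ki_mM=Ki_mM, cfg=cfg)
        for rep in range(replicates):
            # cognate control: full readthrough, same noise model
            if assay == "cosedimentation":
                sig = rng.binomial(cfg.cosed_n_ribosomes, p) / cfg.cosed_n_ribosomes
                ctrl = rng.binomial(cfg.cosed_n_ribosomes, 1.0) / cfg.cosed_n_ribosomes
            elif assay == "fluorescence":
                sig = max(
                    p * cfg.fluor_control_dF + rng.normal(0, cfg.fluor_noise_sd), 0.0
                )
                ctrl = max(
                    cfg.fluor_control_dF + rng.normal(0, cfg.fluor_noise_sd), 1e-9
                )
            else:
                raise ValueError(f"unknown assay {assay!r}")
            rows.append(
                {
                    "complex_id": complex_id,
                    "assay": assay,
                    "suppressor": "Trp_nearcognate",
                    "rfc_present": rfc,
                    "ataluren_mM": at,
                    "g418_uM": g,
                    "replicate": rep,
                    "signal": sig,
                    "control_signal": ctrl,
                    "true_p": p,
                }
            )
    return pd.DataFrame(rows)


def gen_combination_panel(n_complexes: int = 10, sd: float = 0.02,
                          replicates: int = 3,
                          cfg: GeneratorConfig | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Labeled RE quadruples (baseline, A, B, combo) for combination classification.

    Verdict labels are drawn uniformly from null / additive / synergistic;
    synergistic complexes get a +0.10-0.20 interaction excess over the
    additive prediction, null complexes have inactive single agents.
    Observed REs are the truth plus Gaussian noise of scale ``sd`` (the SD
    of ``replicates`` averaged measurements).
    """
    cfg = cfg or GeneratorConfig()
    rng = rng or cfg.rng()
    rows = []
    verdicts = ["null", "additive", "synergistic"]
    for i in range(n_complexes):
        verdict = verdicts[i % len(verdicts)]
        base = rng.uniform(0.05, 0.20)
        if verdict == "null":
            ea = eb = 0.0
            interaction = 0.0
        else:
            ea = rng.uniform(0.10, 0.25)
            eb = rng.uniform(0.10, 0.25)
            interaction = rng.uniform(0.15, 0.30) if verdict == "synergistic" else 0.0
        truth = {
            "re_baseline": base,
            "re_a": base + ea,
            "re_b": base + eb,
            "re_combo": min(base + ea + eb + interaction, 1.0),
        }
        row = {"complex_id": f"combo-{i:02d}", "true_verdict": verdict}
        for name, val in truth.items():
            obs = val + rng.normal(0.0, sd)
            row[name] = float(np.clip(obs, 0.0, 1.05))
            row[name + "_sd"] = sd
            row[name + "_true"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-1-like panel
# ---------------------------------------------------------------------------


def _random_context(rng: np.random.Generator, label: str,
                    constant_caa: bool) -> SequenceContext:
    up = "CAA" if constant_caa else str(rng.choice(_SENSE_CODONS))
    stop = str(rng.choice(_STOPS, p=[0.6, 0.2, 0.2]))  # UGA most common
    down = tuple(str(c) for c in rng.choice(_SENSE_CODONS, size=4))
    return SequenceContext(label=label, upstream_codon=up, stop_codon=stop,
                           downstream_codons=down)


def gen_panel(cfg: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the default 36-context panel with kinetic and ΔRE ground truth.

    Columns: label, codon5, stop, codon7..codon10, upstream_mode,
    model_class, n, k_cat_per_min, K_nM, at_detection_limit, delta_re_true
    (percentage points at 1 mM ataluren).  28 contexts are hyperbolic
    (two of them at the 0.5 nM sub-detection-limit), 8 sigmoidal; K spans
    ≥35-fold above the limit; ΔRE increases with K with a negative offset
    for the sigmoidal class.
    """
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    n_hyp = cfg.panel_size - cfg.n_sigmoidal
    rows = []
    for i in range(cfg.panel_size):
        sigmoidal = i < cfg.n_sigmoidal
        label = f"CTX-{i + 1:02d}"
        ctx = _random_context(rng, label, constant_caa=rng.random() < 0.8)
        k_cat = float(
            np.exp(rng.normal(np.log(cfg.k_cat_log_median), cfg.k_cat_log_sigma))
        )
        if sigmoidal:
            lo, hi = cfg.K_sig_range_nM
            K = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n = 2
        else:
            # first n_at_limit hyperbolic contexts pinned below the 1 nM floor
            if i - cfg.n_sigmoidal < cfg.n_at_limit:
                K = cfg.K_at_limit_nM
            else:
                lo, hi = cfg.K_hyp_range_nM
                K = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n = 1
        x = np.log(K) if cfg.delta_re_log_link else K
        if sigmoidal:
            dre = (cfg.delta_re_sigmoidal_slope_per_nM * x
                   + cfg.delta_re_sigmoidal_offset)
        else:
            dre = cfg.delta_re_slope_per_nM * x
        if cfg.delta_re_noise_sd > 0:
            dre += rng.normal(0.0, cfg.delta_re_noise_sd)
        rows.append(
            {
                "label": label,
                "codon5": ctx.upstream_codon,
                "stop": ctx.stop_codon,
                "codon7": ctx.downstream_codons[0],
                "codon8": ctx.downstream_codons[1],
                "codon9": ctx.downstream_codons[2],
                "codon10": ctx.downstream_codons[3],
                "upstream_mode": ctx.upstream_mode,
                "model_class": "sigmoidal" if sigmoidal else "hyperbolic",
                "n": n,
                "k_cat_per_min": k_cat,
                "K_nM": K,
                "at_detection_limit": K <= 1.0,
                "delta_re_true": max(dre, 0.0),
            }
        )
    assert sum(r["model_class"] == "hyperbolic" for r in rows) == n_hyp
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smFRET traces
# ---------------------------------------------------------------------------


def gen_fret_trace(cfg: GeneratorConfig | None = None,
                   rng: np.random.Generator | None = None,
                   trace_id: str = "",
                   return_truth: bool = False):
    """One synthetic two-color trace with exponential arrival/loss events.

    Donor is high from frame 0 and partially quenched (factor 1-E) while the
    acceptor is bound; the direct-excitation acceptor channel reports the
    bound window; the FRET channel carries E·(total emission) during the
    window bounded by the earlier of the two losses.  Gaussian noise at
    high_level/snr on each channel.
    """
    cfg = cfg or GeneratorConfig()
    rng = rng or cfg.rng()
    nf, dt = cfg.n_frames, cfg.frame_time_s
    t_inj = cfg.injection_frame

    wait = rng.exponential(1.0 / cfg.k_arrival_s)
    arrival = t_inj + int(np.ceil(wait / dt))
    d_tRNA = max(int(np.round(rng.exponential(1.0 / cfg.k_dis_tRNA_s) / dt)), 1)
    d_erf1 = max(int(np.round(rng.exponential(1.0 / cfg.k_dis_eRF1_s) / dt)), 1)
    cy3_loss = arrival + d_tRNA
    alex_loss = arrival + d_erf1

    donor = np.zeros(nf)
    afret = np.zeros(nf)
    adirect = np.zeros(nf)
    total = cfg.donor_high
    E = cfg.E_true
    if arrival < nf:
        adirect[arrival:min(alex_loss, nf)] = cfg.acceptor_direct_high
        fret_end = min(cy3_loss, alex_loss, nf)
        donor[:min(cy3_loss, nf)] = total
        donor[arrival:fret_end] = total * (1.0 - E)
        afret[arrival:fret_end] = total * E
    else:
        donor[:] = total  # RFC never arrived during recording
    if cfg.snr > 0:
        # SNR is per channel: noise scales with that channel's high amplitude
        donor = donor + rng.normal(0, cfg.donor_high / cfg.snr, nf)
        afret = afret + rng.normal(0, total * E / cfg.snr, nf)
        adirect = adirect + rng.normal(0, cfg.acceptor_direct_high / cfg.snr, nf)
    trace = FretTrace(frame_time=dt, donor=donor, acceptor_fret=afret,
                      acceptor_direct=adirect, injection_frame=t_inj,
                      trace_id=trace_id)
    if return_truth:
        truth = {
            "arrival_frame": arrival if arrival < nf else None,
            "cy3_loss_frame": cy3_loss,
            "alex_loss_frame": alex_loss,
        }
        return trace, truth
    return trace
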