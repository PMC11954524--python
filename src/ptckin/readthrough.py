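"""Readthrough-efficiency quantitation and combination-treatment classification.

Readthrough efficiency (RE) is the fraction of pretermination complexes that
are elongated past the stop codon by a suppressor ternary complex (TC,
aa-tRNA.eEF1A.GTP) instead of being terminated by the release factor complex
(RFC).  The two assay formats — tritium co-sedimentation stoichiometry and
the fluorescence change on hexapeptide formation (ΔF at 2 min) — are both
normalized to the cognate full-readthrough control, mapping them onto a
common 0-1 scale.

The kinetic competition at the A site is modeled as a race between
productive TC binding (pseudo-first-order rate a·[TC]) and RFC-catalyzed
termination (the Hill rate law at the prevailing free RFC concentration):

    p_rt = a·[TC] / (a·[TC] + k_term_eff)

Ataluren, a competitive inhibitor of RFC, scales the half-saturation
constant K by (1 + [ataluren]/K_i); G418 multiplies the productive TC
association rate without touching termination; an anticodon-edited
suppressor tRNA (ACE-tRNA) enters as a cognate-level TC.  This competition
model is shared with the synthetic-data generator, making closed-loop
recovery tests possible.

Combination treatments are classified against an additive null model
(effects sum over the shared baseline) using a standardized excess z; the
verdict is synergistic above +2, sub-additive below -2, additive in between
when both single agents are active, and null otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .termination import predict_rate

__all__ = [
    "ReadthroughMeasurement",
    "CombinationResult",
    "compute_re",
    "delta_re",
    "partition_probability",
    "classify_combination",
]

SUPPRESSORS = (
    "Trp_nearcognate",
    "Tyr_nearcognate",
    "Gln_nearcognate",
    "ACE_tRNA_Arg",
    "cognate_control",
)


@dataclass(frozen=True)
class ReadthroughMeasurement:
    """One readthrough determination for one complex and condition."""

    complex_id: str
    assay: str  # "cosedimentation" | "fluorescence"
    suppressor: str
    rfc_present: bool
    ataluren: float  # mM
    g418: float  # uM
    signal: float  # pmol 3H per pmol ribosome, or ΔF at 2 min
    control_signal: float  # same units, cognate control
    re: float = float("nan")
    re_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.assay not in ("cosedimentation", "fluorescence"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.suppressor not in SUPPRESSORS:
            raise ValueError(f"unknown suppressor {self.suppressor!r}")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if math.isnan(self.re):
            object.__setattr__(
                self, "re", compute_re(self.signal, self.control_signal, self.assay)
            )


def compute_re(signal: float, control_signal: float,
               assay: str = "cosedimentation") -> float:
    """Readthrough efficiency: assay signal over the cognate control signal.

    Both assays land on the same scale, with the cognate (full readthrough)
    control defining RE = 1.
    """
    if assay not in ("cosedimentation", "fluorescence"):
        raise ValueError(f"unknown assay {assay!r}")
    if control_signal <= 0:
        raise ValueError("cognate control signal must be > 0")
    if signal < 0:
        raise ValueError("signal must be >= 0")
    return signal / control_signal


def delta_re(re_plus: float, re_minus: float,
             sd_plus: float = 0.0, sd_minus: float = 0.0) -> tuple[float, float]:
    """Treatment-induced change in RE, in percentage points, with SD.

    Returns (ΔRE, SD) where ΔRE = 100·(re_plus − re_minus); the SD is
    propagated in quadrature.  ΔRE may be negative.
    """
    for v in (re_plus, re_minus):
        if not 0.0 <= v <= 1.05:
            raise ValueError(f"RE {v} outside [0, 1.05]")
    d = 100.0 * (re_plus - re_minus)
    sd = 100.0 * math.hypot(sd_plus, sd_minus)
    return d, sd


def partition_probability(tc_conc: float, assoc_rate: float, *,
                          rfc_free: float, k_cat: float, K: float, n: int,
                          ataluren_mM: float = 0.0, Ki_mM: float = 0.3,
                          g418_factor: float = 1.0) -> float:
    """Probability that a pretermination complex reads through rather than terminates.

    Parameters
    ----------
    tc_conc : float
        Suppressor ternary-complex concentration, μM.
    assoc_rate : float
        Productive TC association rate constant, μM⁻¹min⁻¹ (proofreading
        losses folded in).
    rfc_free : float
        Free RFC concentration, nM.
    k_cat, K, n
        Termination rate-law parameters of the complex (min⁻¹, nM, 1 or 2).
    ataluren_mM, Ki_mM
        Competitive inhibition of RFC: the apparent K is scaled by
        (1 + [ataluren]/K_i).
    g418_factor : float
        Multiplier (>=1) on the productive association rate.
    """
    if min(tc_conc, assoc_rate, rfc_free, ataluren_mM) < 0:
        raise ValueError("rates and concentrations must be >= 0")
    if Ki_mM <= 0:
        raise ValueError("Ki_mM must be > 0")
    if g418_factor < 1.0:
        raise ValueError("g418_factor must be >= 1")
    a = assoc_rate * g418_factor
    K_app = K * (1.0 + ataluren_mM / Ki_mM)
    k_term = predict_rate(rfc_free, k_cat, K_app, n) if rfc_free > 0 else 0.0
    num = a * tc_conc
    if num == 0.0 and k_term == 0.0:
        return 1.0  # no termination flux at all: any elongation wins
    return num / (num + k_term)


@dataclass(frozen=True)
class CombinationResult:
    """Verdict on a two-agent readthrough combination for one complex."""

    complex_id: str
    agents: tuple[str, str]
    re_baseline: float
    re_a: float
    re_b: float
    re_combo: float
    additive_prediction: float
    excess: float
    z: float
    z_a: float
    z_b: float
    verdict: str  # "null" | "additive" | "synergistic" | "sub_additive"


def classify_combination(re_baseline: tuple[float, float],
                         re_a: tuple[float, float],
                         re_b: tuple[float, float],
                         re_combo: tuple[float, float],
                         complex_id: str = "",
                         agents: tuple[str, str] = ("A", "B"),
                         z_threshold: float = 2.0) -> CombinationResult:
    """Classify a two-agent combination as null / additive / synergistic / sub-additive.

    Each argument is an (RE, SD) pair from replicate measurements.  The
    additive prediction is baseline + effect(A) + effect(B), capped at 1;
    the standardized excess z uses all four SDs in quadrature.  Single-agent
    activity is judged at the same threshold on its own standardized effect.
    """
    for name, (re, sd) in zip(
        ("baseline", "a", "b", "combo"), (re_baseline, re_a, re_b, re_combo)
    ):
        if not math.isfinite(sd) or sd <= 0:
            raise ValueError(f"SD for {name} missing or non-positive: "
                             "classification is meaningless without error")
    rb, sb = re_baseline
    ra, sa = re_a
    rbb, sbb = re_b
    rc, sc = re_combo
    prediction = min(rb + (ra - rb) + (rbb - rb), 1.0)
    sd_pred = math.sqrt(sa**2 + sbb**2 + sb**2)
    sd_tot = math.sqrt(sd_pred**2 + sc**2)
    excess = rc - prediction
    z = excess / sd_tot
    z_a = (ra - rb) / math.hypot(sa, sb)
    z_b = (rbb - rb) / math.hypot(sbb, sb)
    both_active = z_a > z_threshold and z_b > z_threshold
    if z > z_threshold:
        verdict = "synergistic"
    elif z < -z_threshold:
        verdict = "sub_additive"
    elif both_active:
        verdict = "additive"
    else:
        verdict = "null"
    return CombinationResult(
        complex_id=complex_id,
        agents=tuple(agents),
        re_baseline=rb,
        re_a=ra,
        re_b=rbb,
        re_combo=rc,
        additive_prediction=prediction,
        excess=excess,
        z=z,
        z_a=z_a,
        z_b=z_b,
        verdict=verdict,
    )
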