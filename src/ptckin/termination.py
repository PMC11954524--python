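"""Depletion-corrected termination kinetics.

The observed peptide-release rate k_obs of a pretermination complex (P5,
"Stop-POST5") depends on the *free* concentration of release factor complex
(RFC = eRF1.eRF3.GTP) through a Hill rate law

    k_obs = k_cat * RFC_free**n / (RFC_free**n + K**n)            (rate law)

with n = 1 (Michaelis-Menten, half-saturation constant K_M^RFC) for
hyperbolic titrations or n = 2 (positive homotropic cooperativity, K_A^RFC)
for S-shaped ones.  Because the complexes are titrated at RFC concentrations
comparable to the complex concentration itself (tens of nM), bound RFC is a
non-negligible fraction of total and RFC_free must be recovered from the
mass-balance equilibrium

    K**n * RP5 = RFC_free**n * P5_free
    RFC_free   = RFC_total - n * RP5
    P5_free    = P5_total  - RP5

which reduces to a quadratic in RP5 for n = 1 (solved in closed form on the
numerically stable branch) and a cubic for n = 2 (solved by bracketed root
finding).  Fitting k_obs versus RFC_total therefore couples the rate law to
the binding solve: for every candidate K during the nonlinear fit, RFC_free
is recomputed self-consistently at each titration point.

Observed rates themselves come from fluorescence-anisotropy decays of a
dye-labeled nascent peptide: a single exponential with an asymptote, or a
biphasic decay for the rare complexes that need it (the fast phase is the
reported release rate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

# K values at or below this bound (nM) are reported as detection-limited:
# the lowest usable complex concentration sets the floor for estimating K.
DETECTION_LIMIT_NM = 1.0

__all__ = [
    "AnisotropyTrace",
    "DecayFit",
    "TitrationPoint",
    "TitrationSeries",
    "BindingState",
    "TerminationFit",
    "FitError",
    "fit_decay",
    "solve_bound_complex",
    "predict_rate",
    "fit_titration",
    "select_model",
    "DETECTION_LIMIT_NM",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or inputs are unusable."""


# ---------------------------------------------------------------------------
# anisotropy decays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnisotropyTrace:
    """One plate-reader anisotropy time course.

    time is in minutes, signal is dimensionless anisotropy; rfc_total and
    p5_total are nM, ataluren in mM (0 if absent).
    """

    time: np.ndarray
    signal: np.ndarray
    rfc_total: float = 0.0
    p5_total: float = 50.0
    ataluren: float = 0.0
    trace_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size < 8:
            raise ValueError(f"need >=8 time points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if min(self.rfc_total, self.p5_total, self.ataluren) < 0:
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class DecayFit:
    """Fitted anisotropy decay; k_obs is always the fast-phase rate (min^-1)."""

    model: str  # "single_exponential" | "biphasic"
    k_fast: float
    asymptote: float
    amplitude: float
    k_slow: float | None = None
    fast_fraction: float | None = None
    k_fast_se: float = float("nan")
    k_slow_se: float = float("nan")
    asymptote_se: float = float("nan")
    amplitude_se: float = float("nan")
    fast_fraction_se: float = float("nan")
    rss: float = float("nan")
    selection_stat: dict | None = None

    @property
    def k_obs(self) -> float:
        return self.k_fast


def _single_exp(t, asymptote, amplitude, k):
    return asymptote + amplitude * np.exp(-k * t)


def _biphasic(t, asymptote, amplitude, f, k_fast, k_slow):
    return asymptote + amplitude * (
        f * np.exp(-k_fast * t) + (1.0 - f) * np.exp(-k_slow * t)
    )


def _decay_start(trace: AnisotropyTrace) -> tuple[float, float, float]:
    """Crude starting values (asymptote, amplitude, k) for a decay fit."""
    s, t = trace.signal, trace.time
    asym0 = float(np.min(s[-max(3, s.size // 5) :]))
    amp0 = float(s[0] - asym0)
    if amp0 <= 0:
        amp0 = max(float(np.ptp(s)), 1e-6)
    # time to decay ~63%: first crossing of asym + amp/e
    target = asym0 + amp0 / math.e
    below = np.nonzero(s <= target)[0]
    t63 = float(t[below[0]]) if below.size else float(t[-1] / 2)
    k0 = 1.0 / max(t63, float(t[1] - t[0]))
    return asym0, amp0, k0


def _fit_single(trace: AnisotropyTrace) -> DecayFit:
    asym0, amp0, k0 = _decay_start(trace)
    try:
        popt, pcov = optimize.curve_fit(
            _single_exp,
            trace.time,
            trace.signal,
            p0=[asym0, amp0, k0],
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise FitError(
            f"single-exponential fit did not converge "
            f"(starting values asymptote={asym0:.4g}, amplitude={amp0:.4g}, k={k0:.4g})"
        ) from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = trace.signal - _single_exp(trace.time, *popt)
    return DecayFit(
        model="single_exponential",
        asymptote=popt[0],
        amplitude=popt[1],
        k_fast=popt[2],
        asymptote_se=se[0],
        amplitude_se=se[1],
        k_fast_se=se[2],
        rss=float(resid @ resid),
    )


def _fit_biphasic(trace: AnisotropyTrace) -> DecayFit:
    asym0, amp0, k0 = _decay_start(trace)
    p0 = [asym0, amp0, 0.5, 3.0 * k0, k0 / 3.0]
    try:
        popt, pcov = optimize.curve_fit(
            _biphasic,
            trace.time,
            trace.signal,
            p0=p0,
            bounds=(
                [-np.inf, 0.0, 1e-6, 1e-9, 1e-9],
                [np.inf, np.inf, 1.0 - 1e-6, np.inf, np.inf],
            ),
            maxfev=40000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(
            f"biphasic fit did not converge (starting values {p0})"
        ) from exc
    asym, amp, f, kf, ks = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    if ks > kf:  # enforce k_fast >= k_slow by relabeling the phases
        kf, ks = ks, kf
        f = 1.0 - f
        se[[3, 4]] = se[[4, 3]]
    resid = trace.signal - _biphasic(trace.time, *popt)
    return DecayFit(
        model="biphasic",
        asymptote=asym,
        amplitude=amp,
        fast_fraction=f,
        k_fast=kf,
        k_slow=ks,
        asymptote_se=se[0],
        amplitude_se=se[1],
        fast_fraction_se=se[2],
        k_fast_se=se[3],
        k_slow_se=se[4],
        rss=float(resid @ resid),
    )


def _f_test(rss_small: float, rss_big: float, df_extra: int, n_obs: int,
            p_big: int) -> tuple[float, float]:
    """Extra-sum-of-squares F statistic and p-value for nested fits."""
    df_den = n_obs - p_big
    if df_den <= 0:
        return float("nan"), 1.0
    if rss_big <= 0:
        return float("inf"), 0.0
    f_stat = ((rss_small - rss_big) / df_extra) / (rss_big / df_den)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_extra, df_den))
    return f_stat, p


def fit_decay(trace: AnisotropyTrace, model: str = "auto",
              alpha: float = 0.05) -> DecayFit:
    """Fit an anisotropy decay to extract the peptide-release rate.

    model="auto" fits both the single-exponential-with-asymptote form and the
    biphasic form and keeps the biphasic one only when the extra-sum-of-squares
    F-test (2 extra parameters) is significant at ``alpha``.  The reported
    k_obs is always the fast-phase rate.
    """
    if model == "single_exponential":
        return _fit_single(trace)
    if model == "biphasic":
        if trace.time.size < 6:
            raise FitError("biphasic fit needs >=6 points (5 parameters)")
        return _fit_biphasic(trace)
    if model != "auto":
        raise ValueError(f"unknown decay model {model!r}")
    single = _fit_single(trace)
    try:
        bi = _fit_biphasic(trace)
    except FitError:
        return single
    f_stat, p = _f_test(single.rss, bi.rss, 2, trace.time.size, 5)
    stat = {"f": f_stat, "p": p, "rss_single": single.rss, "rss_biphasic": bi.rss}
    chosen = bi if p < alpha else single
    return DecayFit(**{**chosen.__dict__, "selection_stat": stat})


# ---------------------------------------------------------------------------
# equilibrium binding with ligand depletion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingState:
    """Solved equilibrium species for one titration point (all nM)."""

    rp5: float
    rfc_free: float
    p5_free: float
    rfc_total: float
    p5_total: float
    residual: float


def _binding_residual(rp5: float, rfc_total: float, p5_total: float,
                      K: float, n: int) -> float:
    """g(RP5) = K^n RP5 - (RFC_total - n RP5)^n (P5_total - RP5).

    Strictly increasing on [0, min(P5_total, RFC_total/n)] with a single
    root there for all valid inputs.
    """
    return K**n * rp5 - (rfc_total - n * rp5) ** n * (p5_total - rp5)


def solve_bound_complex(rfc_total: float, p5_total: float, K: float,
                        n: int = 1, tol: float = 1e-12) -> BindingState:
    """Solve the bound-complex concentration RP5 under ligand depletion.

    n = 1 uses the closed-form quadratic on the numerically stable branch;
    n = 2 brackets the unique physical root of the cubic and solves it
    numerically (Brent) with a bisection-tight tolerance.
    """
    if rfc_total < 0 or p5_total < 0:
        raise ValueError("total concentrations must be >= 0")
    if K <= 0:
        raise ValueError("K must be > 0")
    if n not in (1, 2):
        raise ValueError("Hill coefficient n must be 1 or 2")

    upper = min(p5_total, rfc_total / n)
    if upper == 0.0:
        rp5 = 0.0
    elif n == 1:
        # rp5^2 - (R+P+K) rp5 + R P = 0 ; stable root via 2c/(b + sqrt(disc))
        b = rfc_total + p5_total + K
        disc = b * b - 4.0 * rfc_total * p5_total
        rp5 = 2.0 * rfc_total * p5_total / (b + math.sqrt(max(disc, 0.0)))
    else:
        # cubic in rp5; g(0) < 0 <= g(upper), root unique in between
        rp5 = optimize.brentq(
            _binding_residual,
            0.0,
            upper,
            args=(rfc_total, p5_total, K, n),
            xtol=tol,
            rtol=8.881784197001252e-16,  # 4 * eps, brentq minimum
            maxiter=200,
        )
    rp5 = min(max(rp5, 0.0), upper)
    rfc_free = rfc_total - n * rp5
    p5_free = p5_total - rp5
    return BindingState(
        rp5=rp5,
        rfc_free=rfc_free,
        p5_free=p5_free,
        rfc_total=rfc_total,
        p5_total=p5_total,
        residual=_binding_residual(rp5, rfc_total, p5_total, K, n),
    )


def predict_rate(rfc_free, k_cat: float, K: float, n: int = 1):
    """Hill rate law: k_obs = k_cat * x^n / (x^n + K^n); n=1 is Michaelis-Menten.

    Accepts scalar or array rfc_free; strictly increasing in rfc_free,
    bounded above by k_cat, and exactly k_cat/2 at rfc_free = K.
    """
    if k_cat <= 0 or K <= 0:
        raise ValueError("k_cat and K must be > 0")
    if n not in (1, 2):
        raise ValueError("Hill coefficient n must be 1 or 2")
    x = np.asarray(rfc_free, dtype=float)
    if np.any(x < 0):
        raise ValueError("rfc_free must be >= 0")
    out = k_cat * x**n / (x**n + K**n)
    return float(out) if np.isscalar(rfc_free) else out


# ---------------------------------------------------------------------------
# titration fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationPoint:
    rfc_total: float  # nM
    k_obs: float  # min^-1
    k_obs_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_obs < 0:
            raise ValueError("k_obs must be >= 0")


@dataclass(frozen=True)
class TitrationSeries:
    """(RFC_total, k_obs) titration for one pretermination complex."""

    complex_id: str
    points: tuple[TitrationPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def rfc_total(self) -> np.ndarray:
        return np.array([p.rfc_total for p in self.points])

    @property
    def k_obs(self) -> np.ndarray:
        return np.array([p.k_obs for p in self.points])

    @property
    def k_obs_se(self) -> np.ndarray:
        return np.array([p.k_obs_se for p in self.points])


@dataclass(frozen=True)
class TerminationFit:
    """Fitted depletion-corrected rate law for one complex.

    K is named K_M^RFC when n=1 (hyperbolic) and K_A^RFC when n=2 (sigmoidal).
    """

    complex_id: str
    model_class: str  # "hyperbolic" | "sigmoidal"
    n: int
    k_cat: float
    K: float
    k_cat_se: float = float("nan")
    K_se: float = float("nan")
    rss: float = float("nan")
    at_detection_limit: bool = False
    k_identifiable: bool = True
    rfc_free: tuple[float, ...] = field(default_factory=tuple)
    selection_stat: dict | None = None

    @property
    def K_name(self) -> str:
        return "K_M^RFC" if self.n == 1 else "K_A^RFC"


def _predict_series(rfc_total: np.ndarray, p5_total: float, k_cat: float,
                    K: float, n: int, depletion: bool = True) -> np.ndarray:
    """Model k_obs for a titration, with the self-consistent free-RFC solve."""
    if depletion:
        free = np.array(
            [solve_bound_complex(r, p5_total, K, n).rfc_free for r in rfc_total]
        )
    else:
        free = rfc_total
    return predict_rate(free, k_cat, K, n)


def fit_titration(series: TitrationSeries, p5_total: float, n: int = 1,
                  weighted: bool = False, depletion: bool = True) -> TerminationFit:
    """Nonlinear least squares for (k_cat, K) with ligand-depletion correction.

    For every candidate K the free RFC concentration is recomputed at each
    titration point from the mass-balance solve, so the rate law is always
    evaluated against self-consistent RFC_free.  Unweighted by default;
    ``weighted=True`` uses inverse-variance weights from k_obs_se.
    ``depletion=False`` fits the naive model (RFC_free = RFC_total) — used
    to demonstrate the upward K bias the correction removes.
    """
    if len(series.points) < 5:
        raise FitError(
            f"{series.complex_id}: need >=5 titration points, got {len(series.points)}"
        )
    if p5_total < 0:
        raise ValueError("p5_total must be >= 0")
    rfc = series.rfc_total
    y = series.k_obs
    if weighted:
        se = series.k_obs_se
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise FitError("weighted fit requires finite positive k_obs_se")
        w = 1.0 / se
    else:
        w = np.ones_like(y)

    kcat0 = max(float(y.max()) * 1.2, 1e-6)
    # half-max crossing of observed rates as K starting guess
    half = kcat0 / 2.0
    above = np.nonzero(y >= half)[0]
    K0 = float(rfc[above[0]]) if above.size and rfc[above[0]] > 0 else float(
        max(np.median(rfc), 1.0)
    )

    def resid(theta):
        k_cat, K = np.exp(theta)  # log-parameterization keeps both positive
        return w * (_predict_series(rfc, p5_total, k_cat, K, n, depletion) - y)

    best = None
    for K_start in (K0, K0 / 10.0, K0 * 10.0):
        sol = optimize.least_squares(
            resid,
            x0=np.log([kcat0, max(K_start, 1e-3)]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    sol = best
    if not sol.success and not np.isfinite(sol.cost):  # pragma: no cover
        raise FitError(f"{series.complex_id}: titration fit did not converge")

    k_cat, K = np.exp(sol.x)
    r = sol.fun
    rss = float(r @ r)
    dof = max(len(y) - 2, 1)
    s2 = rss / dof
    # SEs via J on the log scale, delta-method back to natural scale
    try:
        JTJ = sol.jac.T @ sol.jac
        cov_log = s2 * np.linalg.inv(JTJ)
        k_cat_se = k_cat * math.sqrt(max(cov_log[0, 0], 0.0))
        K_se = K * math.sqrt(max(cov_log[1, 1], 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        k_cat_se = K_se = float("nan")

    # saturation check: if even the lowest nonzero free-RFC point sits near
    # k_cat, there is no curvature left to pin K down
    free = np.array([solve_bound_complex(rr, p5_total, K, n).rfc_free for rr in rfc])
    nz = y[free > 0]
    k_identifiable = bool(nz.size == 0 or np.min(nz) < 0.9 * k_cat)
    if not k_identifiable:
        warnings.warn(
            f"{series.complex_id}: all points near saturation; K non-identifiable",
            stacklevel=2,
        )
    return TerminationFit(
        complex_id=series.complex_id,
        model_class="hyperbolic" if n == 1 else "sigmoidal",
        n=n,
        k_cat=float(k_cat),
        K=float(K),
        k_cat_se=float(k_cat_se),
        K_se=float(K_se),
        rss=rss,
        at_detection_limit=bool(K <= DETECTION_LIMIT_NM),
        k_identifiable=k_identifiable,
        rfc_free=tuple(free),
    )


def select_model(series: TitrationSeries, p5_total: float,
                 criterion: str = "f_test", alpha: float = 0.05,
                 weighted: bool = False) -> TerminationFit:
    """Fit both n=1 and n=2 and classify the titration as hyperbolic or sigmoidal.

    The cooperative (n=2) model is kept only when it improves the fit and the
    improvement passes the configured comparison: an extra-sum-of-squares
    F-test with one numerator degree of freedom (the discrete switch in n) at
    ``alpha``, or AICc when ``criterion="aicc"``.
    """
    fit1 = fit_titration(series, p5_total, n=1, weighted=weighted)
    fit2 = fit_titration(series, p5_total, n=2, weighted=weighted)
    n_obs = len(series.points)
    if criterion == "f_test":
        f_stat, p = _f_test(fit1.rss, fit2.rss, 1, n_obs, 2)
        choose2 = fit2.rss < fit1.rss and p < alpha
        stat = {"criterion": "f_test", "f": f_stat, "p": p,
                "rss_n1": fit1.rss, "rss_n2": fit2.rss}
    elif criterion == "aicc":
        def aicc(rss, p_):
            if n_obs - p_ - 1 <= 0:
                return float("inf")
            return (n_obs * math.log(max(rss, 1e-300) / n_obs)
                    + 2 * p_ + 2 * p_ * (p_ + 1) / (n_obs - p_ - 1))
        a1, a2 = aicc(fit1.rss, 2), aicc(fit2.rss, 2)
        choose2 = a2 < a1
        stat = {"criterion": "aicc", "aicc_n1": a1, "aicc_n2": a2,
                "rss_n1": fit1.rss, "rss_n2": fit2.rss}
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    chosen = fit2 if choose2 else fit1
    return TerminationFit(**{**chosen.__dict__, "selection_stat": stat})
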