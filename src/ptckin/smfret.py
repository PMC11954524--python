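"""Dwell extraction and rate estimation for two-color single-molecule traces.

The experiment these routines analyze: a surface-tethered pretermination
ribosome complex carries a Cy3-labeled P-site peptidyl-tRNA; a Cy5-labeled
release factor complex (RFC) is injected into the flow cell during
recording.  Alternating-laser excitation (ALEX) reports Cy5 presence
directly, while FRET between Cy5-eRF1 and Cy3-tRNA (proximity ratio
E ≈ 0.25) reports A-site accommodation.  Three apparent rate constants are
extracted per condition from event times on many traces:

* k_arrival,app  — injection → first ALEX appearance (RFC binding),
* k_dis,tRNA,app — FRET appearance → Cy3 disappearance (tRNA release),
* k_dis,eRF1,app — ALEX appearance → ALEX disappearance (eRF1 release).

Events are located by threshold crossing against each channel's fitted high
level with a minimum-dwell filter (no HMM idealization); apparent rates are
maximum-likelihood exponential rates (inverse mean dwell) with bootstrap
confidence intervals, censored dwells excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FretTrace",
    "TraceEvents",
    "DwellSet",
    "extract_events",
    "estimate_rates",
    "fret_efficiency",
]


@dataclass(frozen=True)
class FretTrace:
    """One two-color trace: donor, FRET acceptor, and direct-excitation acceptor."""

    frame_time: float  # s per frame
    donor: np.ndarray
    acceptor_fret: np.ndarray
    acceptor_direct: np.ndarray
    injection_frame: int
    trace_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.donor, dtype=float)
        af = np.asarray(self.acceptor_fret, dtype=float)
        ad = np.asarray(self.acceptor_direct, dtype=float)
        if not (d.shape == af.shape == ad.shape) or d.ndim != 1:
            raise ValueError("all three channels must be 1-D arrays of equal length")
        if not 0 <= self.injection_frame < d.size:
            raise ValueError("injection_frame out of range")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor_fret", af)
        object.__setattr__(self, "acceptor_direct", ad)

    @property
    def n_frames(self) -> int:
        return self.donor.size


@dataclass(frozen=True)
class TraceEvents:
    """Event frames for one trace (None = not observed; censored flags per loss)."""

    arrival_frame: int | None
    fret_start_frame: int | None
    cy3_loss_frame: int | None
    alex_loss_frame: int | None
    cy3_censored: bool = False
    alex_censored: bool = False

    @property
    def empty(self) -> bool:
        return self.arrival_frame is None


def _smooth3(channel: np.ndarray) -> np.ndarray:
    """Centered 3-frame boxcar; shifts change points < 2 frames, tames noise."""
    if channel.size < 3:
        return channel
    out = channel.astype(float).copy()
    out[1:-1] = (channel[:-2] + channel[1:-1] + channel[2:]) / 3.0
    return out


def _two_state_levels(channel: np.ndarray,
                      min_separation: float = 3.5) -> tuple[float, float] | None:
    """Low/high levels by 1-D two-means; None if the channel has no high state.

    The separation test (gap between cluster means vs pooled within-cluster
    spread) rejects channels that are pure noise, where a naive midrange
    threshold would hallucinate events; a mean-split Gaussian scores ~2.7,
    hence the 3.5 floor.
    """
    lo, hi = float(np.min(channel)), float(np.max(channel))
    if hi <= lo:
        return None
    thr = (lo + hi) / 2.0
    for _ in range(50):
        high = channel > thr
        if not high.any() or high.all():
            return None
        mu_lo = float(channel[~high].mean())
        mu_hi = float(channel[high].mean())
        new_thr = (mu_lo + mu_hi) / 2.0
        if abs(new_thr - thr) < 1e-9 * max(abs(hi), 1.0):
            break
        thr = new_thr
    high = channel > thr
    sd = float(np.sqrt((np.var(channel[~high]) * (~high).sum()
                        + np.var(channel[high]) * high.sum()) / channel.size))
    if sd > 0 and (mu_hi - mu_lo) < min_separation * sd:
        return None
    return mu_lo, mu_hi


def _first_run_at_least(mask: np.ndarray, min_len: int, start: int = 0) -> int | None:
    """Index of the first True run of length >= min_len at or after ``start``."""
    run = 0
    for i in range(start, mask.size):
        run = run + 1 if mask[i] else 0
        if run >= min_len:
            return i - min_len + 1
    return None


def extract_events(trace: FretTrace, threshold_fraction: float = 0.5,
                   min_dwell_frames: int = 3) -> TraceEvents:
    """Locate arrival, FRET start, Cy3 loss and ALEX loss by threshold crossing.

    Each channel is compared against ``threshold_fraction`` of its fitted
    high level; a state change must persist for ``min_dwell_frames`` frames
    to count (blink rejection).  A trace with no sustained ALEX appearance
    after injection is returned empty, not an error.  Losses that never
    occur before the recording ends are censored at the last frame.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    m = min_dwell_frames

    ad = _smooth3(trace.acceptor_direct)
    levels = _two_state_levels(ad)
    if levels is None:
        return TraceEvents(None, None, None, None)
    thr_ad = levels[0] + threshold_fraction * (levels[1] - levels[0])
    arrival = _first_run_at_least(ad > thr_ad, m, trace.injection_frame)
    if arrival is None:
        return TraceEvents(None, None, None, None)

    # ALEX disappearance: first sustained low run after arrival
    alex_loss = _first_run_at_least(ad <= thr_ad, m, arrival)
    alex_censored = alex_loss is None
    if alex_censored:
        alex_loss = trace.n_frames - 1

    af = _smooth3(trace.acceptor_fret)
    fret_start = None
    levels_af = _two_state_levels(af)
    if levels_af is not None:
        thr_af = levels_af[0] + threshold_fraction * (levels_af[1] - levels_af[0])
        fret_start = _first_run_at_least(af > thr_af, m, arrival)

    d = _smooth3(trace.donor)
    levels_d = _two_state_levels(d)
    if levels_d is None or levels_d[0] > 0.5 * levels_d[1]:
        # donor never goes dark within the recording: either one level, or
        # only the FRET-quenched level below the high state (not a loss)
        return TraceEvents(arrival, fret_start, trace.n_frames - 1, alex_loss,
                           cy3_censored=True, alex_censored=alex_censored)
    thr_d = levels_d[0] + threshold_fraction * (levels_d[1] - levels_d[0])
    search_from = fret_start if fret_start is not None else arrival
    cy3_loss = _first_run_at_least(d <= thr_d, m, search_from)
    cy3_censored = cy3_loss is None
    if cy3_censored:
        cy3_loss = trace.n_frames - 1

    return TraceEvents(
        arrival_frame=arrival,
        fret_start_frame=fret_start,
        cy3_loss_frame=cy3_loss,
        alex_loss_frame=alex_loss,
        cy3_censored=cy3_censored,
        alex_censored=alex_censored,
    )


@dataclass
class DwellSet:
    """Pooled dwell durations (s) for one condition, with estimated rates."""

    arrival_waits: list = field(default_factory=list)
    tRNA_bound_durations: list = field(default_factory=list)
    erf1_bound_durations: list = field(default_factory=list)
    k_arrival_app: float = float("nan")
    k_dis_tRNA_app: float = float("nan")
    k_dis_eRF1_app: float = float("nan")
    ci: dict = field(default_factory=dict)
    E: float = float("nan")

    @classmethod
    def from_traces(cls, traces, threshold_fraction: float = 0.5,
                    min_dwell_frames: int = 3) -> "DwellSet":
        """Pool event-derived dwells over many traces (censored dwells dropped)."""
        ds = cls()
        efficiencies = []
        for tr in traces:
            ev = extract_events(tr, threshold_fraction, min_dwell_frames)
            if ev.empty:
                continue
            dt = tr.frame_time
            if ev.arrival_frame > tr.injection_frame:
                ds.arrival_waits.append((ev.arrival_frame - tr.injection_frame) * dt)
            if not ev.alex_censored and ev.alex_loss_frame > ev.arrival_frame:
                ds.erf1_bound_durations.append(
                    (ev.alex_loss_frame - ev.arrival_frame) * dt
                )
            if (ev.fret_start_frame is not None and not ev.cy3_censored
                    and ev.cy3_loss_frame > ev.fret_start_frame):
                ds.tRNA_bound_durations.append(
                    (ev.cy3_loss_frame - ev.fret_start_frame) * dt
                )
            if ev.fret_start_frame is not None:
                end = min(ev.cy3_loss_frame, ev.alex_loss_frame)
                if end > ev.fret_start_frame:
                    window = slice(ev.fret_start_frame, end)
                    efficiencies.append(
                        fret_efficiency(tr.donor[window], tr.acceptor_fret[window])
                    )
        if efficiencies:
            ds.E = float(np.mean(efficiencies))
        return ds


def _exp_rate_ci(dwells: np.ndarray, rng: np.random.Generator,
                 n_boot: int = 500) -> tuple[float, float]:
    means = rng.choice(dwells, size=(n_boot, dwells.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return 1.0 / hi, 1.0 / lo


def estimate_rates(dwells: DwellSet, min_dwells: int = 20,
                   seed: int = 0, n_boot: int = 500) -> DwellSet:
    """Fill in apparent rate constants from pooled dwells.

    Each rate is the exponential maximum-likelihood estimate 1/mean(dwell)
    with a bootstrap 95% CI.  Categories with fewer than ``min_dwells``
    uncensored dwells are rejected (rates from a handful of dwells are not
    meaningful).
    """
    rng = np.random.default_rng(seed)
    cats = {
        "k_arrival_app": dwells.arrival_waits,
        "k_dis_tRNA_app": dwells.tRNA_bound_durations,
        "k_dis_eRF1_app": dwells.erf1_bound_durations,
    }
    for name, lst in cats.items():
        arr = np.asarray(lst, dtype=float)
        if arr.size < min_dwells:
            raise ValueError(
                f"{name}: only {arr.size} uncensored dwells (< {min_dwells})"
            )
        if np.any(arr <= 0):
            raise ValueError(f"{name}: non-positive dwell duration")
        setattr(dwells, name, float(1.0 / arr.mean()))
        dwells.ci[name] = _exp_rate_ci(arr, rng, n_boot)
    return dwells


def fret_efficiency(donor, acceptor_fret) -> float:
    """Proximity ratio E = acceptor / (acceptor + donor), averaged over the window.

    Uncorrected for gamma or crosstalk; adequate for the approximate E this
    assay reports.
    """
    d = float(np.sum(np.asarray(donor, dtype=float)))
    a = float(np.sum(np.asarray(acceptor_fret, dtype=float)))
    if d + a <= 0:
        raise ValueError("donor + acceptor intensity must be > 0")
    return a / (a + d)
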