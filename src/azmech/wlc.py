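"""Worm-like-chain analysis of force-extension traces.

The interpolation form of the WLC force law is

    F(x) = (kB T / p) [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

with contour length ``Lc`` and persistence length ``p``.  This module
detects rupture peaks in sawtooth traces, fits each rising flank with
the WLC to extract ``Lc`` (and optionally ``p``), and computes
contour-length increments between successive events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .constants import T_REF, kbt
from .trace import FXTrace

__all__ = [
    "wlc_force",
    "wlc_extension",
    "WLCFit",
    "fit_wlc",
    "single_point_lc",
    "UnfoldingEvent",
    "detect_peaks",
    "extract_events",
    "analyze_trace",
    "delta_lc",
    "filter_traces",
]

#: Default bounds on the fitted persistence length, nm.  Unconstrained p
#: destabilises fits on short flanks.
P_BOUNDS = (0.2, 2.0)


def wlc_force(x, Lc: float, p: float, T: float = T_REF):
    """WLC force (pN) at extension ``x`` (nm).

    Parameters
    ----------
    x : float or array
        Extension, must satisfy 0 <= x < Lc (the force diverges at Lc).
    Lc, p : float
        Contour length and persistence length, nm.
    T : float
        Temperature, K.
    """
    if Lc <= 0:
        raise ValueError(f"Lc must be > 0 nm, got {Lc}")
    if p <= 0:
        raise ValueError(f"p must be > 0 nm, got {p}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be >= 0")
    if np.any(x >= Lc):
        raise ValueError(f"extension must stay below the contour length Lc={Lc} nm (WLC diverges)")
    r = x / Lc
    out = (kbt(T) / p) * (0.25 * (1.0 - r) ** -2 - 0.25 + r)
    return float(out) if out.ndim == 0 else out


def wlc_extension(force: float, Lc: float, p: float, T: float = T_REF) -> float:
    """Inverse of :func:`wlc_force`: extension (nm) at a given force (pN)."""
    if force < 0:
        raise ValueError(f"force must be >= 0 pN, got {force}")
    if force == 0:
        return 0.0
    hi = Lc * (1.0 - 1e-12)
    return optimize.brentq(lambda x: wlc_force(x, Lc, p, T) - force, 0.0, hi)


@dataclass(frozen=True)
class WLCFit:
    """Result of fitting one rising flank with the WLC model."""

    Lc: float  #: nm
    p: float  #: nm
    T: float  #: K
    rss: float  #: pN^2, residual sum of squares
    n_points: int

    def __post_init__(self) -> None:
        if self.Lc <= 0 or self.p <= 0:
            raise ValueError(f"Lc and p must be > 0, got Lc={self.Lc}, p={self.p}")


def single_point_lc(x: float, force: float, p: float, T: float = T_REF) -> float:
    """Contour length implied by one (extension, force) point at known p.

    Inverts the WLC bracket for x/Lc.  Used as a fit-window-free fallback
    estimate for flanks too short to fit.
    """
    return _lc_from_endpoint(x, force, p, T)


def _lc_from_endpoint(x: float, force: float, p: float, T: float) -> float:
    """Initial Lc guess: solve x/Lc from the WLC at a single (x, F) point."""
    c = force * p / kbt(T)

    def g(r: float) -> float:
        return 0.25 * (1.0 - r) ** -2 - 0.25 + r - c

    if g(1e-9) > 0:  # force below any WLC value: nearly slack
        return x * 10.0
    r = optimize.brentq(g, 1e-9, 1.0 - 1e-9)
    return x / r


def fit_wlc(
    x: np.ndarray,
    force: np.ndarray,
    T: float = T_REF,
    p_bounds: tuple[float, float] = P_BOUNDS,
    fix_p: float | None = None,
) -> WLCFit:
    """Least-squares WLC fit of a rising flank.

    ``p`` is fitted jointly with ``Lc`` within ``p_bounds`` unless
    ``fix_p`` pins it globally.
    """
    x = np.asarray(x, dtype=float)
    force = np.asarray(force, dtype=float)
    keep = x > 0
    x, force = x[keep], force[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 positive-extension samples to fit, got {x.size}")
    x_max = float(x.max())
    p0 = fix_p if fix_p is not None else 0.4
    lc0 = np.clip(_lc_from_endpoint(x_max, max(float(force[np.argmax(x)]), 1e-3), p0, T),
                  x_max * 1.001, x_max * 50)

    if fix_p is not None:
        def residuals(theta):
            return wlc_force(x, theta[0], fix_p, T) - force
        theta0, lower, upper = [lc0], [x_max * 1.0000001], [x_max * 1e3]
    else:
        def residuals(theta):
            return wlc_force(x, theta[0], theta[1], T) - force
        theta0 = [lc0, p0]
        lower = [x_max * 1.0000001, p_bounds[0]]
        upper = [x_max * 1e3, p_bounds[1]]

    result = optimize.least_squares(
        residuals, theta0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    Lc = float(result.x[0])
    p = fix_p if fix_p is not None else float(result.x[1])
    return WLCFit(Lc=Lc, p=p, T=T, rss=float(np.sum(result.fun**2)), n_points=x.size)


def _shared_p(
    trace: FXTrace,
    events: list["UnfoldingEvent"],
    flanks: list[np.ndarray],
    T: float,
    p_bounds: tuple[float, float],
) -> float | None:
    """Trace-wide persistence length from the best-conditioned flank.

    Takes the joint-fit p of the flank spanning the widest force range
    (usually the first stretch, rising from slack): narrow high-force
    windows leave the per-flank (Lc, p) fit ill-conditioned.
    """
    p_ref = None
    best_span = 0.0
    for event, flank in zip(events, flanks):
        if not event.fittable or flank.size < 30:
            continue
        span = float(trace.force[flank].max() - trace.force[flank].min())
        if span > best_span:
            best_span = span
            p_ref = event.fit.p
    if p_ref is None:
        fitted = [e.fit.p for e in events if e.fittable]
        p_ref = float(np.median(fitted)) if fitted else None
    return p_ref


@dataclass(frozen=True)
class UnfoldingEvent:
    """One rupture: peak force/extension plus the WLC fit of its flank.

    ``fit`` is None for flanks too short to fit (flagged, never dropped);
    such events carry ``lc_fallback``, a cruder contour estimate from a
    fixed-persistence-length mini-fit of whatever flank samples exist.
    """

    peak_force: float  #: pN
    peak_extension: float  #: nm
    fit: WLCFit | None
    event_index: int  #: sample index of the peak within the trace
    lc_fallback: float | None = None  #: nm, fixed-p estimate for short flanks
    ext_jump: float = 0.0  #: nm, largest single-sample extension gain at the peak

    @property
    def fittable(self) -> bool:
        return self.fit is not None

    @property
    def Lc(self) -> float:
        if self.fit is None:
            raise ValueError("event flagged unfittable: no WLC fit available")
        return self.fit.Lc


def _smooth(force: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return force
    if window % 2 == 0:
        window += 1
    return signal.medfilt(force, kernel_size=window)


def detect_peaks(
    trace: FXTrace,
    min_force: float = 20.0,
    min_drop: float = 10.0,
    smooth_window: int = 7,
    min_ext_jump: float = 0.2,
) -> np.ndarray:
    """Indices of rupture peaks, ordered by extension.

    Scans the (median-smoothed) force left to right, tracking the
    running maximum; when the force falls ``min_drop`` below a running
    maximum that exceeds ``min_force``, that maximum is committed as a
    rupture peak and the scan restarts.  The forward-drop criterion
    keeps small intermediate peaks that sit between two taller native
    peaks (their backward drop is shallow, so topographic prominence
    would reject them).

    With ``min_ext_jump`` > 0, a committed peak must also coincide with
    a sample-to-sample extension jump of at least that size: at constant
    pulling speed a rupture relaxes the cantilever within one sample
    (jump ~ force drop / cantilever stiffness), which force noise never
    mimics.  Set it to 0 for traces without this signature (e.g. curves
    tabulated on a uniform extension grid).
    """
    if len(trace) == 0:
        return np.asarray([], dtype=int)
    smoothed = _smooth(trace.force, smooth_window)
    candidates: list[tuple[int, int]] = []  # (running-max index, drop-trigger index)
    best = 0
    for i in range(1, smoothed.size):
        if smoothed[i] > smoothed[best]:
            best = i
        elif smoothed[best] - smoothed[i] >= min_drop:
            if smoothed[best] >= min_force:
                candidates.append((best, i))
            best = i
    if min_ext_jump <= 0:
        # the smoothed argmax is kept as the peak index: hunting for the
        # raw maximum in a neighbourhood would ride the noise
        return np.asarray([b for b, _ in candidates], dtype=int)
    # the rupture(s) lie between the running maximum and the drop
    # trigger; snap each peak to the sample preceding an extension jump
    # there and reject candidates without one (noise excursions).  Two
    # ruptures in rapid succession blur into a single force drop after
    # smoothing but keep their separate cantilever-relaxation jumps.
    dx = np.diff(trace.extension)
    half = max(smooth_window, 1)
    peaks: list[int] = []
    for best, trigger in candidates:
        lo = max(best - half, 0)
        hi = min(max(trigger, best + 1), dx.size)
        if hi <= lo:
            continue
        peaks.extend(j for j in range(lo, hi) if dx[j] >= min_ext_jump)
    return np.unique(np.asarray(peaks, dtype=int))


def extract_events(
    trace: FXTrace,
    peaks: np.ndarray,
    T: float = T_REF,
    fit_fraction: float = 0.95,
    min_samples: int = 10,
    p_bounds: tuple[float, float] = P_BOUNDS,
    fix_p: float | None = None,
    refit_global_p: bool = True,
) -> list[UnfoldingEvent]:
    """Fit the rising flank of every peak with the WLC model.

    The flank runs from the force minimum after the previous rupture up
    to ``fit_fraction`` of the peak force (excluding the rupture
    transition itself).  Flanks shorter than ``min_samples`` yield an
    event flagged unfittable.

    With ``refit_global_p`` (default) the persistence length is first
    fitted jointly per flank, then pinned to the trace median and all
    flanks are refitted: a single chain has one p, and the joint
    (Lc, p) fit has a shallow trade-off valley that noise exploits.
    On noiseless data the two stages agree exactly.
    """
    peaks = np.asarray(peaks, dtype=int)
    # fit windows are defined as contiguous index ranges with their
    # endpoints located on a smoothed force curve: selecting individual
    # samples by their noisy force value censors the noise distribution
    # asymmetrically and biases the fit
    smoothed = _smooth(trace.force, 7)
    dx = np.diff(trace.extension) if len(trace) > 1 else np.asarray([0.0])
    events: list[UnfoldingEvent] = []
    flanks: list[np.ndarray] = []
    prev = 0
    for idx in peaks:
        segment = smoothed[prev:idx + 1]
        start = prev + int(np.argmin(segment))
        peak_force = float(trace.force[idx])
        # cut the rupture transition: walk back from the peak until the
        # smoothed force falls below fit_fraction of the smoothed peak
        cap = idx
        level = fit_fraction * max(smoothed[idx], 1e-9)
        while cap > start and smoothed[cap] > level:
            cap -= 1
        flank = np.arange(start, cap + 1)
        fit = None
        if flank.size >= min_samples:
            try:
                fit = fit_wlc(trace.extension[flank], trace.force[flank],
                              T=T, p_bounds=p_bounds, fix_p=fix_p)
            except ValueError:
                fit = None
        jump = float(np.max(dx[idx:min(idx + 3, dx.size)])) if idx < dx.size else 0.0
        events.append(
            UnfoldingEvent(
                peak_force=peak_force,
                peak_extension=float(trace.extension[idx]),
                fit=fit,
                event_index=int(idx),
                ext_jump=jump,
            )
        )
        flanks.append(flank)
        prev = idx + 1

    # second pass: a single chain has a single persistence length, so p
    # is refined jointly across all fittable flanks (shared p, one Lc
    # per flank) and every flank is refitted with it.  Narrow high-force
    # windows alone leave the per-flank joint (Lc, p) fit ill-conditioned.
    p_ref = fix_p
    if p_ref is None and any(e.fittable for e in events):
        p_ref = _shared_p(trace, events, flanks, T=T, p_bounds=p_bounds)
    if p_ref is None:
        p_ref = 0.4
    if refit_global_p and fix_p is None:
        for i, (event, flank) in enumerate(zip(events, flanks)):
            if not event.fittable:
                continue
            try:
                refit = fit_wlc(trace.extension[flank], trace.force[flank], T=T, fix_p=p_ref)
            except ValueError:
                continue
            events[i] = UnfoldingEvent(
                peak_force=event.peak_force,
                peak_extension=event.peak_extension,
                fit=refit,
                event_index=event.event_index,
                ext_jump=event.ext_jump,
            )

    # third pass: short flanks get a fixed-p contour estimate so that
    # rapid-succession intermediates are not lost downstream
    for i, (event, flank) in enumerate(zip(events, flanks)):
        if event.fittable:
            continue
        # single-point inversion at the apex beats a mini-fit here: a
        # least-squares fit on a handful of noisy low-range samples is
        # strongly right-skewed, the one-point estimate is not
        fallback = None
        if event.peak_extension > 0 and event.peak_force > 0:
            fallback = single_point_lc(event.peak_extension, event.peak_force, p_ref, T)
        events[i] = UnfoldingEvent(
            peak_force=event.peak_force,
            peak_extension=event.peak_extension,
            fit=None,
            event_index=event.event_index,
            lc_fallback=fallback,
            ext_jump=event.ext_jump,
        )
    return events


def analyze_trace(trace: FXTrace, **kwargs) -> list[UnfoldingEvent]:
    """Detect peaks and extract WLC-fitted events in one call.

    Keyword arguments are routed to :func:`detect_peaks`
    (``min_force``, ``min_drop``, ``smooth_window``) and
    :func:`extract_events` (everything else).
    """
    detect_kwargs = {k: kwargs.pop(k)
                     for k in ("min_force", "min_drop", "smooth_window", "min_ext_jump")
                     if k in kwargs}
    peaks = detect_peaks(trace, **detect_kwargs)
    return extract_events(trace, peaks, **kwargs)


def delta_lc(events: list[UnfoldingEvent]) -> np.ndarray:
    """Successive contour-length increments Lc[i+1] - Lc[i] (nm).

    Takes the events of one domain cascade in extension order; a single
    event yields an empty array.  The stepwise increments sum to the
    total Lc(last) - Lc(first) by construction.
    """
    lcs = np.asarray([e.Lc for e in events if e.fittable], dtype=float)
    return np.diff(lcs)


def filter_traces(
    traces: list[FXTrace],
    min_domains: int = 4,
    expected_total_dlc: float = 37.0,
    lc_tolerance: float = 10.0,
    **analyze_kwargs,
) -> list[FXTrace]:
    """Keep only traces showing complete unravelling of >= ``min_domains`` domains.

    Domain cascades are counted by grouping detected events on their
    fitted contour lengths (see :func:`azmech.pathways.group_cascades`).
    """
    if min_domains <= 0:
        return list(traces)
    from .pathways import group_cascades  # deferred: pathways imports this module

    kept = []
    for trace in traces:
        events = analyze_trace(trace, **analyze_kwargs)
        cascades = group_cascades(events, expected_total_dlc=expected_total_dlc,
                                  lc_tolerance=lc_tolerance)
        n_complete = sum(1 for c in cascades if not c.is_terminal)
        if n_complete >= min_domains:
            kept.append(trace)
    return kept
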