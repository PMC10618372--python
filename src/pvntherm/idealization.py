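"""Idealization: from noisy current traces to open/closed event tables.

The pipeline is the classic single-channel one: estimate the closed and
open current levels from the all-points amplitude distribution
(:func:`fit_amplitude_model`), assign every sample to a level with the
segmental-k-means (SKM) iteration (:func:`skm_idealize`) -- Viterbi state
assignment alternating with re-estimation of levels, noise and transition
probabilities -- and finally impose a dead time (:func:`apply_dead_time`):
dwells shorter than the resolution limit are erased and absorbed into the
flanking dwells, exactly as idealized data are conditioned before
dwell-time fitting or interval-likelihood rate estimation.

Event boundaries are refined to sub-sample precision by interpolating the
half-amplitude crossing of the trace, so durations are continuous rather
than quantized at the sampling interval.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import signal as _signal

from .markov_core import OPEN, CLOSED

__all__ = [
    "EventTable",
    "AmplitudeModel",
    "fit_amplitude_model",
    "skm_idealize",
    "threshold_idealize",
    "apply_dead_time",
]

CLASS_NAMES = (CLOSED, OPEN)  # code 0 = closed, 1 = open


@dataclass(frozen=True)
class EventTable:
    """Idealized record: contiguous, strictly alternating class dwells.

    ``classes`` holds 0 for closed and 1 for open.  Times are ms.  The first
    and last dwells are duration-censored (the record starts and ends inside
    a dwell); consumers that fit dwell distributions exclude them.
    """

    start_ms: np.ndarray
    duration_ms: np.ndarray
    classes: np.ndarray
    dead_time_ms: float = 0.0
    sampling_rate_hz: float | None = None

    def __post_init__(self):
        start = np.ascontiguousarray(self.start_ms, dtype=float)
        dur = np.ascontiguousarray(self.duration_ms, dtype=float)
        cls = np.ascontiguousarray(self.classes, dtype=np.uint8)
        if not (len(start) == len(dur) == len(cls)):
            raise ValueError("start, duration and class arrays must have equal length")
        if np.any(dur <= 0):
            raise ValueError("durations must be strictly positive")
        if np.any(cls[1:] == cls[:-1]):
            raise ValueError("classes must strictly alternate")
        gaps = start[1:] - (start[:-1] + dur[:-1])
        if len(start) > 1 and np.max(np.abs(gaps)) > 1e-6 * max(1.0, float(dur.max())):
            raise ValueError("events must be contiguous and non-overlapping")
        if self.dead_time_ms < 0:
            raise ValueError("dead time must be non-negative")
        for a in (start, dur, cls):
            a.setflags(write=False)
        object.__setattr__(self, "start_ms", start)
        object.__setattr__(self, "duration_ms", dur)
        object.__setattr__(self, "classes", cls)

    @classmethod
    def from_durations(cls, classes, durations, t0: float = 0.0, **kw) -> "EventTable":
        durations = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(durations[:-1])])
        return cls(starts, durations, np.asarray(classes, dtype=np.uint8), **kw)

    def __len__(self) -> int:
        return len(self.duration_ms)

    @property
    def total_ms(self) -> float:
        return float(self.duration_ms.sum())

    def durations_of(self, class_label: str, drop_censored: bool = True) -> np.ndarray:
        """Dwell durations of one class, excluding censored boundary dwells."""
        code = CLASS_NAMES.index(class_label)
        mask = self.classes == code
        if drop_censored and len(self) > 0:
            mask = mask.copy()
            mask[0] = mask[-1] = False
        return self.duration_ms[mask]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "start_ms": self.start_ms,
            "duration_ms": self.duration_ms,
            "class": [CLASS_NAMES[c] for c in self.classes],
        })


@dataclass(frozen=True)
class AmplitudeModel:
    """Two-Gaussian description of the all-points amplitude histogram."""

    closed_level: float
    open_level: float
    closed_sd: float
    open_sd: float
    open_detected: bool = True

    @property
    def separation(self) -> float:
        return self.open_level - self.closed_level

    @property
    def snr(self) -> float:
        """Level separation over the larger noise SD."""
        return abs(self.separation) / max(self.closed_sd, self.open_sd, 1e-30)


def _samples_fs(trace, sampling_rate):
    if hasattr(trace, "samples"):
        return np.asarray(trace.samples, dtype=float), float(trace.sampling_rate)
    if sampling_rate is None:
        raise ValueError("sampling_rate required when passing a bare sample array")
    return np.asarray(trace, dtype=float), float(sampling_rate)


def fit_amplitude_model(trace, sampling_rate: float | None = None,
                        max_points: int = 200_000) -> AmplitudeModel:
    """Fit a two-component Gaussian model to the all-points amplitudes.

    The component nearer the pipette baseline (0 pA) is taken as the closed
    level.  If the two components are not resolvably separated (all-closed
    or unimodal records) a closed-only model is returned with
    ``open_detected=False``.
    """
    x, _ = _samples_fs(trace, sampling_rate or 1.0)
    if x.size < 1000:
        raise ValueError("need at least 1000 samples for an amplitude model")
    step = max(1, x.size // max_points)
    x = x[::step]

    uniq = np.unique(x)
    if uniq.size <= 2:  # noiseless rendering
        if uniq.size == 1:
            return AmplitudeModel(float(uniq[0]), np.nan, 0.0, 0.0, open_detected=False)
        lo, hi = (uniq[0], uniq[1]) if abs(uniq[0]) <= abs(uniq[1]) else (uniq[1], uniq[0])
        return AmplitudeModel(float(lo), float(hi), 0.0, 0.0)

    # two-component Gaussian EM, deterministic percentile initialisation
    mu = np.percentile(x, [10.0, 90.0]).astype(float)
    sd = np.full(2, max(x.std() / 2.0, 1e-12))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(300):
        log_p = (np.log(w) - 0.5 * np.log(2 * np.pi * sd**2)
                 - 0.5 * ((x[:, None] - mu) / sd) ** 2)
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        r = p / tot
        nk = r.sum(axis=0)
        w = nk / x.size
        mu = (r * x[:, None]).sum(axis=0) / nk
        sd = np.sqrt((r * (x[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, 1e-12)
        if abs(ll - ll_old) < 1e-9 * x.size:
            break
        ll_old = ll

    # refine levels as the medians of confidently assigned samples: samples on
    # filter ramps between levels drag a plain Gaussian mean inward
    for k in (0, 1):
        strong = x[(r[:, k] > 0.95) & (np.abs(x - mu[k]) < 2.5 * sd[k])]
        if strong.size > 100:
            mu[k] = float(np.median(strong))
            sd[k] = min(sd[k], 1.4826 * float(np.median(np.abs(strong - mu[k]))))
    order = np.argsort(np.abs(mu))  # nearer baseline first
    mu, sd, w = mu[order], sd[order], w[order]
    sep = abs(mu[1] - mu[0])
    if sep < 3.0 * max(sd) or min(w) < 0.02:
        warnings.warn("amplitude histogram unimodal; returning closed-only model")
        return AmplitudeModel(float(x.mean()), np.nan, float(x.std()), np.nan,
                              open_detected=False)
    return AmplitudeModel(float(mu[0]), float(mu[1]), float(sd[0]), float(sd[1]))


@njit(cache=False)
def _viterbi2(x, mu0, mu1, sd0, sd1, log_stay, log_switch):
    n = x.size
    c0 = -np.log(sd0) - 0.5 * np.log(2 * np.pi)
    c1 = -np.log(sd1) - 0.5 * np.log(2 * np.pi)
    bp = np.empty((n, 2), dtype=np.uint8)
    e0 = c0 - 0.5 * ((x[0] - mu0) / sd0) ** 2
    e1 = c1 - 0.5 * ((x[0] - mu1) / sd1) ** 2
    d0, d1 = e0, e1
    for i in range(1, n):
        e0 = c0 - 0.5 * ((x[i] - mu0) / sd0) ** 2
        e1 = c1 - 0.5 * ((x[i] - mu1) / sd1) ** 2
        a = d0 + log_stay
        b = d1 + log_switch
        if a >= b:
            nd0 = a + e0
            bp[i, 0] = 0
        else:
            nd0 = b + e0
            bp[i, 0] = 1
        a = d0 + log_switch
        b = d1 + log_stay
        if a >= b:
            nd1 = a + e1
            bp[i, 1] = 0
        else:
            nd1 = b + e1
            bp[i, 1] = 1
        d0, d1 = nd0, nd1
    path = np.empty(n, dtype=np.uint8)
    path[-1] = 0 if d0 >= d1 else 1
    for i in range(n - 2, -1, -1):
        path[i] = bp[i + 1, path[i + 1]]
    return path


def _events_from_path(path: np.ndarray, x: np.ndarray, fs: float,
                      mu0: float, mu1: float) -> EventTable:
    """Run-length encode a sample path, interpolating boundary crossings."""
    dt = 1000.0 / fs  # ms per sample
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    mid = 0.5 * (mu0 + mu1)
    if change.size:
        a = x[change - 1]
        b = x[change]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = (mid - a) / (b - a)
        frac = np.where(np.isfinite(frac), np.clip(frac, 0.0, 1.0), 0.5)
        cross_ms = (change - 1 + frac + 0.5) * dt
    else:
        cross_ms = np.empty(0)
    bounds = np.concatenate([[0.0], cross_ms, [path.size * dt]])
    durations = np.diff(bounds)
    seg_classes = path[np.concatenate([[0], change])]
    keep = durations > 1e-12
    durations, seg_classes, starts = durations[keep], seg_classes[keep], bounds[:-1][keep]
    if np.any(seg_classes[1:] == seg_classes[:-1]):
        # zero-length segments dropped above can leave same-class neighbours
        breaks = np.concatenate([[0], np.flatnonzero(seg_classes[1:] != seg_classes[:-1]) + 1])
        durations = np.add.reduceat(durations, breaks)
        seg_classes = seg_classes[breaks]
        starts = starts[breaks]
    return EventTable(starts, durations, seg_classes, sampling_rate_hz=fs)


@functools.lru_cache(maxsize=8)
def _halfamp_duration_map(fc_hz: float, fs_hz: float, n_phases: int = 16):
    """Measured-vs-true duration map for brief pulses through the filter.

    A rectangular pulse of true duration ``w`` through the acquisition
    chain (within-sample integration, then a 4-pole Bessel low-pass at
    ``fc_hz``, sampled at ``fs_hz``) is attenuated once ``w`` is comparable
    to the filter rise time, so its measured half-amplitude-crossing
    duration ``m(w)`` is shorter than ``w``.  This computes ``m`` on a grid
    of widths, averaged over the pulse phase relative to the sampling comb
    (for pulses whose filtered peak still crosses half amplitude), and
    returns the arrays needed to invert it by interpolation -- the classic
    brief-event duration correction for analogue-filtered records.
    """
    dt_ms = 1000.0 / fs_hz
    sos = _signal.bessel(4, fc_hz, fs=fs_hz, output="sos", norm="mag")
    n = int(round(16.0 / dt_ms))
    edges = np.arange(n + 1) * dt_ms
    ws = np.concatenate([np.arange(0.05, 1.0, 0.01), np.arange(1.0, 5.0, 0.05)])
    w_ok, m_ok = [], []
    for w in ws:
        meas = []
        for phase in (np.arange(n_phases) + 0.5) / n_phases:
            t0 = 5.0 + phase * dt_ms
            occ = np.clip(np.minimum(edges[1:], t0 + w) - np.maximum(edges[:-1], t0),
                          0.0, None) / dt_ms
            y = _signal.sosfilt(sos, occ)
            if y.max() <= 0.5:
                continue
            above = y > 0.5
            i0 = int(np.argmax(above))
            i1 = len(y) - int(np.argmax(above[::-1]))
            c0 = i0 - (y[i0] - 0.5) / (y[i0] - y[i0 - 1])
            c1 = i1 - 1 + (y[i1 - 1] - 0.5) / (y[i1 - 1] - y[i1])
            meas.append((c1 - c0) * dt_ms)
        if len(meas) == n_phases:  # only widths detectable at every phase
            w_ok.append(w)
            m_ok.append(float(np.mean(meas)))
    m_arr, w_arr = np.asarray(m_ok), np.asarray(w_ok)
    order = np.argsort(m_arr)
    return m_arr[order], w_arr[order]


def correct_brief_durations(events: EventTable, filter_cutoff_hz: float,
                            sampling_rate_hz: float | None = None) -> EventTable:
    """Undo the half-amplitude shortening of brief filtered events.

    Dwells whose measured duration is short enough to be attenuated by the
    acquisition filter are lengthened to the true pulse width implied by
    the measured half-amplitude duration; each boundary moves symmetrically
    and the flanking (long) dwells give up the difference, conserving the
    total record duration.
    """
    fs = sampling_rate_hz or events.sampling_rate_hz
    if fs is None:
        raise ValueError("sampling rate required for the duration correction")
    m_grid, w_grid = _halfamp_duration_map(float(filter_cutoff_hz), float(fs))
    # beyond this measured duration the correction is below 1%
    full = m_grid[np.flatnonzero(w_grid - m_grid < 0.01 * w_grid)[0]] if np.any(
        w_grid - m_grid < 0.01 * w_grid) else m_grid[-1]
    dur = events.duration_ms.copy()
    brief = dur < full
    if not np.any(brief):
        return events
    corrected = np.interp(dur[brief], m_grid, w_grid,
                          left=w_grid[0], right=w_grid[-1])
    delta = corrected - dur[brief]
    bounds = np.concatenate([events.start_ms,
                             [events.start_ms[-1] + events.duration_ms[-1]]])
    new_bounds = bounds.copy()
    idx = np.flatnonzero(brief)
    np.add.at(new_bounds, idx, -delta / 2.0)
    np.add.at(new_bounds, idx + 1, delta / 2.0)
    new_bounds[0], new_bounds[-1] = bounds[0], bounds[-1]
    bad = np.diff(new_bounds) <= 0
    if np.any(bad):
        # adjacent brief events competing for the same neighbour: drop the
        # corrections involved rather than create negative dwells
        drop = np.unique(np.concatenate([np.flatnonzero(bad), np.flatnonzero(bad) + 1]))
        drop = drop[(drop >= 0) & (drop < len(dur))]
        new_bounds = bounds.copy()
        keep = np.setdiff1d(idx, drop)
        d2 = delta[np.isin(idx, keep)]
        np.add.at(new_bounds, keep, -d2 / 2.0)
        np.add.at(new_bounds, keep + 1, d2 / 2.0)
        new_bounds[0], new_bounds[-1] = bounds[0], bounds[-1]
        if np.any(np.diff(new_bounds) <= 0):
            return events
    new_dur = np.diff(new_bounds)
    return EventTable(new_bounds[:-1], new_dur, events.classes,
                      dead_time_ms=events.dead_time_ms,
                      sampling_rate_hz=events.sampling_rate_hz)


def recover_flicker_events(events: EventTable, x: np.ndarray, fs: float,
                           mu0: float, mu1: float, sd0: float, sd1: float,
                           f_lo: float = 0.12, f_hi: float = 0.25,
                           min_duration_ms: float = 0.15,
                           max_duration_ms: float = 0.8,
                           guard_ms: float = 0.4) -> EventTable:
    """Recover brief events whose filtered peak never reaches half amplitude.

    Flickery gating faster than the filter rise time leaves significant
    sub-half-amplitude deviations inside a dwell that threshold or Viterbi
    assignment cannot classify.  Because a linear filter conserves signal
    area, the true duration of such an event equals the area of its
    fractional deviation toward the opposite level (the classic excess-area
    estimate).  Runs of deviation exceeding ``f_hi`` (extended to ``f_lo``
    contiguity, away from dwell boundaries, and at least 5 within-class
    noise SDs at the peak) are replaced by an inserted opposite-class event
    of that equivalent duration, centred on the deviation centroid.
    """
    dt = 1000.0 / fs
    n = x.size
    amp = mu1 - mu0
    if amp == 0:
        return events
    # per-sample fractional deviation from the assigned level toward the other
    bounds = np.concatenate([events.start_ms, [events.start_ms[-1] + events.duration_ms[-1]]])
    sample_t = (np.arange(n) + 0.5) * dt + bounds[0]
    host = np.clip(np.searchsorted(bounds, sample_t) - 1, 0, len(events) - 1)
    host_cls = events.classes[host]
    level = np.where(host_cls == 0, mu0, mu1)
    f = (x - level) / np.where(host_cls == 0, amp, -amp)
    # exclude samples near any event boundary (filter ramps)
    guard = guard_ms
    t_prev = sample_t - bounds[host]
    t_next = bounds[host + 1] - sample_t
    valid = (t_prev > guard) & (t_next > guard)
    cand = (f > f_lo) & valid
    if not np.any(cand):
        return events
    starts = np.flatnonzero(cand & ~np.roll(cand, 1))
    ends = np.flatnonzero(cand & ~np.roll(cand, -1)) + 1
    inserts: list[tuple[int, float, float]] = []  # (host index, centre ms, duration ms)
    for i0, i1 in zip(starts, ends):
        seg = f[i0:i1]
        if seg.max() < f_hi:
            continue
        h = host[i0]
        if host[i1 - 1] != h:
            continue
        sd_host = sd0 if events.classes[h] == 0 else sd1
        if seg.max() * abs(amp) < 5.0 * sd_host:
            continue
        area = float(seg.sum()) * dt
        if not (min_duration_ms <= area <= max_duration_ms):
            continue
        centre = float((seg * sample_t[i0:i1]).sum() / seg.sum())
        inserts.append((int(h), centre, area))
    if not inserts:
        return events
    # split host dwells around the inserted opposite-class events
    new_b: list[float] = []
    new_c: list[int] = []
    by_host: dict[int, list[tuple[float, float]]] = {}
    for h, c, d in inserts:
        by_host.setdefault(h, []).append((c, d))
    for k in range(len(events)):
        b0, b1 = bounds[k], bounds[k + 1]
        cls = int(events.classes[k])
        new_b.append(b0)
        new_c.append(cls)
        for c, d in sorted(by_host.get(k, [])):
            lo = max(b0 + 1e-6, c - d / 2.0)
            hi = min(b1 - 1e-6, c + d / 2.0)
            if hi <= lo or lo <= new_b[-1]:
                continue
            new_b.append(lo)
            new_c.append(1 - cls)
            new_b.append(hi)
            new_c.append(cls)
    new_b.append(bounds[-1])
    starts_ms = np.array(new_b[:-1])
    durs = np.diff(np.array(new_b))
    return EventTable(starts_ms, durs, np.array(new_c, dtype=np.uint8),
                      dead_time_ms=events.dead_time_ms,
                      sampling_rate_hz=events.sampling_rate_hz)


def skm_idealize(trace, model: AmplitudeModel, sampling_rate: float | None = None,
                 max_iter: int = 50, tol: float = 1e-3,
                 filter_cutoff_hz: float | None = None) -> EventTable:
    """Segmental-k-means idealization of a two-level record.

    Alternates the most likely state path given current levels, noise SDs
    and transition probabilities (Viterbi) with re-estimation of those
    parameters from the assignment, until fewer than ``tol`` of samples
    change class or ``max_iter`` iterations pass.  Event boundaries are
    interpolated at the half-amplitude crossing, and if the acquisition
    filter cutoff is known (argument or trace metadata) brief-event
    durations are corrected for filter attenuation
    (:func:`correct_brief_durations`).
    """
    if not model.open_detected or not np.isfinite(model.open_level):
        raise ValueError("amplitude model has no open level; cannot idealize")
    x, fs = _samples_fs(trace, sampling_rate)
    mu0, mu1 = model.closed_level, model.open_level
    sd_floor = max(1e-9, 1e-6 * abs(mu1 - mu0))
    sd0 = max(model.closed_sd, sd_floor)
    sd1 = max(model.open_sd if np.isfinite(model.open_sd) else sd_floor, sd_floor)
    p_switch = 0.05
    path_old = None
    converged = False
    for _ in range(max_iter):
        path = _viterbi2(x, mu0, mu1, sd0, sd1,
                         np.log1p(-p_switch), np.log(p_switch))
        if path_old is not None and np.mean(path != path_old) < tol:
            path_old = path
            converged = True
            break
        path_old = path
        n1 = int(path.sum())
        if 0 < n1 < path.size:
            x0, x1 = x[path == 0], x[path == 1]
            mu0, mu1 = float(np.median(x0)), float(np.median(x1))
            # robust within-class noise: filter-smeared transition samples and
            # undetected brief events are outliers a plain SD would absorb
            sd0 = max(1.4826 * float(np.median(np.abs(x0 - mu0))), sd_floor)
            sd1 = max(1.4826 * float(np.median(np.abs(x1 - mu1))), sd_floor)
            n_switch = int(np.count_nonzero(path[1:] != path[:-1]))
            p_switch = min(0.4, max(1e-6, (n_switch + 1) / path.size))
        else:  # degenerate assignment; keep level model fixed
            break
    if not converged and max_iter > 1:
        warnings.warn("SKM did not converge; returning best assignment")
    table = _events_from_path(path_old, x, fs, mu0, mu1)
    if filter_cutoff_hz is None and hasattr(trace, "metadata"):
        filter_cutoff_hz = trace.metadata.get("filter_cutoff_hz")
    if filter_cutoff_hz:
        table = correct_brief_durations(table, filter_cutoff_hz, fs)
        table = recover_flicker_events(table, x, fs, mu0, mu1, sd0, sd1)
    return table


def threshold_idealize(trace, model: AmplitudeModel,
                       sampling_rate: float | None = None,
                       filter_cutoff_hz: float | None = None) -> EventTable:
    """Fast half-amplitude threshold idealizer (cross-check for SKM)."""
    if not model.open_detected or not np.isfinite(model.open_level):
        raise ValueError("amplitude model has no open level; cannot idealize")
    x, fs = _samples_fs(trace, sampling_rate)
    mid = 0.5 * (model.closed_level + model.open_level)
    if model.open_level >= model.closed_level:
        path = (x > mid).astype(np.uint8)
    else:
        path = (x < mid).astype(np.uint8)
    table = _events_from_path(path, x, fs, model.closed_level, model.open_level)
    if filter_cutoff_hz is None and hasattr(trace, "metadata"):
        filter_cutoff_hz = trace.metadata.get("filter_cutoff_hz")
    if filter_cutoff_hz:
        table = correct_brief_durations(table, filter_cutoff_hz)
    return table


def apply_dead_time(events: EventTable, dead_time_ms: float = 0.3) -> EventTable:
    """Impose a dead time: erase dwells shorter than ``dead_time_ms``.

    Each sub-resolution dwell is absorbed into the flanking dwells of the
    opposite class, which concatenate into a single dwell (standard
    missed-event conditioning); total record duration is conserved.  A
    censored boundary dwell shorter than the dead time is absorbed into its
    single neighbour.
    """
    if dead_time_ms < 0:
        raise ValueError("dead time must be non-negative")
    if dead_time_ms == 0 or len(events) == 0:
        return replace(events, dead_time_ms=float(dead_time_ms))
    td = float(dead_time_ms)
    cls = events.classes
    dur = events.duration_ms
    out_c: list[int] = []
    out_d: list[float] = []
    acc_c, acc_d = int(cls[0]), float(dur[0])
    for i in range(1, len(dur)):
        c, d = int(cls[i]), float(dur[i])
        if acc_d < td:       # (boundary) accumulated dwell unresolvable
            acc_c, acc_d = c, acc_d + d
        elif d < td:         # erase; time accrues to the current dwell
            acc_d += d
        elif c == acc_c:     # neighbours of an erased dwell concatenate
            acc_d += d
        else:
            out_c.append(acc_c)
            out_d.append(acc_d)
            acc_c, acc_d = c, d
    if acc_d < td and out_d:
        out_d[-1] += acc_d
    else:
        out_c.append(acc_c)
        out_d.append(acc_d)
    table = EventTable.from_durations(
        np.array(out_c, dtype=np.uint8), np.array(out_d),
        t0=float(events.start_ms[0]),
        dead_time_ms=td, sampling_rate_hz=events.sampling_rate_hz,
    )
    return table
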