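"""Dwell-time statistics on idealized records.

Closed and open dwell durations are summarised three ways, mirroring
standard single-channel practice:

* Sigworth-Sine display: log-binned histograms with a square-root ordinate,
  so each exponential component appears as a peak at its time constant
  (:func:`log_bin`; display only -- never used for fitting);
* maximum-likelihood exponential-mixture fits on the *unbinned* dwells,
  left-truncated at the imposed dead time (:func:`fit_mixture`).  Because a
  left-truncated exponential is a shifted exponential with the same time
  constant, the truncated mixture is fitted by EM on the shifted data and
  the mixing fractions are mapped back through the truncation weights;
* component count chosen by a log-likelihood ratio test at the 0.95
  confidence level, two degrees of freedom (one tau, one area) per added
  component (:func:`select_components`);
* open probability and mean dwell times from the record
  (:func:`po_and_means`), censored boundary dwells excluded from the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .markov_core import DwellMixture, OPEN, CLOSED
from .idealization import EventTable

__all__ = [
    "LogBinnedHistogram",
    "MixtureFit",
    "DwellSummary",
    "log_bin",
    "fit_mixture",
    "select_components",
    "po_and_means",
]


@dataclass(frozen=True)
class LogBinnedHistogram:
    """Log-spaced dwell histogram for Sigworth-Sine display."""

    edges_ms: np.ndarray
    counts: np.ndarray
    ordinate_transform: str = "sqrt"

    @property
    def centers_ms(self) -> np.ndarray:
        return np.sqrt(self.edges_ms[:-1] * self.edges_ms[1:])

    @property
    def transformed_counts(self) -> np.ndarray:
        return np.sqrt(self.counts)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted dwell mixture with its likelihood and diagnostics."""

    mixture: DwellMixture
    loglik: float
    n_dwells: int
    dead_time_ms: float
    converged: bool
    n_iter: int

    @property
    def taus(self):
        return self.mixture.taus

    @property
    def areas(self):
        return self.mixture.areas


@dataclass(frozen=True)
class DwellSummary:
    """Record-level summary: Po and mean dwell times."""

    po: float
    mean_open: float
    mean_closed: float
    total_ms: float
    n_events: int


def log_bin(dwells, bins_per_decade: int = 10) -> LogBinnedHistogram:
    """Log-bin dwell durations (ms).  Display only, never used for fitting."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("no dwells to bin")
    if np.any(d <= 0):
        raise ValueError("dwell durations must be positive")
    lo, hi = np.log10(d.min()), np.log10(d.max())
    if hi - lo < 1e-12:  # all equal: one occupied bin
        edges = np.array([d.min() * 0.999, d.max() * 1.001])
    else:
        n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[0] *= 1 - 1e-12
        edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(d, bins=edges)
    return LogBinnedHistogram(edges_ms=edges, counts=counts)


def _em_exponential_mixture(s: np.ndarray, taus0: np.ndarray, areas0: np.ndarray,
                            max_iter: int = 1500, tol: float = 1e-9):
    """EM for an exponential mixture on non-negative data ``s``."""
    taus = taus0.copy()
    areas = areas0.copy()
    n = s.size
    ll_old = -np.inf
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        log_p = np.log(areas) - np.log(taus) - s[:, None] / taus
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        tot = p.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        r = p / tot
        nk = r.sum(axis=0)
        areas = nk / n
        taus = (r * s[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        taus = np.maximum(taus, 1e-6)
        areas = np.maximum(areas, 1e-12)
        areas /= areas.sum()
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    log_p = np.log(areas) - np.log(taus) - s[:, None] / taus
    m = log_p.max(axis=1, keepdims=True)
    ll = float((np.log(np.exp(log_p - m).sum(axis=1)) + m[:, 0]).sum())
    return taus, areas, ll, it, converged


def fit_mixture(dwells, n_components: int, dead_time: float = 0.0,
                class_label: str = CLOSED, n_restarts: int = 10,
                seed: int = 0, temperature: float = 22.0) -> MixtureFit:
    """ML fit of a left-truncated exponential mixture to unbinned dwells.

    All dwells must be >= ``dead_time`` (ms).  Maximises the likelihood of
    the mixture conditioned on exceeding the dead time; ``n_restarts``
    deterministic random initialisations, ties broken by likelihood.
    Returned taus are sorted ascending; areas are fractions of the full
    (untruncated) mixture, as conventionally reported.
    """
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("no dwells to fit")
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be in {1, 2, 3}")
    if np.any(d < dead_time - 1e-9):
        raise ValueError("all dwells must be at least the dead time")
    s = np.maximum(d - dead_time, 0.0)
    if n_components == 1:
        # closed form: MLE tau of a shifted exponential is the mean shift
        tau = max(float(s.mean()), 1e-6)
        ll = float(-np.log(tau) * s.size - s.sum() / tau)
        mix = DwellMixture(class_label, (tau,), (1.0,), temperature=temperature)
        return MixtureFit(mix, ll, s.size, dead_time, True, 0)

    rng = np.random.default_rng(seed)
    qs = np.quantile(s[s > 0] if np.any(s > 0) else s + 1e-6,
                     (np.arange(n_components) + 0.5) / n_components)
    qs = np.maximum(qs, 1e-6)
    # short-run strategy: cheap pilot EMs on a subsample pick the basin,
    # a single full-data EM polishes the best pilot
    pilot = s if s.size <= 8000 else rng.choice(s, size=8000, replace=False)
    best0 = None
    for k in range(n_restarts):
        taus0 = qs * (1.0 if k == 0 else rng.lognormal(0.0, 0.8, size=n_components))
        taus0 = np.maximum(taus0, 1e-6)
        areas0 = np.full(n_components, 1.0 / n_components)
        taus, areas, ll, *_ = _em_exponential_mixture(pilot, taus0, areas0,
                                                      max_iter=250, tol=1e-7)
        if best0 is None or ll > best0[2]:
            best0 = (taus, areas, ll)
    taus, areas, ll, it, conv = _em_exponential_mixture(s, best0[0], best0[1])
    # map truncated-mixture fractions back to full-mixture areas
    full = areas * np.exp(dead_time / taus)
    full /= full.sum()
    order = np.argsort(taus)
    taus, full = taus[order], full[order]
    # merge numerically coincident components (overfitted support)
    keep_t, keep_a = [taus[0]], [full[0]]
    for t, a in zip(taus[1:], full[1:]):
        if t - keep_t[-1] <= 1e-9 * t:
            keep_a[-1] += a
        else:
            keep_t.append(t)
            keep_a.append(a)
    keep_a = [a / sum(keep_a) for a in keep_a]
    mix = DwellMixture(class_label, tuple(keep_t), tuple(keep_a), temperature=temperature)
    return MixtureFit(mix, ll, s.size, dead_time, conv, it)


def select_components(dwells, max_n: int = 3, alpha: float = 0.05,
                      dead_time: float = 0.0, class_label: str = CLOSED,
                      seed: int = 0) -> MixtureFit:
    """Choose the exponential component count by log-likelihood ratio.

    Components are added while twice the log-likelihood gain exceeds the
    chi-squared critical value with two degrees of freedom per added
    component, at confidence ``1 - alpha`` (0.95 by default).
    """
    crit = stats.chi2.ppf(1.0 - alpha, df=2)
    fit = fit_mixture(dwells, 1, dead_time=dead_time, class_label=class_label, seed=seed)
    for k in range(2, max_n + 1):
        cand = fit_mixture(dwells, k, dead_time=dead_time, class_label=class_label,
                           seed=seed + k)
        if 2.0 * (cand.loglik - fit.loglik) > crit:
            fit = cand
        else:
            break
    return fit


def po_and_means(events: EventTable) -> DwellSummary:
    """Open probability and mean dwell times of an idealized record.

    Po is total open time over total time; the mean open/closed times
    exclude the duration-censored first and last dwells.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    open_time = float(events.duration_ms[events.classes == 1].sum())
    po = open_time / events.total_ms
    open_d = events.durations_of(OPEN)
    closed_d = events.durations_of(CLOSED)
    mean_open = float(open_d.mean()) if open_d.size else np.nan
    mean_closed = float(closed_d.mean()) if closed_d.size else np.nan
    return DwellSummary(po=po, mean_open=mean_open, mean_closed=mean_closed,
                        total_ms=events.total_ms, n_events=len(events))
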