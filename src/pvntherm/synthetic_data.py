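"""Synthetic single-channel and action-current data with full seed control.

Generates every input the analysis pipeline needs:

* exact continuous-time Markov gating trajectories from a
  :class:`~pvntherm.markov_core.KineticScheme` (:func:`simulate_gating`);
* noisy cell-attached current traces rendered from those trajectories,
  emulating the acquisition chain of the source recordings -- ohmic unitary
  current, 4-pole low-pass filtering at 1 kHz, Gaussian recording noise,
  sampling at 5 kHz (:func:`render_trace`);
* multi-temperature "experiment" datasets with ground-truth kinetics for
  parameter-recovery testing (:func:`make_temperature_dataset`);
* spontaneous action-current test traces with known event times for
  validating the adaptive-threshold detector (:func:`make_spike_trace`).

Event times are generated in continuous time and only discretised at
rendering, so ground truth stays exact.  Traces are stored as pipette
current with inward unitary current negative (openings deflect downward at
negative driving potentials); ``TraceConfig.invert`` flips the convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal

from .markov_core import KineticScheme, DwellMixture, equilibrium, trpv4_scheme, \
    trpv4_closed_mixture, trpv4_open_mixture, CLOSED, OPEN
from .idealization import EventTable

__all__ = [
    "TraceConfig",
    "CurrentTrace",
    "TemperatureDataset",
    "simulate_gating",
    "render_trace",
    "make_temperature_dataset",
    "make_spike_trace",
]


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition parameters for rendering a current trace.

    ``holding_potential`` is the effective driving potential of the
    cell-attached patch (resting potential and pipette command collapsed
    into one number); unitary current is
    ``g * (holding_potential - V_rev)``.
    """

    sampling_rate: float = 5000.0   # Hz
    filter_cutoff: float = 1000.0   # Hz
    noise_sd: float = 0.30          # pA
    holding_potential: float = -70.0  # mV
    duration: float = 10.0          # s
    n_channels_in_patch: int = 1
    seed: int = 0
    invert: bool = False

    def __post_init__(self):
        if self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed twice the filter cutoff")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_channels_in_patch < 1:
            raise ValueError("n_channels_in_patch must be >= 1")


@dataclass(frozen=True)
class CurrentTrace:
    """A sampled current record in pA with acquisition metadata."""

    samples: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        samples = np.ascontiguousarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@njit(cache=False)
def _ctmc_kernel(exit_rates, cum_jump, start, t_max_ms, cap, seed):
    np.random.seed(seed)
    states = np.empty(cap, dtype=np.int64)
    durs = np.empty(cap, dtype=np.float64)
    t = 0.0
    s = start
    k = 0
    while t < t_max_ms and k < cap:
        dwell = np.random.exponential(1.0 / exit_rates[s])
        if t + dwell > t_max_ms:
            dwell = t_max_ms - t
        states[k] = s
        durs[k] = dwell
        k += 1
        t += dwell
        u = np.random.random()
        ns = 0
        while cum_jump[s, ns] < u:
            ns += 1
        s = ns
    return states[:k], durs[:k]


def simulate_gating(scheme: KineticScheme, duration: float, seed: int = 0) -> EventTable:
    """Exact stochastic gating trajectory collapsed to open/closed dwells.

    Exponential waiting times and embedded-chain jumps; the initial state is
    drawn from the equilibrium distribution.  ``duration`` is in seconds;
    the returned :class:`EventTable` is in ms.  Fully reproducible per seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    eq = equilibrium(scheme)
    Q = scheme.rates
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    exit_rates = off.sum(axis=1)
    P = off / exit_rates[:, None]
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    start = int(rng.choice(scheme.n_states, p=eq.occupancy))
    t_max_ms = duration * 1000.0
    mean_rate = float(eq.occupancy @ exit_rates)  # transitions per ms
    cap = int(t_max_ms * mean_rate * 1.5 + 10_000)
    kernel_seed = int(rng.integers(0, 2**32 - 1))
    states, durs = _ctmc_kernel(exit_rates, cum, start, t_max_ms, cap, kernel_seed)
    codes = np.array([1 if c == OPEN else 0 for c in scheme.class_of_state], dtype=np.uint8)
    cls = codes[states]
    # collapse consecutive same-class sojourns into class dwells
    breaks = np.concatenate([[0], np.flatnonzero(cls[1:] != cls[:-1]) + 1])
    dwell_durs = np.add.reduceat(durs, breaks)
    dwell_cls = cls[breaks]
    return EventTable.from_durations(dwell_cls, dwell_durs)


def _occupancy_signal(events: EventTable, n_samples: int, dt_ms: float) -> np.ndarray:
    """Mean open fraction within each sample interval (exact integration)."""
    bounds = np.concatenate([events.start_ms, [events.start_ms[-1] + events.duration_ms[-1]]])
    open_dur = np.where(events.classes == 1, events.duration_ms, 0.0)
    cum_open = np.concatenate([[0.0], np.cumsum(open_dur)])
    edges = np.arange(n_samples + 1) * dt_ms + bounds[0]
    f = np.interp(edges, bounds, cum_open)
    return np.diff(f) / dt_ms


def render_trace(events, scheme: KineticScheme, config: TraceConfig) -> CurrentTrace:
    """Render an idealized trajectory as a noisy sampled current trace.

    The piecewise-constant conductance signal is integrated within each
    sample interval (anti-aliased sampling), low-pass filtered with a
    4-pole Bessel filter at ``filter_cutoff`` emulating the analogue
    acquisition chain, and Gaussian recording noise of SD ``noise_sd`` is
    added.  ``events`` may be a single :class:`EventTable` or a sequence of
    tables (independent channels superposed when
    ``n_channels_in_patch > 1``).
    """
    tables = [events] if isinstance(events, EventTable) else list(events)
    if len(tables) != config.n_channels_in_patch:
        raise ValueError("need one event table per channel in the patch")
    fs = config.sampling_rate
    dt_ms = 1000.0 / fs
    n = int(round(config.duration * fs))
    for t in tables:
        if t.total_ms < n * dt_ms - 1e-6:
            raise ValueError("events must span at least the configured duration")
    i_open = scheme.unitary_conductance * (
        config.holding_potential - scheme.reversal_potential) * 1e-3  # pA
    sig = np.zeros(n)
    for t in tables:
        sig += _occupancy_signal(t, n, dt_ms)
    sig *= i_open
    if config.filter_cutoff > 0:
        sos = signal.bessel(4, config.filter_cutoff, fs=fs, output="sos", norm="mag")
        zi = signal.sosfilt_zi(sos) * sig[0]
        sig, _ = signal.sosfilt(sos, sig, zi=zi)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        sig = sig + rng.normal(0.0, config.noise_sd, size=n)
    if config.invert:
        sig = -sig
    meta = {
        "holding_potential_mV": config.holding_potential,
        "temperature_C": scheme.reference_temperature,
        "seed": config.seed,
        "unitary_current_pA": i_open,
        "noise_sd_pA": config.noise_sd,
        "filter_cutoff_hz": config.filter_cutoff,
    }
    return CurrentTrace(samples=sig, sampling_rate=fs, metadata=meta)


@dataclass(frozen=True)
class TemperatureDataset:
    """One rendered trace per temperature with exact ground truth attached."""

    temperatures: tuple[float, ...]
    traces: tuple[CurrentTrace, ...]
    events: tuple[EventTable, ...]
    schemes: tuple[KineticScheme, ...]
    closed_mixtures: tuple[DwellMixture, ...]
    open_mixtures: tuple[DwellMixture, ...]
    seeds: tuple[int, ...]


def make_temperature_dataset(temps, per_temp_duration: float, seed: int = 0,
                             noise_sd: float = 0.30,
                             holding_potential: float = -70.0) -> TemperatureDataset:
    """Emulate the multi-temperature single-channel experiment.

    One cell-attached trace per temperature, generated from the
    per-temperature default Trpv4-like scheme; ground-truth gating events
    and dwell mixtures ride along for parameter-recovery tests.
    """
    temps = [float(t) for t in temps]
    if not temps:
        raise ValueError("temperature list is empty")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(temps))]
    traces, events, schemes, cmix, omix, seeds = [], [], [], [], [], []
    for k, T in enumerate(temps):
        scheme = trpv4_scheme(T)
        s_gate, s_noise = child_seeds[2 * k], child_seeds[2 * k + 1]
        ev = simulate_gating(scheme, per_temp_duration, seed=s_gate)
        cfg = TraceConfig(noise_sd=noise_sd, holding_potential=holding_potential,
                          duration=per_temp_duration, seed=s_noise)
        traces.append(render_trace(ev, scheme, cfg))
        events.append(ev)
        schemes.append(scheme)
        cmix.append(trpv4_closed_mixture(T) if T in (22.0, 32.0, 37.0) else None)
        omix.append(trpv4_open_mixture(T) if T in (22.0, 32.0, 37.0) else None)
        seeds.append(s_gate)
    return TemperatureDataset(
        temperatures=tuple(temps), traces=tuple(traces), events=tuple(events),
        schemes=tuple(schemes), closed_mixtures=tuple(cmix),
        open_mixtures=tuple(omix), seeds=tuple(seeds),
    )


def biphasic_waveform(fs: float = 5000.0, width_ms: float = 1.2,
                      amplitude_pA: float = -8.0) -> np.ndarray:
    """Stereotyped biphasic action-current waveform (sharp phase + rebound)."""
    t = np.arange(0.0, 5 * width_ms, 1000.0 / fs)
    t0 = width_ms
    s1, s2 = width_ms / 4.0, width_ms
    w = np.exp(-0.5 * ((t - t0) / s1) ** 2) - 0.45 * np.exp(-0.5 * ((t - t0 - s2) / s2) ** 2)
    return amplitude_pA * w / np.max(np.abs(w))


def make_spike_trace(rate: float, duration: float, waveform: np.ndarray | None = None,
                     noise_sd: float = 1.0, seed: int = 0,
                     sampling_rate: float = 5000.0):
    """Poisson train of stereotyped action currents embedded in noise.

    Returns ``(trace, true_spike_times_ms)``; the truth is the waveform
    onset time of each event.  ``rate`` in Hz, ``duration`` in s.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round(duration * fs))
    if waveform is None:
        waveform = biphasic_waveform(fs=fs, amplitude_pA=-8.0 * max(noise_sd, 1e-12))
    sig = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    n_spk = rng.poisson(rate * duration)
    times_ms = np.sort(rng.uniform(0.0, duration * 1000.0, size=n_spk))
    # keep events fully inside the record so the truth is recoverable
    lim = (n - waveform.size) * 1000.0 / fs
    times_ms = times_ms[times_ms < lim]
    for t in times_ms:
        i0 = int(round(t * fs / 1000.0))
        sig[i0:i0 + waveform.size] += waveform
    meta = {"rate_hz": rate, "seed": seed, "noise_sd_pA": noise_sd}
    return CurrentTrace(samples=sig, sampling_rate=fs, metadata=meta), times_ms
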