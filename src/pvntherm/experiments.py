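"""End-to-end in-silico experiments mirroring the single-channel study.

These drivers regenerate the synthetic raw data and push it through the
full analysis pipeline (gating simulation -> trace rendering -> amplitude
model -> SKM idealization -> dead time -> ML dwell fitting), reporting the
quantities the study tabulates: the unitary current-voltage relation and
the per-temperature closed dwell-time mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import markov_core as mc
from . import synthetic_data as sd
from . import idealization as idz
from . import dwell_analysis as da

__all__ = ["IVResult", "DwellRecoveryResult", "iv_experiment", "dwell_recovery_experiment"]

IV_POTENTIALS = (-70.0, -50.0, -30.0, -10.0, 10.0)


@dataclass(frozen=True)
class IVResult:
    potentials_mv: tuple
    amplitudes_pa: tuple
    conductance_ps: float
    reversal_mv: float
    n_samples: int


@dataclass(frozen=True)
class DwellRecoveryResult:
    temperature_c: float
    taus_ms: tuple
    areas: tuple
    n_dwells: int
    loglik: float


def iv_experiment(seed: int = 0, duration: float = 60.0,
                  potentials=IV_POTENTIALS, min_snr: float = 8.0) -> IVResult:
    """Recover the unitary IV relation from synthetic cell-attached traces.

    One trace per holding potential; the open-channel amplitude comes from
    the two-Gaussian all-points amplitude model and the slope conductance
    and reversal potential from a linear fit.  Recording noise is the
    instrument default (0.15 pA) capped so the amplitude keeps an SNR of at
    least ``min_snr`` even near the reversal potential.
    """
    scheme = mc.trpv4_scheme(22.0)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(potentials))]
    amps = []
    n_total = 0
    for k, V in enumerate(potentials):
        i_true = scheme.unitary_conductance * (V - scheme.reversal_potential) * 1e-3
        cfg = sd.TraceConfig(duration=duration, holding_potential=V,
                             noise_sd=min(0.15, abs(i_true) / min_snr),
                             seed=seeds[2 * k + 1])
        events = sd.simulate_gating(scheme, duration, seed=seeds[2 * k])
        trace = sd.render_trace(events, scheme, cfg)
        model = idz.fit_amplitude_model(trace)
        amps.append(model.separation)
        n_total += trace.samples.size
    A = np.vstack([potentials, np.ones(len(potentials))]).T
    coef, *_ = np.linalg.lstsq(A, np.array(amps), rcond=None)
    return IVResult(potentials_mv=tuple(potentials), amplitudes_pa=tuple(amps),
                    conductance_ps=float(coef[0] * 1000.0),
                    reversal_mv=float(-coef[1] / coef[0]), n_samples=n_total)


def dwell_recovery_experiment(temperature: float, seed: int = 0,
                              target_closed_dwells: int = 50_000,
                              dead_time_ms: float = 0.3) -> DwellRecoveryResult:
    """Full closed dwell-time recovery at one temperature.

    Simulates enough gating to contain ``target_closed_dwells`` closed
    dwells, renders a 5 kHz / 1 kHz-filtered noisy trace, idealizes it with
    SKM, imposes the dead time and ML-fits a 3-component left-truncated
    exponential mixture to the closed dwells.
    """
    scheme = mc.trpv4_scheme(temperature)
    eq = mc.equilibrium(scheme)
    cycle_ms = eq.mean_open + eq.mean_closed
    duration = target_closed_dwells * cycle_ms / 1000.0  # s
    ss = np.random.SeedSequence(seed)
    s_gate, s_noise = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    events = sd.simulate_gating(scheme, duration, seed=s_gate)
    trace = sd.render_trace(events, scheme,
                            sd.TraceConfig(duration=duration, seed=s_noise))
    model = idz.fit_amplitude_model(trace)
    table = idz.apply_dead_time(idz.skm_idealize(trace, model), dead_time_ms)
    closed = table.durations_of("closed")
    fit = da.fit_mixture(closed, 3, dead_time=dead_time_ms, seed=seed)
    return DwellRecoveryResult(temperature_c=float(temperature),
                               taus_ms=fit.taus, areas=fit.areas,
                               n_dwells=fit.n_dwells, loglik=fit.loglik)
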