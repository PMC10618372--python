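"""Stochastic single-compartment model of a PVN pre-sympathetic neurone.

The membrane carries deterministic fast Na+/K+ spike conductances
(Hodgkin-Huxley form) on top of stochastically gated channel populations:
a delayed-rectifier Kv population (5-state chain equivalent to an n^4
gate), the thermosensitive Trpv4-like channel (the 3-closed/3-open scheme
measured at 22/32/37 degC, log-linearly interpolated in between), a
2-state Trpm2-like channel whose opening rate carries Q10 = 15.6, and
small-conductance Ca2+-activated K+ (SK) channels gated by the Ca2+
concentration of a sub-membrane microdomain.

Ca2+ entering through the TRP channels (the GHK flux fraction of each
channel current, weighted by a per-channel-type microdomain coupling
efficiency) accumulates in a small buffered microdomain that exchanges
with the bulk cytosol; SK channels read the microdomain concentration.
Cooling closes both TRP channels, collapses microdomain Ca2+, switches the
hyperpolarising SK conductance off and therefore *raises* spontaneous
firing -- the mechanism under study.  Synaptic drive is a Poisson
excitatory train plus a threshold-linear inhibitory interneurone stage,
with per-run lognormal jitter of the mean rates.

Channel counts change by binomial draws per time step (per-population
state-count algorithm), so every trajectory is reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from numba import njit

from .markov_core import trpv4_scheme

__all__ = [
    "NeuronConfig",
    "SimResult",
    "SweepResult",
    "run_neuron",
    "acf_from_spikes",
    "detect_action_currents",
    "temperature_sweep",
    "drug_sweep",
    "apply_drug",
    "DRUG_TARGETS",
]

#: Which channel populations each blocker acts on (block fractions applied
#: to effective channel counts).  Gadolinium blocks the Trpv4(/Trpv3-like)
#: population but not Trpm2, which is gadolinium-insensitive; econazole
#: blocks the Trpm2-like channel.
DRUG_TARGETS = {
    "gadolinium": ("trpv4",),
    "econazole": ("trpm2",),
}


@dataclass(frozen=True)
class NeuronConfig:
    """Full parameterisation of the stochastic PVN neurone.

    Units: pF, nS, mV, ms, pS, µM, µm^3, Hz, degC.  Free parameters
    (densities, drive rates, microdomain constants) are calibrated once so
    that drug-free firing is sparse (< 1 Hz) at 37 degC and rises
    several-fold on cooling to 22 degC, then frozen here.
    """

    # passive membrane and deterministic spike mechanism
    cm_pf: float = 20.0
    g_leak_ns: float = 1.5
    e_leak_mv: float = -62.0
    gna_ns: float = 1600.0
    gk_ns: float = 480.0
    ena_mv: float = 55.0
    ek_mv: float = -90.0
    # stochastic delayed-rectifier Kv population (5-state n^4-equivalent chain)
    kv_count: int = 100
    kv_gamma_ps: float = 10.0
    # SK channels: 2-state, Ca- and V-dependent rates of Moczydlowski-Latorre
    # form with µM-range half-saturation and a steep Ca dependence
    sk_count: int = 600
    sk_gamma_ps: float = 20.0
    sk_abar_per_ms: float = 0.3
    sk_bbar_per_ms: float = 0.3
    sk_k1_um: float = 0.5
    sk_k2_um: float = 0.4
    sk_delta1: float = 0.1
    sk_delta2: float = 0.1
    sk_hill: float = 4.0
    # thermosensitive Trpv4-like channel (measured kinetics)
    trpv4_count: int = 8
    trpv4_gamma_ps: float = 59.7
    trpv4_erev_mv: float = 0.0
    trpv4_pca_pna: float = 6.0
    trpv4_coupling: float = 0.15
    # hypothetical Trpm2-like channel: 2-state, Q10 on the opening rate
    trpm2_count: int = 30
    trpm2_gamma_ps: float = 60.0
    trpm2_erev_mv: float = 0.0
    trpm2_open_per_ms: float = 0.05
    trpm2_close_per_ms: float = 0.1
    trpm2_q10: float = 15.6
    trpm2_ref_temp_c: float = 37.0
    trpm2_pca_pna: float = 0.7
    trpm2_coupling: float = 1.0
    # Ca2+ microdomain (nanodomain) and bulk compartments
    md_volume_um3: float = 0.5
    md_kappa: float = 20.0
    md_exchange_per_ms: float = 2.0
    bulk_volume_um3: float = 1000.0
    bulk_kappa: float = 50.0
    bulk_pump_per_ms: float = 0.05
    ca_rest_um: float = 0.1
    ca_out_mm: float = 2.4
    na_out_mm: float = 140.0
    na_in_mm: float = 10.0
    # synaptic drive: excitatory Poisson train + threshold-linear
    # inhibitory interneurone driven by its own excitatory train
    exc_rate_hz: float = 210.0
    exc_weight_ns: float = 1.0
    exc_tau_ms: float = 3.0
    e_exc_mv: float = 0.0
    int_exc_rate_hz: float = 400.0
    int_threshold_hz: float = 100.0
    int_gain: float = 0.5
    inh_weight_ns: float = 0.6
    inh_tau_ms: float = 8.0
    e_inh_mv: float = -75.0
    rate_jitter_sigma: float = 0.2
    # experiment settings
    temperature_c: float = 37.0
    drug_block: dict = field(default_factory=dict)
    dt_ms: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.cm_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.dt_ms <= 0 or self.dt_ms > 0.025:
            raise ValueError("time step must be positive and at most 0.025 ms")
        for name in ("kv_count", "sk_count", "trpv4_count", "trpm2_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for ch, frac in self.drug_block.items():
            if ch not in ("trpv4", "trpm2", "sk"):
                raise ValueError(f"unknown drug target {ch!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("block fractions must lie in [0, 1]")
        if not self.exc_rate_hz >= 0 or not self.int_exc_rate_hz >= 0:
            raise ValueError("drive rates must be non-negative")

    def effective_count(self, channel: str) -> int:
        base = getattr(self, f"{channel}_count")
        return int(round(base * (1.0 - self.drug_block.get(channel, 0.0))))

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "seed"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SimResult:
    """One simulated run: decimated trajectories plus spike times."""

    time_ms: np.ndarray
    v_mv: np.ndarray
    ca_md_um: np.ndarray
    ca_bulk_um: np.ndarray
    open_counts: dict
    spike_times_ms: np.ndarray
    temperature_c: float
    seed: int
    acf_hz: float


@dataclass(frozen=True)
class SweepResult:
    """Tidy ACf results of a temperature (x drug) sweep."""

    records: tuple  # of dicts: temperature_c, drug, run, seed, acf_hz
    config_hash: str

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(list(self.records))

    def acf(self, temperature: float, drug: str = "none") -> np.ndarray:
        return np.array([r["acf_hz"] for r in self.records
                         if r["temperature_c"] == temperature and r["drug"] == drug])


@njit(cache=False, inline="always")
def _ghk_ca_fraction(v, pca_pna, cao_mm, cai_mm, nao_mm, nai_mm):
    """Fraction of a TRP channel's current carried by Ca2+ (GHK fluxes)."""
    u = v / 26.7  # F V / R T, ~310 K
    if abs(u) < 1e-4:
        u = 1e-4
    e1 = math.exp(-u)
    e2 = math.exp(-2.0 * u)
    phi_ca = 4.0 * u * (cai_mm - cao_mm * e2) / (1.0 - e2)
    phi_na = u * (nai_mm - nao_mm * e1) / (1.0 - e1)
    num = abs(pca_pna * phi_ca)
    den = num + abs(phi_na)
    if den <= 0.0:
        return 0.0
    return num / den


@njit(cache=False, inline="always")
def _chain_step(counts, up, down, dt):
    """One binomial transition step on a nearest-neighbour chain population."""
    L = counts.size
    moved_up = np.zeros(L, dtype=np.int64)
    moved_down = np.zeros(L, dtype=np.int64)
    for i in range(L):
        n = counts[i]
        if n <= 0:
            continue
        pu = up[i] * dt
        pd = down[i] * dt
        ptot = pu + pd
        if ptot <= 0.0:
            continue
        if ptot > 0.5:  # rare; keep probabilities valid
            pu *= 0.5 / ptot
            pd *= 0.5 / ptot
            ptot = 0.5
        n_out = np.random.binomial(n, ptot)
        if n_out == 0:
            continue
        n_up = np.random.binomial(n_out, pu / ptot)
        moved_up[i] = n_up
        moved_down[i] = n_out - n_up
    for i in range(L):
        counts[i] -= moved_up[i] + moved_down[i]
        if i < L - 1:
            counts[i + 1] += moved_up[i]
        if i > 0:
            counts[i - 1] += moved_down[i]


@njit(cache=False)
def _neuron_kernel(
    n_steps, dt, seed, store_every,
    cm, gl, el, gna, ena, gk, ek,
    kv_n0, kv_gamma,
    sk_n0, sk_gamma, sk_abar, sk_bbar, sk_k1, sk_k2, sk_d1, sk_d2, sk_hill,
    v4_up, v4_down, v4_n0, v4_gamma, v4_erev, v4_pr, v4_coupling,
    m2_a, m2_b, m2_n0, m2_gamma, m2_erev, m2_pr, m2_coupling,
    md_vol, md_kappa, md_exch, bulk_vol, bulk_kappa, bulk_pump, ca_rest,
    cao, nao, nai,
    exc_rate_per_ms, exc_w, exc_decay, e_exc,
    inh_rate_per_ms, inh_w, inh_decay, e_inh,
    max_spikes,
):
    np.random.seed(seed)
    V = el
    m = 0.05
    h = 0.6
    n_gate = 0.32
    g_e = 0.0
    g_i = 0.0
    ca_md = ca_rest
    ca_bulk = ca_rest
    # channel populations start at their resting distributions (drawn below
    # by relaxation during the first simulated moments)
    kv = np.zeros(5, dtype=np.int64)
    kv[0] = kv_n0
    sk = np.zeros(2, dtype=np.int64)
    sk[0] = sk_n0
    v4 = np.zeros(6, dtype=np.int64)
    v4[0] = v4_n0
    m2 = np.zeros(2, dtype=np.int64)
    m2[0] = m2_n0
    kv_up = np.zeros(5)
    kv_down = np.zeros(5)
    sk_up = np.zeros(2)
    sk_down = np.zeros(2)
    m2_up = np.zeros(2)
    m2_down = np.zeros(2)
    m2_up[0] = m2_a
    m2_down[1] = m2_b
    n_store = n_steps // store_every + 1
    out_v = np.empty(n_store)
    out_camd = np.empty(n_store)
    out_cabulk = np.empty(n_store)
    out_v4 = np.empty(n_store, dtype=np.int64)
    out_m2 = np.empty(n_store, dtype=np.int64)
    out_sk = np.empty(n_store, dtype=np.int64)
    out_kv = np.empty(n_store, dtype=np.int64)
    spikes = np.empty(max_spikes)
    n_spk = 0
    last_spike = -1e9
    # pA per (µM·ms) conversion: 1 pA of Ca2+ into vol µm^3 with buffer kappa
    ca_conv = 5.182 / (md_vol * md_kappa)
    vol_ratio = (md_vol * md_kappa) / (bulk_vol * bulk_kappa)
    k_store = 0
    status = 0
    for step in range(n_steps):
        t = step * dt
        # --- HH gates (deterministic) ---
        if abs(V + 40.0) < 1e-6:
            am = 1.0
        else:
            am = 0.1 * (V + 40.0) / (1.0 - math.exp(-(V + 40.0) / 10.0))
        bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
        ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
        if abs(V + 55.0) < 1e-6:
            an = 0.1
        else:
            an = 0.01 * (V + 55.0) / (1.0 - math.exp(-(V + 55.0) / 10.0))
        bn = 0.125 * math.exp(-(V + 65.0) / 80.0)
        m += dt * (am * (1.0 - m) - bm * m)
        h += dt * (ah * (1.0 - h) - bh * h)
        n_gate += dt * (an * (1.0 - n_gate) - bn * n_gate)
        # --- stochastic populations ---
        for i in range(5):
            kv_up[i] = (4.0 - i) * an
            kv_down[i] = i * bn
        _chain_step(kv, kv_up, kv_down, dt)
        # SK rates: ML-form, Ca (Hill) and voltage dependent
        K1 = sk_k1 * math.exp(-2.0 * sk_d1 * V / 26.7)
        K2 = sk_k2 * math.exp(-2.0 * sk_d2 * V / 26.7)
        ca = ca_md if ca_md > 1e-6 else 1e-6
        sk_up[0] = sk_abar / (1.0 + (K1 / ca) ** sk_hill)
        sk_down[1] = sk_bbar / (1.0 + (ca / K2) ** sk_hill)
        _chain_step(sk, sk_up, sk_down, dt)
        _chain_step(v4, v4_up, v4_down, dt)
        _chain_step(m2, m2_up, m2_down, dt)
        # --- synaptic drive ---
        g_e += exc_w * np.random.poisson(exc_rate_per_ms * dt)
        g_i += inh_w * np.random.poisson(inh_rate_per_ms * dt)
        g_e *= exc_decay
        g_i *= inh_decay
        # --- currents (pA) ---
        i_leak = gl * (V - el)
        i_na = gna * m * m * m * h * (V - ena)
        i_k = gk * n_gate ** 4 * (V - ek)
        i_kv = kv_gamma * kv[4] * (V - ek)
        i_sk = sk_gamma * sk[1] * (V - ek)
        n_v4_open = v4[3] + v4[4] + v4[5]
        i_v4 = v4_gamma * n_v4_open * (V - v4_erev)
        i_m2 = m2_gamma * m2[1] * (V - m2_erev)
        i_syn = g_e * (V - e_exc) + g_i * (V - e_inh)
        # --- Ca2+ microdomain ---
        f_v4 = _ghk_ca_fraction(V, v4_pr, cao, ca_bulk * 1e-3, nao, nai)
        f_m2 = _ghk_ca_fraction(V, m2_pr, cao, ca_bulk * 1e-3, nao, nai)
        influx = 0.0
        if i_v4 < 0.0:
            influx += v4_coupling * f_v4 * (-i_v4)
        if i_m2 < 0.0:
            influx += m2_coupling * f_m2 * (-i_m2)
        exch = md_exch * (ca_md - ca_bulk)
        ca_md += dt * (influx * ca_conv - exch)
        ca_bulk += dt * (exch * vol_ratio - bulk_pump * (ca_bulk - ca_rest))
        if ca_md < 0.0:
            ca_md = 0.0
        if ca_bulk < 0.0:
            ca_bulk = 0.0
        # --- membrane equation ---
        v_prev = V
        V += -dt / cm * (i_leak + i_na + i_k + i_kv + i_sk + i_v4 + i_m2 + i_syn)
        if abs(V) > 200.0:
            status = 1
            break
        if v_prev < 0.0 <= V and (t - last_spike) > 3.0:
            if n_spk < max_spikes:
                spikes[n_spk] = t
                n_spk += 1
            last_spike = t
        if step % store_every == 0:
            out_v[k_store] = V
            out_camd[k_store] = ca_md
            out_cabulk[k_store] = ca_bulk
            out_v4[k_store] = n_v4_open
            out_m2[k_store] = m2[1]
            out_sk[k_store] = sk[1]
            out_kv[k_store] = kv[4]
            k_store += 1
    return (status, out_v[:k_store], out_camd[:k_store], out_cabulk[:k_store],
            out_v4[:k_store], out_m2[:k_store], out_sk[:k_store], out_kv[:k_store],
            spikes[:n_spk])


def run_neuron(config: NeuronConfig, duration: float,
               store_every_ms: float = 1.0) -> SimResult:
    """Integrate the stochastic neurone for ``duration`` seconds.

    Fixed-step (<= 0.025 ms) integration; channel populations update by
    binomial draws from their transition probabilities each step.  Raises
    ``RuntimeError`` if the membrane potential diverges.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = config.dt_ms
    n_steps = int(round(duration * 1000.0 / dt))
    store_every = max(1, int(round(store_every_ms / dt)))
    rng = np.random.default_rng(config.seed)
    # per-run lognormal jitter of the mean drive rates
    jitter = config.rate_jitter_sigma
    exc_rate = config.exc_rate_hz * float(np.exp(rng.normal(0.0, jitter)))
    int_rate = config.int_exc_rate_hz * float(np.exp(rng.normal(0.0, jitter)))
    inh_rate = config.int_gain * max(0.0, int_rate - config.int_threshold_hz)
    # thermosensitive kinetics at the run temperature
    T = config.temperature_c
    v4 = trpv4_scheme(T)
    Qv4 = v4.rates
    v4_up = np.ascontiguousarray(np.r_[np.diag(Qv4, 1), 0.0])
    v4_down = np.ascontiguousarray(np.r_[0.0, np.diag(Qv4, -1)])
    m2_a = config.trpm2_open_per_ms * config.trpm2_q10 ** (
        (T - config.trpm2_ref_temp_c) / 10.0)
    kernel_seed = int(rng.integers(0, 2**32 - 1))
    res = _neuron_kernel(
        n_steps, dt, kernel_seed, store_every,
        config.cm_pf, config.g_leak_ns, config.e_leak_mv,
        config.gna_ns, config.ena_mv, config.gk_ns, config.ek_mv,
        config.effective_count("kv") if "kv" in config.drug_block else config.kv_count,
        config.kv_gamma_ps * 1e-3,
        config.effective_count("sk"), config.sk_gamma_ps * 1e-3,
        config.sk_abar_per_ms, config.sk_bbar_per_ms,
        config.sk_k1_um, config.sk_k2_um, config.sk_delta1, config.sk_delta2,
        config.sk_hill,
        v4_up, v4_down, config.effective_count("trpv4"),
        config.trpv4_gamma_ps * 1e-3, config.trpv4_erev_mv,
        config.trpv4_pca_pna, config.trpv4_coupling,
        m2_a, config.trpm2_close_per_ms, config.effective_count("trpm2"),
        config.trpm2_gamma_ps * 1e-3, config.trpm2_erev_mv,
        config.trpm2_pca_pna, config.trpm2_coupling,
        config.md_volume_um3, config.md_kappa, config.md_exchange_per_ms,
        config.bulk_volume_um3, config.bulk_kappa, config.bulk_pump_per_ms,
        config.ca_rest_um,
        config.ca_out_mm, config.na_out_mm, config.na_in_mm,
        exc_rate / 1000.0, config.exc_weight_ns, math.exp(-dt / config.exc_tau_ms),
        config.e_exc_mv,
        inh_rate / 1000.0, config.inh_weight_ns, math.exp(-dt / config.inh_tau_ms),
        config.e_inh_mv,
        int(duration * 200) + 100,
    )
    (status, out_v, camd, cabulk, o_v4, o_m2, o_sk, o_kv, spikes) = res
    if status != 0:
        raise RuntimeError("unstable integration: |V| exceeded 200 mV")
    t_ms = np.arange(out_v.size) * store_every * dt
    acf = spikes.size / duration
    return SimResult(
        time_ms=t_ms, v_mv=out_v, ca_md_um=camd, ca_bulk_um=cabulk,
        open_counts={"trpv4": o_v4, "trpm2": o_m2, "sk": o_sk, "kv": o_kv},
        spike_times_ms=spikes, temperature_c=T, seed=config.seed, acf_hz=acf,
    )


def acf_from_spikes(spike_times_ms: np.ndarray, duration_s: float) -> float:
    """Action-current frequency in Hz."""
    return float(len(spike_times_ms) / duration_s)


def detect_action_currents(trace, k: float = 5.0, refractory_ms: float = 5.0,
                           baseline_window_ms: float = 40.0,
                           sampling_rate: float | None = None) -> np.ndarray:
    """Adaptive-threshold action-current detector.

    Threshold is a running-median baseline plus ``k`` robust noise SDs
    (median absolute deviation); suprathreshold excursions are grouped with
    a refractory lockout and reported at their absolute peak.  Returns
    event times in ms.  The detector is invariant to constant offsets by
    construction.
    """
    if hasattr(trace, "samples"):
        x = np.asarray(trace.samples, dtype=float)
        fs = float(trace.sampling_rate)
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        x = np.asarray(trace, dtype=float)
        fs = float(sampling_rate)
    from scipy.ndimage import median_filter

    win = max(3, int(round(baseline_window_ms * fs / 1000.0)) | 1)
    baseline = median_filter(x, size=win, mode="nearest")
    resid = x - baseline
    sigma = 1.4826 * float(np.median(np.abs(resid)))
    if sigma <= 0:
        sigma = float(np.std(resid)) or 1e-12
    above = np.abs(resid) > k * sigma
    if not np.any(above):
        return np.empty(0)
    idx = np.flatnonzero(above)
    refr = int(round(refractory_ms * fs / 1000.0))
    events = []
    group_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev > refr:
            seg = np.arange(group_start, prev + 1)
            events.append(seg[np.argmax(np.abs(resid[seg]))])
            group_start = i
        prev = i
    seg = np.arange(group_start, prev + 1)
    events.append(seg[np.argmax(np.abs(resid[seg]))])
    return np.array(events) * 1000.0 / fs


def temperature_sweep(config: NeuronConfig, temps=(37.0, 32.0, 27.0, 22.0),
                      n_runs: int = 5, duration: float = 60.0,
                      drug: str = "none") -> SweepResult:
    """ACf at each temperature, ``n_runs`` paired seeds per temperature.

    Run ``r`` uses seed ``config.seed + r`` at every temperature, so
    temperature contrasts are paired.  Thermosensitive channels follow
    their measured/Q10-scaled kinetics; every other element of the model is
    temperature-insensitive.
    """
    temps = [float(t) for t in temps]
    if not temps:
        raise ValueError("temperature list is empty")
    records = []
    for T in temps:
        for r in range(n_runs):
            cfg = replace(config, temperature_c=T, seed=config.seed + r)
            sim = run_neuron(cfg, duration)
            records.append({
                "temperature_c": T, "drug": drug, "run": r,
                "seed": cfg.seed, "acf_hz": sim.acf_hz,
            })
    return SweepResult(records=tuple(records), config_hash=config.config_hash())


def apply_drug(config: NeuronConfig, drug: str,
               block_fraction: float = 1.0) -> NeuronConfig:
    """Return a config with the drug's target populations blocked.

    Gadolinium blocks the Trpv4-like population (Trpm2 is
    gadolinium-insensitive); econazole blocks the Trpm2-like population.
    """
    if drug not in DRUG_TARGETS:
        raise ValueError(f"unknown drug {drug!r}; known: {sorted(DRUG_TARGETS)}")
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block fraction must lie in [0, 1]")
    block = dict(config.drug_block)
    for target in DRUG_TARGETS[drug]:
        block[target] = block_fraction
    return replace(config, drug_block=block)


def drug_sweep(config: NeuronConfig, drug: str, temps=(37.0, 32.0, 27.0, 22.0),
               n_runs: int = 5, duration: float = 60.0,
               block_fraction: float = 1.0) -> SweepResult:
    """Temperature sweep in the presence of a blocker."""
    return temperature_sweep(apply_drug(config, drug, block_fraction),
                             temps=temps, n_runs=n_runs, duration=duration,
                             drug=drug)
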