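import dataclasses

import numpy as np
import pytest

from pvntherm import neuron_sim as ns
from pvntherm import synthetic_data as sd


def quiet_config(**kw):
    base = dict(kv_count=0, sk_count=0, trpv4_count=0, trpm2_count=0,
                gna_ns=0.0, gk_ns=0.0, exc_rate_hz=0.0, int_exc_rate_hz=0.0,
                seed=1)
    base.update(kw)
    return ns.NeuronConfig(**base)


def test_passive_membrane_rests_at_leak_reversal():
    sim = ns.run_neuron(quiet_config(), 1.0)
    assert sim.v_mv[-1] == pytest.approx(-62.0, abs=0.2)
    assert sim.spike_times_ms.size == 0


def test_simulation_is_seed_deterministic():
    cfg = ns.NeuronConfig(seed=3, temperature_c=27.0)
    a = ns.run_neuron(cfg, 5.0)
    b = ns.run_neuron(cfg, 5.0)
    assert np.array_equal(a.v_mv, b.v_mv)
    assert np.array_equal(a.spike_times_ms, b.spike_times_ms)
    c = ns.run_neuron(dataclasses.replace(cfg, seed=4), 5.0)
    assert not np.array_equal(a.v_mv, c.v_mv)


def test_open_counts_bounded_by_population_sizes():
    cfg = ns.NeuronConfig(seed=5)
    sim = ns.run_neuron(cfg, 5.0)
    assert sim.open_counts["trpv4"].min() >= 0
    assert sim.open_counts["trpv4"].max() <= cfg.trpv4_count
    assert sim.open_counts["sk"].max() <= cfg.sk_count
    assert sim.open_counts["trpm2"].max() <= cfg.trpm2_count
    assert sim.open_counts["kv"].max() <= cfg.kv_count


def test_microdomain_exceeds_bulk_and_bulk_stays_near_rest():
    cfg = ns.NeuronConfig(seed=6, temperature_c=37.0)
    sim = ns.run_neuron(cfg, 10.0)
    assert np.all(sim.ca_md_um >= 0)
    assert np.all(sim.ca_bulk_um >= 0)
    # with sustained TRP influx the microdomain runs above bulk ...
    assert np.mean(sim.ca_md_um > sim.ca_bulk_um) > 0.99
    # ... while global Ca2+ stays biologically insignificant (< 2x resting)
    assert sim.ca_bulk_um.max() < 2 * cfg.ca_rest_um
    assert sim.ca_md_um.mean() > 3 * cfg.ca_rest_um


def test_unstable_integration_aborts():
    cfg = quiet_config(e_leak_mv=400.0, g_leak_ns=50.0)
    with pytest.raises(RuntimeError):
        ns.run_neuron(cfg, 0.5)


def test_detector_performance_at_snr8():
    tr, truth = sd.make_spike_trace(rate=2.0, duration=60.0, noise_sd=1.0, seed=7,
                                    waveform=sd.biphasic_waveform(amplitude_pA=-8.0))
    det = ns.detect_action_currents(tr, k=5.0)
    matched = sum(np.min(np.abs(det - t)) < 3.0 for t in truth)
    assert matched / truth.size >= 0.99
    false = det.size - matched
    assert false <= 1  # <= 1 false event per minute


def test_detector_null_and_offset_invariance():
    rng = np.random.default_rng(8)
    noise = rng.normal(0, 1.0, 5000 * 60)
    det0 = ns.detect_action_currents(noise, k=5.5, sampling_rate=5000.0)
    assert det0.size <= 1
    tr, truth = sd.make_spike_trace(rate=2.0, duration=20.0, noise_sd=1.0, seed=9)
    shifted = sd.CurrentTrace(samples=tr.samples + 40.0, sampling_rate=tr.sampling_rate)
    a = ns.detect_action_currents(tr, k=5.0)
    b = ns.detect_action_currents(shifted, k=5.0)
    assert np.array_equal(a, b)


def test_apply_drug_semantics():
    cfg = ns.NeuronConfig()
    assert ns.apply_drug(cfg, "gadolinium", 0.0).effective_count("trpv4") == cfg.trpv4_count
    gd = ns.apply_drug(cfg, "gadolinium")
    assert gd.effective_count("trpv4") == 0
    assert gd.effective_count("trpm2") == cfg.trpm2_count  # Gd-insensitive
    eco = ns.apply_drug(cfg, "econazole")
    assert eco.effective_count("trpm2") == 0
    with pytest.raises(ValueError):
        ns.apply_drug(cfg, "tetrodotoxin")
    with pytest.raises(ValueError):
        ns.apply_drug(cfg, "econazole", 1.5)


def test_config_validation():
    with pytest.raises(ValueError):
        ns.NeuronConfig(cm_pf=0.0)
    with pytest.raises(ValueError):
        ns.NeuronConfig(dt_ms=0.1)
    with pytest.raises(ValueError):
        ns.NeuronConfig(trpv4_count=-1)
    with pytest.raises(ValueError):
        ns.NeuronConfig(drug_block={"trpv4": 2.0})


def test_sweep_is_paired_and_tidy():
    cfg = ns.NeuronConfig(seed=11)
    sweep = ns.temperature_sweep(cfg, temps=(37.0, 22.0), n_runs=2, duration=2.0)
    df = sweep.to_dataframe()
    assert set(df.columns) >= {"temperature_c", "drug", "run", "seed", "acf_hz"}
    assert len(df) == 4
    # paired seeds across temperatures
    assert sorted(df[df.temperature_c == 37.0].seed) == sorted(df[df.temperature_c == 22.0].seed)
    assert np.all(df.acf_hz >= 0)
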