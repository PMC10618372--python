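import numpy as np
import pytest

from pvntherm import markov_core as mc
from pvntherm import synthetic_data as sd
from pvntherm import neuron_sim as ns
from pvntherm.idealization import EventTable


def test_gating_is_reproducible_per_seed(two_state):
    a = sd.simulate_gating(two_state, 5.0, seed=42)
    b = sd.simulate_gating(two_state, 5.0, seed=42)
    c = sd.simulate_gating(two_state, 5.0, seed=43)
    assert np.array_equal(a.duration_ms, b.duration_ms)
    assert np.array_equal(a.classes, b.classes)
    assert not np.array_equal(a.duration_ms[:50], c.duration_ms[:50])


def test_gating_mean_dwells_match_analytic():
    s = mc.linear_chain_scheme([1.0], [1.0])  # both mean dwells 1 ms
    ev = sd.simulate_gating(s, 12.0, seed=9)  # ~1.2e4 dwells
    for label in ("closed", "open"):
        d = ev.durations_of(label)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - 1.0) < 3 * se


def test_gating_open_fraction_matches_equilibrium(scheme37):
    eq = mc.equilibrium(scheme37)
    ev = sd.simulate_gating(scheme37, 300.0, seed=2)
    po = ev.duration_ms[ev.classes == 1].sum() / ev.total_ms
    assert po == pytest.approx(eq.po, rel=0.01)


def test_render_ohmic_level_noiseless(scheme22):
    # a record that is open throughout renders at g * driving force
    ev = EventTable.from_durations([1], [2000.0])
    cfg = sd.TraceConfig(duration=1.0, noise_sd=0.0, holding_potential=-100 + scheme22.reversal_potential)
    tr = sd.render_trace(ev, scheme22, cfg)
    assert tr.samples[2500:] == pytest.approx(-5.97, abs=1e-6)


def test_render_zero_amplitude_at_reversal(scheme22):
    ev = sd.simulate_gating(scheme22, 1.0, seed=3)
    cfg = sd.TraceConfig(duration=1.0, noise_sd=0.0,
                         holding_potential=scheme22.reversal_potential)
    tr = sd.render_trace(ev, scheme22, cfg)
    assert np.max(np.abs(tr.samples)) < 1e-9


def test_rendered_histogram_is_bimodal_at_unitary_current(scheme22):
    ev = sd.simulate_gating(scheme22, 60.0, seed=4)
    cfg = sd.TraceConfig(duration=60.0, noise_sd=0.15, seed=5)
    tr = sd.render_trace(ev, scheme22, cfg)
    i_open = tr.metadata["unitary_current_pA"]
    closed = tr.samples[np.abs(tr.samples) < 0.5]
    open_ = tr.samples[np.abs(tr.samples - i_open) < 0.5]
    assert closed.size > 1000 and open_.size > 1000
    sep = np.median(open_) - np.median(closed)
    assert sep == pytest.approx(i_open, abs=3 * 0.15 / np.sqrt(min(closed.size, open_.size)) + 0.01)


def test_trace_config_validation():
    with pytest.raises(ValueError):
        sd.TraceConfig(sampling_rate=1500.0, filter_cutoff=1000.0)  # sampling theorem
    with pytest.raises(ValueError):
        sd.TraceConfig(duration=0.0)
    with pytest.raises(ValueError):
        sd.TraceConfig(noise_sd=-0.1)


def test_temperature_dataset_carries_exact_ground_truth():
    data = sd.make_temperature_dataset([37.0, 32.0, 22.0], per_temp_duration=2.0, seed=6)
    assert data.temperatures == (37.0, 32.0, 22.0)
    for T, cmix in zip(data.temperatures, data.closed_mixtures):
        assert cmix == mc.trpv4_closed_mixture(T)
    # same seed reproduces, different seed gives a different path
    again = sd.make_temperature_dataset([37.0, 32.0, 22.0], per_temp_duration=2.0, seed=6)
    other = sd.make_temperature_dataset([37.0, 32.0, 22.0], per_temp_duration=2.0, seed=7)
    assert np.array_equal(data.traces[0].samples, again.traces[0].samples)
    assert not np.array_equal(data.traces[0].samples, other.traces[0].samples)
    assert other.closed_mixtures == data.closed_mixtures
    with pytest.raises(ValueError):
        sd.make_temperature_dataset([], per_temp_duration=1.0)
    with pytest.raises(ValueError):
        sd.make_temperature_dataset([22.0], per_temp_duration=0.0)


def test_spike_trace_poisson_statistics():
    tr, truth = sd.make_spike_trace(rate=0.0, duration=5.0, seed=1)
    assert truth.size == 0
    tr, truth = sd.make_spike_trace(rate=1.0, duration=100.0, seed=2)
    assert abs(truth.size - 100) < 3 * np.sqrt(100)
    with pytest.raises(ValueError):
        sd.make_spike_trace(rate=-1.0, duration=1.0)


def test_noiseless_spike_train_fully_recovered_by_detector():
    tr, truth = sd.make_spike_trace(rate=2.0, duration=30.0, noise_sd=0.0, seed=3,
                                    waveform=sd.biphasic_waveform(amplitude_pA=-8.0))
    det = ns.detect_action_currents(tr, k=5.0)
    # every isolated true event is detected; events whose waveforms overlap
    # within the refractory window legitimately merge into one detection
    gaps = np.diff(np.concatenate([[-np.inf], truth, [np.inf]]))
    isolated = (gaps[:-1] > 10.0) & (gaps[1:] > 10.0)
    assert all(np.min(np.abs(det - t)) < 3.0 for t in truth[isolated])
    assert isolated.sum() > 0.8 * truth.size
    assert det.size <= truth.size
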