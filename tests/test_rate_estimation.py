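import numpy as np
import pytest

from pvntherm import markov_core as mc
from pvntherm import synthetic_data as sd
from pvntherm import idealization as idz
from pvntherm import rate_estimation as re_


def test_interval_loglik_matches_exponential_closed_form(two_state):
    ev = sd.simulate_gating(two_state, 20.0, seed=3)
    model = re_.IntervalLikelihoodModel(two_state, dead_time_ms=0.0)
    ll = re_.interval_loglik(model, ev)
    kc, ko = two_state.rate("C1", "O1"), two_state.rate("O1", "C1")
    cd = ev.duration_ms[ev.classes == 0]
    od = ev.duration_ms[ev.classes == 1]
    ll_ref = -kc * cd.sum() - ko * od.sum()
    ll_ref += (cd.size - (ev.classes[-1] == 0)) * np.log(kc)
    ll_ref += (od.size - (ev.classes[-1] == 1)) * np.log(ko)
    assert ll == pytest.approx(ll_ref, abs=1e-8)


def test_loglik_additive_over_concatenated_records(two_state):
    a = sd.simulate_gating(two_state, 10.0, seed=4)
    b = sd.simulate_gating(two_state, 10.0, seed=5)
    model = re_.IntervalLikelihoodModel(two_state, dead_time_ms=0.0)
    lla, llb = re_.interval_loglik(model, a), re_.interval_loglik(model, b)
    # stitch b after a (classes may need a dropped first dwell to alternate)
    off = 0 if (b.classes[0] != a.classes[-1]) else 1
    cls = np.concatenate([a.classes, b.classes[off:]])
    dur = np.concatenate([a.duration_ms, b.duration_ms[off:]])
    cat = idz.EventTable.from_durations(cls, dur)
    llcat = re_.interval_loglik(model, cat)
    # additivity up to boundary terms (entry distribution, one dwell)
    assert llcat == pytest.approx(lla + llb, abs=10.0)


def test_generating_rates_beat_perturbed_rates(two_state):
    ev = sd.simulate_gating(two_state, 15.0, seed=6)  # ~1e4 dwells
    model = re_.IntervalLikelihoodModel(two_state, dead_time_ms=0.0)
    ll_true = re_.interval_loglik(model, ev)
    for fac in (2.0, 0.5):
        pert = mc.linear_chain_scheme([two_state.rate("C1", "O1") * fac],
                                      [two_state.rate("O1", "C1") * fac])
        ll_pert = re_.interval_loglik(re_.IntervalLikelihoodModel(pert, 0.0), ev)
        assert ll_true > ll_pert


def test_dead_time_zero_limit_continuous(two_state):
    ev = sd.simulate_gating(two_state, 5.0, seed=7)
    ev = idz.apply_dead_time(ev, 0.05)
    ll0 = re_.interval_loglik(re_.IntervalLikelihoodModel(two_state, 0.0), ev)
    ll_eps = re_.interval_loglik(re_.IntervalLikelihoodModel(two_state, 1e-7), ev)
    assert ll_eps == pytest.approx(ll0, abs=1e-3)


def test_two_state_rate_recovery_within_5pct(two_state):
    ev = sd.simulate_gating(two_state, 15.0, seed=8)  # >= 1e4 dwells
    fit = re_.fit_rates(ev, topology=(1, 1), dead_time=0.0, seed=0)
    assert fit.scheme.rate("C1", "O1") == pytest.approx(2.0, rel=0.05)
    assert fit.scheme.rate("O1", "C1") == pytest.approx(0.5, rel=0.05)


def test_init_at_truth_is_stationary(two_state):
    ev = sd.simulate_gating(two_state, 15.0, seed=9)
    ll_true = re_.interval_loglik(re_.IntervalLikelihoodModel(two_state, 0.0), ev)
    fit = re_.fit_rates(ev, topology=(1, 1), dead_time=0.0, init=two_state, seed=0)
    assert fit.loglik >= ll_true - 1e-6
    assert fit.loglik == pytest.approx(ll_true, abs=2.0)


def test_rmse_decreases_with_record_length(two_state):
    errs = {}
    for n_target, dur in ((1_000, 1.5), (10_000, 15.0)):
        e2 = []
        for s in range(4):
            ev = sd.simulate_gating(two_state, dur, seed=100 + s)
            fit = re_.fit_rates(ev, topology=(1, 1), dead_time=0.0, seed=s)
            e2.append((fit.scheme.rate("C1", "O1") / 2.0 - 1) ** 2
                      + (fit.scheme.rate("O1", "C1") / 0.5 - 1) ** 2)
        errs[n_target] = np.sqrt(np.mean(e2))
    assert errs[10_000] < errs[1_000]


def test_requires_enough_events(two_state):
    ev = sd.simulate_gating(two_state, 0.01, seed=1)
    with pytest.raises(ValueError):
        re_.fit_rates(ev, topology=(3, 3))


def test_three_state_chain_recovery_with_dead_time(scheme22):
    """MIL on dead-time-imposed events from the measured 22 degC scheme."""
    ev = sd.simulate_gating(scheme22, 400.0, seed=11)
    evd = idz.apply_dead_time(ev, 0.3)
    fit = re_.fit_rates(evd, topology=(3, 3), dead_time=0.3, init=scheme22, seed=0)
    taus = mc.dwell_pdf(fit.scheme, "closed").taus
    assert np.allclose(taus, (0.58, 5.26, 71.22), rtol=0.15)
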