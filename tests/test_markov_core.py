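import numpy as np
import pytest
from scipy import stats

from pvntherm import markov_core as mc
from pvntherm import synthetic_data as sd


def test_scheme_invariants_enforced():
    with pytest.raises(mc.SchemeError):  # bad row sums
        mc.KineticScheme(("C", "O"), ("closed", "open"), np.array([[1.0, 1.0], [1.0, -1.0]]))
    with pytest.raises(mc.SchemeError):  # negative off-diagonal
        mc.KineticScheme(("C", "O"), ("closed", "open"), np.array([[1.0, -1.0], [1.0, -1.0]]))
    with pytest.raises(mc.SchemeError):  # no open state
        mc.KineticScheme(("A", "B"), ("closed", "closed"), np.array([[-1.0, 1.0], [1.0, -1.0]]))
    with pytest.raises(mc.SchemeError):  # reducible (one-way sink)
        mc.KineticScheme(("C", "O"), ("closed", "open"), np.array([[-1.0, 1.0], [0.0, 0.0]]))


@pytest.mark.parametrize("q10, dT, factor", [
    (15.6, 0.0, 1.0),            # same temperature: identity
    (15.6, -10.0, 1 / 15.6),     # cooling by 10 degC divides by Q10
    (2.0, -10.0, 0.5),
])
def test_q10_scaling_of_forward_rates(two_state, q10, dT, factor):
    from dataclasses import replace

    s = replace(two_state, q10_forward=q10)
    scaled = mc.scale_rates_q10(s, s.reference_temperature + dT)
    assert scaled.rate("C1", "O1") == pytest.approx(factor * s.rate("C1", "O1"), rel=1e-12)
    assert scaled.rate("O1", "C1") == pytest.approx(s.rate("O1", "C1"), rel=1e-12)
    assert np.allclose(scaled.rates.sum(axis=1), 0.0, atol=1e-12)


def test_q10_scaling_composes(scheme22):
    from dataclasses import replace

    s = replace(scheme22, q10_forward=3.0)
    one_hop = mc.scale_rates_q10(s, 27.0)
    two_hop = mc.scale_rates_q10(mc.scale_rates_q10(s, 32.0), 27.0)
    assert np.allclose(one_hop.rates, two_hop.rates, rtol=1e-12)


def test_equilibrium_two_state_closed_forms():
    sym = mc.linear_chain_scheme([1.0], [1.0])
    assert mc.equilibrium(sym).po == pytest.approx(0.5, abs=1e-12)
    biased = mc.linear_chain_scheme([3.0], [1.0])  # opening 3/ms, closing 1/ms
    eq = mc.equilibrium(biased)
    assert eq.po == pytest.approx(0.75, abs=1e-12)
    assert eq.mean_open == pytest.approx(1.0, rel=1e-12)
    assert eq.mean_closed == pytest.approx(1 / 3, rel=1e-12)


def test_equilibrium_matches_long_simulation(scheme37):
    eq = mc.equilibrium(scheme37)
    ev = sd.simulate_gating(scheme37, 400.0, seed=77)
    po_sim = ev.duration_ms[ev.classes == 1].sum() / ev.total_ms
    assert po_sim == pytest.approx(eq.po, rel=0.01)


def test_dwell_pdf_single_exponential():
    s = mc.linear_chain_scheme([2.0], [1.0])  # closing rate 1/ms
    mix = mc.dwell_pdf(s, "open")
    assert mix.taus == pytest.approx((1.0,))
    assert mix.areas == pytest.approx((1.0,))


def test_default_22C_scheme_reproduces_measured_closed_mixture(scheme22):
    mix = mc.dwell_pdf(scheme22, "closed")
    assert np.allclose(mix.taus, (0.58, 5.26, 71.22), rtol=1e-4)
    assert np.allclose(mix.areas, (0.58, 0.30, 0.12), atol=1e-3)


def test_dwell_pdf_agrees_with_simulated_dwells(scheme22):
    ev = sd.simulate_gating(scheme22, 450.0, seed=5)
    for label in ("closed", "open"):
        mix = mc.dwell_pdf(scheme22, label)
        d = ev.durations_of(label)
        res = stats.kstest(d, mix.cdf)
        assert res.pvalue > 0.01, f"{label} dwell KS rejected: p={res.pvalue}"


def test_scheme_from_mixtures_two_state_closed_form():
    cm = mc.DwellMixture("closed", (2.0,), (1.0,))
    om = mc.DwellMixture("open", (4.0,), (1.0,))
    s = mc.scheme_from_mixtures(cm, om)
    assert s.rate("C1", "O1") == pytest.approx(0.5, rel=1e-9)
    assert s.rate("O1", "C1") == pytest.approx(0.25, rel=1e-9)


@pytest.mark.parametrize("k", range(12))
def test_scheme_from_mixtures_round_trips_random_mixtures(k):
    rng = np.random.default_rng(900 + k)
    n_c, n_o = rng.integers(1, 4, size=2)

    def draw(n, label):
        taus = np.sort(np.exp(rng.uniform(np.log(0.3), np.log(80.0), size=n)))
        while np.any(np.diff(taus) < 0.5 * taus[:-1]):  # keep components separated
            taus = np.sort(np.exp(rng.uniform(np.log(0.3), np.log(80.0), size=n)))
        areas = rng.dirichlet(np.ones(n) * 3)
        areas = np.maximum(areas, 0.05)
        areas /= areas.sum()
        return mc.DwellMixture(label, tuple(taus), tuple(areas))

    cm, om = draw(int(n_c), "closed"), draw(int(n_o), "open")
    s = mc.scheme_from_mixtures(cm, om, seed=k)
    back_c = mc.dwell_pdf(s, "closed")
    back_o = mc.dwell_pdf(s, "open")
    assert np.allclose(back_c.taus, cm.taus, rtol=1e-4)
    assert np.allclose(back_c.areas, cm.areas, atol=1e-3)
    assert np.allclose(back_o.taus, om.taus, rtol=1e-4)
    assert np.allclose(back_o.areas, om.areas, atol=1e-3)


def test_po_increases_with_temperature():
    pos = [mc.equilibrium(mc.trpv4_scheme(T)).po for T in (22.0, 32.0, 37.0)]
    assert pos[0] < pos[1] < pos[2]


def test_interpolated_scheme_between_measured_temperatures():
    po27 = mc.equilibrium(mc.trpv4_scheme(27.0)).po
    po22 = mc.equilibrium(mc.trpv4_scheme(22.0)).po
    po32 = mc.equilibrium(mc.trpv4_scheme(32.0)).po
    assert po22 < po27 < po32
    q10 = mc.trpv4_q10_profile()
    assert set(q10) == set(mc.trpv4_scheme(37.0).forward_transitions) | {
        t[::-1] for t in mc.trpv4_scheme(37.0).forward_transitions}
    assert all(v > 0 for v in q10.values())


def test_dwell_mixture_validation():
    with pytest.raises(ValueError):
        mc.DwellMixture("closed", (1.0, 0.5), (0.5, 0.5))  # not increasing
    with pytest.raises(ValueError):
        mc.DwellMixture("closed", (1.0, 2.0), (0.5, 0.4))  # areas don't sum to 1
    with pytest.raises(ValueError):
        mc.DwellMixture("shut", (1.0,), (1.0,))
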