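"""Boundary-condition tuning: distribution rules and the iterative loops."""

import math

import pytest

from coroflow.lumped_solver import assemble, simulate
from coroflow.network import build_network
from coroflow.tuning import (ComplianceDistribution, ResistanceDistribution,
                             TuningTargets, distribute_compliance,
                             distribute_coronary, split_rcr,
                             total_systemic_resistance, tune_rcr)


def test_total_systemic_resistance_value():
    # 99 mmHg over 5 L/min (83.33 cm³/s)
    r = total_systemic_resistance(99.0, 83.33)
    assert r == pytest.approx(99.0 * 1333.22 / 83.33, rel=1e-9)
    assert total_systemic_resistance(99.0, 2 * 83.33) == pytest.approx(r / 2)
    assert total_systemic_resistance(0.0, 83.33) == 0.0
    with pytest.raises(ValueError):
        total_systemic_resistance(99.0, 0.0)


def test_split_rcr():
    rp, rd = split_rcr(1000.0, 0.09)
    assert (rp, rd) == (90.0, 910.0)
    rp, rd = split_rcr(1000.0, 0.5)
    assert rp == rd == 500.0
    rp, rd = split_rcr(12345.678, 0.09)
    assert rp + rd == pytest.approx(12345.678, abs=0.0)
    with pytest.raises(ValueError):
        split_rcr(1000.0, 1.5)


@pytest.mark.parametrize("dist,expected", [
    (ResistanceDistribution.rest(), (32000.0, 52000.0, 16000.0)),
    (ResistanceDistribution.stress(), (41000.0, 28000.0, 31000.0)),
])
def test_distribute_coronary_ratios(dist, expected):
    parts = distribute_coronary(100000.0, dist)
    assert parts == pytest.approx(expected)
    assert sum(parts) == 100000.0  # exact
    assert distribute_coronary(0.0, dist) == pytest.approx((0.0, 0.0, 0.0))


def test_distribute_coronary_sums_exactly():
    dist = ResistanceDistribution.stress()
    for total in (123456.789, 7.0e4, 1.0):
        assert sum(distribute_coronary(total, dist)) == total


def test_resistance_distribution_validation():
    with pytest.raises(ValueError):
        ResistanceDistribution(ra_frac=0.5, ramicro_frac=0.5, rv_frac=0.5,
                               mode="rest")


def test_distribute_compliance():
    pairs = distribute_compliance(2.0e-5, [1.0, 1.0])
    for ca, cim in pairs:
        assert cim == pytest.approx(0.89e-5)
        assert ca == pytest.approx(0.11e-5)
    single = distribute_compliance(3.6e-5, [2.0])
    assert single[0][0] + single[0][1] == pytest.approx(3.6e-5)
    zeros = distribute_compliance(0.0, [1.0, 2.0])
    assert all(ca == cim == 0.0 for ca, cim in zeros)
    with pytest.raises(ValueError):
        ComplianceDistribution(cim_frac=0.9, ca_frac=0.2)


def test_targets_reject_inverted_pressures():
    with pytest.raises(ValueError):
        TuningTargets(p_sys=80.0, p_dia=120.0, p_mean=100.0, cardiac_output=90.0)


def test_tune_rcr_matches_pressure_targets(ref_patient):
    """Self-consistency: the tuned Windkessel reproduces the systolic and
    diastolic targets within the stated tolerance in a fresh simulation."""
    net = build_network(ref_patient, "pre", "rest")
    targets = TuningTargets.from_state(ref_patient.pre)
    rcr, report = tune_rcr(targets, net)
    assert report.converged
    net.systemic = rcr
    res = simulate(assemble(net), n_cycles=6)
    s = res.cycle_slice(6)
    assert res.p_aorta[s].max() == pytest.approx(targets.p_sys, abs=2.5)
    assert res.p_aorta[s].min() == pytest.approx(targets.p_dia, abs=2.5)


def test_tune_rcr_infinite_tolerance_returns_initial(ref_patient):
    net = build_network(ref_patient, "pre", "rest")
    targets = TuningTargets.from_state(ref_patient.pre)
    rcr, report = tune_rcr(targets, net, tol=math.inf)
    assert report.converged and report.n_iter == 1
    assert rcr is net.systemic


def test_rest_coronary_fraction_within_tolerance(sim_rest):
    frac = sim_rest.coronary_outflow_mean() / sim_rest.cycle_mean(sim_rest.q_inflow)
    assert frac == pytest.approx(0.04, abs=0.005)


def test_hyperemic_fraction_in_band(sim_hyper):
    frac = sim_hyper.coronary_outflow_mean() / sim_hyper.cycle_mean(sim_hyper.q_inflow)
    assert 0.10 <= frac <= 0.12


def test_hyperemia_lowers_total_coronary_resistance(tuned_rest, tuned_hyper):
    for name in ("LAD", "LCx", "RCA"):
        r_rest = tuned_rest.branch(name).outlet.r_total
        r_hyper = tuned_hyper.branch(name).outlet.r_total
        assert r_hyper < r_rest


def test_lesion_free_symmetric_tuning(sims_lesion_free):
    """Without a stenosis the tuned fractions and the 3:1 left:right ostial
    velocity ratio are met simultaneously."""
    from coroflow.indices import velocity_ratio
    rest = sims_lesion_free["rest"]
    frac = rest.coronary_outflow_mean() / rest.cycle_mean(rest.q_inflow)
    assert frac == pytest.approx(0.04, abs=0.005)
    assert velocity_ratio(rest) == pytest.approx(3.0, rel=0.15)
    hyper = sims_lesion_free["hyper"]
    frach = hyper.coronary_outflow_mean() / hyper.cycle_mean(hyper.q_inflow)
    assert 0.10 <= frach <= 0.12
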