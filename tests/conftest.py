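"""Shared fixtures: a deterministic cohort-mean patient, tuned networks and
seven-cycle simulations reused across the index, WSS and acceptance tests."""

from types import SimpleNamespace

import pytest

from coroflow.lumped_solver import assemble, simulate
from coroflow.synthetic_cohort import reference_patient
from coroflow.tuning import tune_patient
from coroflow.waveforms import CardiacState


@pytest.fixture(scope="session")
def ref_patient():
    """Cohort-mean patient: LAD lesion, degree 0.57, length 15 mm."""
    return reference_patient()


@pytest.fixture(scope="session")
def tuned_rest(ref_patient):
    net, reports = tune_patient(ref_patient, "pre", "rest")
    assert all(r.converged for r in reports.values())
    return net


@pytest.fixture(scope="session")
def tuned_hyper(ref_patient):
    net, reports = tune_patient(ref_patient, "pre", "hyper")
    assert all(r.converged for r in reports.values())
    return net


@pytest.fixture(scope="session")
def sim_rest(tuned_rest):
    return simulate(assemble(tuned_rest), n_cycles=7)


@pytest.fixture(scope="session")
def sim_hyper(tuned_hyper):
    return simulate(assemble(tuned_hyper), n_cycles=7)


@pytest.fixture(scope="session")
def lesion_free_patient(ref_patient):
    """Same physiology, stenosis degree zero (bypasses the cohort-range
    validator on purpose: a healthy vessel is out of cohort range but a
    legitimate model input)."""
    return SimpleNamespace(
        id="FREE", pre=ref_patient.pre, post=ref_patient.post,
        lesion_vessel="LAD", stenosis_degree=0.0, stenosis_length=15.0,
        branch_radii={}, rap=5.0)


@pytest.fixture(scope="session")
def sims_lesion_free(lesion_free_patient):
    nets = {m: tune_patient(lesion_free_patient, "pre", m)[0]
            for m in ("rest", "hyper")}
    return {m: simulate(assemble(n), n_cycles=7) for m, n in nets.items()}


def make_state(**kw) -> CardiacState:
    defaults = dict(heart_rate=70.0, stroke_volume=79.1, ejection_time=336.0,
                    aortic_valve_area=0.6, p_sys=141.0, p_dia=78.5,
                    p_mean=99.0, lv_peak=202.0, lv_edp=16.0, tr_velocity=2.5)
    defaults.update(kw)
    return CardiacState(**defaults)
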