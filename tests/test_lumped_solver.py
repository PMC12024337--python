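"""ODE solver: stenosis law, assembly, integration, periodicity, and an
independent dense linear-system oracle."""

import math
import numpy as np
import pytest

from coroflow.lumped_solver import (SimulationResult, assemble,
                                    cycles_to_converge, periodicity_residual,
                                    simulate, stenosis_dp)
from coroflow.network import (Branch, CoronaryOutletParams, FluidProperties,
                              NetworkSpec, RCRParams, StenosisSpec,
                              VesselSegment)
from coroflow.units import MMHG_TO_DYN_CM2
from coroflow.waveforms import Waveform, make_inflow

from conftest import make_state

FLUID = FluidProperties()


# frozen oracle: independent scalar evaluation of the stenosis law at
# degree=0.5, ref_radius=0.2, length=1.5 cm, kt=1.52, rho=1.06, mu=0.04, q=5
#   R_visc = 8*0.04*1.5/(pi*0.1^4) = 1527.8874536822OK dyn·s/cm^5
#   K = 1.52*1.06/(2*(pi*0.04)^2)*(4-1)^2 = 459.06817...
#   dP = (R_visc*5 + K*25)/1333.22 mmHg
_RV = 8 * 0.04 * 1.5 / (math.pi * 0.1**4)
_K = 1.52 * 1.06 / (2 * (math.pi * 0.04) ** 2) * 9.0
STEN_DP_ORACLE = (_RV * 5 + _K * 25) / 1333.22


def test_stenosis_dp_examples():
    s = StenosisSpec(degree=0.5, length=15.0, ref_radius=0.2, kt=1.52)
    assert stenosis_dp(0.0, s, FLUID) == 0.0
    assert stenosis_dp(5.0, s, FLUID) == pytest.approx(STEN_DP_ORACLE, rel=1e-9)
    # odd in q
    assert stenosis_dp(-5.0, s, FLUID) == pytest.approx(-STEN_DP_ORACLE, rel=1e-9)
    # degree 0: quadratic term vanishes, pure Poiseuille remains
    s0 = StenosisSpec(degree=0.0, length=15.0, ref_radius=0.2)
    rv0 = 8 * 0.04 * 1.5 / (math.pi * 0.2**4)
    assert stenosis_dp(5.0, s0, FLUID) == pytest.approx(5 * rv0 / 1333.22, rel=1e-9)


def _toy_outlet(pim, ra=2.0e4, ram=3.0e4, rv=1.0e4, ca=2.0e-6, cim=1.5e-5):
    return CoronaryOutletParams(ra=ra, ra_micro=ram, rv=rv, ca=ca, cim=cim, pim=pim)


def _flat_pim(period, value=0.0):
    t = np.linspace(0.0, period, int(round(period / 1e-3)) + 1)
    return Waveform(times=t, values=np.full_like(t, value), kind="pressure")


def _toy_network(n_branches=1, inflow=None, stenosis=None, r_outlet=None):
    state = make_state()
    inflow = inflow or make_inflow(state)
    period = inflow.period
    branches = []
    for i in range(n_branches):
        seg = VesselSegment(name=f"b{i}", radius=0.18, length=10.0, side="left")
        outlet = _toy_outlet(_flat_pim(period)) if r_outlet is None else \
            _toy_outlet(_flat_pim(period), ra=r_outlet, ram=r_outlet, rv=r_outlet)
        branches.append(Branch(name=f"b{i}", chain=[seg], outlet=outlet,
                               stenosis=stenosis if i == 0 else None))
    systemic = RCRParams(rp=134.0, c=1.0e-3, rd=1356.0)
    return NetworkSpec(inflow=inflow, systemic=systemic, branches=branches)


def test_assemble_state_dimension():
    assert assemble(_toy_network(1)).dim == 3
    assert assemble(_toy_network(4)).dim == 9
    sten = StenosisSpec(degree=0.5, length=15.0, ref_radius=0.18)
    assert assemble(_toy_network(1, stenosis=sten)).dim == 3


def test_constant_inflow_reaches_rcr_steady_state():
    """With constant inflow and (effectively) no coronary path, the mean
    aortic pressure settles at Q0*(Rp+Rd)."""
    q0 = 80.0
    period = 60.0 / 70.0
    t = np.linspace(0.0, period, 858)
    inflow = Waveform(times=t, values=np.full_like(t, q0), kind="flow")
    # a single branch with enormous resistance isolates the systemic RCR
    net = _toy_network(1, inflow=inflow, r_outlet=1.0e12)
    res = simulate(assemble(net), n_cycles=12)
    expected = q0 * (net.systemic.rp + net.systemic.rd) / MMHG_TO_DYN_CM2
    assert res.cycle_mean(res.p_aorta) == pytest.approx(expected, rel=0.01)


def test_zero_inflow_decays_to_reference():
    period = 60.0 / 70.0
    t = np.linspace(0.0, period, 858)
    inflow = Waveform(times=t, values=np.zeros_like(t), kind="flow")
    net = _toy_network(1, inflow=inflow)
    res = simulate(assemble(net), n_cycles=12, init="warm")
    assert abs(res.cycle_mean(res.p_aorta)) < 1.0  # mmHg, decayed toward 0


def _synthetic_result(cycle_means, n_per=100):
    """SimulationResult whose per-cycle aortic means are prescribed."""
    n_cycles = len(cycle_means)
    period = 1.0
    time = np.linspace(0.0, n_cycles * period, n_cycles * n_per + 1)
    p = np.empty_like(time)
    for k, m in enumerate(cycle_means):
        mask = (time >= k * period) & (time <= (k + 1) * period)
        p[mask] = m
    return SimulationResult(
        time=time, p_aorta=p, q_inflow=np.zeros_like(time),
        q_systemic=np.zeros_like(time), branches={},
        cycle_index=np.minimum((time / period).astype(int) + 1, n_cycles),
        n_cycles=n_cycles, period=period, network=None, mode="rest", state="pre")


def test_periodicity_residual_on_constructed_series():
    exact = _synthetic_result([100.0, 100.0, 100.0])
    assert periodicity_residual(exact, 3) == pytest.approx(0.0, abs=1e-12)
    drift = _synthetic_result([100.0, 102.0])  # 2% cycle-to-cycle drift
    assert periodicity_residual(drift, 2) == pytest.approx(0.02, rel=0.05)
    with pytest.raises(ValueError):
        periodicity_residual(drift, 1)
    with pytest.raises(ValueError):
        periodicity_residual(drift, 5)


def test_default_simulation_cyclically_converges(sim_rest):
    assert periodicity_residual(sim_rest, 7) < 0.01


def test_mass_conservation_in_periodic_state(tuned_rest):
    res = simulate(assemble(tuned_rest), n_cycles=12)
    assert res.mass_balance_error() < 1.0e-3


def test_time_step_refinement_stability(tuned_rest):
    coarse = simulate(assemble(tuned_rest), n_cycles=7, dt=1.0e-3)
    fine = simulate(assemble(tuned_rest), n_cycles=7, dt=0.5e-3)
    for get in (lambda r: r.cycle_mean(r.p_aorta),
                lambda r: r.cycle_mean(r.branches["LAD"].q),
                lambda r: r.coronary_outflow_mean()):
        assert get(fine) == pytest.approx(get(coarse), rel=0.02)


def test_left_branch_flow_is_diastole_dominant(sim_rest, ref_patient):
    """Systolic intramyocardial compression suppresses left coronary flow."""
    s = sim_rest.cycle_slice(7)
    t = np.mod(sim_rest.time[s] - sim_rest.time[s][0], sim_rest.period)
    q = sim_rest.branches["LAD"].q[s]
    et = ref_patient.pre.ejection_time / 1000.0
    assert q[t < et].mean() < q[t >= et].mean()


def test_linear_network_matches_dense_matrix_oracle():
    """With Pim = 0 and no stenosis the network is linear time-invariant;
    an independent dense-matrix exponential integrator must agree."""
    state = make_state()
    inflow = make_inflow(state)
    net = _toy_network(1, inflow=inflow)
    sys_ = assemble(net)
    res = simulate(sys_, n_cycles=6, init="zero")

    # --- independent oracle: y' = A y + b(t), piecewise-constant b over dt
    from scipy.linalg import expm
    rp, rd, c = net.systemic.rp, net.systemic.rd, net.systemic.c
    o = net.branches[0].outlet
    from coroflow.network import chain_resistance
    r1 = chain_resistance(net.branches[0], net.fluid) + o.ra
    ram, rv, ca, cim = o.ra_micro, o.rv, o.ca, o.cim
    # P_ao = (Qin + Pc/rp + Pca/r1) / (1/rp + 1/r1) — algebraic elimination
    den = 1.0 / rp + 1.0 / r1

    def p_ao(qin, pc, pca):
        return (qin + pc / rp + pca / r1) / den

    A = np.zeros((3, 3))
    # dPc = ((Pao-Pc)/rp - Pc/rd)/c ; dPca = ((Pao-Pca)/r1 - (Pca-Pcim)/ram)/ca
    # dPcim = ((Pca-Pcim)/ram - Pcim/rv)/cim  (dPim = 0)
    dpao_dpc = (1.0 / rp) / den
    dpao_dpca = (1.0 / r1) / den
    A[0, 0] = ((dpao_dpc - 1) / rp - 1.0 / rd) / c
    A[0, 1] = (dpao_dpca / rp) / c
    A[1, 0] = (dpao_dpc / r1) / ca
    A[1, 1] = ((dpao_dpca - 1) / r1 - 1.0 / ram) / ca
    A[1, 2] = (1.0 / ram) / ca
    A[2, 1] = (1.0 / ram) / cim
    A[2, 2] = (-1.0 / ram - 1.0 / rv) / cim
    b_of_q = np.array([(1.0 / den) / rp / c, (1.0 / den) / r1 / ca, 0.0])

    dt = 1.0e-3
    n_steps = int(round(6 * inflow.period / dt))
    y = np.zeros(3)  # zero initial state, matching the simulation above
    ead = expm(A * dt)
    Ainv_b = np.linalg.solve(A, b_of_q)
    series = []
    for i in range(n_steps):
        qin = 0.5 * (float(inflow(i * dt)) + float(inflow((i + 1) * dt)))
        # y_{k+1} = e^{A dt} (y + A^{-1} b q) − A^{-1} b q
        shift = Ainv_b * qin
        y = ead @ (y + shift) - shift
        series.append(p_ao(float(inflow((i + 1) * dt)), y[0], y[1]))
    oracle_final = np.array(series[-int(round(inflow.period / dt)):]) / 1333.22
    sim_final = res.p_aorta[res.cycle_slice(6)][1:]
    assert np.max(np.abs(sim_final - oracle_final)) < 0.02 * np.mean(oracle_final)


def test_cycles_to_converge_reports_first_cycle_below_tolerance():
    r = _synthetic_result([50.0, 80.0, 95.0, 99.0, 99.5, 99.9, 99.95])
    # residuals: 0.375, 0.158, 0.040, 0.005 → first < 1% is cycle 5
    assert cycles_to_converge(r, tol=0.01) == 5


def test_simulate_validates_arguments(tuned_rest):
    sys_ = assemble(tuned_rest)
    with pytest.raises(ValueError):
        simulate(sys_, n_cycles=0)
    with pytest.raises(ValueError):
        simulate(sys_, dt=-1.0)
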