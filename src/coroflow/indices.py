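"""Coronary physiology indices from simulation results.

FFR is the cycle-mean distal-to-proximal pressure ratio across the lesion
under hyperemia; iFR is the same ratio at rest averaged over the diastolic
wave-free period; CFR is hyperemic over resting flow.  All quantities are
read from the final simulated cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lumped_solver import SimulationResult
from .waveforms import CardiacState, Waveform


@dataclass
class IndexSet:
    """Physiology indices for one patient-state."""

    ffr: float
    ifr: float
    pd_pa_rest: float
    cfr: float
    q_rest: float          # total coronary flow at rest, cm³/s
    q_hyper: float         # total coronary flow at hyperemia, cm³/s
    pa_mean: float         # hyperemic cycle-mean proximal pressure, mmHg
    pd_mean: float         # hyperemic cycle-mean distal pressure, mmHg
    cfr_lesion: float = math.nan   # CFR of the lesion vessel itself
    lesion_vessel: str = ""


class ModeMismatchError(ValueError):
    """A simulation of the wrong mode (rest vs hyperemia) was supplied."""


def _require_mode(sim: SimulationResult, mode: str) -> None:
    if sim.mode != mode:
        raise ModeMismatchError(f"expected a {mode}-mode simulation, got {sim.mode!r}")


def compute_ffr(sim_hyper: SimulationResult, branch: str) -> float:
    """Cycle-mean Pd over cycle-mean Pa on the final hyperemic cycle.

    Pd is sampled immediately distal to the stenosis element, Pa at the
    branch ostium.
    """
    _require_mode(sim_hyper, "hyper")
    b = sim_hyper.branches[branch]
    return sim_hyper.cycle_mean(b.p_dist) / sim_hyper.cycle_mean(b.p_prox)


def wave_free_window(inflow: Waveform, state: CardiacState) -> tuple[float, float]:
    """Diastolic wave-free period: from 25% into diastole to 5 ms before
    end-diastole.  Diastole starts when ejection ends."""
    et = state.ejection_time / 1000.0
    period = state.period
    diastole = period - et
    if diastole <= 0.05:
        raise ValueError("diastole shorter than 50 ms; no wave-free window")
    t0 = et + 0.25 * diastole
    t1 = period - 0.005
    if t1 <= t0:
        raise ValueError("empty wave-free window")
    return t0, t1


def _window_mean(sim: SimulationResult, series: np.ndarray,
                 window: tuple[float, float]) -> float:
    """Mean of a series over the window placed inside the final cycle."""
    t0 = (sim.n_cycles - 1) * sim.period + window[0]
    t1 = (sim.n_cycles - 1) * sim.period + window[1]
    if window[0] < 0 or window[1] > sim.period or t1 <= t0:
        raise ValueError("window outside the cardiac cycle")
    m = (sim.time >= t0) & (sim.time <= t1)
    if m.sum() < 2:
        raise ValueError("window too narrow for the output grid")
    return float(np.trapezoid(series[m], sim.time[m]) / (sim.time[m][-1] - sim.time[m][0]))


def compute_ifr(sim_rest: SimulationResult, branch: str,
                window: tuple[float, float]) -> float:
    """Wave-free-period mean Pd over mean Pa on the final resting cycle."""
    _require_mode(sim_rest, "rest")
    b = sim_rest.branches[branch]
    return _window_mean(sim_rest, b.p_dist, window) / _window_mean(sim_rest, b.p_prox, window)


def compute_cfr(sim_rest: SimulationResult, sim_hyper: SimulationResult,
                branch: str | None = None) -> float:
    """Hyperemic over resting cycle-mean flow (total, or one branch)."""
    _require_mode(sim_rest, "rest")
    _require_mode(sim_hyper, "hyper")
    if branch is None:
        q_r = sim_rest.coronary_outflow_mean()
        q_h = sim_hyper.coronary_outflow_mean()
    else:
        q_r = sim_rest.cycle_mean(sim_rest.branches[branch].q)
        q_h = sim_hyper.cycle_mean(sim_hyper.branches[branch].q)
    if q_r == 0:
        raise ZeroDivisionError("resting flow is zero; CFR undefined")
    return q_h / q_r


def velocity_ratio(sim: SimulationResult) -> float:
    """Mean left ostial velocity over mean right ostial velocity."""
    net = sim.network
    if not (net.left_branches and net.right_branches):
        raise ValueError("need branches on both sides")
    q_l = sum(sim.cycle_mean(sim.branches[b.name].q) for b in net.left_branches)
    q_r = sum(sim.cycle_mean(sim.branches[b.name].q) for b in net.right_branches)
    a_l = math.pi * net.left_branches[0].ostium_radius**2
    a_r = math.pi * net.right_branches[0].ostium_radius**2
    return (q_l / a_l) / (q_r / a_r)


def compute_indices(sim_rest: SimulationResult, sim_hyper: SimulationResult,
                    state: CardiacState, lesion_vessel: str) -> IndexSet:
    """Full index set for one patient-state."""
    window = wave_free_window(sim_rest.network.inflow, state)
    b_r = sim_rest.branches[lesion_vessel]
    return IndexSet(
        ffr=compute_ffr(sim_hyper, lesion_vessel),
        ifr=compute_ifr(sim_rest, lesion_vessel, window),
        pd_pa_rest=sim_rest.cycle_mean(b_r.p_dist) / sim_rest.cycle_mean(b_r.p_prox),
        cfr=compute_cfr(sim_rest, sim_hyper),
        cfr_lesion=compute_cfr(sim_rest, sim_hyper, lesion_vessel),
        q_rest=sim_rest.coronary_outflow_mean(),
        q_hyper=sim_hyper.coronary_outflow_mean(),
        pa_mean=sim_hyper.cycle_mean(sim_hyper.branches[lesion_vessel].p_prox),
        pd_mean=sim_hyper.cycle_mean(sim_hyper.branches[lesion_vessel].p_dist),
        lesion_vessel=lesion_vessel,
    )
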