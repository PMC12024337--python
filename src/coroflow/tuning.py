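"""Iterative boundary-condition tuning.

Reproduces the two tuning loops of the study protocol:

* systemic RCR — total resistance from mean pressure over cardiac output,
  then short ("first-order") simulations adjusting the proximal-resistance
  fraction (0.5% steps) and the compliance (0.0002 cm⁵/dyn steps from an
  initial 0.001) until simulated systolic/diastolic aortic pressures match
  the targets;
* coronary outlets — total coronary flow 4% of cardiac output at rest and
  10–12% under adenosine stress, resistances split Ra:Ramicro:Rv =
  0.32:0.52:0.16 (rest) or 0.41:0.28:0.31 (stress), left:right ostial
  velocity ratio 3:1, compliances distributed by cross-sectional area with
  Cim 89% / Ca 11%.

Tuning simulations are short (a few cycles, warm-started); only final
verification runs use the full seven cycles.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

from . import network as nw
from .lumped_solver import assemble, simulate
from .network import (CoronaryOutletParams, NetworkSpec, RCRParams,
                      allocate_flows)
from .units import MMHG_TO_DYN_CM2
from .waveforms import CardiacState

#: tuning step granularities
RP_FRACTION_STEP = 0.005      # 0.5% of total resistance
C_STEP = 2.0e-4               # cm⁵/dyn
CORONARY_R_STEP = 100.0       # dyn·s/cm⁵
STRESS_FLOW_STEP = 0.05       # cm³/s


class TuningTargets(BaseModel):
    """Physiologic targets and tolerances for one patient-state."""

    p_sys: float
    p_dia: float
    p_mean: float
    cardiac_output: float                       # cm³/s
    rest_coronary_fraction: float = nw.REST_CORONARY_FRACTION
    stress_coronary_fraction_range: tuple = nw.STRESS_CORONARY_BAND
    lr_velocity_ratio: float = nw.LR_VELOCITY_RATIO
    pressure_tol: float = 2.0                   # mmHg
    flow_fraction_tol: float = 0.005            # absolute (0.5 percentage points)
    velocity_ratio_tol: float = 0.15            # relative

    @model_validator(mode="after")
    def _check(self):
        if not self.p_dia < self.p_sys:
            raise ValueError("require p_dia < p_sys")
        if not 0 < self.rest_coronary_fraction < 1:
            raise ValueError("rest_coronary_fraction must lie in (0,1)")
        lo, hi = self.stress_coronary_fraction_range
        if not 0 < lo <= hi < 1:
            raise ValueError("invalid stress fraction band")
        return self

    @classmethod
    def from_state(cls, state: CardiacState) -> "TuningTargets":
        co = state.stroke_volume * state.heart_rate / 60.0
        return cls(p_sys=state.p_sys, p_dia=state.p_dia, p_mean=state.p_mean,
                   cardiac_output=co)


class ResistanceDistribution(BaseModel):
    ra_frac: float
    ramicro_frac: float
    rv_frac: float
    mode: str

    @model_validator(mode="after")
    def _check(self):
        f = (self.ra_frac, self.ramicro_frac, self.rv_frac)
        if min(f) < 0 or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        return self

    @classmethod
    def rest(cls) -> "ResistanceDistribution":
        return cls(ra_frac=0.32, ramicro_frac=0.52, rv_frac=0.16, mode="rest")

    @classmethod
    def stress(cls) -> "ResistanceDistribution":
        return cls(ra_frac=0.41, ramicro_frac=0.28, rv_frac=0.31, mode="stress")


class ComplianceDistribution(BaseModel):
    cim_frac: float = nw.CIM_FRACTION
    ca_frac: float = nw.CA_FRACTION
    total: float = nw.TOTAL_COMPLIANCE["left"]  # cm⁵/dyn, one side

    @model_validator(mode="after")
    def _check(self):
        if abs(self.cim_frac + self.ca_frac - 1.0) > 1e-9:
            raise ValueError("cim_frac + ca_frac must equal 1")
        return self


@dataclass
class TuningReport:
    """Outcome of a tuning loop; carries best-so-far parameters on failure."""

    converged: bool
    n_iter: int
    residuals: dict
    history: list = field(default_factory=list)

    def __bool__(self) -> bool:  # truthiness == convergence
        return self.converged


class TuningFailure(RuntimeError):
    """Structured non-convergence: carries the best parameters found."""

    def __init__(self, message: str, params, report: TuningReport):
        super().__init__(message)
        self.params = params
        self.report = report


def total_systemic_resistance(p_mean: float, co: float, p_ref: float = 0.0) -> float:
    """Total resistance = mean pressure over cardiac output (CGS)."""
    if co <= 0:
        raise ValueError("cardiac output must be positive")
    return max((p_mean - p_ref), 0.0) * MMHG_TO_DYN_CM2 / co


def split_rcr(r_total: float, rp_fraction: float) -> tuple[float, float]:
    """Distribute a total resistance into proximal and distal parts."""
    if not 0 < rp_fraction < 1:
        raise ValueError("rp_fraction must lie in (0,1)")
    rp = rp_fraction * r_total
    return rp, r_total - rp


def distribute_coronary(r_total_cor: float,
                        dist: ResistanceDistribution) -> tuple[float, float, float]:
    """Split one outlet's total resistance into (Ra, Ramicro, Rv); the venous
    element takes the remainder so the parts sum back exactly."""
    ra = dist.ra_frac * r_total_cor
    ram = dist.ramicro_frac * r_total_cor
    return ra, ram, r_total_cor - (ra + ram)


def distribute_compliance(total: float, areas,
                          dist: ComplianceDistribution | None = None) -> list[tuple[float, float]]:
    """Per-branch (ca, cim) from one side's total compliance, shares ∝ area."""
    dist = dist or ComplianceDistribution()
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    shares = areas / areas.sum()
    return [(dist.ca_frac * s * total, dist.cim_frac * s * total) for s in shares]


def _quantize(x: float, step: float) -> float:
    return max(round(x / step) * step, step)


def _pressure_extremes(network: NetworkSpec, n_cycles: int = 4):
    res = simulate(assemble(network), n_cycles=n_cycles)
    s = res.cycle_slice(n_cycles)
    p = res.p_aorta[s]
    return float(p.max()), float(p.min()), res.cycle_mean(res.p_aorta), res


def tune_rcr(targets: TuningTargets, network: NetworkSpec,
             rp_fraction: float = 0.09, c_init: float = 1.0e-3,
             tol: float | None = None, max_iter: int = 25,
             sim_cycles: int = 4) -> tuple[RCRParams, TuningReport]:
    """Fit the systemic Windkessel to the aortic pressure targets.

    Each iteration runs a short simulation, then (i) rescales the total
    resistance by the mean-pressure mismatch, (ii) steps the compliance by
    the pulse-pressure ratio (0.0002 cm⁵/dyn granularity), and (iii) nudges
    the proximal fraction in 0.5% steps on the residual systolic error.
    Returns fitted parameters plus a convergence report; on non-convergence
    the report carries the best-so-far parameters and residuals.
    """
    tol = targets.pressure_tol if tol is None else tol
    if not math.isfinite(tol):
        rcr = network.systemic
        return rcr, TuningReport(converged=True, n_iter=1, residuals={})
    net = copy.deepcopy(network)
    co_sys = targets.cardiac_output * (
        1.0 - (targets.rest_coronary_fraction if net.mode == "rest"
               else sum(targets.stress_coronary_fraction_range) / 2))
    r_total = total_systemic_resistance(targets.p_mean, co_sys)
    c = c_init
    pp_target = targets.p_sys - targets.p_dia
    best = None
    history = []
    for it in range(1, max_iter + 1):
        rp, rd = split_rcr(r_total, rp_fraction)
        net.systemic = RCRParams(rp=rp, c=c, rd=rd)
        p_sys, p_dia, p_mean, _ = _pressure_extremes(net, sim_cycles)
        err_s = p_sys - targets.p_sys
        err_d = p_dia - targets.p_dia
        history.append(dict(iter=it, rp=rp, rd=rd, c=c, p_sys=p_sys, p_dia=p_dia))
        score = max(abs(err_s), abs(err_d))
        if best is None or score < best[0]:
            best = (score, net.systemic, dict(p_sys=err_s, p_dia=err_d))
        if abs(err_s) <= tol and abs(err_d) <= tol:
            rep = TuningReport(converged=True, n_iter=it,
                               residuals=dict(p_sys=err_s, p_dia=err_d),
                               history=history)
            return net.systemic, rep
        # pressure level → total resistance (continuous rescale); the level
        # is tracked as sys+dia, the quantities the protocol validates —
        # pinning the waveform time-mean instead would leave a systematic
        # offset between the clinical mean formula and the time mean
        r_total *= (targets.p_sys + targets.p_dia) / (p_sys + p_dia)
        # pulse pressure → compliance, one 0.0002 cm⁵/dyn step at a time
        pp_err = (p_sys - p_dia) - pp_target
        if abs(pp_err) > 0.5 * tol:
            c = max(c + C_STEP * math.copysign(1.0, pp_err), C_STEP)
        else:
            # pulse matched: shift the proximal fraction on the residual
            # systolic error (raising Rp raises the systolic peak)
            rp_fraction = min(max(rp_fraction - RP_FRACTION_STEP *
                                  math.copysign(1.0, err_s), 0.02), 0.3)
    rep = TuningReport(converged=False, n_iter=max_iter,
                       residuals=best[2], history=history)
    raise TuningFailure("systemic RCR tuning did not converge", best[1], rep)


def _measure_coronary(network: NetworkSpec, sim_cycles: int = 4):
    res = simulate(assemble(network), n_cycles=sim_cycles)
    q_in = res.cycle_mean(res.q_inflow)
    q_br = {n: res.cycle_mean(b.q) for n, b in res.branches.items()}
    frac = sum(q_br.values()) / q_in
    q_left = sum(q_br[b.name] for b in network.left_branches)
    q_right = sum(q_br[b.name] for b in network.right_branches)
    ratio = math.nan
    if network.left_branches and network.right_branches and q_right > 0:
        a_l = math.pi * network.left_branches[0].ostium_radius**2
        a_r = math.pi * network.right_branches[0].ostium_radius**2
        ratio = (q_left / a_l) / (q_right / a_r)
    return frac, q_br, ratio, res


def tune_coronary(targets: TuningTargets, network: NetworkSpec,
                  mode: str | None = None, max_iter: int = 8,
                  sim_cycles: int = 4) -> tuple[dict, TuningReport]:
    """Size and iterate the coronary outlet parameters for rest or hyperemia.

    Rest: every branch's outlet resistance is corrected toward its allocated
    flow (autoregulation), until the total coronary fraction is within
    ±0.5 pp of 4% of cardiac output and the left:right ostial velocity ratio
    is within tolerance of 3:1.  Stress: targets are quantized to 0.05 cm³/s,
    outlets are sized without compensating the stenosis (maximal
    vasodilation), and only a global resistance rescale is iterated until
    the total fraction lies inside the 10–12% band.
    """
    mode = mode or network.mode
    if mode not in ("rest", "hyper"):
        raise ValueError("mode must be 'rest' or 'hyper'")
    net = copy.deepcopy(network)
    net.mode = mode
    co = targets.cardiac_output
    if mode == "rest":
        frac_target = targets.rest_coronary_fraction
        band = (frac_target - targets.flow_fraction_tol,
                frac_target + targets.flow_fraction_tol)
    else:
        band = targets.stress_coronary_fraction_range
        frac_target = 0.5 * (band[0] + band[1])
    q_targets = allocate_flows(net.branches, frac_target * co,
                               net.murray_exponent, targets.lr_velocity_ratio)
    if mode == "hyper":
        q_targets = {k: max(_quantize(v, STRESS_FLOW_STEP), STRESS_FLOW_STEP)
                     for k, v in q_targets.items()}
    p_mean_dyn = targets.p_mean * MMHG_TO_DYN_CM2

    # initial sizing and compliance distribution
    r_tot = {}
    for b in net.branches:
        r_tot[b.name] = _quantize(
            nw.initial_outlet_resistance(b, q_targets[b.name], p_mean_dyn,
                                         net.fluid, "rest" if mode == "rest" else "stress"),
            CORONARY_R_STEP)
    for side in ("left", "right"):
        sb = net.left_branches if side == "left" else net.right_branches
        if not sb:
            continue
        pairs = distribute_compliance(
            nw.TOTAL_COMPLIANCE[side], [b.vessel.radius**2 for b in sb])
        for b, (ca, cim) in zip(sb, pairs):
            b._ca, b._cim = ca, cim

    def apply(scale_map):
        fr = (ResistanceDistribution.rest() if mode == "rest"
              else ResistanceDistribution.stress())
        for b in net.branches:
            r = _quantize(r_tot[b.name] * scale_map.get(b.name, 1.0), CORONARY_R_STEP)
            r_tot[b.name] = r
            ra, ram, rv = distribute_coronary(r, fr)
            b.outlet = CoronaryOutletParams(ra=ra, ra_micro=ram, rv=rv,
                                            ca=b._ca, cim=b._cim,
                                            pim=b.outlet.pim)

    apply({})
    best = None
    history = []
    for it in range(1, max_iter + 1):
        frac, q_br, ratio, _ = _measure_coronary(net, sim_cycles)
        ratio_ok = (math.isnan(ratio) or
                    abs(ratio / targets.lr_velocity_ratio - 1.0) <= targets.velocity_ratio_tol)
        in_band = band[0] <= frac <= band[1]
        history.append(dict(iter=it, frac=frac, ratio=ratio, q=dict(q_br)))
        score = abs(frac - frac_target)
        if best is None or score < best[0]:
            best = (score, {b.name: b.outlet for b in net.branches},
                    dict(frac=frac, ratio=ratio))
        if in_band and (ratio_ok or mode == "hyper"):
            rep = TuningReport(converged=True, n_iter=it,
                               residuals=dict(frac=frac, ratio=ratio),
                               history=history)
            return {b.name: b.outlet for b in net.branches}, rep
        if mode == "rest":
            apply({n: q_br[n] / q_targets[n] for n in q_br})
        else:
            apply({n: frac / frac_target for n in q_br})
    rep = TuningReport(converged=False, n_iter=max_iter,
                       residuals=best[2], history=history)
    raise TuningFailure(f"coronary tuning ({mode}) did not converge", best[1], rep)


def tune_patient(patient, state: str = "pre", mode: str = "rest",
                 shape=None, strict: bool = False) -> tuple[NetworkSpec, dict]:
    """Full tuning for one patient-state: build, fit RCR, fit coronaries.

    With ``strict=False`` (default) non-converged loops fall back to their
    best-so-far parameters, mirroring cohort practice where a difficult
    patient is carried with a documented residual rather than dropped.
    """
    net = nw.build_network(patient, state, mode, shape=shape)
    cstate = getattr(patient, state)
    targets = TuningTargets.from_state(cstate)
    reports = {}
    try:
        rcr, reports["rcr"] = tune_rcr(targets, net)
    except TuningFailure as f:
        if strict:
            raise
        rcr, reports["rcr"] = f.params, f.report
    net.systemic = rcr
    try:
        outlets, reports["coronary"] = tune_coronary(targets, net, mode)
    except TuningFailure as f:
        if strict:
            raise
        outlets, reports["coronary"] = f.params, f.report
    for b in net.branches:
        b.outlet = outlets[b.name]
    return net, reports
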