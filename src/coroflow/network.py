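"""Lumped aorto-coronary circulation graph.

One inflow node (aortic root) feeds a systemic RCR Windkessel outlet and a
set of epicardial coronary branches.  Each branch is a series chain of
Poiseuille segment resistances, an optional stenosis element, and a coronary
Windkessel outlet (Ra – Ca – Ramicro – Cim/Pim – Rv) draining to venous
pressure 0.  Outlet flow shares follow a generalized Murray law; left-tree
outlets are compressed by the LV-derived intramyocardial pressure and the
right coronary by the RV-derived one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .waveforms import Waveform


class FluidProperties(BaseModel):
    """Blood in CGS units: density g/cm³, dynamic viscosity poise."""

    rho: float = 1.06
    mu: float = 0.04

    @model_validator(mode="after")
    def _check(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")
        return self


class VesselSegment(BaseModel):
    """Epicardial conduit segment (cm)."""

    name: str
    radius: float
    length: float
    wall_thickness: Optional[float] = None
    side: str = "left"  # {"left", "right"}

    @model_validator(mode="after")
    def _check(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.wall_thickness is None:
            self.wall_thickness = wall_thickness(self.radius)
        return self


class StenosisSpec(BaseModel):
    """Focal stenosis from QCA: diameter-reduction ``degree`` and length (mm)."""

    degree: float
    length: float          # mm
    ref_radius: float      # cm, healthy reference radius
    kt: float = 1.52       # turbulent-expansion loss coefficient

    @model_validator(mode="after")
    def _check(self):
        if not 0 <= self.degree < 1:
            raise ValueError("degree must lie in [0, 1)")
        if self.length <= 0 or self.ref_radius <= 0:
            raise ValueError("length and ref_radius must be positive")
        return self

    @property
    def throat_radius(self) -> float:
        return self.ref_radius * (1.0 - self.degree)

    @property
    def length_cm(self) -> float:
        return self.length / 10.0


class RCRParams(BaseModel):
    """Systemic three-element Windkessel (dyn·s/cm⁵, cm⁵/dyn)."""

    rp: float
    c: float
    rd: float
    p_ref: float = 0.0  # mmHg, distal reference

    @model_validator(mode="after")
    def _check(self):
        if self.rp <= 0 or self.rd <= 0 or self.c <= 0:
            raise ValueError("rp, rd, c must be positive")
        return self


@dataclass
class CoronaryOutletParams:
    """Coronary outlet Windkessel.

    ``pim`` is the intramyocardial pressure waveform (LV- or RV-derived by
    side); ``rv_micro`` is fixed at 0 (no micro-venous resistance).
    """

    ra: float
    ra_micro: float
    rv: float
    ca: float
    cim: float
    pim: Waveform
    rv_micro: float = 0.0

    def __post_init__(self):
        if min(self.ra, self.ra_micro, self.rv) < 0:
            raise ValueError("resistances must be non-negative")
        if self.ca <= 0 or self.cim <= 0:
            raise ValueError("compliances must be positive")
        if self.rv_micro != 0.0:
            raise ValueError("rv_micro is fixed at 0")

    @property
    def r_total(self) -> float:
        return self.ra + self.ra_micro + self.rv


@dataclass
class Branch:
    """One coronary path from the aortic root to a coronary outlet.

    ``chain`` lists the series conduit segments from the root (a shared trunk
    such as the left main appears first); the optional stenosis sits on the
    last (named) vessel at ``lesion_start_cm`` from that vessel's origin.
    """

    name: str
    chain: list  # list[VesselSegment]
    outlet: CoronaryOutletParams
    stenosis: Optional[StenosisSpec] = None
    lesion_start_cm: float = 2.0

    @property
    def side(self) -> str:
        return self.chain[-1].side

    @property
    def vessel(self) -> VesselSegment:
        return self.chain[-1]

    @property
    def ostium_radius(self) -> float:
        """Radius at the coronary ostium (first segment of the chain)."""
        return self.chain[0].radius


@dataclass
class NetworkSpec:
    """The lumped circulation graph for one patient-state."""

    inflow: Waveform
    systemic: RCRParams
    branches: list  # list[Branch]
    fluid: FluidProperties = field(default_factory=FluidProperties)
    murray_exponent: float = 3.0
    mode: str = "rest"   # {"rest", "hyper"}
    state: str = "pre"   # {"pre", "post"}

    def __post_init__(self):
        if not self.branches:
            raise ValueError("network needs at least one coronary branch")
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError("branch names must be unique")

    def branch(self, name: str) -> Branch:
        for b in self.branches:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def left_branches(self):
        return [b for b in self.branches if b.side == "left"]

    @property
    def right_branches(self):
        return [b for b in self.branches if b.side == "right"]


def murray_split(radii, m: float, q_total: float) -> np.ndarray:
    """Allocate ``q_total`` among outlets with q_i ∝ r_i^m.

    The last element absorbs the rounding remainder so the split sums to
    ``q_total`` exactly.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radii must be non-empty")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if q_total < 0:
        raise ValueError("q_total must be non-negative")
    w = radii**m
    q = q_total * w / w.sum()
    q[-1] = q_total - q[:-1].sum()
    return q


def poiseuille_resistance(radius: float, length: float,
                          fluid: FluidProperties | None = None) -> float:
    """Fully developed laminar-flow resistance 8·mu·L/(pi·r^4), dyn·s/cm⁵."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    fluid = fluid or FluidProperties()
    return 8.0 * fluid.mu * length / (math.pi * radius**4)


def wall_thickness(radius: float) -> float:
    """Wall thickness assumed as one tenth of the mean radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return radius / 10.0


def chain_resistance(branch: Branch, fluid: FluidProperties) -> float:
    """Total Poiseuille resistance of the branch's conduit chain."""
    return sum(poiseuille_resistance(s.radius, s.length, fluid) for s in branch.chain)


def stenosis_coefficients(sten: StenosisSpec, fluid: FluidProperties) -> tuple[float, float]:
    """Viscous and turbulent coefficients of the stenosis pressure-drop law.

    ΔP = r_visc·q + k_turb·q·|q| with
    r_visc = 8·mu·L/(pi·r_throat⁴) and
    k_turb = kt·rho/(2·A0²)·(A0/As − 1)².
    """
    if sten.degree >= 1:
        raise ValueError("degree must be < 1")
    a0 = math.pi * sten.ref_radius**2
    a_s = math.pi * sten.throat_radius**2
    r_visc = 8.0 * fluid.mu * sten.length_cm / (math.pi * sten.throat_radius**4)
    k_turb = sten.kt * fluid.rho / (2.0 * a0**2) * (a0 / a_s - 1.0) ** 2
    return r_visc, k_turb


# ---------------------------------------------------------------------------
# default geometry and distribution constants
# ---------------------------------------------------------------------------

#: rest / pharmacological-stress splits of each outlet's total resistance
#: into (Ra, Ramicro, Rv)
REST_R_DISTRIBUTION = (0.32, 0.52, 0.16)
STRESS_R_DISTRIBUTION = (0.41, 0.28, 0.31)
#: intramyocardial / arterial split of the total coronary compliance
CIM_FRACTION = 0.89
CA_FRACTION = 0.11
#: initial total coronary compliance per side, cm⁵/dyn
TOTAL_COMPLIANCE = {"left": 3.6e-5, "right": 2.5e-5}
#: coronary share of cardiac output
REST_CORONARY_FRACTION = 0.04
STRESS_CORONARY_BAND = (0.10, 0.12)
#: target mean left:right ostial velocity ratio
LR_VELOCITY_RATIO = 3.0

#: literature-typical conduit lengths, cm
DEFAULT_LENGTHS = {"LM": 1.0, "LAD": 12.0, "LCx": 9.0, "RCA": 11.0, "ramus": 7.0}
#: literature-typical radii, cm
DEFAULT_RADII = {"LM": 0.225, "LAD": 0.18, "LCx": 0.17, "RCA": 0.17, "ramus": 0.14}


def allocate_flows(branches, q_cor: float, murray_exponent: float = 3.0,
                   lr_velocity_ratio: float = LR_VELOCITY_RATIO) -> dict:
    """Target mean flow per branch.

    The left:right split enforces the target ostial mean-velocity ratio
    (velocity = Q/(pi·r²) at the left-main and RCA ostia); within a side,
    flows follow the generalized Murray law on the named vessel radii.
    """
    left = [b for b in branches if b.side == "left"]
    right = [b for b in branches if b.side == "right"]
    if left and right:
        a_l = math.pi * left[0].ostium_radius**2
        a_r = math.pi * right[0].ostium_radius**2
        # Q_L/a_l = ratio * Q_R/a_r  and  Q_L + Q_R = q_cor
        w_l = lr_velocity_ratio * a_l
        q_left = q_cor * w_l / (w_l + a_r)
        q_right = q_cor - q_left
    elif left:
        q_left, q_right = q_cor, 0.0
    else:
        q_left, q_right = 0.0, q_cor
    out = {}
    for side_branches, q_side in ((left, q_left), (right, q_right)):
        if not side_branches:
            continue
        radii = [b.vessel.radius for b in side_branches]
        for b, q in zip(side_branches, murray_split(radii, murray_exponent, q_side)):
            out[b.name] = float(q)
    return out


def initial_outlet_resistance(branch: Branch, q_target: float, p_mean_dyn: float,
                              fluid: FluidProperties, mode: str) -> float:
    """Size a branch outlet's total resistance for a target mean flow.

    At rest, autoregulation holds the resting flow, so the expected stenosis
    and conduit pressure drops at the target flow are subtracted from the
    driving pressure before dividing (the microcirculation compensates the
    lesion).  Under maximal hyperemia no such compensation exists: the
    outlet resistance is sized from the full mean pressure and the stenosis
    then genuinely limits the achieved flow.
    """
    if q_target <= 0:
        raise ValueError("q_target must be positive")
    r_chain = chain_resistance(branch, fluid)
    if mode == "rest" and branch.stenosis is not None:
        r_visc, k_turb = stenosis_coefficients(branch.stenosis, fluid)
        dp = r_visc * q_target + k_turb * q_target**2 + r_chain * q_target
    else:
        dp = r_chain * q_target
    r = (p_mean_dyn - dp) / q_target
    return max(r, 500.0)


def outlet_params_for(branch: Branch, r_total: float, side_compliance_share: float,
                      pim: Waveform, mode: str) -> CoronaryOutletParams:
    """Assemble CoronaryOutletParams from a total resistance and compliance share."""
    fr = REST_R_DISTRIBUTION if mode == "rest" else STRESS_R_DISTRIBUTION
    total_c = TOTAL_COMPLIANCE[branch.side] * side_compliance_share
    return CoronaryOutletParams(
        ra=fr[0] * r_total, ra_micro=fr[1] * r_total, rv=fr[2] * r_total,
        ca=CA_FRACTION * total_c, cim=CIM_FRACTION * total_c, pim=pim)


def build_network(patient, state: str = "pre", mode: str = "rest",
                  shape=None, fluid: FluidProperties | None = None,
                  murray_exponent: float = 3.0) -> NetworkSpec:
    """Build the lumped circulation for one patient-state with provisionally
    sized boundary parameters (the tuning module refines them).

    Left branches receive the LV-derived intramyocardial pressure, the right
    coronary the RV-derived one; the topology is right-dominant with
    LM→(LAD, LCx) plus RCA, and a ramus branch only when the lesion sits on
    the ramus intermedius.
    """
    from .waveforms import InflowShapeParams, make_inflow, make_lv_pressure, make_rv_pressure

    if state not in ("pre", "post"):
        raise ValueError("state must be 'pre' or 'post'")
    if mode not in ("rest", "hyper"):
        raise ValueError("mode must be 'rest' or 'hyper'")
    fluid = fluid or FluidProperties()
    cstate = getattr(patient, state)
    radii = dict(DEFAULT_RADII)
    radii.update(getattr(patient, "branch_radii", {}) or {})

    vessels = ["LAD", "LCx", "RCA"]
    if patient.lesion_vessel == "ramus":
        vessels.insert(2, "ramus")
    if patient.lesion_vessel not in vessels:
        raise ValueError(f"lesion vessel {patient.lesion_vessel!r} not among branches")

    inflow = make_inflow(cstate, shape)
    pim_left = make_lv_pressure(cstate)
    pim_right = make_rv_pressure(cstate, rap=getattr(patient, "rap", 5.0))

    def seg(name, side):
        return VesselSegment(name=name, radius=radii[name],
                             length=DEFAULT_LENGTHS[name], side=side)

    lm = seg("LM", "left")
    skeleton = []
    for v in vessels:
        side = "right" if v == "RCA" else "left"
        chain = [seg(v, side)] if side == "right" else [lm, seg(v, side)]
        sten = None
        if v == patient.lesion_vessel and patient.stenosis_degree > 0:
            sten = StenosisSpec(degree=patient.stenosis_degree,
                                length=patient.stenosis_length,
                                ref_radius=radii[v])
        pim = pim_right if side == "right" else pim_left
        b = Branch(name=v, chain=chain, stenosis=sten, outlet=None,
                   lesion_start_cm=2.0)
        b._pim = pim  # consumed below when sizing outlets
        skeleton.append(b)

    co = cstate.stroke_volume * cstate.heart_rate / 60.0  # cm³/s
    frac = REST_CORONARY_FRACTION if mode == "rest" else sum(STRESS_CORONARY_BAND) / 2
    q_targets = allocate_flows(skeleton, frac * co, murray_exponent)
    p_mean_dyn = cstate.p_mean * 1333.22

    # area shares within each side for compliance distribution
    for side in ("left", "right"):
        sb = [b for b in skeleton if b.side == side]
        if not sb:
            continue
        areas = np.array([b.vessel.radius**2 for b in sb])
        shares = areas / areas.sum()
        for b, share in zip(sb, shares):
            r_tot = initial_outlet_resistance(b, q_targets[b.name], p_mean_dyn, fluid, mode)
            b.outlet = outlet_params_for(b, r_tot, float(share), b._pim, mode)

    # provisional systemic RCR: total resistance from mean pressure over the
    # systemic share of cardiac output, default proximal fraction 9%
    r_sys = p_mean_dyn / (co * (1.0 - frac))
    systemic = RCRParams(rp=0.09 * r_sys, rd=0.91 * r_sys, c=1.0e-3)

    return NetworkSpec(inflow=inflow, systemic=systemic, branches=skeleton,
                       fluid=fluid, murray_exponent=murray_exponent,
                       mode=mode, state=state)
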