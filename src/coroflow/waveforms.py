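"""Inflow and intramyocardial pressure waveforms.

The aortic inflow is a skewed half-sine systolic pulse scaled so that its
integral over systole equals the stroke volume; a stenotic aortic valve
(small effective orifice area) shifts the flow peak later in systole, which
is the characteristic late-peaking ejection profile of severe aortic
stenosis.  Left- and right-ventricular pressure templates provide the
intramyocardial pressure Pim that compresses the coronary microcirculation.
All waveforms describe one cardiac cycle and extend periodically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, model_validator

#: waveform sampling interval, s.  1 ms is far below any dynamics of interest.
SAMPLE_DT = 1.0e-3


class CardiacState(BaseModel):
    """One cardiac condition (pre- or post-valve-replacement) of a patient.

    Pressures are aortic targets in mmHg; ``lv_peak``/``lv_edp`` parametrize
    the left-ventricular pressure template and ``tr_velocity`` (tricuspid
    regurgitation jet, m/s) scales the right-ventricular template.
    """

    heart_rate: float = 70.0          # beats/min
    stroke_volume: float              # mL
    ejection_time: float              # ms
    aortic_valve_area: float          # cm^2
    p_sys: float                      # mmHg
    p_dia: float                      # mmHg
    p_mean: float                     # mmHg
    lv_peak: float = 140.0            # mmHg
    lv_edp: float = 12.0              # mmHg
    tr_velocity: float = 2.5          # m/s

    @property
    def period(self) -> float:
        """Cycle length in seconds."""
        return 60.0 / self.heart_rate

    @model_validator(mode="after")
    def _check(self) -> "CardiacState":
        if self.ejection_time >= 60000.0 / self.heart_rate:
            raise ValueError("ejection_time must be shorter than the cycle period")
        if not (0 < self.p_dia < self.p_mean < self.p_sys):
            raise ValueError("require 0 < p_dia < p_mean < p_sys")
        if self.stroke_volume < 0:
            raise ValueError("stroke_volume must be non-negative")
        if self.aortic_valve_area <= 0:
            raise ValueError("aortic_valve_area must be positive")
        if self.tr_velocity < 0:
            raise ValueError("tr_velocity must be non-negative")
        return self


@dataclass
class Waveform:
    """One periodic cycle of a sampled flow (cm³/s) or pressure (mmHg) signal."""

    times: np.ndarray
    values: np.ndarray
    kind: str  # {"flow", "pressure"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("flow", "pressure"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times[0] != 0.0:
            raise ValueError("waveform must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")

    @property
    def period(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        """Periodic linear interpolation."""
        return np.interp(np.mod(t, self.period), self.times, self.values)

    def mean(self) -> float:
        return float(np.trapezoid(self.values, self.times) / self.period)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "value"])
            for t, v in zip(self.times, self.values):
                w.writerow([repr(float(t)), repr(float(v))])


def read_waveform_csv(path, kind: str) -> Waveform:
    data = np.genfromtxt(Path(path), delimiter=",", names=True)
    return Waveform(times=np.atleast_1d(data["time_s"]),
                    values=np.atleast_1d(data["value"]), kind=kind)


class InflowShapeParams(BaseModel):
    """Systolic inflow profile family.

    ``skew_coeff`` (cm²) controls how strongly a small valve area delays the
    flow peak: the profile is sin(pi * u**c) on normalized systolic time u
    with c = 1 + skew_coeff / AVA, so c > 1 (late peak) for stenotic valves
    and c -> 1 (plain half-sine) as AVA grows.  ``skew_coeff = 0`` gives the
    pure half-sine for any valve area.
    """

    family: str = "half-sine"
    skew_coeff: float = 0.25  # cm^2; 0 disables the AVA-dependent skew


def _time_grid(period: float) -> np.ndarray:
    n = int(round(period / SAMPLE_DT))
    return np.linspace(0.0, period, n + 1)


def make_inflow(state: CardiacState, shape: InflowShapeParams | None = None) -> Waveform:
    """Prescribed aortic inflow: skewed half-sine over systole, zero in diastole.

    The systolic integral equals ``state.stroke_volume`` by construction
    (the sampled profile is rescaled by its own trapezoidal integral).
    """
    shape = shape or InflowShapeParams()
    period = state.period
    et = state.ejection_time / 1000.0
    t = _time_grid(period)
    q = np.zeros_like(t)
    if state.stroke_volume > 0:
        c = 1.0 + shape.skew_coeff / state.aortic_valve_area
        sys_mask = t <= et
        u = t[sys_mask] / et
        q[sys_mask] = np.abs(np.sin(np.pi * u**c))
        area = np.trapezoid(q, t)
        q *= state.stroke_volume / area
    # valve closed in diastole; enforce exact periodicity
    q[-1] = q[0] = 0.0
    return Waveform(times=t, values=q, kind="flow")


def _systolic_template(period: float, duration: float, lead: float = 0.0,
                       sharpness: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Smooth rise–peak–decay bump: sin(pi·t/dur)**sharpness over
    ``duration``, zero elsewhere.

    ``lead`` shifts the bump earlier (cyclically): ventricular pressure
    starts rising during isovolumic contraction, before ejection (t = 0)
    begins.  This lead is what drives the early-systolic coronary backflow
    characteristic of high intramyocardial pressures.  ``sharpness`` < 2
    flattens the top, reproducing the sustained plateau of the ventricular
    pressure trace through ejection (a rounded trapezoid rather than a
    spike); pressure-overloaded ventricles hold near-peak pressure for most
    of systole.
    """
    t = _time_grid(period)
    tau = np.mod(t + lead, period)
    phi = np.zeros_like(t)
    m = tau <= duration
    phi[m] = np.sin(np.pi * tau[m] / duration) ** sharpness
    return t, phi

#: isovolumic contraction + relaxation added to the ejection time to form the
#: duration of the ventricular pressure bump, s
ISOVOLUMIC_PAD = 0.12
#: head start of ventricular contraction before ejection onset, s
ISOVOLUMIC_LEAD = 0.06


def make_lv_pressure(state: CardiacState) -> Waveform:
    """Left-ventricular pressure template: peaks at ``lv_peak`` in systole and
    decays to the end-diastolic pressure ``lv_edp``."""
    if not state.lv_peak > state.lv_edp >= 0:
        raise ValueError("require lv_peak > lv_edp >= 0")
    dur = min(state.ejection_time / 1000.0 + ISOVOLUMIC_PAD, 0.9 * state.period)
    t, phi = _systolic_template(state.period, dur, ISOVOLUMIC_LEAD)
    p = state.lv_edp + (state.lv_peak - state.lv_edp) * phi
    return Waveform(times=t, values=p, kind="pressure")


def make_rv_pressure(state: CardiacState, rap: float = 5.0) -> Waveform:
    """Right-ventricular pressure template.

    Peak pressure follows the simplified Bernoulli relation used to read
    Doppler tricuspid-regurgitation jets: RV systolic = 4·v² + right atrial
    pressure (mmHg).  The diastolic floor is half the atrial pressure.
    """
    peak = 4.0 * state.tr_velocity**2 + rap
    floor = 0.5 * rap
    dur = min(state.ejection_time / 1000.0 + ISOVOLUMIC_PAD, 0.9 * state.period)
    t, phi = _systolic_template(state.period, dur, ISOVOLUMIC_LEAD)
    p = floor + max(peak - floor, 0.0) * phi
    return Waveform(times=t, values=p, kind="pressure")
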