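"""Synthetic aortic-stenosis cohort generator.

Generates virtual patients with the statistical structure of a severe-AS
TAVI cohort: lesion distribution dominated by the LAD, stenosis degree
0.568 ± 0.085 (range 0.40–0.71), lesion length 15.1 ± 4.4 mm (range 8–23),
and paired pre/post valve-replacement cardiac states (valve area 0.6 →
2.4 cm², ejection time 336 → 252 ms, stroke volume 79.1 → 81.4 mL, aortic
pressures unchanged on average).  The left-ventricular peak pressure is
derived from the aortic systolic pressure plus the mean transvalvular
gradient (simplified Bernoulli on the mean systolic jet velocity), which is
what makes valve replacement unload the ventricle.  A noisy "invasive FFR"
channel supports the agreement (Bland–Altman) analysis.
"""

from __future__ import annotations

import json
from functools import lru_cache

import numpy as np
from pydantic import BaseModel, model_validator

from .waveforms import CardiacState

#: lesion-vessel distribution (LAD, RCA, LCx, ramus intermedius)
LESION_VESSELS = ("LAD", "RCA", "LCx", "ramus")
LESION_PROBS = (0.62, 0.23, 0.112, 0.038)

#: descriptive statistics of the emulated cohort
AGE_MEAN, AGE_SD, AGE_RANGE = 79.6, 10.1, (50.0, 89.0)
LVEF_MEAN, LVEF_SD, LVEF_RANGE = 0.578, 0.066, (0.45, 0.70)
DEGREE_MEAN, DEGREE_SD, DEGREE_RANGE = 0.568, 0.0853, (0.40, 0.71)
LENGTH_MEAN, LENGTH_SD, LENGTH_RANGE = 15.1, 4.36, (8.0, 23.0)
SV_MEAN, SV_SD = 79.1, 17.0
ET_MEAN, ET_SD = 336.0, 27.3
PSYS_MEAN, PSYS_SD = 141.0, 19.2
PDIA_MEAN, PDIA_SD = 78.5, 10.2
#: log-normal valve areas matched to median [IQR] 0.60 [0.542, 0.700] pre
#: and 2.40 [2.17, 2.80] post (sigma = ln(q75/q25)/(2*0.6745))
AVA_PRE_MEDIAN, AVA_PRE_SIGMA = 0.60, 0.190
AVA_POST_MEDIAN, AVA_POST_SIGMA = 2.40, 0.189
#: paired pre→post changes: mean shifts from the cohort tables, spreads are
#: generator choices (paired SDs are not derivable from marginal tables)
D_SV_MEAN, D_SV_SD = 2.31, 3.0
D_ET_MEAN, D_ET_SD = -83.9, 15.0
D_PSYS_MEAN, D_PSYS_SD = 2.04, 6.0
D_PDIA_MEAN, D_PDIA_SD = -0.231, 3.0
#: heart rate is not reported; a resting TAVI-age population default
HR_MEAN, HR_SD, HR_RANGE = 70.0, 7.0, (55.0, 85.0)
D_HR_SD = 4.0
#: LV end-diastolic pressure (elevated in pressure-overload hypertrophy)
LVEDP_MEAN, LVEDP_SD, LVEDP_RANGE = 16.0, 4.0, (8.0, 28.0)
#: tricuspid regurgitation velocity, m/s
TR_MEAN, TR_SD, TR_RANGE = 2.5, 0.3, (1.8, 3.2)
#: default branch radius scale (cm) with mild anatomic variability
RADIUS_JITTER_SD = 0.05
#: synthetic invasive-FFR channel: percentage bias and SD of the
#: model-vs-invasive percentage difference
INVASIVE_BIAS_PCT = -1.486
INVASIVE_SD_PCT = 1.938

COMORBIDITY_PROBS = {
    "hypertension": 0.92, "dyslipidemia": 0.77, "diabetes": 0.23,
    "smoking": 0.31, "ckd": 0.15, "lvh": 0.96, "mitral_disease": 0.15,
    "cad_history": 0.15,
}


class VirtualPatient(BaseModel):
    """One synthetic patient: lesion, anatomy, and paired cardiac states."""

    id: str
    age: float
    lvef: float
    lesion_vessel: str
    stenosis_degree: float
    stenosis_length: float      # mm
    pre: CardiacState
    post: CardiacState
    branch_radii: dict
    rap: float = 5.0            # right atrial pressure, mmHg
    comorbidities: dict = {}    # inert cohort-realism fields

    @model_validator(mode="after")
    def _check(self):
        if not DEGREE_RANGE[0] <= self.stenosis_degree <= DEGREE_RANGE[1]:
            raise ValueError("stenosis degree outside the cohort range")
        if not LENGTH_RANGE[0] <= self.stenosis_length <= LENGTH_RANGE[1]:
            raise ValueError("stenosis length outside the cohort range")
        if self.lesion_vessel not in LESION_VESSELS:
            raise ValueError(f"unknown lesion vessel {self.lesion_vessel!r}")
        if not self.post.ejection_time < self.pre.ejection_time:
            raise ValueError("post-AVR ejection time must shorten")
        if not self.post.aortic_valve_area > self.pre.aortic_valve_area:
            raise ValueError("post-AVR valve area must increase")
        return self

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "VirtualPatient":
        return cls.model_validate(json.loads(text))



@lru_cache(maxsize=64)
def _truncnorm_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated-normal mean equals ``mean``.

    Without this correction an asymmetric truncation window (e.g. an age cap
    within one SD of the mean) would shift the sample mean away from the
    reported cohort value.
    """
    from scipy.optimize import brentq
    from scipy.stats import truncnorm as tn

    def err(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return tn.mean(a, b, loc=loc, scale=sd) - mean

    span = max(hi - lo, sd)
    try:
        return float(brentq(err, mean - span, mean + span, xtol=1e-9))
    except ValueError:
        return mean


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Truncated normal by rejection, mean-matched under truncation."""
    loc = _truncnorm_loc(mean, sd, lo, hi)
    for _ in range(1000):
        x = rng.normal(loc, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def lv_peak_pressure(state_sv: float, state_et_ms: float, ava: float,
                     p_sys: float) -> float:
    """LV systolic peak = aortic systolic + mean transvalvular gradient.

    The gradient follows the simplified Bernoulli relation 4·v² on the mean
    systolic jet velocity v = (SV/ET)/AVA (converted to m/s).
    """
    v = (state_sv / (state_et_ms / 1000.0)) / ava / 100.0  # m/s
    return p_sys + 4.0 * v * v


def sample_patient(rng: np.random.Generator | int, pid: str = "P000") -> VirtualPatient:
    """Draw one virtual patient from the cohort distributions."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    age = _truncnorm(rng, AGE_MEAN, AGE_SD, *AGE_RANGE)
    lvef = _truncnorm(rng, LVEF_MEAN, LVEF_SD, *LVEF_RANGE)
    vessel = str(rng.choice(LESION_VESSELS, p=np.array(LESION_PROBS) / sum(LESION_PROBS)))
    degree = _truncnorm(rng, DEGREE_MEAN, DEGREE_SD, *DEGREE_RANGE)
    length = _truncnorm(rng, LENGTH_MEAN, LENGTH_SD, *LENGTH_RANGE)

    hr = _truncnorm(rng, HR_MEAN, HR_SD, *HR_RANGE)
    sv = _truncnorm(rng, SV_MEAN, SV_SD, 40.0, 130.0)
    et = _truncnorm(rng, ET_MEAN, ET_SD, 250.0, 430.0)
    p_sys = _truncnorm(rng, PSYS_MEAN, PSYS_SD, 95.0, 200.0)
    p_dia = _truncnorm(rng, PDIA_MEAN, PDIA_SD, 45.0, min(p_sys - 25.0, 110.0))
    p_mean = p_dia + (p_sys - p_dia) / 3.0 + rng.normal(0.0, 1.5)
    p_mean = float(min(max(p_mean, p_dia + 2.0), p_sys - 2.0))
    ava = float(AVA_PRE_MEDIAN * np.exp(rng.normal(0.0, AVA_PRE_SIGMA)))
    lvedp = _truncnorm(rng, LVEDP_MEAN, LVEDP_SD, *LVEDP_RANGE)
    tr = _truncnorm(rng, TR_MEAN, TR_SD, *TR_RANGE)

    pre = CardiacState(
        heart_rate=hr, stroke_volume=sv, ejection_time=et,
        aortic_valve_area=ava, p_sys=p_sys, p_dia=p_dia, p_mean=p_mean,
        lv_peak=lv_peak_pressure(sv, et, ava, p_sys), lv_edp=lvedp,
        tr_velocity=tr)

    # paired post-AVR state
    hr_post = _truncnorm(rng, hr, D_HR_SD, *HR_RANGE)
    sv_post = max(sv + rng.normal(D_SV_MEAN, D_SV_SD), 40.0)
    et_post = min(max(et + rng.normal(D_ET_MEAN, D_ET_SD), 180.0), et - 20.0)
    p_sys_post = _truncnorm(rng, p_sys + D_PSYS_MEAN, D_PSYS_SD, 95.0, 200.0)
    p_dia_post = _truncnorm(rng, p_dia + D_PDIA_MEAN, D_PDIA_SD, 45.0,
                            min(p_sys_post - 25.0, 110.0))
    p_mean_post = p_dia_post + (p_sys_post - p_dia_post) / 3.0 + rng.normal(0.0, 1.5)
    p_mean_post = float(min(max(p_mean_post, p_dia_post + 2.0), p_sys_post - 2.0))
    ava_post = float(AVA_POST_MEDIAN * np.exp(rng.normal(0.0, AVA_POST_SIGMA)))
    ava_post = max(ava_post, ava + 0.2)

    post = CardiacState(
        heart_rate=hr_post, stroke_volume=sv_post, ejection_time=et_post,
        aortic_valve_area=ava_post, p_sys=p_sys_post, p_dia=p_dia_post,
        p_mean=p_mean_post,
        lv_peak=lv_peak_pressure(sv_post, et_post, ava_post, p_sys_post),
        lv_edp=lvedp, tr_velocity=tr)

    from .network import DEFAULT_RADII
    radii = {name: float(r * np.exp(rng.normal(0.0, RADIUS_JITTER_SD)))
             for name, r in DEFAULT_RADII.items()}
    comorbidities = {k: bool(rng.random() < p) for k, p in COMORBIDITY_PROBS.items()}

    return VirtualPatient(
        id=pid, age=age, lvef=lvef, lesion_vessel=vessel,
        stenosis_degree=degree, stenosis_length=length,
        pre=pre, post=post, branch_radii=radii, comorbidities=comorbidities)


def generate_cohort(n: int = 26, seed: int = 0) -> list:
    """Draw ``n`` independent patients from one seeded stream."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    return [sample_patient(rng, pid=f"P{i:03d}") for i in range(n)]


def synth_invasive_ffr(model_ffr: float, rng: np.random.Generator | int,
                       bias_pct: float = INVASIVE_BIAS_PCT,
                       noise_sd_pct: float = INVASIVE_SD_PCT) -> float:
    """Synthetic invasive FFR: the model value plus a percentage-scale
    measurement difference, clipped to (0, 1.1]."""
    if not 0 < model_ffr <= 1:
        raise ValueError("model_ffr must lie in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.normal(bias_pct, noise_sd_pct) / 100.0
    return float(min(max(model_ffr * (1.0 + eps), 1e-6), 1.1))


def reference_patient(degree: float = 0.57, length: float = 15.0,
                      lesion_vessel: str = "LAD") -> VirtualPatient:
    """The cohort-mean patient: table-mean pre/post states, default radii.

    Useful as a deterministic test subject (no sampling involved).
    """
    pre = CardiacState(
        heart_rate=70.0, stroke_volume=SV_MEAN, ejection_time=ET_MEAN,
        aortic_valve_area=0.6, p_sys=PSYS_MEAN, p_dia=PDIA_MEAN, p_mean=99.0,
        lv_peak=lv_peak_pressure(SV_MEAN, ET_MEAN, 0.6, PSYS_MEAN),
        lv_edp=LVEDP_MEAN, tr_velocity=TR_MEAN)
    post = CardiacState(
        heart_rate=70.0, stroke_volume=81.4, ejection_time=252.0,
        aortic_valve_area=2.4, p_sys=143.0, p_dia=78.3, p_mean=99.8,
        lv_peak=lv_peak_pressure(81.4, 252.0, 2.4, 143.0),
        lv_edp=LVEDP_MEAN, tr_velocity=TR_MEAN)
    return VirtualPatient(
        id="REF", age=AGE_MEAN, lvef=LVEF_MEAN, lesion_vessel=lesion_vessel,
        stenosis_degree=degree, stenosis_length=length,
        pre=pre, post=post, branch_radii={})
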