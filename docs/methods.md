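# Methods

`coroflow` is a reduced-order (0-D / lumped-parameter) model of the
aorto-coronary circulation in patients with severe aortic stenosis (AS),
built to analyse how transcatheter aortic valve replacement (TAVI/AVR)
changes coronary physiology indices (FFR, iFR, CFR) and wall-shear-stress
metrics (TAWSS, OSI, high-WSS fraction) across a cohort.

## Circulation model

The network has one aortic root node fed by a prescribed inflow waveform,
one systemic three-element Windkessel outlet (proximal resistance Rp,
compliance C, distal resistance Rd, reference pressure 0 mmHg), and one
epicardial branch per coronary vessel.  The default tree is right-dominant:
LM → (LAD, LCx) plus an RCA off the root; a ramus intermedius branch is
instantiated only for patients whose lesion sits on it.  Each branch is a
series chain of Poiseuille conduit resistances (the LM trunk resistance is
folded into each left branch's chain; the error of counting its ~0.1 mmHg
drop per-branch instead of on the summed left flow is negligible), an
optional stenosis element, and a coronary outlet Windkessel:
small-artery resistance Ra, arterial compliance Ca, microcirculatory
resistance Ramicro, intramyocardial compliance Cim compressed by the
intramyocardial pressure Pim(t), and venous resistance Rv draining to
0 mmHg.  Left branches receive an LV-derived Pim, the RCA an RV-derived
one.  Inertial elements are omitted (the element set contains only
resistances and compliances).

The stenosis follows a Young–Tsai-type law

ΔP = R_visc·q + kt·(ρ/2A₀²)·(A₀/A_s − 1)²·q·|q|,

with R_visc the Poiseuille resistance of the throat, A₀/A_s the reference
and throat lumen areas from the QCA diameter reduction, and kt = 1.52 by
default.  Blood is Newtonian with ρ = 1.06 g/cm³ and μ = 0.04 P; all
internal computation is CGS, with mmHg (1 mmHg = 1333.22 dyn/cm²) at the
interfaces and Pa for wall shear.

State variables are the capacitor pressures (systemic node plus Ca and Cim
nodes per branch); the aortic pressure is algebraic, obtained at every
instant by a scalar Newton solve of flow balance (the stenosis law is
inverted in closed form).  The Cim node integrates d(P_cim − Pim)/dt, so
Pim acts as an external pressure source.  Integration uses LSODA with
rtol 1e-6, output interpolated on a fixed 1 ms grid; results are read from
the final cycle of a 7-cycle run.  Warm initialization places each
capacitor at its quasi-static end-diastolic estimate, which brings the
cycle-to-cycle periodicity residual (max relative change of cycle-mean
nodal pressures) below 1% by cycle 7.  From zero initial conditions the
same residual needs ~10 cycles: the tuned systemic time constant
Rd·C ≈ 1.9 s (a physiologic total arterial compliance of ~1.9 mL/mmHg)
cannot settle an empty capacitor to <1% in 7 cycles — a physical property
of the Windkessel, not a solver choice.

## Driving waveforms

The aortic inflow is a skewed half-sine over systole, rescaled so its
integral equals the stroke volume exactly; the skew exponent grows with
1/AVA, delaying the flow peak for stenotic valves (the late-peaking AS
ejection profile).  LV and RV pressures use a smooth rise–plateau–decay
template (sin to the power 1 — a rounded trapezoid, since
pressure-overloaded ventricles hold near-peak pressure through ejection)
spanning the ejection time plus 120 ms of isovolumic phases, shifted 60 ms
earlier than ejection onset (isovolumic contraction).  That lead is what
produces the early-systolic coronary flow suppression characteristic of
high intramyocardial pressure.  The LV peak is the aortic systolic pressure
plus the mean transvalvular gradient 4·v² (simplified Bernoulli on the mean
systolic jet velocity v = (SV/ET)/AVA): ≈ 200 mmHg for the cohort-mean AS
state, ≈ 150 mmHg after valve replacement.  The RV template peak is
4·v_TR² + RAP from the tricuspid regurgitation jet (default RAP 5 mmHg).
Heart rate is a free parameter (default 70/min; the emulated study does not
report it).

## Boundary-condition tuning

Systemic: total resistance starts at mean pressure over the systemic share
of cardiac output, split Rp:Rd = 9:91 (the downstream-dominant 7–11%
convention), compliance at 0.001 cm⁵/dyn.  Short 4-cycle simulations then
iterate: the total resistance is rescaled by the (systolic+diastolic) level
error — pinning the waveform time-mean instead would leave a systematic
offset against the clinical mean-pressure formula — the compliance steps by
0.0002 cm⁵/dyn on the pulse-pressure error, and the proximal fraction moves
in 0.5% steps on the residual systolic error, until both extremes are
within 2 mmHg (default) of target.

Coronary: target flows allocate 4% of cardiac output at rest and the
10–12% adenosine band under stress, split between sides so the left:right
ostial mean-velocity ratio is 3:1 and within a side by Murray's law
(exponent 3).  At rest the outlet resistance of each branch is sized with
the expected stenosis drop subtracted (autoregulation holds resting flow)
and per-branch corrections iterate to the targets (±0.5 pp stop).  Under
maximal hyperemia no such compensation exists: outlets are sized from the
full mean pressure, the stenosis genuinely limits the achieved flow, and
only a global rescale iterates until the total fraction lies inside the
band (stress flow targets quantized to 0.05 cm³/s, resistances to
100 dyn·s/cm⁵).  This asymmetry is what makes FFR and lesion-vessel CFR
decrease monotonically with stenosis degree.  Resistances distribute
Ra:Ramicro:Rv = 0.32:0.52:0.16 at rest and 0.41:0.28:0.31 under stress;
compliances start from 3.6e-5 (left) / 2.5e-5 (right) cm⁵/dyn per side,
distributed by cross-sectional area with Cim 89% / Ca 11%.  Compliance
values are not iterated further (no per-patient ostial pressure curves
exist to fit them against).

## Indices

FFR is the cycle-mean distal/proximal pressure ratio across the lesion
under hyperemia; Pd is sampled immediately distal to the stenosis element
and Pa at the branch ostium.  iFR is the same ratio at rest averaged over
the diastolic wave-free window, defined as 25% into diastole (diastole =
ejection end to cycle end, detected from the prescribed inflow) until 5 ms
before end-diastole.  CFR is hyperemic over resting cycle-mean flow,
reported both for the total coronary tree and for the lesion vessel.

## Wall shear surrogate

The peri-lesion region spans 15 mm upstream of the lesion through the
lesion end, discretized at Δx = 0.25 mm on a raised-cosine radius taper
(throat at mid-lesion).  The attached-flow wall shear is Poiseuille,
4μq/(πr³).  A one-dimensional separable field τ = g(x)·q(t) cannot change
its oscillatory index (no reversal) or its high-WSS element fraction
(threshold and profile scale together) between two states, so the surrogate
adds the physics of the separated post-stenotic jet, gated on separation:
the jet detaches around the flow peak and the following deceleration
(instantaneous flow above ~1.35× its cycle mean, with an absolute
throat-Reynolds floor).  While separated, (i) the boundary layer over the
throat and diverging zone (outside the bubble) is transitionally turbulent,
multiplying the attached shear by up to 3× — the high-WSS patch at and just
distal to the throat; and (ii) the recirculation bubble in the outer half
of the diverging section carries a weak wall shear reversed against the
core flow (10% of the local dynamic pressure) — the source of oscillatory
shear.  The coefficients were set so that the surrogate registers the
separated-flow contrast at all (reattachment shear of the same order as
throat shear, reversal achievable during the diastolic surge), consistent
with three-dimensional post-stenotic flow fields; they are exposed in the
module constants.

The high-WSS fraction counts axial elements whose TAWSS exceeds k = 4
times a reference mean.  The reference defaults to the mean TAWSS of the
healthy upstream segment; referencing the regional mean instead (available
via configuration) bounds the fraction at 1/k = 0.25 by construction —
which is why reported fractions around 0.4–0.6 in this literature must use
an external reference — and makes the paired pre/post change degenerate at
the grid-element level.

Because resting mean flow is pinned by tuning while pre-AVR systole is
suppressed by the high intramyocardial pressure, the pre-AVR diastolic
flow must overshoot: the pre state is more pulsatile by conservation.
All three wall-shear metrics inherit a consistent pre>post contrast from
that surge; this is the model's mechanism for the post-AVR reduction in
OSI, TAWSS and high-WSS exposure.

## Synthetic cohort

Patients are drawn from the descriptive statistics of a severe-AS TAVI
cohort: age ~ truncated normal 79.6 ± 10.1 on [50, 89] (location corrected
so the truncated mean matches), stenosis degree 0.568 ± 0.0853 on
[0.40, 0.71], length 15.1 ± 4.36 mm on [8, 23], lesion vessel categorical
(LAD 62%, RCA 23%, LCx 12%, ramus 3.8%), stroke volume 79.1 ± 17 mL,
ejection time 336 ± 27 ms, AVA log-normal matched to median 0.60
(IQR 0.542–0.700) cm².  The paired post-AVR state shifts ejection time by
−83.9 ms (SD 15), stroke volume by +2.31 mL (SD 3), resamples aortic
pressures with near-zero mean shifts (systolic +2.0 SD 6; diastolic −0.23
SD 3), heart rate by N(0, 4), and redraws AVA log-normal around 2.40 cm².
The paired spreads are generator choices (only marginal tables exist); the
pressure spreads were chosen so the pre/post pressure comparisons come out
non-significant at n = 26, as reported.  Mean aortic pressure is derived
as diastolic + pulse/3 plus small noise.  Branch radii take
literature-typical values (LM 2.25, LAD 1.8, LCx 1.7, RCA 1.7, ramus
1.4 mm) with 5% log-normal anatomic jitter shared between states; lesion
geometry is identical pre/post.  Comorbidity flags are generated for
cohort realism but do not enter the model.  A synthetic "invasive FFR"
channel multiplies the model FFR by 1 + ε with ε ~ N(−1.486, 1.938)%,
clipped to (0, 1.1].

What the generator does NOT emulate: per-state re-measurement of lesion
geometry (real pre/post models are segmented from separate angiograms),
wire-based measurement artefacts, and any 3-D flow feature.  Passing
cohort-level tests therefore demonstrates the internal consistency of the
model chain, not clinical agreement.  One known consequence: with lesion
geometry shared exactly and mean flows pinned by tuning, the small
systematic post-AVR reduction in flow pulsatility propagates into slightly
HIGHER post-AVR iFR (≈ +0.01) and CFR (≈ +0.05) in every patient, which at
n = 26 is statistically significant, whereas clinical studies (with much
larger idiosyncratic re-modeling noise) report these comparisons as
non-significant.  This deviation is deliberate: suppressing it would
require either violating the shared-lesion pairing or inflating generator
noise beyond its physiologic justification.

## Statistics

Each index is compared pre vs post with a paired test gated on the
Shapiro–Wilk normality of the paired differences at α = 0.05 (normal →
paired t; otherwise Wilcoxon signed-rank, zeros excluded).  All-zero
difference vectors return p = 1 by sign-symmetry; constant non-zero
differences are reported as degenerate.  An exact signed-rank p-value by
full 2^n enumeration serves as the small-sample oracle for the production
path.  Agreement between modelled and (synthetic) invasive FFR uses
Bland–Altman on percentage differences of the invasive channel relative to
the model (bias ± 1.96 sample SD), computed on a 10-patient validation
subset.  No multiplicity correction is applied.

## Problem sizes and numerical choices

Default runs use 7 cardiac cycles at 1 ms output resolution per condition
(pre/post × rest/hyperemia), 26 patients per cohort, tuning loops on
4-cycle warm-started simulations; a full cohort completes in a few minutes
on one core.  Tolerances: 2 mmHg on tuned aortic extremes, ±0.5 pp on the
resting coronary fraction, the 10–12% band under stress, ±15% on the
velocity ratio.  Degenerate inputs (zero stroke volume, zero stenosis
degree, missing sides of the tree) fall back to well-defined limits; the
stenosis quadratic inverts smoothly through zero flow.

## Known limitations

The 1-D Poiseuille + separation surrogate produces wall-shear magnitudes
of a few Pa (hyperemic tens of Pa at the throat), below 3-D CFD values for
the same vessels; its OSI levels are likewise smaller than 3-D ones.  The
model has no heart-motion, no wave propagation (0-D), no valve dynamics
beyond the inflow shape and the derived LV load, and venous/reference
pressures are fixed at zero.  Hyperemia is a parameter set (resistance
redistribution and flow targets), not a pharmacokinetic model.
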