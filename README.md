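# coroflow

Reduced-order patient-specific coronary hemodynamics for severe aortic
stenosis (AS): a lumped-parameter (0-D) aorto-coronary circulation with
protocol-faithful boundary-condition tuning, coronary physiology indices
(FFR, iFR, CFR), an axial wall-shear-stress surrogate (TAWSS, OSI,
high-WSS fraction), a synthetic TAVI cohort generator, and the paired
pre/post valve-replacement statistics — so the whole analysis runs with no
clinical data.

**Who it is for.** Cardiovascular modellers who want a desk-scale,
fully-reproducible stand-in for the 3-D CFD pipelines used to study how
transcatheter aortic valve implantation (TAVI/AVR) changes coronary
physiology in patients with coronary lesions.

## Model

The aortic root feeds a systemic RCR Windkessel (Rp–C–Rd) and a
right-dominant coronary tree (LM → LAD/LCx, RCA); each coronary branch is
a Poiseuille conduit plus an optional stenosis element in series with a
coronary outlet Windkessel (Ra, Ca, Ramicro, Cim with intramyocardial
pressure Pim(t), Rv).  The stenosis obeys a Young–Tsai law
ΔP = R_v·q + kt·(ρ/2A₀²)(A₀/A_s − 1)²·q|q|.  Tuning reproduces the
protocol targets: aortic systolic/diastolic pressures within 2 mmHg,
resting coronary flow = 4% of cardiac output, adenosine-stress flow in the
10–12% band with resistances redistributed 0.32:0.52:0.16 → 0.41:0.28:0.31
(Ra:Ramicro:Rv), and a 3:1 left:right ostial velocity ratio.  Indices
follow their standard definitions: FFR = mean Pd/Pa under hyperemia,
iFR = Pd/Pa over the diastolic wave-free period at rest,
CFR = hyperemic/resting flow.  See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
from coroflow.synthetic_cohort import reference_patient
from coroflow.tuning import tune_patient
from coroflow.lumped_solver import assemble, simulate
from coroflow.indices import compute_indices
from coroflow.wss import compute_wss_report

patient = reference_patient()            # cohort-mean AS patient, LAD lesion 57%
net_rest, _ = tune_patient(patient, "pre", "rest")
net_hyper, _ = tune_patient(patient, "pre", "hyper")
sim_rest = simulate(assemble(net_rest))      # 7 cardiac cycles
sim_hyper = simulate(assemble(net_hyper))
idx = compute_indices(sim_rest, sim_hyper, patient.pre, "LAD")
wss = compute_wss_report(sim_rest, "LAD")
print(f"FFR={idx.ffr:.3f} iFR={idx.ifr:.3f} CFR={idx.cfr:.2f}")
print(f"TAWSS={wss.tawss_mean:.2f} Pa  OSI={wss.osi_mean:.4f}  high-WSS={wss.high_frac:.3f}")
```

prints

```
FFR=0.690 iFR=0.871 CFR=2.60
TAWSS=5.37 Pa  OSI=0.0086  high-WSS=0.233
```

The tuned pre-AVR state reaches 140.6/78.2 mmHg aortic pressure (targets
141/78.5), a resting coronary share of 4.08% of cardiac output, a
hyperemic share of 10.6%, and a left:right ostial velocity ratio of 2.99.
FFR 0.69 across the 57% LAD lesion marks it hemodynamically significant
(threshold 0.80); the lesion-vessel CFR is 2.12.  `high-WSS=0.233` means
23% of the peri-lesion wall elements see a time-averaged shear above four
times the healthy upstream level.

A full cohort (generation → tuning → 4 simulations/patient → indices, WSS
and paired statistics) runs from the command line:

```bash
coroflow run-all --n 26 --seed 0 --out results/cohort
coroflow cohort --n 26 --seed 0 --out cohort/          # patients as JSON
coroflow indices --config cohort/P000.json --state pre
```

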