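"""Full-cohort orchestration.

cohort generation → per-patient boundary-condition tuning → rest and
hyperemia simulations, pre and post valve replacement → physiology indices
and wall-shear reports → paired statistics and agreement tables.  Per-
patient failures are recorded and skipped rather than aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .indices import IndexSet, compute_indices
from .lumped_solver import assemble, simulate
from .stats import bland_altman, paired_table
from .synthetic_cohort import generate_cohort, synth_invasive_ffr
from .tuning import tune_patient
from .wss import DEFAULT_DX, DEFAULT_K, compute_wss_report

log = logging.getLogger("coroflow")


class RunConfig(BaseModel):
    """Configuration of a full cohort run."""

    n_patients: int = 26
    seed: int = 0
    n_cycles: int = 7
    dt: float = 1.0e-3
    wss_dx: float = DEFAULT_DX
    wss_k: float = DEFAULT_K
    invasive_subset: int = 10       # patients with a synthetic invasive FFR
    alpha: float = 0.05
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclasses.dataclass
class PatientResult:
    patient_id: str
    state: str
    indices: IndexSet
    wss: object
    converged: dict
    sim_rest: object = None
    sim_hyper: object = None


def run_patient_state(patient, state: str, config: RunConfig,
                      keep_sims: bool = False) -> PatientResult:
    """Tune and simulate one patient-state (rest + hyperemia), then compute
    indices and the wall-shear report of the lesion vessel at rest."""
    net_rest, rep_r = tune_patient(patient, state, "rest")
    net_hyper, rep_h = tune_patient(patient, state, "hyper")
    sim_rest = simulate(assemble(net_rest), n_cycles=config.n_cycles, dt=config.dt)
    sim_hyper = simulate(assemble(net_hyper), n_cycles=config.n_cycles, dt=config.dt)
    idx = compute_indices(sim_rest, sim_hyper, getattr(patient, state),
                          patient.lesion_vessel)
    wss = compute_wss_report(sim_rest, patient.lesion_vessel,
                             dx=config.wss_dx, k=config.wss_k)
    converged = {f"{k}_{m}": r.converged
                 for m, reps in (("rest", rep_r), ("hyper", rep_h))
                 for k, r in reps.items()}
    return PatientResult(patient_id=patient.id, state=state, indices=idx,
                         wss=wss, converged=converged,
                         sim_rest=sim_rest if keep_sims else None,
                         sim_hyper=sim_hyper if keep_sims else None)


def cohort_frame(results: list) -> pd.DataFrame:
    """Tidy per-patient-state frame of indices and WSS summaries."""
    rows = []
    for r in results:
        row = dict(patient=r.patient_id, state=r.state,
                   ffr=r.indices.ffr, ifr=r.indices.ifr,
                   pd_pa_rest=r.indices.pd_pa_rest, cfr=r.indices.cfr,
                   cfr_lesion=r.indices.cfr_lesion,
                   q_rest=r.indices.q_rest, q_hyper=r.indices.q_hyper,
                   pa_mean=r.indices.pa_mean, pd_mean=r.indices.pd_mean,
                   tawss_mean=r.wss.tawss_mean, tawss_median=r.wss.tawss_median,
                   osi_mean=r.wss.osi_mean, high_frac=r.wss.high_frac)
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns tables and a manifest.

    Output keys: ``cohort`` (tidy per-state frame), ``paired`` (pre/post
    test table), ``agreement`` (Bland–Altman of model vs synthetic invasive
    FFR), ``failures``, ``manifest``.
    """
    t_start = time.time()
    patients = generate_cohort(config.n_patients, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    results, failures, timings = [], [], {}
    for p in patients:
        t0 = time.time()
        for state in ("pre", "post"):
            try:
                results.append(run_patient_state(p, state, config))
            except Exception as exc:  # per-patient failures never abort
                log.warning("patient %s %s failed: %s", p.id, state, exc)
                failures.append(dict(patient=p.id, state=state, error=str(exc)))
        timings[p.id] = round(time.time() - t0, 2)
    frame = cohort_frame(results)

    complete = frame.groupby("patient")["state"].nunique()
    paired_ids = complete[complete == 2].index
    paired_frame = frame[frame.patient.isin(paired_ids)]
    paired = (paired_table(paired_frame, alpha=config.alpha)
              if len(paired_ids) >= 3 else pd.DataFrame())

    # agreement on the validation subset: pre-AVR model FFR vs synthetic
    # invasive FFR
    pre_rows = frame[frame.state == "pre"].sort_values("patient")
    sub = pre_rows.head(config.invasive_subset)
    agreement = None
    if len(sub) >= 2:
        model = sub.ffr.to_numpy()
        invasive = np.array([synth_invasive_ffr(f, rng) for f in model])
        # convention: percentage difference of the invasive channel relative
        # to the model value (negative bias = invasive reads lower)
        agreement = bland_altman(model, invasive, mode="percent")

    manifest = dict(version=__version__, seed=config.seed,
                    config=config.model_dump(), config_hash=config.config_hash(),
                    n_patients=config.n_patients,
                    n_completed_states=len(results),
                    completion_fraction=len(results) / (2 * config.n_patients),
                    wall_time_s=round(time.time() - t_start, 2),
                    per_patient_s=timings)
    out = dict(cohort=frame, paired=paired, agreement=agreement,
               failures=failures, manifest=manifest)
    if config.out_dir:
        write_outputs(out, config)
    return out


def write_outputs(out: dict, config: RunConfig) -> None:
    d = Path(config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    out["cohort"].assign(config_hash=h).to_csv(d / "cohort_indices.csv", index=False)
    if len(out["paired"]):
        out["paired"].assign(config_hash=h).to_csv(d / "paired_tests.csv", index=False)
    if out["agreement"] is not None:
        ba = out["agreement"]
        pd.DataFrame(dict(mean=ba.means, diff_pct=ba.differences)).assign(
            config_hash=h).to_csv(d / "bland_altman.csv", index=False)
        summary = dict(bias=ba.bias, sd=ba.sd, loa_low=ba.loa_low,
                       loa_high=ba.loa_high, pct_within_loa=ba.pct_within_loa)
        (d / "bland_altman.json").write_text(json.dumps(summary, indent=2))
        from .stats import bland_altman_plot
        bland_altman_plot(ba, d / "bland_altman.png",
                          title="model vs synthetic invasive FFR")
    (d / "manifest.json").write_text(json.dumps(out["manifest"], indent=2))
    if out["failures"]:
        (d / "failures.json").write_text(json.dumps(out["failures"], indent=2))
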