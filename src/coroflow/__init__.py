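"""coroflow: reduced-order patient-specific coronary hemodynamics.

Lumped-parameter aorto-coronary circulation with boundary-condition tuning,
coronary physiology indices (FFR, iFR, CFR), axial wall-shear-stress
surrogates, a synthetic aortic-stenosis cohort generator, and paired
pre/post valve-replacement statistics.
"""

__version__ = "0.1.0"

from .network import NetworkSpec, build_network, murray_split
from .waveforms import CardiacState, Waveform, make_inflow

__all__ = [
    "CardiacState", "NetworkSpec", "Waveform", "build_network",
    "make_inflow", "murray_split", "__version__",
]


def __getattr__(name):
    # convenience lazy access to the heavier submodule entry points
    if name in ("tune_patient",):
        from .tuning import tune_patient
        return tune_patient
    if name in ("simulate", "assemble"):
        from . import lumped_solver
        return getattr(lumped_solver, name)
    if name == "run_all":
        from .pipeline import run_all
        return run_all
    raise AttributeError(name)
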