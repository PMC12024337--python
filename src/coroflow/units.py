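"""Unit conventions.

All internal computation is in CGS (cm, g, s, dyn); pressures cross the user
interface in mmHg and wall shear stress is reported in Pa.
"""

MMHG_TO_DYN_CM2 = 1333.22
DYN_CM2_TO_MMHG = 1.0 / MMHG_TO_DYN_CM2
DYN_CM2_TO_PA = 0.1
PA_TO_DYN_CM2 = 10.0


def mmhg_to_dyn(p: float) -> float:
    return p * MMHG_TO_DYN_CM2


def dyn_to_mmhg(p: float) -> float:
    return p * DYN_CM2_TO_MMHG
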