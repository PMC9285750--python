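"""Unit conventions.

All internal computation is in CGS: lengths in cm, time in s, mass in g,
pressure in dyn/cm^2, flow in cm^3/s, resistance in dyn·s/cm^5 and
compliance in cm^5/dyn.  Millimetres of mercury appear only at I/O
boundaries, converted with the fixed constant below.
"""

#: 1 mmHg in dyn/cm^2 (bit-exact constant used everywhere in the package).
MMHG_TO_DYN_CM2 = 1333.22


def mmhg_to_cgs(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to dyn/cm^2."""
    return p_mmhg * MMHG_TO_DYN_CM2


def cgs_to_mmhg(p_dyn_cm2: float) -> float:
    """Convert a pressure from dyn/cm^2 to mmHg."""
    return p_dyn_cm2 / MMHG_TO_DYN_CM2
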