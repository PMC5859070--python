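"""Unit conversions.

Everything inside the package is SI (m, s, Pa, m³/s). Millimetres of
mercury and millimetres appear only at the interface; the single
conversion constant lives here: 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import numpy as np

MMHG_TO_PA: float = 133.322
"""Pressure of one millimetre of mercury in pascal."""


def mmhg_to_pa(p_mmhg):
    """Convert pressure from mmHg to Pa."""
    return np.multiply(p_mmhg, MMHG_TO_PA)


def pa_to_mmhg(p_pa):
    """Convert pressure from Pa to mmHg."""
    return np.divide(p_pa, MMHG_TO_PA)


def mm_to_m(x_mm):
    """Convert length from millimetres to metres."""
    return np.multiply(x_mm, 1e-3)


def mm2_to_m2(a_mm2):
    """Convert area from mm² to m²."""
    return np.multiply(a_mm2, 1e-6)
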