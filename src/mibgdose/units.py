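"""Physical constants and unit conversions used across the toolkit.

Canonical internal units: activity in MBq, time in hours, absorbed dose in
Gy, body mass in kg, organ/lesion mass in g, count rates in cps.  S values
circulate in two unit systems and every conversion between them is exact.
"""

from __future__ import annotations

import math

#: 131I physical half-life, days (standard decay data).
I131_HALF_LIFE_D: float = 8.0252

#: 131I physical half-life, hours.
I131_HALF_LIFE_H: float = I131_HALF_LIFE_D * 24.0  # 192.6048 h

#: 131I physical decay constant, 1/h.
I131_LAMBDA_PER_H: float = math.log(2.0) / I131_HALF_LIFE_H

#: Exact conversion: 1 mGy/(MBq·s) = 3.6 Gy/(MBq·h).
MGY_MBQ_S_TO_GY_MBQ_H: float = 3.6

#: Unit tags accepted for S values.
S_UNIT_GY_MBQ_H = "Gy/(MBq·h)"
S_UNIT_MGY_MBQ_S = "mGy/(MBq·s)"
S_UNITS = (S_UNIT_GY_MBQ_H, S_UNIT_MGY_MBQ_S)


def decay_factor(elapsed_h: float, half_life_h: float = I131_HALF_LIFE_H) -> float:
    """Fraction of activity remaining after ``elapsed_h`` hours."""
    return 2.0 ** (-elapsed_h / half_life_h)


def decay_correct(activity: float, elapsed_h: float,
                  half_life_h: float = I131_HALF_LIFE_H) -> float:
    """Decay-correct an assayed activity forward by ``elapsed_h`` hours.

    Positive ``elapsed_h`` moves the reference time later (activity decays);
    negative moves it earlier.
    """
    return activity * decay_factor(elapsed_h, half_life_h)
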