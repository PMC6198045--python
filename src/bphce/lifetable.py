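"""Background all-cause mortality stand-in.

The model needs an annual all-cause mortality schedule for Hong Kong men
from the cohort start age onwards.  The published life table is not part
of the model inputs shipped here, so a calibrated Gompertz stand-in is
used instead: the adult human force of mortality is well described by

    mu(a) = b * exp(c * a)

with a log-slope ``c`` around 0.09/year.  The level ``b`` is calibrated
so that the cumulative background mortality of the starting cohort over
the first four model years matches a target consistent with the overall
4-year death risk the model is meant to reproduce (~5-6% at start age
66, net of surgical deaths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["LifeTable", "build_life_table_standin", "gompertz_annual_probability",
           "DEFAULT_GOMPERTZ_SLOPE", "DEFAULT_CALIBRATION_TARGET"]

#: Gompertz log-slope c (1/year); typical adult human value.
DEFAULT_GOMPERTZ_SLOPE = 0.09

#: Default 4-year cumulative background mortality of the starting cohort:
#: the overall printed 4-year death risk (0.0577) less the ~0.002 surgical
#: (30-day post-TURP) deaths the disease model itself generates.
DEFAULT_CALIBRATION_TARGET = 0.055

MAX_AGE = 110


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality probability per integer age.

    Probabilities are in [0, 1] and non-decreasing over the supported
    range; ages beyond the last supported age reuse the final value.
    """

    start_age: int
    annual_prob: tuple  # annual_prob[i] = q(start_age + i)

    def prob_at(self, age: float) -> float:
        """Annual death probability at (integer part of) ``age``."""
        idx = int(np.floor(age)) - self.start_age
        if idx < 0:
            raise ValueError(f"age {age} below life-table support ({self.start_age})")
        idx = min(idx, len(self.annual_prob) - 1)
        return self.annual_prob[idx]

    def cumulative_mortality(self, from_age: int, years: int) -> float:
        """Probability of dying within ``years`` years starting at ``from_age``."""
        surv = 1.0
        for k in range(years):
            surv *= 1.0 - self.prob_at(from_age + k)
        return 1.0 - surv


def gompertz_annual_probability(age: float, b: float, c: float) -> float:
    """Annual death probability from a Gompertz hazard mu(a) = b*exp(c*a).

    q(a) = 1 - exp(-H) with H = (b/c)*(exp(c*(a+1)) - exp(c*a)) for c > 0,
    and H = b for c = 0.
    """
    if b < 0:
        raise ValueError("Gompertz level b must be >= 0")
    if b == 0:
        return 0.0
    if c == 0:
        cum = b
    else:
        cum = (b / c) * (np.exp(c * (age + 1.0)) - np.exp(c * age))
    return float(min(1.0, 1.0 - np.exp(-cum)))


def _four_year_cumulative(b: float, c: float, start_age: int) -> float:
    surv = 1.0
    for k in range(4):
        surv *= 1.0 - gompertz_annual_probability(start_age + k, b, c)
    return 1.0 - surv


def build_life_table_standin(
    start_age: int = 66,
    calibration_target: float = DEFAULT_CALIBRATION_TARGET,
    slope: float = DEFAULT_GOMPERTZ_SLOPE,
    max_age: int = MAX_AGE,
) -> LifeTable:
    """Build the calibrated Gompertz life-table stand-in.

    Parameters
    ----------
    start_age
        Cohort entry age; the model population is men >= 50.
    calibration_target
        4-year cumulative background mortality of a cohort entering at
        ``start_age``.  ``0`` yields an immortal (all-zero) table.
    slope
        Gompertz log-slope c (per year of age).
    """
    if start_age < 50:
        raise ValueError("start_age must be >= 50 (model population is men >= 50)")
    if not 0.0 <= calibration_target < 1.0:
        raise ValueError("calibration_target must be in [0, 1)")

    if calibration_target == 0.0:
        b = 0.0
    else:
        # q is monotone in b; bracket then root-find b.
        hi = 1e-6
        while _four_year_cumulative(hi, slope, start_age) < calibration_target:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("calibration target unreachable with positive b, c")
        b = brentq(
            lambda x: _four_year_cumulative(x, slope, start_age) - calibration_target,
            0.0, hi, xtol=1e-16, rtol=1e-14,
        )

    ages = range(start_age, max_age + 1)
    probs = tuple(gompertz_annual_probability(a, b, slope) for a in ages)
    return LifeTable(start_age=start_age, annual_prob=probs)


def constant_life_table(start_age: int, annual_prob: float, max_age: int = MAX_AGE) -> LifeTable:
    """Flat mortality schedule; used by toy fixtures with closed forms."""
    if not 0.0 <= annual_prob <= 1.0:
        raise ValueError("annual_prob must be in [0, 1]")
    n = max_age - start_age + 1
    return LifeTable(start_age=start_age, annual_prob=(annual_prob,) * n)
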