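"""Incremental cost-effectiveness arithmetic and decision rules.

The comparison is always combination therapy minus monotherapy:
``ICER = (C_comb - C_mono) / (E_comb - E_mono)`` in US$ per QALY gained.
A strategy that is cheaper and more effective is *dominant*; dearer and
less effective is *dominated*.  Willingness-to-pay decisions use the net
monetary benefit ``NMB = WTP * E - C``: incremental NMB > 0 is
equivalent to ICER < WTP whenever the QALY gain is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .parameters import WTP_3X_GDP_PER_CAPITA, WTP_GDP_PER_CAPITA  # noqa: F401
from .simulation import SimulationResult

__all__ = ["ICERResult", "CEPlanePoint", "compute_icer", "net_monetary_benefit",
           "classify_quadrant", "WTP_GDP_PER_CAPITA", "WTP_3X_GDP_PER_CAPITA"]


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]     # numeric iff delta_qaly != 0
    label: str                # "icer" | "dominant" | "dominated" | "undefined"
    combination: Optional[SimulationResult] = None
    monotherapy: Optional[SimulationResult] = None


@dataclass(frozen=True)
class CEPlanePoint:
    """A point on the cost-effectiveness plane.

    Exact zeros are assigned to the positive side and flagged as ties.
    """

    delta_cost: float
    delta_qaly: float

    @property
    def quadrant(self) -> str:
        return classify_quadrant(self.delta_cost, self.delta_qaly)

    @property
    def tie(self) -> bool:
        return self.delta_cost == 0.0 or self.delta_qaly == 0.0


def compute_icer(result_combination: SimulationResult,
                 result_monotherapy: SimulationResult) -> ICERResult:
    """Incremental cost per QALY of combination vs monotherapy.

    A zero QALY difference yields ``icer=None`` with label
    ``"undefined"`` rather than an exception.
    """
    rc, rm = result_combination, result_monotherapy
    if rc.horizon_years != rm.horizon_years:
        raise ValueError("arms were run over different horizons")
    dc = rc.total_cost - rm.total_cost
    de = rc.total_qaly - rm.total_qaly
    if de == 0.0:
        icer, label = None, "undefined"
    else:
        icer = dc / de
        if dc <= 0.0 and de > 0.0:
            label = "dominant"
        elif dc >= 0.0 and de < 0.0:
            label = "dominated"
        else:
            label = "icer"
    return ICERResult(delta_cost=dc, delta_qaly=de, icer=icer, label=label,
                      combination=rc, monotherapy=rm)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """``NMB = wtp * qaly - cost`` (US$)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    return wtp * qaly - cost


def classify_quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-effectiveness plane quadrant by sign; zeros count as
    positive (NE by convention for the origin)."""
    if delta_qaly >= 0.0:
        return "NE" if delta_cost >= 0.0 else "SE"
    return "NW" if delta_cost >= 0.0 else "SW"
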