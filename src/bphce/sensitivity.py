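"""Deterministic one-way sensitivity analysis and probabilistic
sensitivity analysis.

OWSA re-runs the deterministic cohort engine with one parameter at a
time set to the low then high bound of its published uncertainty range
and records the ICER at each bound; entries sorted by ICER spread give
the tornado diagram.

PSA is a second-order Monte Carlo: each iteration draws a complete
parameter set from the published beta (probabilities, efficacies) and
gamma (costs) distributions, runs both arms with the deterministic
cohort engine on the same draw, and records the incremental cost and
QALY pair.  The scatter yields cost-effectiveness plane quadrant shares
and, through the net monetary benefit rule, the cost-effectiveness
acceptability curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .economics import compute_icer
from .parameters import (
    ModelParameters,
    ParameterDistribution,
    ParameterRange,
    get_field,
    set_field,
    validate_parameters,
)
from .simulation import run_cohort
from .states import Arm

__all__ = ["TornadoEntry", "TornadoTable", "PSAScatter", "CEACCurve",
           "run_owsa", "sample_psa_parameters", "run_psa", "compute_ceac",
           "quadrant_shares"]

_MAX_RESAMPLE = 1000


# --------------------------------------------------------------------------
# one-way sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float     # NaN when the QALY difference vanished
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class TornadoTable:
    base_icer: float
    entries: tuple  # TornadoEntry, sorted by spread descending


def _icer_at(params: ModelParameters, target: str, value: float) -> float:
    trial = set_field(params, target, value)
    rep = validate_parameters(trial)
    if not rep.ok:
        raise ValueError(f"range for {target} produces invalid parameters:\n{rep}")
    res = compute_icer(run_cohort(trial, Arm.COMBINATION)[0],
                       run_cohort(trial, Arm.MONOTHERAPY)[0])
    return res.icer if res.icer is not None else float("nan")


def run_owsa(params: ModelParameters,
             ranges: Optional[Sequence[ParameterRange]] = None,
             horizon: Optional[int] = None) -> TornadoTable:
    """One-way sensitivity analysis over the published ranges.

    All other parameters stay at base; the deterministic cohort engine
    is used throughout, so the output is reproducible bit-for-bit.
    """
    if horizon is not None:
        params = replace(params, settings=replace(params.settings, horizon_years=horizon))
    if ranges is None:
        ranges = params.owsa_ranges

    base = compute_icer(run_cohort(params, Arm.COMBINATION)[0],
                        run_cohort(params, Arm.MONOTHERAPY)[0])
    base_icer = base.icer if base.icer is not None else float("nan")

    entries = []
    for r in ranges:
        base_value = get_field(params, r.target)
        if not r.low <= base_value <= r.high:
            raise ValueError(
                f"range for {r.target}: base {base_value} outside [{r.low}, {r.high}]")
        entries.append(TornadoEntry(
            parameter=r.target, low=r.low, high=r.high,
            icer_at_low=_icer_at(params, r.target, r.low),
            icer_at_high=_icer_at(params, r.target, r.high),
        ))
    entries.sort(key=lambda e: (-e.spread if np.isfinite(e.spread) else np.inf,
                                e.parameter))
    return TornadoTable(base_icer=base_icer, entries=tuple(entries))


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------

def _draw_one(rng: np.random.Generator, dist: ParameterDistribution) -> float:
    if dist.family == "beta":
        return float(rng.beta(dist.shape_alpha, dist.shape_beta_or_rate))
    if dist.family == "gamma":
        return float(rng.gamma(dist.shape_alpha, 1.0 / dist.rate))
    raise ValueError(f"unknown distribution family {dist.family!r} for {dist.target}")


def sample_psa_parameters(distributions: Sequence[ParameterDistribution],
                          n: int, seed: int,
                          base: Optional[ModelParameters] = None):
    """Draw ``n`` complete parameter sets for the PSA.

    Unsampled fields stay at base.  Draws that violate a model
    invariant (e.g. BPH exits exceeding one) are rejected and redrawn;
    the count of rejections is returned alongside the draws.

    Returns ``(list_of_ModelParameters, n_resampled)``.
    """
    if base is None:
        from .parameters import base_case_parameters
        base = base_case_parameters()
    for d in distributions:
        is_cost = d.target.startswith("costs.")
        if d.family == "beta" and is_cost:
            raise ValueError(f"{d.target}: beta distribution on a cost parameter")
        if d.family == "gamma" and not is_cost:
            raise ValueError(f"{d.target}: gamma distribution on a probability parameter")

    rng = np.random.default_rng(seed)
    # the OWSA range invariants (low <= base <= high) constrain the base
    # case, not sampled sets; a draw only has to be runnable.
    base = replace(base, owsa_ranges=())
    draws, n_resampled = [], 0
    for _ in range(n):
        for attempt in range(_MAX_RESAMPLE):
            trial = base
            for d in distributions:
                trial = set_field(trial, d.target, _draw_one(rng, d))
            if validate_parameters(trial).ok:
                draws.append(trial)
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw a valid parameter set "
                               f"after {_MAX_RESAMPLE} attempts")
    return draws, n_resampled


@dataclass(frozen=True)
class PSAScatter:
    """Paired incremental (cost, QALY) draws from the PSA."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    horizon_years: int
    n_resampled: int = 0

    @property
    def n(self) -> int:
        return len(self.delta_cost)


def run_psa(params: ModelParameters, n: int, horizon: Optional[int] = None,
            seed: int = 0) -> PSAScatter:
    """Second-order Monte Carlo: one deterministic cohort evaluation of
    both arms per parameter draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if horizon is not None:
        params = replace(params, settings=replace(params.settings, horizon_years=horizon))
    draws, n_resampled = sample_psa_parameters(params.psa_distributions, n,
                                               seed=seed, base=params)
    dc = np.empty(n)
    de = np.empty(n)
    for i, drawn in enumerate(draws):
        res = compute_icer(run_cohort(drawn, Arm.COMBINATION)[0],
                           run_cohort(drawn, Arm.MONOTHERAPY)[0])
        dc[i] = res.delta_cost
        de[i] = res.delta_qaly
    return PSAScatter(delta_cost=dc, delta_qaly=de, seed=seed,
                      horizon_years=params.settings.horizon_years,
                      n_resampled=n_resampled)


def quadrant_shares(scatter: PSAScatter) -> dict:
    """Fractions of draws per CE-plane quadrant (zeros count positive)."""
    dc, de = scatter.delta_cost, scatter.delta_qaly
    ne = float(((dc >= 0) & (de >= 0)).mean())
    se = float(((dc < 0) & (de >= 0)).mean())
    nw = float(((dc >= 0) & (de < 0)).mean())
    sw = float(((dc < 0) & (de < 0)).mean())
    return {"NE": ne, "SE": se, "NW": nw, "SW": sw}


@dataclass(frozen=True)
class CEACCurve:
    """Probability that combination therapy is cost-effective per WTP."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp_value: float) -> float:
        idx = np.nonzero(np.isclose(self.wtp, wtp_value))[0]
        if len(idx) == 0:
            raise KeyError(f"WTP {wtp_value} not on the curve grid")
        return float(self.probability[idx[0]])


def compute_ceac(scatter: PSAScatter, wtp_grid: Sequence[float]) -> CEACCurve:
    """CEAC from a PSA scatter: at each WTP, the fraction of draws with
    strictly positive incremental net monetary benefit (an exact zero
    counts as not cost-effective)."""
    if scatter.n == 0:
        raise ValueError("cannot compute a CEAC from an empty scatter")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if (wtp < 0).any():
        raise ValueError("willingness to pay must be >= 0")
    nmb = wtp[:, None] * scatter.delta_qaly[None, :] - scatter.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=wtp, probability=prob)
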