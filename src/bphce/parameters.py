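"""Model inputs: transition probabilities, treatment efficacy, costs,
utilities, economic settings, sensitivity ranges and PSA distributions.

The default (base-case) parameter set is the published Hong Kong payer
analysis: per-cycle disease transitions and resource costs from a Prince
of Wales Hospital BPH cohort and the public hospital formulary, relative
risk reductions for AUR and BPH-related surgery from the 4-year CombAT
trial, and health-state utilities from earlier BPH cost-utility studies.
All costs are 2018 US$; no currency or inflation adjustment is applied.

Parameters load from / save to a flat key-value YAML document whose keys
mirror the dataclass fields (``costs.turp_procedure: 6334``); an empty
document is exactly the base case.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .lifetable import (
    DEFAULT_CALIBRATION_TARGET,
    DEFAULT_GOMPERTZ_SLOPE,
    LifeTable,
    build_life_table_standin,
)

__all__ = [
    "TransitionParameters", "EfficacyParameters", "CostParameters",
    "UtilityParameters", "EconomicSettings", "ParameterDistribution",
    "ParameterRange", "ModelParameters", "ValidationReport",
    "base_case_parameters", "load_parameters", "dump_parameters",
    "validate_parameters", "get_field", "set_field",
]


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionParameters:
    """Per-cycle disease transition probabilities.

    Stay probabilities (``p_bph_stay``, ``p_recovery_stay``,
    ``p_medical_stay``) and ``p_turp_full_recovery`` are carried as
    printed but informational under the default residual-mass rule: the
    canonical self-loop of each row is one minus its explicit exits and
    death mass (see the parameter-mapping document).
    """

    p_bph_stay: float = 0.345
    p_bph_to_turp: float = 0.021
    p_bph_to_aur: float = 0.004
    p_aur_to_turp: float = 0.8
    p_turp_30day_mortality: float = 0.0237
    p_turp_to_medical: float = 0.059
    p_turp_to_repeat: float = 0.059
    p_repeat_turp_mortality: float = 0.0
    p_recovery_stay: float = 0.329
    p_recovery_to_medical: float = 0.0467
    p_medical_to_second_turp: float = 0.036
    p_medical_stay: float = 0.393
    p_medical_to_aur: float = 0.0
    p_repeat_to_medical: float = 0.0025
    p_turp_full_recovery: float = 0.998  # stored, unused by the canonical mapping


@dataclass(frozen=True)
class EfficacyParameters:
    """CombAT relative risk reductions of combination vs monotherapy."""

    rrr_aur: float = 0.676
    rrr_turp: float = 0.706


@dataclass(frozen=True)
class CostParameters:
    """Resource costs, 2018 US$ (annual unless stated per episode)."""

    annual_drug_combination: float = 464.97
    annual_drug_tamsulosin: float = 55.79
    annual_bph_management: float = 471.0
    aur_episode: float = 1312.0
    turp_procedure: float = 6334.0
    annual_medical_intervention: float = 371.0
    #: one-off follow-up cost charged on first entry into recovery; no
    #: published value, defaults to zero.
    recovery_followup: float = 0.0


@dataclass(frozen=True)
class UtilityParameters:
    """QALY weights per health state per year; death is fixed at 0."""

    u_bph: float = 0.876  # severity-weighted single BPH state
    u_aur: float = 0.25
    u_turp: float = 0.25
    u_medical: float = 0.25
    u_recovery: float = 1.0
    u_death: float = 0.0


@dataclass(frozen=True)
class EconomicSettings:
    """Run configuration for the economic evaluation."""

    discount_rate: float = 0.03          # annual, on both costs and QALYs
    horizon_years: int = 4               # 4 = trial duration; 35 = lifetime
    cycles_per_year: int = 1
    cohort_start_age: int = 66
    n_microsim_patients: int = 10_000
    wtp_grid: tuple = ()                 # filled by base_case_parameters
    #: 'annual' applies the printed probabilities per yearly cycle;
    #: 'monthly' reads them as monthly and converts p_a = 1-(1-p_m)^12.
    probability_timescale: str = "annual"
    #: 'residual' assigns each row's leftover mass to the self-loop;
    #: 'printed' renormalises exits around the printed stay values.
    residual_mode: str = "residual"
    half_cycle_correction: bool = False


@dataclass(frozen=True)
class ParameterDistribution:
    """A PSA sampling distribution for one model parameter.

    Beta for probabilities/efficacies, gamma for costs.  When
    ``mean_override`` is set the gamma rate is rederived as
    shape/mean so that the sampled mean matches the published base
    value (the printed rates are inconsistent with the printed means).
    """

    target: str                 # dotted field path, e.g. "costs.turp_procedure"
    family: str                 # "beta" | "gamma"
    shape_alpha: float
    shape_beta_or_rate: float
    mean_override: Optional[float] = None

    @property
    def rate(self) -> float:
        if self.family != "gamma":
            raise AttributeError("rate only defined for gamma distributions")
        if self.mean_override is not None:
            return self.shape_alpha / self.mean_override
        return self.shape_beta_or_rate

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.shape_alpha / (self.shape_alpha + self.shape_beta_or_rate)
        return self.shape_alpha / self.rate


@dataclass(frozen=True)
class ParameterRange:
    """Low/high bounds for one-way sensitivity analysis."""

    target: str
    low: float
    high: float


@dataclass(frozen=True)
class ModelParameters:
    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    efficacy: EfficacyParameters = field(default_factory=EfficacyParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    settings: EconomicSettings = field(default_factory=EconomicSettings)
    life_table: Optional[LifeTable] = None
    psa_distributions: tuple = ()
    owsa_ranges: tuple = ()


# --------------------------------------------------------------------------
# dotted field access (used by OWSA/PSA to retarget single fields)
# --------------------------------------------------------------------------

_BLOCKS = ("transitions", "efficacy", "costs", "utilities", "settings")


def get_field(params: ModelParameters, target: str) -> float:
    """Read a scalar field by dotted path, e.g. ``'efficacy.rrr_aur'``."""
    block, _, name = target.partition(".")
    if block not in _BLOCKS or not name:
        raise KeyError(f"unknown parameter target {target!r}")
    sub = getattr(params, block)
    if not hasattr(sub, name):
        raise KeyError(f"unknown parameter target {target!r}")
    return getattr(sub, name)


def set_field(params: ModelParameters, target: str, value) -> ModelParameters:
    """Return a copy of ``params`` with one dotted field replaced."""
    block, _, name = target.partition(".")
    if block not in _BLOCKS or not name:
        raise KeyError(f"unknown parameter target {target!r}")
    sub = getattr(params, block)
    if not hasattr(sub, name):
        raise KeyError(f"unknown parameter target {target!r}")
    return replace(params, **{block: replace(sub, **{name: value})})


# --------------------------------------------------------------------------
# base case
# --------------------------------------------------------------------------

#: one-way sensitivity ranges (printed uncertainty ranges / 95% CIs).
_BASE_RANGES = (
    ("transitions.p_bph_stay", 0.248, 0.45),
    ("transitions.p_bph_to_turp", 0.0098, 0.036),
    ("transitions.p_aur_to_turp", 0.75, 0.85),
    ("transitions.p_turp_30day_mortality", 0.0179, 0.0296),
    ("transitions.p_recovery_stay", 0.275, 0.41),
    ("transitions.p_recovery_to_medical", 0.0295, 0.0744),
    ("transitions.p_medical_to_second_turp", 0.0215, 0.061),
    ("transitions.p_medical_stay", 0.378, 0.438),
    ("transitions.p_turp_full_recovery", 0.978, 1.0),
    ("transitions.p_bph_to_aur", 0.00064, 0.0154),
    ("efficacy.rrr_aur", 0.527, 0.778),
    ("efficacy.rrr_turp", 0.577, 0.795),
    ("costs.annual_drug_combination", 348.0, 581.0),
    ("costs.annual_drug_tamsulosin", 41.8, 69.7),
    ("costs.annual_bph_management", 223.0, 720.0),
    ("costs.aur_episode", 590.0, 4199.0),
    ("costs.turp_procedure", 4549.0, 8119.0),
    ("costs.annual_medical_intervention", 123.0, 620.0),
    ("utilities.u_bph", 0.83, 0.92),
    ("utilities.u_aur", 0.24, 0.26),
    ("utilities.u_turp", 0.24, 0.26),
    ("utilities.u_medical", 0.24, 0.26),
    ("utilities.u_recovery", 0.95, 1.0),
)

#: PSA distributions (second-order uncertainty).  Beta parameters as
#: published; gamma rates rederived from the published means.
_BASE_DISTRIBUTIONS = (
    ParameterDistribution("transitions.p_bph_to_turp", "beta", 0.62, 29.27),
    ParameterDistribution("transitions.p_recovery_stay", "beta", 2.83, 7.79),
    ParameterDistribution("transitions.p_recovery_to_medical", "beta", 2.24, 27.97),
    ParameterDistribution("transitions.p_medical_to_second_turp", "beta", 2.3, 35.16),
    ParameterDistribution("transitions.p_bph_to_aur", "beta", 0.06, 2.9),
    ParameterDistribution("efficacy.rrr_aur", "beta", 1.77, 0.85),
    ParameterDistribution("efficacy.rrr_turp", "beta", 2.5, 1.04),
    ParameterDistribution("costs.annual_bph_management", "gamma", 3.61, 0.01, mean_override=471.0),
    ParameterDistribution("costs.aur_episode", "gamma", 0.21, 1.57, mean_override=1312.0),
    ParameterDistribution("costs.turp_procedure", "gamma", 12.59, 0.002, mean_override=6334.0),
    ParameterDistribution("costs.annual_medical_intervention", "gamma", 2.24, 0.006, mean_override=371.0),
)

#: WHO-CHOICE style decision thresholds, 2017 HK GDP per capita (US$).
WTP_GDP_PER_CAPITA = 45_887.0
WTP_3X_GDP_PER_CAPITA = 137_661.0


def _default_wtp_grid() -> tuple:
    grid = set(range(0, 200_001, 1_000))
    grid.update({20_000, 40_000, int(WTP_GDP_PER_CAPITA), int(WTP_3X_GDP_PER_CAPITA)})
    return tuple(sorted(grid))


def base_case_parameters() -> ModelParameters:
    """The published base case, including the calibrated life-table
    stand-in, OWSA ranges and PSA distributions.  Deterministic."""
    settings = EconomicSettings(wtp_grid=_default_wtp_grid())
    life_table = build_life_table_standin(
        start_age=settings.cohort_start_age,
        calibration_target=DEFAULT_CALIBRATION_TARGET,
        slope=DEFAULT_GOMPERTZ_SLOPE,
    )
    return ModelParameters(
        settings=settings,
        life_table=life_table,
        psa_distributions=_BASE_DISTRIBUTIONS,
        owsa_ranges=tuple(ParameterRange(t, lo, hi) for t, lo, hi in _BASE_RANGES),
    )


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Collected invariant violations; empty iff the model is runnable."""

    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, field_name: str, message: str) -> None:
        self.errors.append((field_name, message))

    def __str__(self) -> str:
        if self.ok:
            return "parameters valid"
        return "\n".join(f"{f}: {m}" for f, m in self.errors)


_PROB_FIELDS = [f.name for f in dataclasses.fields(TransitionParameters)]

# explicit per-row exit groups checked for sub-stochasticity
_ROW_EXITS = {
    "BPH": ("p_bph_to_turp", "p_bph_to_aur"),
    "TURP": ("p_turp_to_medical", "p_turp_to_repeat"),
    "REPEAT_TURP": ("p_repeat_to_medical",),
    "MEDICAL_INTERVENTION": ("p_medical_to_second_turp", "p_medical_to_aur"),
    "RECOVERY": ("p_recovery_to_medical",),
}


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check every model invariant; violations are reported, not raised."""
    rep = ValidationReport()
    tr = params.transitions

    for name in _PROB_FIELDS:
        v = getattr(tr, name)
        if not 0.0 <= v <= 1.0:
            rep.add(f"transitions.{name}", f"probability {v} outside [0, 1]")
    for row, names in _ROW_EXITS.items():
        total = sum(getattr(tr, n) for n in names)
        if total > 1.0 + 1e-12:
            rep.add(row, f"explicit exit probabilities sum to {total:.6g} > 1")

    for name in ("rrr_aur", "rrr_turp"):
        v = getattr(params.efficacy, name)
        if not 0.0 <= v <= 1.0:
            rep.add(f"efficacy.{name}", f"relative risk reduction {v} outside [0, 1]")

    for f in dataclasses.fields(CostParameters):
        v = getattr(params.costs, f.name)
        if v < 0:
            rep.add(f"costs.{f.name}", f"cost {v} is negative")

    for f in dataclasses.fields(UtilityParameters):
        v = getattr(params.utilities, f.name)
        if not 0.0 <= v <= 1.0:
            rep.add(f"utilities.{f.name}", f"utility {v} outside [0, 1]")
    if params.utilities.u_death != 0.0:
        rep.add("utilities.u_death", "death utility must be 0")

    s = params.settings
    if s.discount_rate < 0:
        rep.add("settings.discount_rate", "discount rate must be >= 0")
    if s.horizon_years < 1:
        rep.add("settings.horizon_years", "horizon must be a positive integer")
    if s.cycles_per_year < 1:
        rep.add("settings.cycles_per_year", "cycles_per_year must be >= 1")
    if s.n_microsim_patients < 1:
        rep.add("settings.n_microsim_patients", "n_microsim_patients must be >= 1")
    if s.probability_timescale not in ("annual", "monthly"):
        rep.add("settings.probability_timescale", f"unknown timescale {s.probability_timescale!r}")
    if s.residual_mode not in ("residual", "printed"):
        rep.add("settings.residual_mode", f"unknown residual mode {s.residual_mode!r}")

    if params.life_table is not None:
        probs = params.life_table.annual_prob
        if any(not 0.0 <= q <= 1.0 for q in probs):
            rep.add("life_table", "annual probabilities outside [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(probs, probs[1:])):
            rep.add("life_table", "annual mortality must be non-decreasing with age")

    for d in params.psa_distributions:
        is_cost = d.target.startswith("costs.")
        if d.family not in ("beta", "gamma"):
            rep.add(d.target, f"unknown distribution family {d.family!r}")
        elif d.family == "beta" and is_cost:
            rep.add(d.target, "beta distribution used for a cost parameter")
        elif d.family == "gamma" and not is_cost:
            rep.add(d.target, "gamma distribution used for a probability parameter")
        if d.shape_alpha <= 0 or d.shape_beta_or_rate <= 0:
            rep.add(d.target, "distribution shape/rate must be positive")

    for r in params.owsa_ranges:
        try:
            base = get_field(params, r.target)
        except KeyError:
            rep.add(r.target, "range targets an unknown field")
            continue
        if not r.low <= base <= r.high:
            rep.add(r.target, f"base value {base} outside range [{r.low}, {r.high}]")

    return rep


# --------------------------------------------------------------------------
# config I/O (flat key-value YAML)
# --------------------------------------------------------------------------

class ParameterConfigError(ValueError):
    """Malformed or invalid parameter configuration document."""


def _flatten_scalars(params: ModelParameters) -> dict:
    out = {}
    for block in _BLOCKS:
        sub = getattr(params, block)
        for f in dataclasses.fields(sub):
            v = getattr(sub, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f"{block}.{f.name}"] = v
    return out


def dump_parameters(params: ModelParameters) -> str:
    """Serialise to the flat key-value config format (round-trips with
    :func:`load_parameters`)."""
    doc = _flatten_scalars(params)
    for r in params.owsa_ranges:
        doc[f"range.{r.target}"] = [r.low, r.high]
    for d in params.psa_distributions:
        entry = {"family": d.family, "alpha": d.shape_alpha, "beta_or_rate": d.shape_beta_or_rate}
        if d.mean_override is not None:
            entry["mean"] = d.mean_override
        doc[f"dist.{d.target}"] = entry
    if params.life_table is not None:
        doc["lifetable.calibration_target"] = _infer_calibration_target(params)
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, default_flow_style=None, sort_keys=True)
    return buf.getvalue()


def _infer_calibration_target(params: ModelParameters) -> float:
    lt = params.life_table
    return round(lt.cumulative_mortality(params.settings.cohort_start_age, 4), 12)


def load_parameters(config_text: str = "") -> ModelParameters:
    """Build a parameter set from a flat key-value YAML document.

    Missing keys fall back to the base case; an empty document is the
    base case itself.  Raises :class:`ParameterConfigError` naming the
    offending line/field on parse or validation failure.
    """
    try:
        doc = yaml.safe_load(config_text) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParameterConfigError(f"malformed config document{line}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParameterConfigError("config document must be a key-value mapping")

    params = base_case_parameters()
    ranges = {r.target: r for r in params.owsa_ranges}
    dists = {d.target: d for d in params.psa_distributions}
    lifetable_overrides = {}

    for key, value in doc.items():
        if key.startswith("range."):
            target = key[len("range."):]
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ParameterConfigError(f"{key}: expected [low, high]")
            ranges[target] = ParameterRange(target, float(value[0]), float(value[1]))
        elif key.startswith("dist."):
            target = key[len("dist."):]
            if not isinstance(value, dict) or "family" not in value:
                raise ParameterConfigError(f"{key}: expected mapping with family/alpha/beta_or_rate")
            dists[target] = ParameterDistribution(
                target=target,
                family=str(value["family"]),
                shape_alpha=float(value["alpha"]),
                shape_beta_or_rate=float(value["beta_or_rate"]),
                mean_override=(float(value["mean"]) if "mean" in value else None),
            )
        elif key.startswith("lifetable."):
            lifetable_overrides[key[len("lifetable."):]] = value
        else:
            try:
                current = get_field(params, key)
            except KeyError as exc:
                raise ParameterConfigError(f"unknown config key {key!r}") from exc
            if isinstance(current, tuple):
                value = tuple(value)
            elif isinstance(current, bool) or isinstance(value, bool):
                value = bool(value)
            elif isinstance(current, int) and not isinstance(current, bool):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            params = set_field(params, key, value)

    target = lifetable_overrides.get("calibration_target", DEFAULT_CALIBRATION_TARGET)
    slope = lifetable_overrides.get("slope", DEFAULT_GOMPERTZ_SLOPE)
    params = replace(
        params,
        life_table=build_life_table_standin(
            start_age=params.settings.cohort_start_age,
            calibration_target=float(target),
            slope=float(slope),
        ),
        owsa_ranges=tuple(ranges.values()),
        psa_distributions=tuple(dists.values()),
    )

    report = validate_parameters(params)
    if not report.ok:
        raise ParameterConfigError(f"invalid parameter configuration:\n{report}")
    return params
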