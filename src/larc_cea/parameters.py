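"""Typed registry of model inputs for the rectal-cancer treatment comparison.

The model compares two neoadjuvant strategies for locally advanced rectal
cancer — short-course radiotherapy followed by total neoadjuvant therapy
(SCRT-TNT) and long-course chemoradiotherapy with adjuvant chemotherapy
(LCCRT) — over a five-state Markov disease process.  Every input the engine
consumes lives in a :class:`ParameterSet`:

* transition probabilities, each stated as a cumulative probability over an
  explicit horizon (2, 3 or 5 years) or as an instantaneous ``per_event``
  split (surgery type; resectable vs unresectable recurrence),
* health-state utilities, surgery-specific for the disease-free state,
* costs in 2020 USD with explicit timing semantics (paid once at entry into
  the model, on entry into a state, per cycle of membership, or per year
  alive), and
* the economic settings (3% annual discount rate, 3-month cycles, 5-year
  horizon, $50,000/QALY willingness to pay).

Sensitivity ranges default to ±25% of the base value (probabilities capped
at 1), which is how the published ranges were constructed.
"""

from __future__ import annotations

import copy
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

SCHEMA_VERSION = 1

PER_EVENT = "per_event"


class StrategyArm(str, enum.Enum):
    """The two treatment strategies under comparison."""

    SCRT_TNT = "SCRT_TNT"
    LCCRT_ADJ = "LCCRT_ADJ"


class SurgeryType(str, enum.Enum):
    """Definitive surgery pathway after neoadjuvant therapy.

    APR leaves a permanent colostomy; LAR uses a temporary defunctioning
    ileostomy with a planned reversal.
    """

    APR = "APR"
    LAR = "LAR"


class HealthState(str, enum.Enum):
    NED = "NED"
    LRR_RESECTABLE = "LRR_RESECTABLE"
    LRR_UNRESECTABLE = "LRR_UNRESECTABLE"
    DM = "DM"
    DEATH = "DEATH"


#: Canonical state ordering used by every matrix/trace in the package.
STATE_ORDER: list[HealthState] = [
    HealthState.NED,
    HealthState.LRR_RESECTABLE,
    HealthState.LRR_UNRESECTABLE,
    HealthState.DM,
    HealthState.DEATH,
]

STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}

#: Maps an arm to the prefix its arm-specific parameters use.
ARM_PREFIX = {StrategyArm.SCRT_TNT: "scrt", StrategyArm.LCCRT_ADJ: "lccrt"}


class CostTiming(str, enum.Enum):
    ONE_TIME_T0 = "one_time_t0"
    ON_ENTRY = "on_entry"
    PER_CYCLE_WHILE_IN = "per_cycle_while_in"
    PER_YEAR_WHILE_ALIVE = "per_year_while_alive"
    BUNDLED = "bundled"


class ProbabilityParam(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    value: float = Field(ge=0.0, le=1.0)
    horizon_years: Union[float, Literal["per_event"]]
    low: float = Field(ge=0.0, le=1.0)
    high: float = Field(ge=0.0, le=1.0)
    source: str = ""


class UtilityParam(BaseModel):
    model_config = ConfigDict(extra="forbid")

    state: HealthState
    surgery: Union[SurgeryType, Literal["either"]] = "either"
    value: float = Field(ge=0.0, le=1.0)
    low: float = Field(ge=0.0, le=1.0)
    high: float = Field(ge=0.0, le=1.0)
    source: str = ""


class CostParam(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    value: float = Field(ge=0.0)
    timing: CostTiming
    states: list[HealthState] = Field(default_factory=list)
    arm: Optional[StrategyArm] = None
    surgery: Optional[SurgeryType] = None
    low: float = Field(ge=0.0)
    high: float = Field(ge=0.0)
    enabled: bool = True
    source: str = ""


class ParameterSet(BaseModel):
    """Complete model input.  Unknown keys are rejected on load."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    probabilities: dict[str, ProbabilityParam]
    utilities: dict[str, UtilityParam]
    costs: dict[str, CostParam]
    #: complementary split groups whose members must sum to 1
    splits: list[tuple[str, str]]
    discount_rate_annual: float = Field(ge=0.0)
    cycle_length_years: float = Field(gt=0.0)
    horizon_years: float = Field(gt=0.0)
    wtp_per_qaly: float = Field(ge=0.0)

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))

    def probability(self, name: str) -> float:
        return self.probabilities[name].value

    def cost_value(self, name: str) -> float:
        return self.costs[name].value

    def utility_value(self, state: HealthState, surgery: SurgeryType) -> float:
        """Resolve a state utility, preferring a surgery-specific entry."""
        generic = None
        for u in self.utilities.values():
            if u.state != state:
                continue
            if u.surgery == surgery:
                return u.value
            if u.surgery == "either":
                generic = u.value
        if generic is None:
            raise KeyError(f"no utility defined for state {state.value} / {surgery.value}")
        return generic

    def utility_vector(self, surgery: SurgeryType) -> list[float]:
        return [self.utility_value(s, surgery) for s in STATE_ORDER]

    def copy_deep(self) -> "ParameterSet":
        return self.model_copy(deep=True)


# ---------------------------------------------------------------------------
# base case
# ---------------------------------------------------------------------------

def _rng_bounds(value: float, cap: float | None = None) -> tuple[float, float]:
    """±25% sensitivity range around a base value, optionally capped."""
    low = 0.75 * value
    high = 1.25 * value
    if cap is not None:
        high = min(cap, high)
    return low, high


_TRIAL = "RAPIDO phase 3 trial (Bahadoer 2021)"
_SALVAGE_LIT = "pooled salvage-therapy outcomes (Ikoma 2017)"
_LRR_LIT = "resectability of locoregional recurrence (Tepper 2003)"
_UTIL_LIT = "utility elicitation after rectal-cancer surgery (Ness 1999)"
_CMS = "CMS Medicare payment schedules, 2020 USD"


def _prob(name: str, value: float, horizon, source: str) -> ProbabilityParam:
    low, high = _rng_bounds(value, cap=1.0)
    return ProbabilityParam(
        name=name, value=value, horizon_years=horizon, low=low, high=high, source=source
    )


def _util(state: HealthState, surgery, value: float, source: str = _UTIL_LIT) -> UtilityParam:
    low, high = _rng_bounds(value, cap=1.0)
    return UtilityParam(state=state, surgery=surgery, value=value, low=low, high=high, source=source)


def _cost(name: str, value: float, timing: CostTiming, *, states=(), arm=None,
          surgery=None, enabled=True, source: str = _CMS) -> CostParam:
    low, high = _rng_bounds(value)
    return CostParam(
        name=name, value=value, timing=timing, states=list(states), arm=arm,
        surgery=surgery, low=low, high=high, enabled=enabled, source=source,
    )


#: Mean of the three printed salvage-surgery costs (APR, LAR, exenteration).
SALVAGE_SURGERY_MEAN = (17087.60 + 18760.43 + 17924.01) / 3.0


def base_case_parameters() -> ParameterSet:
    """The published base case, transcribed from the printed input tables.

    Transition probabilities are cumulative over the annotated horizon.
    Costs are 2020 USD.  The routine-surveillance cost is not printed in the
    main tables ("cost varies"); its default of $400 per 3-month cycle in the
    disease-free state is a calibration value, flagged as such in its source
    string.
    """
    H = HealthState
    probs = {
        # surgery mix after each strategy (decision-tree split, not a cycle event)
        "scrt.apr": _prob("scrt.apr", 0.357, PER_EVENT, _TRIAL),
        "scrt.lar": _prob("scrt.lar", 0.643, PER_EVENT, _TRIAL),
        "lccrt.apr": _prob("lccrt.apr", 0.407, PER_EVENT, _TRIAL),
        "lccrt.lar": _prob("lccrt.lar", 0.593, PER_EVENT, _TRIAL),
        # arm-specific exits from the disease-free state (3-year cumulative)
        "scrt.ned_to_lrr": _prob("scrt.ned_to_lrr", 0.083, 3.0, _TRIAL),
        "scrt.ned_to_dm": _prob("scrt.ned_to_dm", 0.200, 3.0, _TRIAL),
        "lccrt.ned_to_lrr": _prob("lccrt.ned_to_lrr", 0.060, 3.0, _TRIAL),
        "lccrt.ned_to_dm": _prob("lccrt.ned_to_dm", 0.268, 3.0, _TRIAL),
        # resectability split on entry into locoregional recurrence
        "lrr.resectable": _prob("lrr.resectable", 0.37, PER_EVENT, _LRR_LIT),
        "lrr.unresectable": _prob("lrr.unresectable", 0.63, PER_EVENT, _LRR_LIT),
        # arm-independent disease transitions
        "res.to_dm": _prob("res.to_dm", 0.75, 5.0, _SALVAGE_LIT),
        "res.to_death": _prob("res.to_death", 0.49, 5.0, _SALVAGE_LIT),
        "unres.to_dm": _prob("unres.to_dm", 0.16, 2.0, _SALVAGE_LIT),
        "unres.to_death": _prob("unres.to_death", 0.87, 5.0, _SALVAGE_LIT),
        "dm.to_death": _prob("dm.to_death", 0.87, 5.0, _SALVAGE_LIT),
    }
    utilities = {
        "utility.ned.lar": _util(H.NED, SurgeryType.LAR, 0.59),
        "utility.ned.apr": _util(H.NED, SurgeryType.APR, 0.50),
        "utility.lrr_resectable": _util(H.LRR_RESECTABLE, "either", 0.45),
        "utility.lrr_unresectable": _util(H.LRR_UNRESECTABLE, "either", 0.40),
        "utility.dm": _util(H.DM, "either", 0.25),
        "utility.death": UtilityParam(
            state=H.DEATH, surgery="either", value=0.0, low=0.0, high=0.0, source="by definition"
        ),
    }
    T = CostTiming
    A = StrategyArm
    S = SurgeryType
    costs = {
        # up-front therapy + surgery, paid once when the cohort enters the model
        "scrt_tnt.course": _cost("scrt_tnt.course", 9960.93, T.ONE_TIME_T0, arm=A.SCRT_TNT),
        "lccrt.course": _cost("lccrt.course", 17270.86, T.ONE_TIME_T0, arm=A.LCCRT_ADJ),
        "lccrt.adjuvant_chemo": _cost(
            "lccrt.adjuvant_chemo", 6885.21, T.ONE_TIME_T0, arm=A.LCCRT_ADJ
        ),
        "tme.apr": _cost("tme.apr", 11514.07, T.ONE_TIME_T0, surgery=S.APR),
        "tme.lar": _cost("tme.lar", 11807.84, T.ONE_TIME_T0, surgery=S.LAR),
        "tme.ileostomy_reversal": _cost(
            "tme.ileostomy_reversal", 11582.50, T.ONE_TIME_T0, surgery=S.LAR
        ),
        # recurring costs
        "surveillance.per_cycle": _cost(
            "surveillance.per_cycle", 400.0, T.PER_CYCLE_WHILE_IN, states=[H.NED],
            source="CALIBRATION: routine follow-up surveillance, not printed per item",
        ),
        "ostomy.maintenance_annual": _cost(
            "ostomy.maintenance_annual", 2000.0, T.PER_YEAR_WHILE_ALIVE, surgery=S.APR
        ),
        # event bundles charged on entry into a state
        "workup.lrr": _cost(
            "workup.lrr", 1328.65, T.ON_ENTRY, states=[H.LRR_RESECTABLE, H.LRR_UNRESECTABLE]
        ),
        "workup.dm": _cost("workup.dm", 1318.73, T.ON_ENTRY, states=[H.DM]),
        "salvage.reirradiation": _cost(
            "salvage.reirradiation", 17530.95, T.ON_ENTRY, states=[H.LRR_RESECTABLE]
        ),
        "salvage.concurrent_capecitabine": _cost(
            "salvage.concurrent_capecitabine", 269.32, T.ON_ENTRY, states=[H.LRR_RESECTABLE]
        ),
        "salvage.surgery": _cost(
            "salvage.surgery", SALVAGE_SURGERY_MEAN, T.ON_ENTRY, states=[H.LRR_RESECTABLE],
            source=_CMS + "; mean of the three printed salvage-surgery rows",
        ),
        "palliative.reirradiation": _cost(
            "palliative.reirradiation", 17530.95, T.ON_ENTRY, states=[H.LRR_UNRESECTABLE]
        ),
        "palliative.capecitabine_annual": _cost(
            "palliative.capecitabine_annual", 4517.17, T.ON_ENTRY,
            states=[H.LRR_UNRESECTABLE, H.DM],
            source=_CMS + "; 1-year course charged as a single bundle on entry",
        ),
        "palliative.diverting_ostomy": _cost(
            "palliative.diverting_ostomy", 11163.14, T.BUNDLED, enabled=False,
            source=_CMS + "; no stated recipient population, disabled by default",
        ),
    }
    return ParameterSet(
        probabilities=probs,
        utilities=utilities,
        costs=costs,
        splits=[
            ("scrt.apr", "scrt.lar"),
            ("lccrt.apr", "lccrt.lar"),
            ("lrr.resectable", "lrr.unresectable"),
        ],
        discount_rate_annual=0.03,
        cycle_length_years=0.25,
        horizon_years=5.0,
        wtp_per_qaly=50_000.0,
    )


# ---------------------------------------------------------------------------
# config round-tripping
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """A model-definition file failed schema validation."""


def save_model_config(p: ParameterSet, path: str | Path) -> Path:
    path = Path(path)
    payload = p.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_model_config(path: str | Path) -> ParameterSet:
    """Load a YAML (canonical) or JSON model definition.

    Raises :class:`ConfigError` on missing keys, unknown keys, or values
    outside their type bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: not parseable: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return ParameterSet.model_validate(payload)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"{path}: {exc}") from exc


def packaged_base_config() -> Path:
    """Path of the base-case fixture shipped with the package."""
    return Path(__file__).parent / "data" / "base_case_2020usd.yaml"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


_REQUIRED_PROBABILITIES = [
    "scrt.apr", "scrt.lar", "lccrt.apr", "lccrt.lar",
    "scrt.ned_to_lrr", "scrt.ned_to_dm", "lccrt.ned_to_lrr", "lccrt.ned_to_dm",
    "lrr.resectable", "lrr.unresectable",
    "res.to_dm", "res.to_death", "unres.to_dm", "unres.to_death", "dm.to_death",
]


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every cross-field invariant; report-valued, never raises."""
    rep = ValidationReport()
    for name in _REQUIRED_PROBABILITIES:
        if name not in p.probabilities:
            rep.errors.append(f"missing required probability '{name}'")
    for a, b in p.splits:
        if a not in p.probabilities or b not in p.probabilities:
            rep.errors.append(f"split ({a}, {b}) references a missing parameter")
            continue
        total = p.probabilities[a].value + p.probabilities[b].value
        if abs(total - 1.0) > 1e-9:
            rep.errors.append(f"split ({a}, {b}) sums to {total:.6g}, expected 1")
    for name, prob in p.probabilities.items():
        if not (prob.low <= prob.value <= prob.high):
            rep.errors.append(f"probability '{name}' value outside [low, high]")
    for key, u in p.utilities.items():
        if u.state == HealthState.DEATH and u.value != 0.0:
            rep.errors.append(f"utility '{key}': death utility must be exactly 0")
        if not (u.low <= u.value <= u.high):
            rep.errors.append(f"utility '{key}' value outside [low, high]")
    for name, c in p.costs.items():
        if not (c.low <= c.value <= c.high):
            rep.errors.append(f"cost '{name}' value outside [low, high]")
        if c.enabled and c.timing == CostTiming.BUNDLED:
            rep.warnings.append(f"cost '{name}' has timing 'bundled' and is never accrued")
        if c.timing in (CostTiming.ON_ENTRY, CostTiming.PER_CYCLE_WHILE_IN) and not c.states:
            rep.errors.append(f"cost '{name}' with timing {c.timing.value} names no states")
    n = p.horizon_years / p.cycle_length_years
    if abs(n - round(n)) > 1e-9:
        rep.errors.append("horizon_years is not an integer multiple of cycle_length_years")
    # severity ordering is expected but not structurally required
    for surgery in SurgeryType:
        try:
            seq = [p.utility_value(s, surgery) for s in STATE_ORDER[:-1]]
        except KeyError as exc:
            rep.errors.append(str(exc))
            continue
        if any(a < b - 1e-12 for a, b in zip(seq, seq[1:])):
            rep.warnings.append(
                f"utilities are not monotone in disease severity for {surgery.value}"
            )
    return rep


# ---------------------------------------------------------------------------
# parameter perturbation (sensitivity plumbing)
# ---------------------------------------------------------------------------

def _split_partner(p: ParameterSet, name: str) -> str | None:
    for a, b in p.splits:
        if name == a:
            return b
        if name == b:
            return a
    return None


def _assign(param, value: float) -> None:
    """Set a value, stretching [low, high] so the record stays consistent.

    low/high describe the base-case sensitivity range; a perturbed set keeps
    them only as far as they still bracket the new value.
    """
    param.value = value
    param.low = min(param.low, value)
    param.high = max(param.high, value)


def set_parameter(p: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a new ParameterSet with one value replaced.

    Probabilities are clamped to [0, 1]; the partner of a complementary
    split is renormalized so the split still sums to 1.  The input set is
    not modified.
    """
    out = p.copy_deep()
    if name in out.probabilities:
        new = min(1.0, max(0.0, value))
        _assign(out.probabilities[name], new)
        partner = _split_partner(out, name)
        if partner is not None:
            _assign(out.probabilities[partner], 1.0 - new)
    elif name in out.utilities:
        if out.utilities[name].state == HealthState.DEATH and value != 0.0:
            raise ValueError("death utility is fixed at 0")
        _assign(out.utilities[name], min(1.0, max(0.0, value)))
    elif name in out.costs:
        _assign(out.costs[name], max(0.0, value))
    else:
        raise KeyError(f"unknown parameter '{name}'")
    return out


def current_value(p: ParameterSet, name: str) -> float:
    if name in p.probabilities:
        return p.probabilities[name].value
    if name in p.utilities:
        return p.utilities[name].value
    if name in p.costs:
        return p.costs[name].value
    raise KeyError(f"unknown parameter '{name}'")


def scale_parameter(p: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Multiply one parameter by ``factor`` (sensitivity perturbation)."""
    return set_parameter(p, name, current_value(p, name) * factor)


def scalable_parameter_names(p: ParameterSet) -> list[str]:
    """All names eligible for one-way sensitivity analysis."""
    names = list(p.probabilities)
    names += [k for k, u in p.utilities.items() if u.state != HealthState.DEATH]
    names += [k for k, c in p.costs.items() if c.enabled and c.timing != CostTiming.BUNDLED]
    return names


def parameter_table(p: ParameterSet) -> pd.DataFrame:
    """Flat dump of every parameter (name, value, range, timing, source)."""
    rows = []
    for name, pr in p.probabilities.items():
        rows.append(dict(name=name, kind="probability", value=pr.value, low=pr.low,
                         high=pr.high, horizon_or_timing=str(pr.horizon_years),
                         source=pr.source))
    for name, u in p.utilities.items():
        surgery = u.surgery if isinstance(u.surgery, str) else u.surgery.value
        rows.append(dict(name=name, kind="utility", value=u.value, low=u.low, high=u.high,
                         horizon_or_timing=f"{u.state.value}/{surgery}", source=u.source))
    for name, c in p.costs.items():
        rows.append(dict(name=name, kind="cost", value=c.value, low=c.low, high=c.high,
                         horizon_or_timing=c.timing.value, source=c.source))
    return pd.DataFrame(rows)
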