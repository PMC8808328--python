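"""One-way, two-way, threshold, and willingness-to-pay sensitivity analyses.

The effect measure throughout is the incremental net monetary benefit of
SCRT-TNT relative to LCCRT at a stated willingness to pay.  NMB is used
instead of the raw ICER because the base case is dominant (cheaper and more
effective), where the ICER's sign flips discontinuously and cannot be
ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .outcomes import CEAComparison, evaluate_comparison
from .parameters import (
    ParameterSet,
    StrategyArm,
    current_value,
    scalable_parameter_names,
    scale_parameter,
    set_parameter,
)

log = logging.getLogger(__name__)


def incremental_nmb(p: ParameterSet, wtp: float | None = None) -> float:
    """NMB(SCRT-TNT) − NMB(LCCRT) at the given willingness to pay."""
    cmp_ = evaluate_comparison(p, wtp)
    return cmp_.nmb[StrategyArm.SCRT_TNT] - cmp_.nmb[StrategyArm.LCCRT_ADJ]


@dataclass
class TornadoRow:
    parameter: str
    ev_low: float
    ev_high: float
    preferred_at_low: StrategyArm
    preferred_at_high: StrategyArm

    @property
    def spread(self) -> float:
        return abs(self.ev_high - self.ev_low)


def one_way_tornado(
    p: ParameterSet,
    params: Sequence[str] | None = None,
    wtp: float | None = None,
    rel_range: float = 0.25,
) -> list[TornadoRow]:
    """Incremental NMB at ±``rel_range`` of each parameter's base value.

    Probabilities scaled above 1 are clamped; complementary split members
    are renormalized so the split keeps summing to 1.  Rows come back sorted
    by descending spread, ready for a tornado plot.
    """
    if params is None:
        params = scalable_parameter_names(p)
    rows = []
    for name in params:
        evs = {}
        pref = {}
        for side, factor in (("low", 1.0 - rel_range), ("high", 1.0 + rel_range)):
            perturbed = scale_parameter(p, name, factor)
            cmp_ = evaluate_comparison(perturbed, wtp)
            evs[side] = cmp_.nmb[StrategyArm.SCRT_TNT] - cmp_.nmb[StrategyArm.LCCRT_ADJ]
            pref[side] = cmp_.preferred_arm
        rows.append(
            TornadoRow(
                parameter=name, ev_low=evs["low"], ev_high=evs["high"],
                preferred_at_low=pref["low"], preferred_at_high=pref["high"],
            )
        )
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows


def tornado_table(rows: Sequence[TornadoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "ev_low": [r.ev_low for r in rows],
            "ev_high": [r.ev_high for r in rows],
            "spread": [r.spread for r in rows],
            "preferred_at_low": [r.preferred_at_low.value for r in rows],
            "preferred_at_high": [r.preferred_at_high.value for r in rows],
        }
    )


@dataclass
class PreferenceGrid:
    x_param: str
    y_param: str
    x_values: np.ndarray
    y_values: np.ndarray
    preferred: np.ndarray  # shape (len(y_values), len(x_values)) of StrategyArm
    incremental_nmb: np.ndarray
    wtp: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(self.y_values):
            for j, x in enumerate(self.x_values):
                rows.append(
                    {
                        self.x_param: x,
                        self.y_param: y,
                        "incremental_nmb": self.incremental_nmb[i, j],
                        "preferred": self.preferred[i, j].value,
                    }
                )
        return pd.DataFrame(rows)


def two_way_grid(
    p: ParameterSet,
    x_param: str,
    y_param: str,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
    n_x: int = 41,
    n_y: int = 41,
    wtp: float | None = None,
) -> PreferenceGrid:
    """Full-factorial preferred-arm map over two parameters.

    Ranges default to ±25% of the base values.  The preference boundary is
    the contour where the incremental NMB changes sign.
    """
    def default_range(name: str) -> tuple[float, float]:
        v = current_value(p, name)
        return 0.75 * v, 1.25 * v

    x_range = x_range or default_range(x_param)
    y_range = y_range or default_range(y_param)
    xs = np.linspace(*x_range, n_x)
    ys = np.linspace(*y_range, n_y)
    wtp_eff = p.wtp_per_qaly if wtp is None else wtp
    pref = np.empty((n_y, n_x), dtype=object)
    inc = np.zeros((n_y, n_x))
    for i, y in enumerate(ys):
        py = set_parameter(p, y_param, float(y))
        for j, x in enumerate(xs):
            pxy = set_parameter(py, x_param, float(x))
            cmp_ = evaluate_comparison(pxy, wtp_eff)
            inc[i, j] = cmp_.nmb[StrategyArm.SCRT_TNT] - cmp_.nmb[StrategyArm.LCCRT_ADJ]
            pref[i, j] = cmp_.preferred_arm
    return PreferenceGrid(
        x_param=x_param, y_param=y_param, x_values=xs, y_values=ys,
        preferred=pref, incremental_nmb=inc, wtp=wtp_eff,
    )


@dataclass
class ThresholdResult:
    parameter: str
    found: bool
    value: Optional[float]
    base_value: float
    wtp: float

    @property
    def ratio_to_base(self) -> Optional[float]:
        if self.value is None or self.base_value == 0:
            return None
        return self.value / self.base_value


def threshold_analysis(
    p: ParameterSet,
    param: str,
    wtp: float | None = None,
    bracket: tuple[float, float] | None = None,
    tol_nmb: float = 0.01,
    max_iter: int = 200,
) -> ThresholdResult:
    """Tipping-point value of one parameter, by bisection on incremental NMB.

    Returns a no-threshold result (not an exception) when the incremental
    NMB does not change sign across the bracket.  Bisection stops when
    |ΔNMB| at the midpoint falls below ``tol_nmb`` (USD).
    """
    wtp_eff = p.wtp_per_qaly if wtp is None else wtp
    base = current_value(p, param)
    if bracket is None:
        bracket = (0.25 * base, 4.0 * base)
    lo, hi = bracket

    def f(v: float) -> float:
        return incremental_nmb(set_parameter(p, param, v), wtp_eff)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return ThresholdResult(param, True, lo, base, wtp_eff)
    if f_hi == 0.0:
        return ThresholdResult(param, True, hi, base, wtp_eff)
    if np.sign(f_lo) == np.sign(f_hi):
        return ThresholdResult(param, False, None, base, wtp_eff)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < tol_nmb or (hi - lo) < 1e-9 * max(1.0, abs(mid)):
            return ThresholdResult(param, True, mid, base, wtp_eff)
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    log.warning("threshold bisection did not reach tolerance within %d iterations", max_iter)
    return ThresholdResult(param, True, 0.5 * (lo + hi), base, wtp_eff)


def wtp_sweep(p: ParameterSet, wtps: Sequence[float]) -> list[CEAComparison]:
    """Base-case comparison at each willingness-to-pay value."""
    for w in wtps:
        if w < 0:
            raise ValueError("willingness to pay must be nonnegative")
    return [evaluate_comparison(p, w) for w in wtps]
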