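"""The catastrophic-health-expenditure (CHE) statistic.

Implements the capacity-to-pay methodology of Xu and colleagues (WHO health
expenditure distribution method) on annualized household data:

1. *Equivalized household size* ``eq_size = household_size ** beta`` with
   ``beta = 0.56``, capturing consumption economies of scale.
2. *Food-share poverty line*: the mean per-equivalent-adult food expenditure
   of the households whose food budget share lies in a mid-percentile window
   (default the 45th–55th percentiles) of the sample food-share distribution.
3. *Subsistence expenditure* ``SE_h = poverty_line * eq_size_h``.
4. *Capacity to pay* ``PC_h = THE_h − SE_h``; when this is negative (very
   poor households spending below the estimated subsistence level) the
   poverty line is replaced by the household's own food expenditure, so
   ``PC_h = THE_h − food_h ≥ 0``.
5. *CHE flag*: ``CHE_h = 1`` iff ``OOP_h / PC_h ≥ z`` (closed boundary),
   with the headline threshold ``z = 0.30`` and a sensitivity sweep over
   10/20/30/40%.
6. *Incidence*: percentage of households flagged, with a Wilson 95% CI.

All functions require annualized, single-currency data and refuse anything
else: the statistic is scale-invariant in the currency but not in the period.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io_model import PeriodError, SurveyDataset, oop_total

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BETA",
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLDS",
    "PovertyLine",
    "IncidenceResult",
    "EmptyWindowError",
    "DegenerateLineError",
    "equivalized_size",
    "food_share",
    "poverty_line",
    "subsistence_expenditure",
    "capacity_to_pay",
    "che_flag",
    "che_incidence",
    "decompose",
    "sensitivity_analysis",
]

#: Equivalence-scale exponent (Xu 2005).
DEFAULT_BETA = 0.56
#: Food-share percentile window used to pick poverty-line reference households.
DEFAULT_WINDOW = (45.0, 55.0)
#: CHE thresholds for the sensitivity sweep; 0.30 is the headline.
DEFAULT_THRESHOLDS = (0.10, 0.20, 0.30, 0.40)


class EmptyWindowError(ValueError):
    """No household's food share fell inside the percentile window."""


class DegenerateLineError(ValueError):
    """The poverty line is degenerate (no positive food spending in window)."""


@dataclass(frozen=True)
class PovertyLine:
    """Per-equivalent-adult annual subsistence value and how it was obtained."""

    value_per_eq_adult: float
    window_lo: float
    window_hi: float
    n_reference: int


@dataclass(frozen=True)
class IncidenceResult:
    """CHE incidence at one threshold: count, percentage, Wilson 95% CI."""

    threshold: float
    n_households: int
    n_che: int
    incidence_pct: float
    ci95: tuple[float, float]


def equivalized_size(household_size, beta: float = DEFAULT_BETA):
    """Equivalent-adult household size, ``household_size ** beta``.

    ``beta`` must lie in (0, 1]; ``beta = 1`` gives the raw head count and a
    one-person household is always exactly one equivalent adult.
    """
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    size = np.asarray(household_size, dtype=float)
    if np.any(size < 1):
        raise ValueError("household_size must be >= 1")
    out = size ** beta
    return float(out) if np.isscalar(household_size) else out


def food_share(expenditure_food, expenditure_total):
    """Food budget share food/total; NaN (with a warning) where total is 0."""
    food = np.asarray(expenditure_food, dtype=float)
    total = np.asarray(expenditure_total, dtype=float)
    scalar = food.ndim == 0
    food, total = np.atleast_1d(food), np.atleast_1d(total)
    zero = total <= 0
    if zero.any():
        logger.warning(
            "%d household(s) with zero total expenditure excluded from "
            "food-share computation", int(zero.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(zero, np.nan, food / np.where(zero, 1.0, total))
    return float(share[0]) if scalar else share


def _nearest_rank(sorted_vals: np.ndarray, p: float) -> float:
    """Empirical (nearest-rank) percentile: value at rank ceil(p/100 * n)."""
    n = len(sorted_vals)
    k = max(1, math.ceil(p / 100.0 * n))
    return float(sorted_vals[min(k, n) - 1])


def _require_annual(ds: SurveyDataset) -> None:
    if ds.convention.period != "annual":
        raise PeriodError("CHE computations require annualized data")


def poverty_line(
    ds: SurveyDataset,
    beta: float = DEFAULT_BETA,
    window: tuple[float, float] = DEFAULT_WINDOW,
    weight_col: str | None = None,
) -> PovertyLine:
    """Food-share poverty line per equivalent adult.

    Households whose food share lies within the inclusive percentile window
    ``[lo, hi]`` (nearest-rank percentiles of the sample food-share
    distribution) are the reference group; the line is the (optionally
    weighted) mean of their per-equivalent-adult food expenditure.
    Deterministic given the data and parameters.
    """
    _require_annual(ds)
    lo, hi = window
    if not (0 <= lo < hi <= 100):
        raise ValueError(f"invalid percentile window {window}")
    frame = ds.frame
    if len(frame) == 0:
        raise ValueError("cannot compute a poverty line from an empty dataset")
    shares = food_share(frame["expenditure_food"].to_numpy(),
                        frame["expenditure_total"].to_numpy())
    valid = ~np.isnan(shares)
    vshares = shares[valid]
    if len(vshares) == 0:
        raise DegenerateLineError("no household has positive total expenditure")
    svals = np.sort(vshares)
    s_lo, s_hi = _nearest_rank(svals, lo), _nearest_rank(svals, hi)
    in_window = valid & (shares >= s_lo) & (shares <= s_hi)
    if not in_window.any():
        raise EmptyWindowError(
            f"no household has food share in [{s_lo:.4g}, {s_hi:.4g}]; "
            "widen the percentile window"
        )
    ref = frame[in_window]
    eq = equivalized_size(ref["household_size"].to_numpy(), beta)
    per_eq_food = ref["expenditure_food"].to_numpy() / eq
    if weight_col is not None:
        w = ref[weight_col].to_numpy(dtype=float)
        value = float(np.average(per_eq_food, weights=w))
    else:
        value = float(per_eq_food.mean())
    if value <= 0:
        raise DegenerateLineError(
            "reference households report no food spending; poverty line is 0"
        )
    return PovertyLine(value_per_eq_adult=value, window_lo=lo, window_hi=hi,
                       n_reference=int(in_window.sum()))


def subsistence_expenditure(household_size, pl: PovertyLine,
                            beta: float = DEFAULT_BETA):
    """Subsistence expenditure ``SE_h = poverty_line × size^beta``."""
    return pl.value_per_eq_adult * equivalized_size(household_size, beta)


def capacity_to_pay(the_h, food_h, se_h):
    """Capacity to pay ``PC_h = THE_h − SE_h`` with the food substitution rule.

    Where ``THE_h − SE_h`` is negative the poverty line is replaced by the
    household's own food expenditure, giving ``PC_h = THE_h − food_h``.
    Returns ``(pc_h, substitution_applied)``; with validated data
    (food ≤ total) PC is never negative.
    """
    the = np.asarray(the_h, dtype=float)
    food = np.asarray(food_h, dtype=float)
    se = np.asarray(se_h, dtype=float)
    if np.any(food > the * (1 + 1e-12)):
        raise ValueError(
            "food expenditure exceeds total expenditure; input should have "
            "been rejected upstream"
        )
    direct = the - se
    substituted = direct < 0
    pc = np.where(substituted, the - food, direct)
    pc = np.maximum(pc, 0.0)  # guard float dust when food ~= total
    if np.isscalar(the_h):
        return float(pc), bool(substituted)
    return pc, substituted


def che_flag(oop_h, pc_h, threshold: float = 0.30):
    """CHE indicator: 1 iff ``OOP_h / PC_h ≥ threshold`` (closed boundary).

    A household with zero capacity to pay but positive OOP spending is
    catastrophic at any threshold (flag 1, logged); zero OOP against zero
    capacity is flag 0.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    oop = np.asarray(oop_h, dtype=float)
    pc = np.asarray(pc_h, dtype=float)
    degenerate = (pc <= 0) & (oop > 0)
    if degenerate.any():
        logger.warning(
            "%d household(s) with zero capacity to pay and positive OOP "
            "spending flagged catastrophic", int(np.atleast_1d(degenerate).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(pc > 0, oop / np.where(pc > 0, pc, 1.0), np.inf)
    flags = np.where(pc > 0, (ratio >= threshold).astype(int),
                     (oop > 0).astype(int))
    return int(flags) if np.isscalar(oop_h) else flags


def che_incidence(flags: Iterable[int], threshold: float) -> IncidenceResult:
    """Incidence: 100 × (households with CHE) / (all households).

    The ratio is formed in exact rational arithmetic before the final float;
    the 95% CI is the Wilson score interval (well-behaved near 0% and 100%).
    """
    flags = np.asarray(list(flags) if not isinstance(flags, np.ndarray) else flags)
    n = len(flags)
    if n == 0:
        raise ValueError("cannot compute incidence of an empty collection")
    k = int(flags.sum())
    pct = float(Fraction(100 * k, n))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return IncidenceResult(threshold=threshold, n_households=n, n_che=k,
                           incidence_pct=pct, ci95=(100 * float(lo), 100 * float(hi)))


def decompose(
    ds: SurveyDataset,
    beta: float = DEFAULT_BETA,
    window: tuple[float, float] = DEFAULT_WINDOW,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    weight_col: str | None = None,
    pl: PovertyLine | None = None,
) -> tuple[PovertyLine, pd.DataFrame]:
    """Per-household CHE decomposition in a single pass.

    Returns the poverty line and a DataFrame with, per household: THE_h,
    food_h, OOP_h, equivalized size, SE_h, PC_h, whether the food
    substitution was applied, the OOP/PC ratio, and a CHE flag column
    ``flag_<pct>`` per threshold.  A precomputed poverty line may be passed
    (e.g. to evaluate counterfactual data against the line estimated on the
    observed sample); by default it is estimated from ``ds`` itself.
    """
    _require_annual(ds)
    if pl is None:
        pl = poverty_line(ds, beta=beta, window=window, weight_col=weight_col)
    frame = ds.frame
    the = frame["expenditure_total"].to_numpy(dtype=float)
    food = frame["expenditure_food"].to_numpy(dtype=float)
    oop = oop_total(frame).to_numpy(dtype=float)
    eq = equivalized_size(frame["household_size"].to_numpy(), beta)
    se = pl.value_per_eq_adult * eq
    pc, subst = capacity_to_pay(the, food, se)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(pc > 0, oop / np.where(pc > 0, pc, 1.0),
                         np.where(oop > 0, np.inf, 0.0))
    out = pd.DataFrame({
        "household_id": frame["household_id"].to_numpy(),
        "the_h": the, "food_h": food, "oop_h": oop,
        "eq_size": eq, "se_h": se, "pc_h": pc,
        "substitution_applied": subst, "ratio": ratio,
    })
    for z in thresholds:
        out[f"flag_{int(round(z * 100))}"] = che_flag(oop, pc, z)
    return pl, out


def sensitivity_analysis(
    ds: SurveyDataset,
    beta: float = DEFAULT_BETA,
    window: tuple[float, float] = DEFAULT_WINDOW,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    weight_col: str | None = None,
) -> pd.DataFrame:
    """CHE incidence at each threshold from one shared decomposition pass.

    Thresholds must be ascending; because the flag is a thresholded ratio,
    incidence is non-increasing in the threshold.
    """
    thresholds = list(thresholds)
    if any(not (0 < z < 1) for z in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    _, dec = decompose(ds, beta=beta, window=window, thresholds=thresholds,
                       weight_col=weight_col)
    rows = []
    for z in thresholds:
        res = che_incidence(dec[f"flag_{int(round(z * 100))}"].to_numpy(), z)
        rows.append({
            "threshold": z, "n_households": res.n_households,
            "n_che": res.n_che, "incidence_pct": res.incidence_pct,
            "ci95_lo": res.ci95[0], "ci95_hi": res.ci95[1],
        })
    return pd.DataFrame(rows)
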