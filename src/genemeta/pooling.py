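"""Pooling of study odds ratios and between-study heterogeneity.

Three pooling routes are provided:

* inverse-variance fixed effect (``pool_fixed``): weights w_i = 1/v_i on the
  Woolf log-OR variances;
* DerSimonian-Laird random effects (``pool_random``): moment estimate of the
  between-study variance tau^2, weights w*_i = 1/(v_i + tau^2);
* Mantel-Haenszel fixed effect (``pool_mh``): pooled directly from the
  fourfold tables as ln[sum(a_i d_i / N_i) / sum(b_i c_i / N_i)] with the
  Robins-Breslow-Greenland variance. This is the classical stratified-table
  estimator and the default fixed-effect method of the major meta-analysis
  packages for binary outcomes.

Heterogeneity is Cochran's Q — the inverse-variance weighted sum of squared
deviations of study effects from the inverse-variance fixed pooled effect —
referred to a chi-square with k-1 degrees of freedom, plus I^2 and the
DerSimonian-Laird tau^2. ``pool_auto`` applies the model-selection rule used
throughout this package's analyses: random effects when the heterogeneity
p-value falls below ``alpha_h`` (default 0.05), fixed effect otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .contrasts import ContrastModel, FourfoldTable, apply_continuity
from .effects import EffectEstimate, _z_quantile, estimate_effect
from .errors import DegenerateDataError, ValidationError

__all__ = [
    "PoolingMethod",
    "HeterogeneityResult",
    "PooledEstimate",
    "heterogeneity",
    "pool_fixed",
    "pool_random",
    "pool_auto",
    "pool_mh",
]


class PoolingMethod(enum.Enum):
    FIXED_IV = "fixed_iv"
    RANDOM_DL = "random_dl"
    FIXED_MH = "fixed_mh"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its p-value, I-squared and DL tau-squared.

    ``p_value`` is ``None`` when there is a single study (df = 0), mirroring
    the blank heterogeneity cells of single-study report rows.
    """

    q_statistic: float
    df: int
    p_value: float | None
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledEstimate:
    """A pooled odds ratio with its weights and heterogeneity diagnostics."""

    model: ContrastModel
    method: PoolingMethod
    k: int
    pooled_log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    weights: tuple[float, ...]
    heterogeneity: HeterogeneityResult
    level: float = 0.95

    @property
    def is_fixed(self) -> bool:
        return self.method is not PoolingMethod.RANDOM_DL


def _check_effects(effects: Sequence[EffectEstimate]) -> list[EffectEstimate]:
    effects = list(effects)
    if not effects:
        raise ValidationError("pooling requires at least one effect estimate")
    models = {e.model for e in effects}
    if len(models) > 1:
        raise ValueError(
            f"cannot pool effects from different contrasts: {sorted(m.value for m in models)}"
        )
    return effects


def heterogeneity(
    effects: Sequence[EffectEstimate], pooled_fixed_log_or: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q and derived statistics for a set of study effects.

    Q is computed with inverse-variance weights around the inverse-variance
    fixed-effect pooled value (supplied, or recomputed when omitted); tau^2
    is the DerSimonian-Laird moment estimator
    max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    effects = _check_effects(effects)
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.variance for e in effects])
    if pooled_fixed_log_or is None:
        pooled_fixed_log_or = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled_fixed_log_or) ** 2))
    df = len(effects) - 1
    p_value = float(chi2.sf(q, df)) if df > 0 else None
    i_squared = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau_squared = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q, df, p_value, i_squared, tau_squared)


def _wald(pooled_log_or: float, se: float, level: float) -> tuple[float, float, float]:
    z = _z_quantile(level)
    return (
        math.exp(pooled_log_or),
        math.exp(pooled_log_or - z * se),
        math.exp(pooled_log_or + z * se),
    )


def pool_fixed(
    effects: Sequence[EffectEstimate], level: float = 0.95
) -> PooledEstimate:
    """Inverse-variance fixed-effect pooled odds ratio."""
    effects = _check_effects(effects)
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.variance for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    or_value, ci_low, ci_high = _wald(pooled, se, level)
    return PooledEstimate(
        model=effects[0].model,
        method=PoolingMethod.FIXED_IV,
        k=len(effects),
        pooled_log_or=pooled,
        se=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        weights=tuple(float(x) for x in w),
        heterogeneity=heterogeneity(effects, pooled),
        level=level,
    )


def pool_random(
    effects: Sequence[EffectEstimate], level: float = 0.95
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooled odds ratio.

    With tau^2 = 0 the starred weights equal the fixed-effect weights and the
    result coincides numerically with :func:`pool_fixed`.
    """
    effects = _check_effects(effects)
    het = heterogeneity(effects)
    theta = np.array([e.log_or for e in effects])
    w_star = np.array([1.0 / (e.variance + het.tau_squared) for e in effects])
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    or_value, ci_low, ci_high = _wald(pooled, se, level)
    return PooledEstimate(
        model=effects[0].model,
        method=PoolingMethod.RANDOM_DL,
        k=len(effects),
        pooled_log_or=pooled,
        se=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        weights=tuple(float(x) for x in w_star),
        heterogeneity=het,
        level=level,
    )


def pool_mh(
    tables: Sequence[FourfoldTable],
    level: float = 0.95,
    continuity_increment: float | None = None,
) -> PooledEstimate:
    """Mantel-Haenszel fixed-effect pooled odds ratio over fourfold tables.

    The point estimate needs no continuity correction (a zero cell simply
    contributes nothing to one of the sums); pass ``continuity_increment``
    to pool corrected tables instead, which is what the pipeline does so the
    point estimate and the per-study displays use identical cells. The
    variance is Robins-Breslow-Greenland. The attached heterogeneity is the
    standard Cochran Q computed from the Woolf effects of the
    (zero-cell-corrected) tables.
    """
    tables = list(tables)
    if not tables:
        raise ValidationError("pooling requires at least one table")
    models = {t.model for t in tables}
    if len(models) > 1:
        raise ValueError("cannot pool tables from different contrasts")
    if continuity_increment is not None:
        tables = [apply_continuity(t, continuity_increment) for t in tables]

    cells = np.array([t.cells for t in tables], dtype=float)
    a, b, c, d = cells.T
    n = cells.sum(axis=1)
    r = a * d / n
    s = b * c / n
    sum_r, sum_s = float(r.sum()), float(s.sum())
    if sum_r == 0 or sum_s == 0:
        raise DegenerateDataError(
            "Mantel-Haenszel pooled odds ratio undefined: a cross-product sum is zero"
        )
    pooled = math.log(sum_r / sum_s)
    p = (a + d) / n
    q = (b + c) / n
    variance = (
        float(np.sum(p * r)) / (2 * sum_r**2)
        + float(np.sum(p * s + q * r)) / (2 * sum_r * sum_s)
        + float(np.sum(q * s)) / (2 * sum_s**2)
    )
    se = math.sqrt(variance)
    or_value, ci_low, ci_high = _wald(pooled, se, level)
    # Q needs finite per-study log-ORs: correct zero-cell tables if not done.
    effect_tables = [t if not t.has_zero_cell else apply_continuity(t) for t in tables]
    het = heterogeneity([estimate_effect(t, level) for t in effect_tables])
    return PooledEstimate(
        model=tables[0].model,
        method=PoolingMethod.FIXED_MH,
        k=len(tables),
        pooled_log_or=pooled,
        se=se,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        weights=tuple(float(x) for x in s),
        heterogeneity=het,
        level=level,
    )


def pool_auto(
    effects: Sequence[EffectEstimate],
    alpha_h: float = 0.05,
    level: float = 0.95,
    *,
    tables: Sequence[FourfoldTable] | None = None,
) -> PooledEstimate:
    """Pool with the heterogeneity-driven model choice.

    Random effects (DerSimonian-Laird) when Cochran's Q gives p < ``alpha_h``;
    otherwise a fixed-effect model — Mantel-Haenszel when the fourfold
    ``tables`` are supplied (the pipeline default), inverse-variance
    otherwise. A single study is always pooled as fixed (Q is undefined).
    """
    effects = _check_effects(effects)
    het = heterogeneity(effects)
    if het.p_value is not None and het.p_value < alpha_h:
        return pool_random(effects, level)
    if tables is not None:
        return pool_mh(tables, level)
    return pool_fixed(effects, level)
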