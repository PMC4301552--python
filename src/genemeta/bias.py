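"""Publication-bias diagnostics: Begg-Mazumdar rank correlation, funnel data.

The Begg-Mazumdar test looks for a correlation between study effects and
their precisions: under selective publication, small (high-variance) studies
survive only when their effect is large, inducing rank correlation. Each
study effect is first standardised against the inverse-variance fixed
pooled value,

    t_i = (theta_i - theta_F) / sqrt(v_i - 1/sum(w)),

removing the common mean so that the ranks of t_i are exchangeable under
the null. Kendall's score between t and v is then referred to its exact
null variance k(k-1)(2k+5)/18 with a continuity correction of one unit
toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .effects import EffectEstimate, _z_quantile
from .errors import ValidationError
from .pooling import PooledEstimate

__all__ = ["BeggTestResult", "FunnelPoint", "FunnelData", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class BeggTestResult:
    """Result of the Begg-Mazumdar rank-correlation test.

    ``kendall_score`` is the concordant-minus-discordant pair count; ``tau``
    the tau-b correlation; ``degenerate`` flags inputs with no rank
    variation in the variances (tau undefined, reported as 0 with p = 1);
    ``low_power`` flags k < 3.
    """

    kendall_score: int
    tau: float
    z_statistic: float
    p_value: float
    k: int
    degenerate: bool = False
    low_power: bool = False


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    effect: float  # log odds ratio (x axis)
    precision: float  # standard error (y axis, conventionally inverted)


@dataclass(frozen=True)
class FunnelData:
    """Scatter points plus the centre line and pseudo confidence limits."""

    points: tuple[FunnelPoint, ...]
    center_log_or: float
    se_grid: tuple[float, ...]
    lower_limit: tuple[float, ...]
    upper_limit: tuple[float, ...]


def begg_test(effects: Sequence[EffectEstimate]) -> BeggTestResult:
    """Begg-Mazumdar publication-bias test on a set of study effects.

    Needs k >= 2; results for k < 3 are flagged ``low_power``. When every
    variance is identical there is nothing to rank against: the test is
    degenerate and returns tau = 0 with p = 1.
    """
    effects = list(effects)
    k = len(effects)
    if k < 2:
        raise ValidationError("the Begg-Mazumdar test needs at least two studies")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    theta_f = float(np.sum(w * theta) / np.sum(w))
    # v_i - 1/sum(w) is the variance of theta_i - theta_F; positive for k >= 2.
    t = (theta - theta_f) / np.sqrt(v - 1.0 / np.sum(w))

    score = 0
    ties_t = 0
    ties_v = 0
    for i in range(k):
        for j in range(i + 1, k):
            dt = np.sign(t[j] - t[i])
            dv = np.sign(v[j] - v[i])
            score += int(dt * dv)
            ties_t += dt == 0
            ties_v += dv == 0
    n_pairs = k * (k - 1) // 2
    if ties_v == n_pairs:
        return BeggTestResult(
            kendall_score=0, tau=0.0, z_statistic=0.0, p_value=1.0,
            k=k, degenerate=True, low_power=k < 3,
        )
    denom = math.sqrt((n_pairs - ties_t) * (n_pairs - ties_v))
    tau = score / denom if denom > 0 else 0.0
    sd = math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    z = max(0.0, abs(score) - 1) / sd  # continuity correction toward zero
    p_value = 1.0 if score == 0 else float(2 * norm.sf(z))
    return BeggTestResult(
        kendall_score=int(score),
        tau=float(tau),
        z_statistic=z,
        p_value=min(1.0, p_value),
        k=k,
        low_power=k < 3,
    )


def funnel_data(
    effects: Sequence[EffectEstimate],
    pooled: PooledEstimate,
    n_grid: int = 50,
) -> FunnelData:
    """Funnel-plot coordinates: one point per study plus pseudo 95% limits.

    Points are (log OR, standard error); the limit curves are
    center +/- z * se over a grid of standard errors from 0 to just above
    the largest observed se.
    """
    effects = list(effects)
    if not effects:
        raise ValidationError("funnel_data requires at least one effect")
    points = tuple(
        FunnelPoint(study_id=e.study_id, effect=e.log_or, precision=e.se)
        for e in effects
    )
    z = _z_quantile(pooled.level)
    se_max = max(e.se for e in effects) * 1.05
    grid = np.linspace(0.0, se_max, n_grid)
    center = pooled.pooled_log_or
    return FunnelData(
        points=points,
        center_log_or=center,
        se_grid=tuple(float(x) for x in grid),
        lower_limit=tuple(float(center - z * s) for s in grid),
        upper_limit=tuple(float(center + z * s) for s in grid),
    )
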