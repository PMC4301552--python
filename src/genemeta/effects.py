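"""Per-study effect estimation: odds ratio, Woolf variance, Wald interval.

For a fourfold table (a, b, c, d) the crude odds ratio is ad/bc. Estimation
is done on the natural-log scale: theta = ln(ad/bc) with the Woolf
(delta-method) variance v = 1/a + 1/b + 1/c + 1/d, and the confidence
interval exp(theta +/- z * sqrt(v)) — asymmetric on the OR scale, as is
standard for ratio estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .contrasts import ContrastModel, FourfoldTable

__all__ = ["EffectEstimate", "estimate_effect"]


def _z_quantile(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(norm.ppf(0.5 + level / 2))


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio of one study under one contrast, with variance and CI."""

    study_id: str
    model: ContrastModel
    log_or: float
    variance: float
    or_value: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    continuity_applied: bool = False

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def estimate_effect(table: FourfoldTable, level: float = 0.95) -> EffectEstimate:
    """Estimate the odds ratio of a fourfold table.

    All four cells must be strictly positive; apply the continuity
    correction upstream (:func:`genemeta.contrasts.apply_continuity`) if the
    table contains a zero.
    """
    z = _z_quantile(level)
    if table.has_zero_cell:
        raise ValueError(
            f"study {table.study_id!r}: zero cell in fourfold table; apply a "
            "continuity correction before estimating the odds ratio"
        )
    a, b, c, d = table.cells
    log_or = math.log((a * d) / (b * c))
    variance = 1 / a + 1 / b + 1 / c + 1 / d
    half_width = z * math.sqrt(variance)
    return EffectEstimate(
        study_id=table.study_id,
        model=table.model,
        log_or=log_or,
        variance=variance,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - half_width),
        ci_high=math.exp(log_or + half_width),
        level=level,
        continuity_applied=table.continuity_applied,
    )
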