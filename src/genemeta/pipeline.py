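"""Full meta-analysis orchestration: contrasts x strata, sensitivity, report.

``run_meta`` reproduces the standard association-study summary table: one
row per stratum of a grouping variable (cancer type by default) plus a
"Total" row pooling every study, one column block per genetic contrast,
each cell holding the pooled OR, its confidence interval and the
heterogeneity p-value. ``leave_one_out`` re-pools k times with one study
removed each time; ``format_report`` renders the table as text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .contrasts import ContrastModel, collapse, apply_continuity
from .corpus import StudyRecord
from .effects import estimate_effect
from .errors import ValidationError
from .pooling import PooledEstimate, pool_auto

__all__ = [
    "MetaResult",
    "LeaveOneOutResult",
    "run_meta",
    "leave_one_out",
    "format_report",
    "result_records",
]

#: Column order of the report: recessive, dominant, both codominant, allele.
MODEL_ORDER = (
    ContrastModel.RECESSIVE,
    ContrastModel.DOMINANT,
    ContrastModel.CODOM_HOM,
    ContrastModel.CODOM_HET,
    ContrastModel.ALLELE,
)

TOTAL_STRATUM = "Total"


@dataclass(frozen=True)
class MetaResult:
    """All pooled estimates of one variant, by stratum and contrast."""

    variant_id: str
    stratify_by: str
    strata: tuple[str, ...]  # named strata in first-appearance order; Total last
    rows: Mapping[tuple[str, ContrastModel], PooledEstimate]
    study_counts: Mapping[str, int] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, ContrastModel]) -> PooledEstimate:
        return self.rows[key]


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Sensitivity analysis: the pooled estimate after dropping each study."""

    model: ContrastModel
    entries: tuple[tuple[str, PooledEstimate], ...]  # (excluded study_id, pooled)


def _pool_cell(
    studies: Sequence[StudyRecord],
    model: ContrastModel,
    alpha_h: float,
    level: float,
    increment: float,
    fixed_method: str,
) -> PooledEstimate:
    tables = [apply_continuity(collapse(s, model), increment) for s in studies]
    effects = [estimate_effect(t, level) for t in tables]
    return pool_auto(
        effects,
        alpha_h=alpha_h,
        level=level,
        tables=tables if fixed_method == "mh" else None,
    )


def run_meta(
    studies: Sequence[StudyRecord],
    models: Sequence[ContrastModel] = MODEL_ORDER,
    stratify_by: str = "cancer_type",
    alpha_h: float = 0.05,
    level: float = 0.95,
    increment: float = 0.5,
    fixed_method: str = "mh",
) -> MetaResult:
    """Run the meta-analysis over every contrast and stratum.

    Parameters
    ----------
    studies
        One corpus; all records must share a variant_id.
    models
        Contrasts to analyse (all five by default).
    stratify_by
        StudyRecord attribute used for subgrouping (default ``cancer_type``).
    alpha_h
        Heterogeneity threshold of the fixed/random choice.
    increment
        Haldane-Anscombe continuity increment for zero-cell tables.
    fixed_method
        ``"mh"`` (Mantel-Haenszel, default) or ``"iv"`` (inverse-variance)
        for cells where the fixed-effect model is selected.
    """
    studies = list(studies)
    if not studies:
        raise ValidationError("run_meta requires a non-empty corpus")
    variants = {s.variant_id for s in studies}
    if len(variants) > 1:
        raise ValueError(f"corpus mixes variant ids: {sorted(variants)}")
    if fixed_method not in ("mh", "iv"):
        raise ValueError(f"fixed_method must be 'mh' or 'iv', got {fixed_method!r}")

    strata: list[str] = []
    for s in studies:
        label = getattr(s, stratify_by)
        if label not in strata:
            strata.append(label)

    rows: dict[tuple[str, ContrastModel], PooledEstimate] = {}
    counts: dict[str, int] = {}
    for stratum in [*strata, TOTAL_STRATUM]:
        members = (
            studies
            if stratum == TOTAL_STRATUM
            else [s for s in studies if getattr(s, stratify_by) == stratum]
        )
        counts[stratum] = len(members)
        for model in models:
            rows[(stratum, model)] = _pool_cell(
                members, model, alpha_h, level, increment, fixed_method
            )
    return MetaResult(
        variant_id=studies[0].variant_id,
        stratify_by=stratify_by,
        strata=(*strata, TOTAL_STRATUM),
        rows=rows,
        study_counts=counts,
    )


def leave_one_out(
    studies: Sequence[StudyRecord],
    model: ContrastModel,
    alpha_h: float = 0.05,
    level: float = 0.95,
    increment: float = 0.5,
    fixed_method: str = "mh",
) -> LeaveOneOutResult:
    """Re-pool k times, omitting one study per entry, in corpus order.

    The full fixed/random selection rule is re-applied on every reduced
    corpus, so the pooling model may differ between entries.
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValidationError("leave-one-out needs at least two studies")
    entries = []
    for i, excluded in enumerate(studies):
        rest = studies[:i] + studies[i + 1 :]
        pooled = _pool_cell(rest, model, alpha_h, level, increment, fixed_method)
        entries.append((excluded.study_id, pooled))
    return LeaveOneOutResult(model=model, entries=tuple(entries))


def _fmt_cell(est: PooledEstimate) -> str:
    return f"{est.or_value:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})"


def _fmt_ph(est: PooledEstimate) -> str:
    p = est.heterogeneity.p_value
    return "NA" if p is None else f"{p:.2f}"


def format_report(result: MetaResult) -> str:
    """Render a MetaResult as a fixed-width text table (ORs at 2 decimals)."""
    models = sorted(
        {m for (_, m) in result.rows}, key=lambda m: MODEL_ORDER.index(m)
    )
    header = [result.stratify_by] + [
        col for m in models for col in (m.label, "P_h")
    ]
    body: list[list[str]] = []
    for stratum in result.strata:
        row = [stratum]
        for m in models:
            est = result.rows[(stratum, m)]
            row += [_fmt_cell(est), _fmt_ph(est)]
        body.append(row)
    widths = [max(len(r[i]) for r in [header, *body]) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in [header, *body]
    ]
    lines.insert(1, "-" * max(len(line) for line in lines))
    return "\n".join(lines)


def result_records(result: MetaResult) -> list[dict]:
    """Flatten a MetaResult into JSON-ready records, one per (stratum, model)."""
    out = []
    for (stratum, model), est in result.rows.items():
        het = est.heterogeneity
        out.append(
            {
                "variant_id": result.variant_id,
                "stratum": stratum,
                "model": model.value,
                "method": est.method.value,
                "k": est.k,
                "or": est.or_value,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "log_or": est.pooled_log_or,
                "se": est.se,
                "q": het.q_statistic,
                "p_h": het.p_value,
                "i_squared": het.i_squared,
                "tau_squared": het.tau_squared,
                "level": est.level,
            }
        )
    return out
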