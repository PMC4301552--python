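"""Synthetic multi-study case-control genotype corpora with known truth.

Controls are drawn multinomially from Hardy-Weinberg proportions at a
variant-allele frequency p; cases from the same proportions tilted by
genotype-level odds ratios (psi_het for Aa, psi_hom for aa, both relative
to AA):

    P_case(g)  proportional to  P_ctrl(g) * psi_g .

This is the retrospective equivalent of a prospective logistic disease
model, so the population odds ratio of any collapsed contrast is under
exact control — in particular the recessive odds ratio equals psi_hom
whenever psi_het = 1. Between-study heterogeneity is modelled as a normal
perturbation of log psi_hom with standard deviation ``tau`` (the
heterozygote effect stays fixed), giving per-study recessive log odds
ratios N(ln psi_hom, tau^2) when psi_het = 1. An optional selection rule
emulates publication bias: small studies are published only when their
crude odds ratio exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import cycle

import numpy as np

from .contrasts import ContrastModel, collapse, apply_continuity
from .corpus import GenotypeCounts, StudyRecord
from .errors import DegenerateDataError, ValidationError

__all__ = [
    "SelectionRule",
    "SyntheticMetaConfig",
    "hwe_genotype_probs",
    "case_genotype_probs",
    "simulate_corpus",
]

_ETHNICITY_CYCLE = ("Caucasian", "Asian", "African", "Mixed")
_CANCER_CYCLE = ("Prostate", "Colorectal", "Lung")


def hwe_genotype_probs(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2).

    ``p`` is the variant-allele frequency, strictly inside (0, 1).
    """
    if not 0 < p < 1:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return (q * q, 2 * p * q, p * p)


def case_genotype_probs(
    control_probs: tuple[float, float, float],
    psi_het: float,
    psi_hom: float,
) -> tuple[float, float, float]:
    """Tilt control genotype probabilities by genotype odds ratios.

    Case probabilities are proportional to (P_AA, P_Aa * psi_het,
    P_aa * psi_hom). With psi_het = psi_hom = 1 the case distribution
    equals the control distribution.
    """
    if psi_het <= 0 or psi_hom <= 0:
        raise ValueError("genotype odds ratios must be positive")
    raw = np.array(control_probs, dtype=float) * np.array([1.0, psi_het, psi_hom])
    probs = raw / raw.sum()
    return (float(probs[0]), float(probs[1]), float(probs[2]))


@dataclass(frozen=True)
class SelectionRule:
    """Publish a small study only if its crude odds ratio exceeds a threshold.

    ``small_n_cases``: studies with at most this many cases are subject to
    selection; larger studies are always published. The crude odds ratio is
    evaluated under ``model`` with a 0.5 zero-cell correction.
    """

    or_threshold: float
    small_n_cases: int
    model: ContrastModel = ContrastModel.ALLELE


@dataclass(frozen=True)
class SyntheticMetaConfig:
    """Configuration of a synthetic multi-study corpus.

    Sample sizes and the allele frequency may be fixed values or (low, high)
    ranges sampled per study (sizes uniformly on integers, frequency
    uniformly on reals). ``tau`` is the between-study standard deviation of
    log psi_hom; 0 gives fixed-effect truth. ``seed`` fully determines the
    corpus.
    """

    k: int
    n_cases: int | tuple[int, int]
    n_controls: int | tuple[int, int]
    p: float | tuple[float, float]
    psi_hom: float = 1.0
    psi_het: float = 1.0
    tau: float = 0.0
    selection: SelectionRule | None = None
    seed: int = 0
    variant_id: str = "rs0000000"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError("k must be non-negative")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if self.psi_hom <= 0 or self.psi_het <= 0:
            raise ValidationError("genotype odds ratios must be positive")


def _draw_size(rng: np.random.Generator, size: int | tuple[int, int]) -> int:
    if isinstance(size, tuple):
        lo, hi = size
        value = int(rng.integers(lo, hi + 1))
    else:
        value = int(size)
    if value < 1:
        raise ValidationError(f"sample size must be >= 1, got {value}")
    return value


def _draw_freq(rng: np.random.Generator, p: float | tuple[float, float]) -> float:
    if isinstance(p, tuple):
        lo, hi = p
        value = float(rng.uniform(lo, hi))
    else:
        value = float(p)
    if not 0 < value < 1:
        raise ValidationError(f"allele frequency must be in (0, 1), got {value}")
    return value


def _crude_or(record: StudyRecord, model: ContrastModel) -> float:
    table = apply_continuity(collapse(record, model))
    return (table.a * table.d) / (table.b * table.c)


def simulate_corpus(config: SyntheticMetaConfig) -> list[StudyRecord]:
    """Generate a corpus of study records under the configured truth.

    Deterministic given ``config.seed``. Metadata labels (country,
    ethnicity, cancer type) cycle through fixed small sets so subgroup
    machinery is exercisable.

    Raises
    ------
    DegenerateDataError
        If the selection rule discards every generated study.
    """
    rng = np.random.default_rng(config.seed)
    ethnicities = cycle(_ETHNICITY_CYCLE)
    cancers = cycle(_CANCER_CYCLE)
    records: list[StudyRecord] = []
    for i in range(config.k):
        n_cases = _draw_size(rng, config.n_cases)
        n_controls = _draw_size(rng, config.n_controls)
        p = _draw_freq(rng, config.p)
        log_psi_hom = np.log(config.psi_hom)
        if config.tau > 0:
            log_psi_hom += rng.normal(0.0, config.tau)
        ctrl_probs = hwe_genotype_probs(p)
        case_probs = case_genotype_probs(
            ctrl_probs, config.psi_het, float(np.exp(log_psi_hom))
        )
        # redraw the rare all-in-one-class degenerate arms (total>0 invariant)
        while True:
            ctrl = rng.multinomial(n_controls, ctrl_probs)
            case = rng.multinomial(n_cases, case_probs)
            if ctrl.sum() > 0 and case.sum() > 0:
                break
        record = StudyRecord(
            study_id=f"synth{i:03d}",
            first_author=f"Synth{i:03d}",
            year=2000 + (i % 25),
            country="Simulandia",
            ethnicity=next(ethnicities),
            cancer_type=next(cancers),
            variant_id=config.variant_id,
            cases=GenotypeCounts(int(case[0]), int(case[1]), int(case[2])),
            controls=GenotypeCounts(int(ctrl[0]), int(ctrl[1]), int(ctrl[2])),
        )
        if config.selection is not None and n_cases <= config.selection.small_n_cases:
            if _crude_or(record, config.selection.model) <= config.selection.or_threshold:
                continue
        records.append(record)
    if config.k > 0 and not records:
        raise DegenerateDataError("selection rule discarded every generated study")
    return records
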