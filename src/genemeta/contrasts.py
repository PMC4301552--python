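"""Genetic contrast models: collapse genotype counts into 2x2 tables.

Each contrast dichotomises the three genotype classes (AA, Aa, aa with 'a'
the variant allele) into exposed/unexposed and yields a fourfold table

    =========  ======  ========
               cases   controls
    =========  ======  ========
    exposed      a        c
    unexposed    b        d
    =========  ======  ========

The allele contrast counts the two alleles carried by each subject as
independent observations, so its margins are twice the subject totals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .corpus import GenotypeCounts, StudyRecord
from .errors import ExclusionError

__all__ = ["ContrastModel", "FourfoldTable", "collapse", "apply_continuity"]


class ContrastModel(enum.Enum):
    """The five standard genetic contrasts of a biallelic variant."""

    RECESSIVE = "recessive"      # aa vs Aa+AA
    DOMINANT = "dominant"        # aa+Aa vs AA
    CODOM_HOM = "codom_hom"      # aa vs AA (heterozygotes dropped)
    CODOM_HET = "codom_het"      # Aa vs AA (variant homozygotes dropped)
    ALLELE = "allele"            # a vs A, two alleles per subject

    @classmethod
    def from_name(cls, name: str) -> "ContrastModel":
        key = name.strip().lower().replace("-", "_")
        for member in cls:
            if member.value == key or member.name.lower() == key:
                return member
        raise KeyError(f"unknown contrast model {name!r}")

    @property
    def label(self) -> str:
        return {
            ContrastModel.RECESSIVE: "aa vs. Aa+AA",
            ContrastModel.DOMINANT: "aa+Aa vs. AA",
            ContrastModel.CODOM_HOM: "aa vs. AA",
            ContrastModel.CODOM_HET: "Aa vs. AA",
            ContrastModel.ALLELE: "a vs. A",
        }[self]


@dataclass(frozen=True)
class FourfoldTable:
    """A 2x2 exposed/unexposed by case/control table for one study.

    Cells are real-valued so that a continuity correction can offset them
    from the integer counts; ``continuity_applied`` records whether it did.
    """

    a: float  # exposed cases
    b: float  # unexposed cases
    c: float  # exposed controls
    d: float  # unexposed controls
    model: ContrastModel
    study_id: str
    continuity_applied: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("fourfold table cells must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.cells) == 0


def _dichotomise(
    counts: GenotypeCounts, model: ContrastModel
) -> tuple[float, float]:
    if model is ContrastModel.RECESSIVE:
        return counts.n_hom_variant, counts.n_het + counts.n_hom_common
    if model is ContrastModel.DOMINANT:
        return counts.n_hom_variant + counts.n_het, counts.n_hom_common
    if model is ContrastModel.CODOM_HOM:
        return counts.n_hom_variant, counts.n_hom_common
    if model is ContrastModel.CODOM_HET:
        return counts.n_het, counts.n_hom_common
    if model is ContrastModel.ALLELE:
        return counts.variant_alleles, counts.common_alleles
    raise KeyError(model)  # pragma: no cover


def collapse(record: StudyRecord, model: ContrastModel) -> FourfoldTable:
    """Collapse a study record into a fourfold table under one contrast.

    Total for every record and model; no continuity correction is applied
    here (see :func:`apply_continuity`).
    """
    a, b = _dichotomise(record.cases, model)
    c, d = _dichotomise(record.controls, model)
    return FourfoldTable(
        a=float(a), b=float(b), c=float(c), d=float(d),
        model=model, study_id=record.study_id,
    )


def apply_continuity(table: FourfoldTable, increment: float = 0.5) -> FourfoldTable:
    """Haldane-Anscombe correction: add ``increment`` to every cell if any is 0.

    Tables without a zero cell are returned unchanged. A table whose case
    margin (a+b) or control margin (c+d) is entirely zero carries no
    information about the contrast and is rejected.

    Raises
    ------
    ExclusionError
        If the case or control margin is zero.
    ValueError
        If ``increment`` is not positive.
    """
    if increment <= 0:
        raise ValueError(f"continuity increment must be positive, got {increment}")
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise ExclusionError(
            f"study {table.study_id!r} has an empty "
            f"{'case' if table.a + table.b == 0 else 'control'} margin under "
            f"{table.model.value}; it cannot contribute to this contrast"
        )
    if not table.has_zero_cell:
        return table
    return replace(
        table,
        a=table.a + increment,
        b=table.b + increment,
        c=table.c + increment,
        d=table.d + increment,
        continuity_applied=True,
    )
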