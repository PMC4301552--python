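"""Study-level domain types and delimited-text I/O.

A *study* is one case-control arm genotyped at a biallelic variant: three
genotype counts for cases (common homozygote AA, heterozygote Aa, variant
homozygote aa) and three for controls, plus the stratification metadata
(first author, year, country, ethnicity, cancer type) used for subgrouping.
Counts are stored per genotype and never pre-collapsed, so every genetic
contrast is derived from the same record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "GenotypeCounts",
    "StudyRecord",
    "ETHNICITIES",
    "SCHEMA_COLUMNS",
    "load_studies",
    "write_studies",
    "total_counts",
]

#: Closed set of ethnicity labels; multi-ethnicity arms are labelled Mixed.
ETHNICITIES = frozenset({"Caucasian", "African", "Asian", "Mixed"})

#: Column order of the delimited interchange format.
SCHEMA_COLUMNS = (
    "study_id",
    "first_author",
    "year",
    "country",
    "ethnicity",
    "cancer_type",
    "variant_id",
    "case_AA",
    "case_Aa",
    "case_aa",
    "ctrl_AA",
    "ctrl_Aa",
    "ctrl_aa",
)


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm of a case-control study.

    Attributes
    ----------
    n_hom_common : int
        Common-allele homozygotes (AA).
    n_het : int
        Heterozygotes (Aa).
    n_hom_variant : int
        Variant-allele homozygotes (aa).
    """

    n_hom_common: int
    n_het: int
    n_hom_variant: int

    def __post_init__(self) -> None:
        for name in ("n_hom_common", "n_het", "n_hom_variant"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value}")
        if self.total == 0:
            raise ValidationError("genotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_hom_common + self.n_het + self.n_hom_variant

    @property
    def variant_alleles(self) -> int:
        """Number of variant alleles carried by the arm (2·aa + Aa)."""
        return 2 * self.n_hom_variant + self.n_het

    @property
    def common_alleles(self) -> int:
        return 2 * self.n_hom_common + self.n_het


@dataclass(frozen=True)
class StudyRecord:
    """One study arm: metadata plus case and control genotype counts.

    ``ethnicity`` and ``cancer_type`` are title-cased on construction so
    subgrouping is robust to capitalisation of the source labels.
    """

    study_id: str
    first_author: str
    year: int
    country: str
    ethnicity: str
    cancer_type: str
    variant_id: str
    cases: GenotypeCounts
    controls: GenotypeCounts

    def __post_init__(self) -> None:
        object.__setattr__(self, "ethnicity", str(self.ethnicity).strip().title())
        object.__setattr__(self, "cancer_type", str(self.cancer_type).strip().title())
        if not self.study_id:
            raise ValidationError("study_id must be a non-empty string")
        if self.ethnicity not in ETHNICITIES:
            raise ValidationError(
                f"study {self.study_id!r}: ethnicity {self.ethnicity!r} not in "
                f"{sorted(ETHNICITIES)}"
            )


def _record_from_row(row: "pd.Series") -> StudyRecord:
    def count(field: str) -> int:
        raw = row[field]
        try:
            value = int(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"study {row['study_id']!r}: field {field!r} is not an integer "
                f"({raw!r})"
            ) from None
        if float(raw) != value:
            raise ValidationError(
                f"study {row['study_id']!r}: field {field!r} is not an integer "
                f"({raw!r})"
            )
        if value < 0:
            raise ValidationError(
                f"study {row['study_id']!r}: field {field!r} is negative ({value})"
            )
        return value

    try:
        cases = GenotypeCounts(count("case_AA"), count("case_Aa"), count("case_aa"))
        controls = GenotypeCounts(count("ctrl_AA"), count("ctrl_Aa"), count("ctrl_aa"))
    except ValidationError as exc:
        raise ValidationError(f"study {row['study_id']!r}: {exc}") from None
    return StudyRecord(
        study_id=str(row["study_id"]),
        first_author=str(row["first_author"]),
        year=int(row["year"]),
        country=str(row["country"]),
        ethnicity=str(row["ethnicity"]),
        cancer_type=str(row["cancer_type"]),
        variant_id=str(row["variant_id"]),
        cases=cases,
        controls=controls,
    )


def load_studies(source: str | IO[str], sep: str | None = None) -> list[StudyRecord]:
    """Read study records from delimited text (comma or tab).

    Parameters
    ----------
    source : path or text stream
        UTF-8 delimited text with the header defined by ``SCHEMA_COLUMNS``.
    sep : str, optional
        Field separator; auto-detected (csv sniffing) when omitted.

    Returns
    -------
    list of StudyRecord
        One validated record per data row, in file order.
    """
    frame = pd.read_csv(source, sep=sep, engine="python", dtype=str, skipinitialspace=True)
    missing = [c for c in SCHEMA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = [_record_from_row(row) for _, row in frame.iterrows()]
    seen: set[str] = set()
    for record in records:
        if record.study_id in seen:
            raise ValidationError(f"duplicate study_id {record.study_id!r}")
        seen.add(record.study_id)
    return records


def write_studies(
    studies: Iterable[StudyRecord], target: str | IO[str], sep: str = ","
) -> None:
    """Write records in the interchange schema (integer fields bit-identical)."""
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "first_author": s.first_author,
                "year": s.year,
                "country": s.country,
                "ethnicity": s.ethnicity,
                "cancer_type": s.cancer_type,
                "variant_id": s.variant_id,
                "case_AA": s.cases.n_hom_common,
                "case_Aa": s.cases.n_het,
                "case_aa": s.cases.n_hom_variant,
                "ctrl_AA": s.controls.n_hom_common,
                "ctrl_Aa": s.controls.n_het,
                "ctrl_aa": s.controls.n_hom_variant,
            }
        )
    pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(target, sep=sep, index=False)


def total_counts(studies: Sequence[StudyRecord]) -> tuple[int, int]:
    """Total genotyped cases and controls across a corpus.

    Raises
    ------
    ValidationError
        If the corpus is empty.
    """
    studies = list(studies)
    if not studies:
        raise ValidationError("total_counts requires a non-empty corpus")
    n_cases = sum(s.cases.total for s in studies)
    n_controls = sum(s.controls.total for s in studies)
    return n_cases, n_controls
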