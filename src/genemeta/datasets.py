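"""Bundled example corpus: CRP variants rs2808630 and rs1417938 and cancer risk.

The corpus collects the published per-study genotype counts of case-control
studies of two single-nucleotide polymorphisms in the C-reactive protein
(*CRP*) gene — 3407 A>G (rs2808630) and 29 A>T (rs1417938) — in prostate,
lung and colorectal cancer. The variant allele (G, respectively T) is the
exposure allele throughout; counts are kept exactly as published, with no
minor-allele re-orientation (for rs1417938 the variant allele is the major
allele in two study populations). One publication reporting two ethnic
strata contributes two independent arms (Pierce 2009, Caucasian and
African).

Totals: 888 cases / 3,167 controls over five arms for rs2808630, and
3,110 cases / 5,951 controls over six arms for rs1417938.
"""

from __future__ import annotations

from .corpus import GenotypeCounts, StudyRecord

__all__ = ["builtin_fixture", "FIXTURE_VARIANTS"]

# study_id, first_author, year, country, ethnicity, cancer_type,
# case (AA, Aa, aa), control (AA, Aa, aa) -- 'a' is the variant allele.
_RS2808630 = (
    ("pierce2009_cauc", "Pierce", 2009, "USA", "Caucasian", "Prostate",
     (89, 73, 13), (1026, 760, 148)),
    ("pierce2009_afr", "Pierce", 2009, "USA", "African", "Prostate",
     (24, 16, 0), (184, 107, 9)),
    ("tsilidis2009", "Tsilidis", 2009, "USA", "Caucasian", "Colorectal",
     (96, 84, 19), (204, 124, 34)),
    ("chaturvedi2010", "Chaturvedi", 2010, "USA", "Mixed", "Lung",
     (206, 153, 19), (242, 172, 33)),
    ("xu2012", "Xu", 2012, "China", "Asian", "Lung",
     (52, 38, 6), (65, 51, 8)),
)

_RS1417938 = (
    ("pierce2009_cauc", "Pierce", 2009, "USA", "Caucasian", "Prostate",
     (83, 69, 23), (921, 830, 183)),
    ("pierce2009_afr", "Pierce", 2009, "USA", "African", "Prostate",
     (31, 8, 1), (230, 66, 4)),
    ("tsilidis2009", "Tsilidis", 2009, "USA", "Caucasian", "Colorectal",
     (15, 74, 109), (43, 140, 177)),
    ("chaturvedi2010", "Chaturvedi", 2010, "USA", "Mixed", "Lung",
     (186, 149, 42), (221, 177, 49)),
    ("slattery2011", "Slattery", 2011, "USA", "Mixed", "Colorectal",
     (186, 918, 1120), (238, 1175, 1373)),
    ("xu2012", "Xu", 2012, "China", "Asian", "Lung",
     (49, 38, 9), (59, 50, 15)),
)

_FIXTURES = {"rs2808630": _RS2808630, "rs1417938": _RS1417938}

#: Variant ids available from :func:`builtin_fixture`.
FIXTURE_VARIANTS = tuple(sorted(_FIXTURES))


def builtin_fixture(variant_id: str) -> list[StudyRecord]:
    """Return the bundled study corpus for one of the two CRP variants.

    Parameters
    ----------
    variant_id : {"rs2808630", "rs1417938"}

    Raises
    ------
    KeyError
        For any other variant id.
    """
    try:
        rows = _FIXTURES[variant_id]
    except KeyError:
        raise KeyError(
            f"no bundled corpus for {variant_id!r}; available: {FIXTURE_VARIANTS}"
        ) from None
    return [
        StudyRecord(
            study_id=study_id,
            first_author=author,
            year=year,
            country=country,
            ethnicity=ethnicity,
            cancer_type=cancer,
            variant_id=variant_id,
            cases=GenotypeCounts(*case),
            controls=GenotypeCounts(*ctrl),
        )
        for study_id, author, year, country, ethnicity, cancer, case, ctrl in rows
    ]
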