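"""Core domain types for individual case safety report (ICSR) analysis.

An ICSR is one spontaneous adverse-event report: patient demographics,
seriousness, the drugs on the report (with role, dose, dates and
dechallenge/rechallenge outcomes) and the reported reaction terms.
These types are deliberately plain containers; all heavy lifting is done
on tabular (pandas) views of a report collection.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

# Controlled vocabularies ---------------------------------------------------

AGE_GROUPS: tuple[str, ...] = ("18-44", "45-64", "65-74", "75plus")
AGE_LEVELS: tuple[str, ...] = AGE_GROUPS + ("unknown",)
SEX_LEVELS: tuple[str, ...] = ("female", "male", "unknown")
SERIOUS_LEVELS: tuple[str, ...] = ("yes", "no", "unknown")
SERIOUSNESS_CRITERIA: tuple[str, ...] = (
    "hospitalization",
    "congenital_anomaly",
    "death",
    "disabling",
    "life_threatening",
    "other",
)
DRUG_ROLES: tuple[str, ...] = ("suspect", "concomitant", "interacting")
DECHALLENGE_LEVELS: tuple[str, ...] = ("positive", "negative", "unknown")
RECHALLENGE_LEVELS: tuple[str, ...] = ("positive", "negative", "not_done", "unknown")

#: Age-band boundaries used when binning a raw age in years: [18,45), [45,65),
#: [65,75), [75, inf).  Ages below 18 map to ``unknown`` so that the adult
#: restriction applied downstream removes them.
AGE_BIN_EDGES: tuple[int, ...] = (18, 45, 65, 75)


def canonical_term(term: str) -> str:
    """Canonical form of a reaction term: stripped and case-folded.

    Idempotent by construction (stripping and case-folding are both
    idempotent), which makes vocabulary matching order-insensitive.
    """
    return term.strip().casefold()


def canonical_code(code: str) -> str:
    """Canonical form of an ATC code: stripped, upper-cased."""
    return code.strip().upper()


def code_matches(code: str, code_set: frozenset[str] | set[str]) -> bool:
    """True when ``code`` equals, or descends from, any entry of ``code_set``.

    ATC is hierarchical, so vocabulary entries act as prefixes: the class
    entry ``C02`` matches the full substance code ``C02AC01``.
    """
    c = canonical_code(code)
    return any(c.startswith(prefix) for prefix in code_set)


def bin_age(age_years: float | None) -> str:
    """Bin a raw age in years into the adult age bands used for analysis."""
    if age_years is None or age_years != age_years:  # None or NaN
        return "unknown"
    if age_years < AGE_BIN_EDGES[0]:
        return "unknown"
    if age_years < AGE_BIN_EDGES[1]:
        return "18-44"
    if age_years < AGE_BIN_EDGES[2]:
        return "45-64"
    if age_years < AGE_BIN_EDGES[3]:
        return "65-74"
    return "75plus"


# Report structure ----------------------------------------------------------


@dataclass
class DrugEntry:
    """One drug on a report."""

    report_id: str
    drug_code: str
    role: str = "suspect"
    daily_dose_mg: Optional[float] = None
    start_date: Optional[_dt.date] = None
    stop_date: Optional[_dt.date] = None
    dechallenge: str = "unknown"
    rechallenge: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"invalid drug role {self.role!r}")
        if self.dechallenge not in DECHALLENGE_LEVELS:
            raise ValueError(f"invalid dechallenge outcome {self.dechallenge!r}")
        if self.rechallenge not in RECHALLENGE_LEVELS:
            raise ValueError(f"invalid rechallenge outcome {self.rechallenge!r}")
        if self.daily_dose_mg is not None and self.daily_dose_mg < 0:
            raise ValueError("daily_dose_mg must be non-negative")
        if (
            self.start_date is not None
            and self.stop_date is not None
            and self.stop_date < self.start_date
        ):
            raise ValueError("stop_date precedes start_date")


@dataclass
class ReactionEntry:
    """One reported reaction term on a report."""

    report_id: str
    term: str
    onset_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if not self.term or not self.term.strip():
            raise ValueError("reaction term must be non-empty")


@dataclass
class ICSRReport:
    """One individual case safety report (the unit of analysis)."""

    report_id: str
    age_group: str = "unknown"
    sex: str = "unknown"
    serious: str = "unknown"
    seriousness_criteria: frozenset[str] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_group not in AGE_LEVELS:
            raise ValueError(f"invalid age_group {self.age_group!r}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.serious not in SERIOUS_LEVELS:
            raise ValueError(f"invalid serious flag {self.serious!r}")
        self.seriousness_criteria = frozenset(self.seriousness_criteria)
        bad = self.seriousness_criteria - set(SERIOUSNESS_CRITERIA)
        if bad:
            raise ValueError(f"invalid seriousness criteria {sorted(bad)}")
        if self.seriousness_criteria and self.serious != "yes":
            raise ValueError("seriousness_criteria present on a non-serious report")


# Vocabulary ----------------------------------------------------------------


@dataclass
class Vocabulary:
    """Controlled vocabularies driving case and exposure classification.

    ``smq_terms`` is a flat list of reaction terms standing in for a
    standardized MedDRA query; matching is exact on canonicalized strings.
    Drug code sets are ATC prefixes (see :func:`code_matches`).
    """

    smq_terms: frozenset[str]
    target_drugs: dict[str, frozenset[str]]
    antihypertensive_codes: frozenset[str] = frozenset()
    hypertensive_inducer_codes: frozenset[str] = frozenset()
    comparator_population_codes: frozenset[str] = frozenset()
    stroke_terms: frozenset[str] = frozenset()
    mi_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.smq_terms = frozenset(canonical_term(t) for t in self.smq_terms)
        if not self.smq_terms:
            raise ValueError("smq_terms must be non-empty")
        self.target_drugs = {
            label: frozenset(canonical_code(c) for c in codes)
            for label, codes in self.target_drugs.items()
        }
        for attr in (
            "antihypertensive_codes",
            "hypertensive_inducer_codes",
            "comparator_population_codes",
        ):
            setattr(self, attr, frozenset(canonical_code(c) for c in getattr(self, attr)))
        for attr in ("stroke_terms", "mi_terms"):
            setattr(self, attr, frozenset(canonical_term(t) for t in getattr(self, attr)))

    @property
    def drug_labels(self) -> list[str]:
        """Target drug labels in alphabetical order (output table order)."""
        return sorted(self.target_drugs)

    def is_smq_term(self, term: str) -> bool:
        return canonical_term(term) in self.smq_terms

    def all_target_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for codes in self.target_drugs.values():
            out |= codes
        return frozenset(out)


# Analysis results ----------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells of a drug-event cross-classification.

    a: exposed cases, b: exposed non-cases, c: unexposed cases,
    d: unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b


@dataclass
class SignalResult:
    """Crude and adjusted reporting odds ratio for one drug-event pair.

    ``None`` fields render as "NA": a drug with no exposed case has an
    undefined ROR, and a failed/separated adjusted fit has an undefined aROR.
    """

    drug: str
    a: int
    b: int
    ror: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    aror: Optional[float] = None
    aci_low: Optional[float] = None
    aci_high: Optional[float] = None
    signal: Optional[bool] = None
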