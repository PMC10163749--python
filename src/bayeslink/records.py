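"""Person record containers shared across the package.

Two parallel representations exist: :class:`PersonRecord` holds plaintext
identifiers, and :class:`HashedPersonRecord` is its de-identified twin in
which every identifier and fuzzy tier has been replaced by a keyed digest,
with population frequencies attached on the proband side so the identical
Bayesian comparison can run without plaintext.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Any

__all__ = ["DatedValue", "PersonRecord", "HashedName", "HashedSurname",
           "HashedDob", "HashedGender", "HashedPostcode", "HashedPersonRecord"]


@dataclass(frozen=True)
class DatedValue:
    """An identifier token with an optional validity period.

    Null dates mean "unknown/open".  Two dated values *explicitly* do not
    overlap only when one's end date strictly precedes the other's start
    date with both present; any null endpoint counts as possibly
    overlapping.
    """
    value: str
    start_date: date | None = None
    end_date: date | None = None

    def __post_init__(self) -> None:
        if (self.start_date is not None and self.end_date is not None
                and self.start_date > self.end_date):
            raise ValueError(f"start_date after end_date for {self.value!r}")

    def explicitly_nonoverlapping(self, other: "DatedValue") -> bool:
        if self.end_date is not None and other.start_date is not None \
                and self.end_date < other.start_date:
            return True
        if other.end_date is not None and self.start_date is not None \
                and other.end_date < self.start_date:
            return True
        return False


@dataclass
class PersonRecord:
    """Plaintext identity bundle for one person.

    local_id is unique within its file and never used as linkage evidence;
    gender is one of F/M/X or None (absent); perfect_ids holds named
    person-unique identifiers (e.g. NHS number) that short-circuit
    probabilistic matching; payload is passed through unmodified.
    """
    local_id: str
    forenames: list[DatedValue] = field(default_factory=list)
    surnames: list[DatedValue] = field(default_factory=list)
    dob: date | None = None
    gender: str | None = None
    postcodes: list[DatedValue] = field(default_factory=list)
    perfect_ids: dict[str, str] = field(default_factory=dict)
    payload: Any = None


# ---------------------------------------------------------------------------
# Hashed (de-identified) representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HashedName:
    """Digests of one name and its fuzzy tiers, with proband-side frequencies.

    Frequencies (rounded to the configured significant figures) are present
    in proband-mode files and None in sample-mode files.  Dates stay in
    plaintext.
    """
    name: str
    metaphone: str
    f2c: str
    name_freq: float | None = None
    metaphone_freq: float | None = None
    f2c_freq: float | None = None
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other) -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


@dataclass(frozen=True)
class HashedSurname:
    """One recorded surname as a set of hashed fragments (joined form first)."""
    fragments: tuple[HashedName, ...]
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other) -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


@dataclass(frozen=True)
class HashedDob:
    """Digest of the full DOB plus the three two-component projections.

    The projections (year-month, month-day, year-day) let the comparer
    detect a single-component mismatch without plaintext: a partial match
    is a differing full digest with at least one projection digest equal.
    """
    full: str
    year_month: str
    month_day: str
    year_day: str


@dataclass(frozen=True)
class HashedGender:
    digest: str
    frequency: float | None = None  # proband-side P(this gender)


@dataclass(frozen=True)
class HashedPostcode:
    unit: str
    sector: str
    pseudo: bool
    unit_freq: float | None = None    # national f_f; None for pseudo/unknown units
    sector_freq: float | None = None  # national f_p
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other) -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


@dataclass
class HashedPersonRecord:
    """De-identified person record.

    mode is "proband" (frequencies and gender-resolved error rates
    attached) or "sample" (digests only).  The error-rate triples are
    (p_ep1, p_ep2np1, p_en) resolved for the proband's gender; attaching
    them reveals nothing beyond the attached gender frequency, and lets the
    hashed comparison reproduce plaintext decisions exactly.
    """
    local_id: str
    mode: str = "sample"
    forenames: list[HashedName] = field(default_factory=list)
    surnames: list[HashedSurname] = field(default_factory=list)
    dob: HashedDob | None = None
    gender: HashedGender | None = None
    postcodes: list[HashedPostcode] = field(default_factory=list)
    perfect_ids: dict[str, str] = field(default_factory=dict)
    payload: Any = None
    forename_error_rates: tuple[float, float, float] | None = None
    surname_error_rates: tuple[float, float, float] | None = None
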