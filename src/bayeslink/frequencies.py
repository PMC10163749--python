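"""Population frequency models: every P(D | different person) the matcher needs.

Covers gender-conditional name/metaphone/F2C frequency tables with minimum
floors, the closed-form date-of-birth model parameterised by the
birth-year range b, the UK postcode unit/sector population model with
pseudopostcode handling, and the pairwise-sharing probability calculator
used to derive summary statistics from a frequency table.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .config import GENDER_FEMALE, GENDER_MALE
from .phonetics import metaphone

__all__ = [
    "round_sig",
    "dob_probabilities",
    "DobModel",
    "NameFrequencyTable",
    "PostcodeModel",
    "FrequencyModel",
    "pairwise_sharing_probability",
    "estimate_nfa_proportion",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375
MONTHS_PER_YEAR = 12


def round_sig(x: float, significant_figures: int) -> float:
    """Round to the given number of significant figures (ties to even).

    Used when emitting frequencies into hashed files: rounding reduces the
    identifiability of very precise frequency values while keeping enough
    precision to distinguish name from metaphone frequencies.
    """
    if significant_figures < 1:
        raise ValueError("significant_figures must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{significant_figures}g}")


# ---------------------------------------------------------------------------
# Date of birth
# ---------------------------------------------------------------------------

def dob_probabilities(b: float) -> tuple[float, float, float]:
    """(p_f, p_pnf, p_n): chance DOB agreement between two random people.

    With birthdays spread over a b-year range, two different people share a
    full DOB with probability p_f = 1/(365.25·b).  A partial match (exactly
    one of year/month/day differing) has probability
    p_pnf = 1/365.25 + 1/(30.4375·b) + 1/(12·b) − 3/(365.25·b)
          = (16·b + 631)/(5844·b).
    29 February is treated like any other day.
    """
    if b <= 0:
        raise ValueError("b must be > 0")
    p_f = 1.0 / (DAYS_PER_YEAR * b)
    p_pnf = (16.0 * b + 631.0) / (5844.0 * b)
    return p_f, p_pnf, 1.0 - p_f - p_pnf


@dataclass(frozen=True)
class DobModel:
    """Closed-form DOB chance-match model, parameterised by b (years)."""
    b: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")

    def probabilities(self) -> tuple[float, float, float]:
        return dob_probabilities(self.b)

    @property
    def shortlist_probability(self) -> float:
        """P(random candidate passes the full-or-partial DOB filter)."""
        p_f, p_pnf, _ = self.probabilities()
        return p_f + p_pnf

    @property
    def prefilter_speedup(self) -> float:
        """Expected fold speed-up of the full-or-partial DOB pre-filter."""
        return 1.0 / self.shortlist_probability

    @property
    def exact_only_extra_speedup(self) -> float:
        """Further fold speed-up when restricting to exact DOB matches."""
        p_f, p_pnf, _ = self.probabilities()
        return (p_f + p_pnf) / p_f

    @staticmethod
    def b_from_p_f(p_f: float) -> float:
        """Recover b from an empirically measured full-match probability."""
        if p_f <= 0:
            raise ValueError("p_f must be > 0")
        return 1.0 / (DAYS_PER_YEAR * p_f)


# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------

TIER_NAME = "name"
TIER_METAPHONE = "metaphone"
TIER_F2C = "f2c"


class NameFrequencyTable:
    """Gender-conditional name frequencies with derived fuzzy-tier tables.

    ``entries`` maps (standardized name, gender in {F, M}) to the
    population frequency of that name within that gender.  Metaphone and
    first-two-character (F2C) frequencies are derived by summing the
    frequencies of all contributing names, so a fuzzy-tier frequency is
    never smaller than that of any name it covers.  Lookups are floored at
    ``f_min`` (required for names absent from the table); probands of
    gender X or unknown use the whole-population weighted mean of the F/M
    values.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float], f_min: float,
                 p_female_given_fm: float = 0.51) -> None:
        if f_min <= 0:
            raise ValueError("f_min must be > 0")
        self.f_min = f_min
        self.p_female_given_fm = p_female_given_fm
        self._names: dict[tuple[str, str], float] = {}
        self._metaphones: dict[tuple[str, str], float] = {}
        self._f2c: dict[tuple[str, str], float] = {}
        for (name, gender), freq in entries.items():
            if gender not in (GENDER_FEMALE, GENDER_MALE):
                raise ValueError(f"table gender must be F or M, got {gender!r}")
            if not 0 < freq <= 1:
                raise ValueError(f"frequency for {name!r}/{gender} must be in (0,1]")
            key = (name, gender)
            self._names[key] = self._names.get(key, 0.0) + freq
        for (name, gender), freq in self._names.items():
            mkey = (metaphone(name), gender)
            self._metaphones[mkey] = self._metaphones.get(mkey, 0.0) + freq
            fkey = (name[:2], gender)
            self._f2c[fkey] = self._f2c.get(fkey, 0.0) + freq

    @classmethod
    def from_tsv(cls, path: str | Path, f_min: float,
                 p_female_given_fm: float = 0.51,
                 delimiter: str = "\t") -> "NameFrequencyTable":
        """Load a (name, gender, frequency) table with a header row."""
        entries: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            for row in reader:
                entries[(row["name"].strip().upper(), row["gender"].strip().upper())] = \
                    float(row["frequency"])
        return cls(entries, f_min=f_min, p_female_given_fm=p_female_given_fm)

    def to_tsv(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["name", "gender", "frequency"])
            for (name, gender), freq in sorted(self._names.items()):
                writer.writerow([name, gender, repr(freq)])

    def _lookup(self, table: Mapping[tuple[str, str], float], key: str,
                gender: str | None) -> float:
        if gender in (GENDER_FEMALE, GENDER_MALE):
            return max(table.get((key, gender), 0.0), self.f_min)
        w = self.p_female_given_fm
        female = max(table.get((key, GENDER_FEMALE), 0.0), self.f_min)
        male = max(table.get((key, GENDER_MALE), 0.0), self.f_min)
        return w * female + (1 - w) * male

    def frequency(self, key: str, tier: str, gender: str | None) -> float:
        """Floored frequency of a name / metaphone / F2C token for a gender."""
        if tier == TIER_NAME:
            return self._lookup(self._names, key, gender)
        if tier == TIER_METAPHONE:
            return self._lookup(self._metaphones, key, gender)
        if tier == TIER_F2C:
            return self._lookup(self._f2c, key, gender)
        raise ValueError(f"unknown tier {tier!r}")

    def tier_frequencies(self, name: str, gender: str | None) -> tuple[float, float, float]:
        """(name, metaphone, F2C) frequencies for one standardized name."""
        return (self.frequency(name, TIER_NAME, gender),
                self.frequency(metaphone(name), TIER_METAPHONE, gender),
                self.frequency(name[:2], TIER_F2C, gender))

    def names(self, gender: str) -> dict[str, float]:
        return {name: f for (name, g), f in self._names.items() if g == gender}


def pairwise_sharing_probability(
    frequencies: Mapping[str, float],
    predicate: Callable[[str, str], bool],
    tolerance: float = 1e-6,
) -> float:
    """Σ_A Σ_B p_a·p_b·x over all ordered name pairs from one name set.

    ``x`` is the binary predicate of interest (e.g. "metaphone matches but
    name does not").  Frequencies must be normalized to sum to 1; this is
    how population-level sharing probabilities (such as the chance that two
    random people share a name metaphone) are derived from a table.
    """
    total = math.fsum(frequencies.values())
    if abs(total - 1.0) > tolerance:
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    return math.fsum(
        pa * pb
        for a, pa in frequencies.items()
        for b, pb in frequencies.items()
        if predicate(a, b)
    )


# ---------------------------------------------------------------------------
# Postcodes
# ---------------------------------------------------------------------------

#: Prefix marking UK administrative pseudopostcodes (ZZ99 3VZ = no fixed
#: abode, ZZ99 3CZ = England/UK not otherwise specified, ...).
PSEUDOPOSTCODE_PREFIX = "ZZ99"


def normalize_postcode(unit: str) -> str:
    """Canonical form: uppercase, no internal whitespace."""
    return "".join(unit.split()).upper()


def postcode_sector(unit: str) -> str:
    """Sector = normalized unit minus its final two characters."""
    normalized = normalize_postcode(unit)
    return normalized[:-2]


@dataclass(frozen=True)
class PostcodeUnitInfo:
    unit: str
    sector: str
    oa_id: str
    oa_mean_population: float
    postcodes_per_oa: int
    oas_per_sector: int

    @property
    def unit_population(self) -> float:
        return self.oa_mean_population / self.postcodes_per_oa

    @property
    def sector_population(self) -> float:
        return self.oa_mean_population * self.oas_per_sector


class PostcodeModel:
    """Postcode unit/sector population estimates and chance frequencies.

    Unit populations are estimated as the mean Output Area (OA) population
    divided by the number of postcodes in the unit's OA; sector populations
    as the mean OA population times the number of OAs in the sector.
    National frequencies are these populations divided by the total
    national population.  Units starting with the pseudopostcode prefix, or
    unknown to the model, are handled via the configurable pseudopostcode
    probabilities instead.
    """

    def __init__(self, units: Iterable[PostcodeUnitInfo],
                 total_population: float) -> None:
        if total_population <= 0:
            raise ValueError("total_population must be > 0")
        self.total_population = total_population
        self._units: dict[str, PostcodeUnitInfo] = {}
        for info in units:
            self._units[normalize_postcode(info.unit)] = info

    @classmethod
    def from_csv(cls, path: str | Path, total_population: float) -> "PostcodeModel":
        """Load (unit, sector, oa_id, oa_mean_population, postcodes_per_oa,
        oas_per_sector) rows with a header."""
        units = []
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                units.append(PostcodeUnitInfo(
                    unit=normalize_postcode(row["unit"]),
                    sector=normalize_postcode(row["sector"]),
                    oa_id=row["oa_id"],
                    oa_mean_population=float(row["oa_mean_population"]),
                    postcodes_per_oa=int(row["postcodes_per_oa"]),
                    oas_per_sector=int(row["oas_per_sector"]),
                ))
        return cls(units, total_population=total_population)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["unit", "sector", "oa_id", "oa_mean_population",
                             "postcodes_per_oa", "oas_per_sector"])
            for unit in sorted(self._units):
                info = self._units[unit]
                writer.writerow([info.unit, info.sector, info.oa_id,
                                 repr(info.oa_mean_population),
                                 info.postcodes_per_oa, info.oas_per_sector])

    def is_pseudo_or_unknown(self, unit: str) -> bool:
        normalized = normalize_postcode(unit)
        return (normalized.startswith(PSEUDOPOSTCODE_PREFIX)
                or normalized not in self._units)

    def unit_frequency(self, unit: str) -> float | None:
        """National frequency f_f of a known unit; None if pseudo/unknown."""
        info = self._units.get(normalize_postcode(unit))
        if info is None:
            return None
        return info.unit_population / self.total_population

    def sector_frequency(self, unit: str) -> float | None:
        """National frequency f_p of a known unit's sector; None otherwise."""
        info = self._units.get(normalize_postcode(unit))
        if info is None:
            return None
        return info.sector_population / self.total_population

    def known_units(self) -> list[str]:
        return sorted(self._units)


def postcode_chance_probabilities(
    unit_freq: float | None,
    sector_freq: float | None,
    is_pseudo: bool,
    k_postcode: float,
    p_pseudopostcode_unit: float,
    k_pseudopostcode: float,
) -> tuple[float, float, float, float]:
    """(p_f, p_p, p_pnf, p_n) for one proband postcode.

    Ordinary postcodes scale national frequencies by k_postcode and weight
    by (1 − p_pseudopostcode_sector); pseudopostcodes (and unknown units)
    use the configured pseudopostcode probabilities, with the sector
    probability k_pseudopostcode (> 1) times the unit probability.
    """
    if k_pseudopostcode <= 1:
        raise ValueError("k_pseudopostcode must be > 1")
    p_pseudo_sector = k_pseudopostcode * p_pseudopostcode_unit
    if is_pseudo or unit_freq is None or sector_freq is None:
        p_f = p_pseudopostcode_unit
        p_p = p_pseudo_sector
    else:
        p_f = k_postcode * unit_freq * (1 - p_pseudo_sector)
        p_p = k_postcode * sector_freq * (1 - p_pseudo_sector)
    p_pnf = p_p - p_f
    if p_pnf <= 0:
        raise ValueError(
            f"sector probability {p_p} must exceed unit probability {p_f}")
    return p_f, p_p, p_pnf, 1.0 - p_p


def estimate_nfa_proportion(
    households: float,
    mean_household_size: float,
    pct_in_england: float,
    n_homeless_households: float,
    pct_nfa: float,
    frac_single: float,
    other_household_size: float,
) -> float:
    """National estimate of the proportion of people with no fixed abode.

    Computed from published household counts: the number of NFA households
    (pct_nfa × n_homeless_households, in England), converted to people
    (single households count 1 person, the rest the alternative household
    size), divided by the national population implied by household count ×
    mean size scaled by England's population share.  Percentages are given
    as fractions.
    """
    people_per_nfa_household = frac_single * 1.0 + (1 - frac_single) * other_household_size
    nfa_people = pct_nfa * n_homeless_households * people_per_nfa_household
    national_people = pct_in_england * households * mean_household_size
    return nfa_people / national_people


# ---------------------------------------------------------------------------
# Aggregate
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """All population-frequency information in one bundle.

    Answers every P(D|¬H) query: forename/surname tier frequencies
    conditional on the proband's gender, gender priors (via MatchConfig),
    DOB closed forms, and postcode unit/sector frequencies.
    """
    forenames: NameFrequencyTable
    surnames: NameFrequencyTable
    postcodes: PostcodeModel

    def forename_tier_frequencies(self, name: str, gender: str | None):
        return self.forenames.tier_frequencies(name, gender)

    def surname_tier_frequencies(self, name: str, gender: str | None):
        return self.surnames.tier_frequencies(name, gender)
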