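"""Identifier-specific standardization, fuzzy tiers, and comparison logic.

Names are standardized (uppercase, punctuation/whitespace stripped,
accents handled), surnames additionally split into fragments so that
variably recorded compound names (Mozart-Smith vs Smith) can still match,
and each identifier class is compared through the generic two/three/
four-state systems of :mod:`bayeslink.comparison`:

* DOB: three-state; partial = exactly one of year/month/day differs.
* Gender: two-state against the proband's gender prior.
* Forenames: four-state (name / metaphone / F2C / none) per pair, ordered
  multi-identifier correction across the lists.
* Surnames: four-state on the best fragment pair, unordered pick-the-best
  across multiple recorded surnames.
* Postcodes: three-state (unit / sector / none), unordered, skipping pairs
  whose validity periods explicitly do not overlap.

Every comparison here operates on *comparable* representations holding
opaque tier keys: plaintext tokens and keyed digests behave identically,
which is what makes de-identified linkage give the same answers as
plaintext linkage.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from datetime import date

from .comparison import (
    TIER_FULL,
    TIER_NONE,
    TIER_PARTIAL1,
    TIER_PARTIAL2,
    ComparisonOutcome,
    FourStateParams,
    MultiComparisonContext,
    ThreeStateParams,
    TwoStateParams,
    best_pairing_unordered,
    ordered_correction,
    tier_rank,
    unordered_correction,
)
from .phonetics import metaphone
from .records import DatedValue

__all__ = [
    "standardize_name", "transliterate_variants", "fuzzy_tiers",
    "fragment_surname", "DEFAULT_IGNORE_PARTICLES",
    "ComparableName", "ComparableSurname", "ComparableDob",
    "ComparablePostcode",
    "compare_dob", "dob_tier", "compare_gender",
    "compare_forename_pair", "compare_forenames",
    "compare_surnames", "compare_postcodes",
]

# Nonspecific surname components (nobiliary particles etc.) that are not
# informative as standalone fragments; user-overridable.
DEFAULT_IGNORE_PARTICLES = frozenset({
    "VAN", "VON", "DE", "DEL", "DELLA", "DER", "DEN", "DU", "DA", "DI",
    "LA", "LE", "ST", "TER", "TEN",
})

# Transliterations applied before accent stripping to produce the
# alternative (e.g. Germanic) spelling variant of an accented name.
_TRANSLITERATIONS = {
    "Ä": "AE", "Ö": "OE", "Ü": "UE", "ß": "SS", "Å": "AA",
    "Ø": "OE", "Æ": "AE", "Þ": "TH", "Ð": "DH",
}

_NON_ALPHA = re.compile(r"[^A-Z]+")


def _strip_accents(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def standardize_name(raw: str) -> str:
    """Canonical name token: uppercase, no punctuation/whitespace, no accents.

    An empty result (e.g. input of pure punctuation) signals a missing
    identifier and is returned as the empty string for the caller to treat
    as absent.
    """
    return _NON_ALPHA.sub("", _strip_accents(raw.upper()))


def transliterate_variants(raw: str) -> list[str]:
    """Canonical variants of a possibly accented name.

    Returns the accent-stripped form first (Müller → MULLER) and, when it
    differs, the transliterated form (→ MUELLER).  Either variant may match
    during comparison.
    """
    stripped = standardize_name(raw)
    transliterated_raw = raw.upper()
    for accented, replacement in _TRANSLITERATIONS.items():
        transliterated_raw = transliterated_raw.replace(accented, replacement)
    transliterated = standardize_name(transliterated_raw)
    variants = [stripped]
    if transliterated and transliterated != stripped:
        variants.append(transliterated)
    return [v for v in variants if v]


def fuzzy_tiers(canonical: str) -> tuple[str, str]:
    """(metaphone, F2C) for a standardized name.

    Names yielding no metaphone return the empty ("null") metaphone, which
    is still a comparable token with its own population frequency.
    """
    return metaphone(canonical), canonical[:2]


def fragment_surname(raw: str,
                     ignore_particles: frozenset[str] = DEFAULT_IGNORE_PARTICLES,
                     ) -> list[str]:
    """Split a surname into >= 1 canonical fragments.

    The whole joined form always comes first (Mozart-Smith → MOZARTSMITH),
    followed by the individual components (MOZART, SMITH) and any
    transliteration variants; components on the ignore list (nobiliary
    particles such as VAN) are dropped as standalone fragments but remain
    part of the joined form.
    """
    fragments: list[str] = []

    def add(token: str) -> None:
        if token and token not in fragments:
            fragments.append(token)

    for joined in transliterate_variants(raw):
        add(joined)
    components = [part for part in re.split(r"[\s\-'’.,/]+", raw) if part]
    if len(components) > 1:
        for component in components:
            for variant in transliterate_variants(component):
                if variant not in ignore_particles:
                    add(variant)
    return fragments


# ---------------------------------------------------------------------------
# Comparable representations (plaintext tokens or digests, interchangeably)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparableName:
    """One name ready for comparison: tier keys plus proband-side data.

    ``frequencies`` is the (name, metaphone, F2C) frequency triple resolved
    for the proband's gender; it is None on the candidate side, where only
    the keys matter.
    """
    name_key: str
    meta_key: str
    f2c_key: str
    frequencies: tuple[float, float, float] | None = None
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other: "ComparableName | ComparableSurname") -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


@dataclass(frozen=True)
class ComparableSurname:
    """One recorded surname as comparable fragments (joined form first)."""
    fragments: tuple[ComparableName, ...]
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other) -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


@dataclass(frozen=True)
class ComparableDob:
    """DOB tier keys: the full date and its three two-component projections."""
    full: str
    year_month: str
    month_day: str
    year_day: str

    @classmethod
    def from_date(cls, dob: date) -> "ComparableDob":
        return cls(full=dob.isoformat(),
                   year_month=f"{dob.year:04d}-{dob.month:02d}",
                   month_day=f"{dob.month:02d}-{dob.day:02d}",
                   year_day=f"{dob.year:04d}-{dob.day:02d}")


@dataclass(frozen=True)
class ComparablePostcode:
    """One postcode with resolved chance probabilities (proband side).

    p_f and p_p are the already-scaled probabilities that a random other
    person shares the unit / the sector; None on the candidate side.
    """
    unit_key: str
    sector_key: str
    p_f: float | None = None
    p_p: float | None = None
    start_date: date | None = None
    end_date: date | None = None

    def explicitly_nonoverlapping(self, other) -> bool:
        return DatedValue("x", self.start_date, self.end_date).explicitly_nonoverlapping(
            DatedValue("x", other.start_date, other.end_date))


# ---------------------------------------------------------------------------
# DOB
# ---------------------------------------------------------------------------

def dob_tier(proband: ComparableDob, candidate: ComparableDob) -> str:
    """full / partial1 / none from tier keys.

    Exactly one differing component leaves exactly one projection intact,
    so: full digests equal → full; any projection equal (without full) →
    partial1; otherwise none.  Two projections can only both match when the
    full DOB matches, so the mapping is exact.
    """
    if proband.full == candidate.full:
        return TIER_FULL
    if (proband.year_month == candidate.year_month
            or proband.month_day == candidate.month_day
            or proband.year_day == candidate.year_day):
        return TIER_PARTIAL1
    return TIER_NONE


def compare_dob(proband_dob: date, candidate_dob: date) -> str:
    """Agreement tier of two plaintext dates of birth."""
    return dob_tier(ComparableDob.from_date(proband_dob),
                    ComparableDob.from_date(candidate_dob))


def dob_llr(tier: str, b: float, p_ep: float, p_en: float) -> float:
    from .frequencies import dob_probabilities
    p_f, p_pnf, _ = dob_probabilities(b)
    params = ThreeStateParams(p_ep=p_ep, p_en=p_en, p_f=p_f, p_pnf=p_pnf)
    return params.llr(tier)


# ---------------------------------------------------------------------------
# Gender
# ---------------------------------------------------------------------------

def compare_gender(proband_key: str | None, candidate_key: str | None,
                   proband_gender_freq: float | None, p_e: float) -> float:
    """Two-state gender comparison; absent gender on either side → 0."""
    if proband_key is None or candidate_key is None or proband_gender_freq is None:
        return 0.0
    params = TwoStateParams(p_e=p_e, p_f=proband_gender_freq)
    return params.llr(TIER_FULL if proband_key == candidate_key else TIER_NONE)


# ---------------------------------------------------------------------------
# Names (four-state)
# ---------------------------------------------------------------------------

def name_tier(proband: ComparableName, candidate: ComparableName) -> str:
    if proband.name_key == candidate.name_key:
        return TIER_FULL
    if proband.meta_key == candidate.meta_key:
        return TIER_PARTIAL1
    if proband.f2c_key == candidate.f2c_key:
        return TIER_PARTIAL2
    return TIER_NONE


def four_state_params(frequencies: tuple[float, float, float],
                      rates: tuple[float, float, float],
                      floor: float) -> FourStateParams:
    """Build the four-state system from attached marginal tier frequencies.

    The chance columns are derived as nested differences, p_p1nf =
    p_metaphone − p_name and p_p2np1 = p_f2c − p_metaphone, clamped below
    at the frequency floor: for unusual names the tiers are not strictly
    nested in probability and the clamp keeps every denominator positive.
    """
    p_name, p_meta, p_f2c = frequencies
    p_ep1, p_ep2np1, p_en = rates
    p_f = p_name
    p_p1nf = max(p_meta - p_name, floor)
    p_p2np1 = max(p_f2c - p_meta, floor)
    return FourStateParams(p_ep1=p_ep1, p_ep2np1=p_ep2np1, p_en=p_en,
                           p_f=p_f, p_p1nf=p_p1nf, p_p2np1=p_p2np1)


def compare_forename_pair(proband: ComparableName, candidate: ComparableName,
                          rates: tuple[float, float, float],
                          floor: float) -> ComparisonOutcome:
    """Four-state comparison of one forename pair (proband-side frequencies)."""
    if proband.frequencies is None:
        raise ValueError("proband-side name lacks frequencies")
    tier = name_tier(proband, candidate)
    params = four_state_params(proband.frequencies, rates, floor)
    return ComparisonOutcome(tier=tier, llr=params.llr(tier))


def _name_mismatch_llr(proband: ComparableName,
                       rates: tuple[float, float, float], floor: float) -> float:
    return four_state_params(proband.frequencies, rates, floor).llr(TIER_NONE)


def compare_forenames(probands: list[ComparableName],
                      candidates: list[ComparableName],
                      rates: tuple[float, float, float],
                      floor: float, p_u: float) -> float:
    """Total forename LLR: best pairing + ordered multi-comparison correction.

    Either list empty → 0 (no evidence).  Pairs whose validity periods
    explicitly do not overlap are never compared.  Unpaired proband names
    that had at least one eligible pair contribute their own no-match LLR
    once each.
    """
    if not probands or not candidates:
        return 0.0
    matrix: list[list[float | None]] = []
    eligible_rows: list[bool] = []
    for p in probands:
        row: list[float | None] = []
        any_eligible = False
        for c in candidates:
            if p.explicitly_nonoverlapping(c):
                row.append(None)
            else:
                row.append(compare_forename_pair(p, c, rates, floor).llr)
                any_eligible = True
        matrix.append(row)
        eligible_rows.append(any_eligible)
    selected, c = best_pairing_unordered(matrix)
    total = sum(llr for _, _, llr in selected)
    paired_rows = {i for i, _, _ in selected}
    for i, p in enumerate(probands):
        if i not in paired_rows and eligible_rows[i]:
            total += _name_mismatch_llr(p, rates, floor)
    m = len(candidates)
    if c >= 1 and m > 1:
        strict = all(i == j for i, j, llr in selected if llr > 0)
        context = MultiComparisonContext(n=len(probands), m=m, c=c,
                                         ordered=True, strict_order=strict,
                                         p_o=1.0 - p_u)
        total += ordered_correction(context)
    return total


def surname_pair_outcome(proband: ComparableSurname, candidate: ComparableSurname,
                         rates: tuple[float, float, float],
                         floor: float) -> ComparisonOutcome:
    """Best fragment comparison between two recorded surnames.

    Preference: full > metaphone > F2C > none; within a tier, the most
    informative (lowest-frequency) matching fragment.  The population
    frequency is taken from the proband fragment that actually matched; a
    complete mismatch is scored with the whole joined form.
    """
    best: tuple[int, float, int] | None = None  # (-rank, freq, fragment idx)
    best_pair: tuple[ComparableName, str] | None = None
    for idx, fp in enumerate(proband.fragments):
        if fp.frequencies is None:
            raise ValueError("proband-side surname fragment lacks frequencies")
        for fc in candidate.fragments:
            tier = name_tier(fp, fc)
            if tier == TIER_NONE:
                continue
            freq = {TIER_FULL: fp.frequencies[0],
                    TIER_PARTIAL1: fp.frequencies[1],
                    TIER_PARTIAL2: fp.frequencies[2]}[tier]
            key = (-tier_rank(tier), freq, idx)
            if best is None or key < best:
                best = key
                best_pair = (fp, tier)
    if best_pair is None:
        joined = proband.fragments[0]
        return ComparisonOutcome(
            tier=TIER_NONE,
            llr=four_state_params(joined.frequencies, rates, floor).llr(TIER_NONE))
    fragment, tier = best_pair
    params = four_state_params(fragment.frequencies, rates, floor)
    return ComparisonOutcome(tier=tier, llr=params.llr(tier))


def compare_surnames(probands: list[ComparableSurname],
                     candidates: list[ComparableSurname],
                     rates: tuple[float, float, float],
                     floor: float) -> float:
    """Total surname LLR: unordered pick-the-best across recorded surnames."""
    if not probands or not candidates:
        return 0.0
    matrix: list[list[float | None]] = []
    eligible_rows: list[bool] = []
    for p in probands:
        row: list[float | None] = []
        any_eligible = False
        for c in candidates:
            if p.explicitly_nonoverlapping(c):
                row.append(None)
            else:
                row.append(surname_pair_outcome(p, c, rates, floor).llr)
                any_eligible = True
        matrix.append(row)
        eligible_rows.append(any_eligible)
    selected, c = best_pairing_unordered(matrix)
    total = sum(llr for _, _, llr in selected)
    paired_rows = {i for i, _, _ in selected}
    for i, p in enumerate(probands):
        if i not in paired_rows and eligible_rows[i]:
            total += four_state_params(p.fragments[0].frequencies, rates,
                                       floor).llr(TIER_NONE)
    total += unordered_correction(c, len(candidates))
    return total


# ---------------------------------------------------------------------------
# Postcodes (three-state, unordered)
# ---------------------------------------------------------------------------

def postcode_tier(proband: ComparablePostcode, candidate: ComparablePostcode) -> str:
    if proband.unit_key == candidate.unit_key:
        return TIER_FULL
    if proband.sector_key == candidate.sector_key:
        return TIER_PARTIAL1
    return TIER_NONE


def _postcode_params(proband: ComparablePostcode, p_ep: float,
                     p_en: float) -> ThreeStateParams:
    if proband.p_f is None or proband.p_p is None:
        raise ValueError("proband-side postcode lacks chance probabilities")
    return ThreeStateParams(p_ep=p_ep, p_en=p_en, p_f=proband.p_f,
                            p_pnf=proband.p_p - proband.p_f)


def compare_postcodes(probands: list[ComparablePostcode],
                      candidates: list[ComparablePostcode],
                      p_ep: float, p_en: float) -> float:
    """Total postcode LLR: unordered pick-the-best with temporal exclusion.

    Differing postcodes are weak negative evidence (people move home), so
    mismatches contribute via p_en; pairs that explicitly do not overlap in
    time are skipped entirely; shared-duration length is not used.
    """
    if not probands or not candidates:
        return 0.0
    matrix: list[list[float | None]] = []
    eligible_rows: list[bool] = []
    for p in probands:
        row: list[float | None] = []
        any_eligible = False
        for c in candidates:
            if p.explicitly_nonoverlapping(c):
                row.append(None)
            else:
                row.append(_postcode_params(p, p_ep, p_en).llr(postcode_tier(p, c)))
                any_eligible = True
        matrix.append(row)
        eligible_rows.append(any_eligible)
    selected, c = best_pairing_unordered(matrix)
    total = sum(llr for _, _, llr in selected)
    paired_rows = {i for i, _, _ in selected}
    for i, p in enumerate(probands):
        if i not in paired_rows and eligible_rows[i]:
            total += _postcode_params(p, p_ep, p_en).llr(TIER_NONE)
    total += unordered_correction(c, len(candidates))
    return total
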