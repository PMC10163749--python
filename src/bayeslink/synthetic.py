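"""Synthetic populations with realistic identifier structure and errors.

The generator emulates the statistical structure the matcher assumes:
forenames drawn gender-conditionally from a frequency table containing
phonetic spelling clusters (so metaphone-level confusions exist), one or
two surnames including compound forms, DOBs uniform over a birth-year
window of width b years, and postcodes drawn from a synthetic unit/sector
model including pseudopostcodes at the configured rate.  Error injection
then mimics real inter-database discrepancies at the empirically measured
rates: metaphone-preserving spelling edits, F2C-preserving edits, complete
replacements, single-component DOB errors, gender flips, sector-preserving
postcode changes, and forename order shuffles.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .config import (
    GENDER_FEMALE,
    GENDER_MALE,
    GENDER_OTHER,
    GenderedRates,
    MatchConfig,
    NameErrorRates,
)
from .frequencies import (
    FrequencyModel,
    NameFrequencyTable,
    PostcodeModel,
    PostcodeUnitInfo,
)
from .phonetics import metaphone
from .records import DatedValue, PersonRecord

__all__ = ["ErrorProfile", "demo_frequency_model", "generate_population",
           "derive_sample_with_errors"]

# Forename spelling clusters: names within a cluster share a metaphone, so
# the table contains the phonetic neighbours that both the fuzzy matcher
# and the error injector need.
_FORENAME_CLUSTERS_F = [
    ["ANNA", "ANA"], ["CATHERINE", "KATHRYN", "CATHRYN"], ["CLAIRE", "CLARE"],
    ["SARAH", "SARA"], ["ELIZABETH", "ELISABETH"], ["REBECCA"],
    ["MARIE", "MARY"], ["ISLA"], ["OLIVIA", "ALIVIA"], ["SOPHIE", "SOFIE"],
    ["EMILY", "EMILIE"], ["HANNAH", "HANNA"], ["LUCY"], ["GRACE"],
    ["CHARLOTTE"], ["AMELIA"], ["ISABELLE", "ISOBEL"], ["JESSICA"],
    ["MARGARET"], ["ELEANOR", "ELINOR"],
]
_FORENAME_CLUSTERS_M = [
    ["JAMES", "JAIMES"], ["JOHN", "JON"], ["RUDOLF", "RUDOLPH"],
    ["JONATHAN", "JONATHON"], ["STEPHEN", "STEVEN"], ["MARC", "MARK"],
    ["ERIC", "ERIK"], ["PHILIP", "PHILLIP"], ["WILLIAM"], ["THOMAS", "TOMAS"],
    ["GEORGE"], ["HENRY"], ["OLIVER"], ["HARRY"], ["CHARLES"],
    ["EDWARD"], ["ALAN", "ALLAN", "ALLEN"], ["PETER"], ["RICHARD"],
    ["DAVID"],
]
_SURNAME_CLUSTERS = [
    ["SMITH", "SMYTH"], ["JONES"], ["TAYLOR", "TAYLER"], ["BROWN", "BRAUN"],
    ["WILSON"], ["EVANS"], ["THOMPSON", "THOMSON"], ["ROBERTS"],
    ["WALKER"], ["WRIGHT", "RIGHT"], ["WHITE", "WHYTE"], ["GREEN", "GREENE"],
    ["HALL"], ["WOOD", "WOODS"], ["MARTIN"], ["JACKSON"],
    ["CLARKE", "CLARK"], ["HARRIS"], ["LEWIS"], ["ALLEN", "ALAN"],
    ["MOZART"], ["BEETHOVEN"], ["STEWART", "STUART"], ["MURPHY"],
    ["KELLY"], ["BAKER"], ["CARTER"], ["MITCHELL"], ["TURNER"], ["HILL"],
]

NFA_PSEUDOPOSTCODE = "ZZ993VZ"

# Syllable inventory for the programmatically generated long tail of names.
_SYL_START = ["BAR", "BEL", "BRAD", "CAR", "DAL", "DON", "EL", "FAR", "GAR",
              "HAL", "HAR", "KEN", "LAN", "MAR", "MOR", "NOR", "OS", "PEN",
              "RAD", "SEL", "TAL", "VER", "WIL", "YAR", "BRAN", "COL", "DUN",
              "FEN", "GRAN", "HOL"]
_SYL_SURNAME_END = ["SON", "TON", "FIELD", "WELL", "WOOD", "FORD", "HAM",
                    "LEY", "WORTH", "BURY", "SHAW", "COMBE", "DALE", "MORE",
                    "WICK", "STONE", "BROOK", "THORPE", "GATE", "HURST"]
_SYL_FORENAME_END_F = ["A", "INE", "ELLA", "ETTE", "IA", "INA", "ISSA",
                       "ORA", "LYN", "ELLE"]
_SYL_FORENAME_END_M = ["O", "US", "AN", "IN", "ERT", "ARD", "RIC", "WIN",
                       "FRED", "TON"]


def _tail_names(n: int, enders: list[str], taken: set[str],
                rng: np.random.Generator) -> list[str]:
    """n unique generated names, deterministic for a fixed internal seed."""
    names: list[str] = []
    while len(names) < n:
        name = _SYL_START[int(rng.integers(len(_SYL_START)))]
        if rng.random() < 0.3:
            name += _SYL_START[int(rng.integers(len(_SYL_START)))].lower().upper()
        name += enders[int(rng.integers(len(enders)))]
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def _zipf_table(clusters: list[list[str]], gender: str, shift: float,
                total_mass: float = 0.9) -> dict[tuple[str, str], float]:
    """Zipf-like frequencies over spelling clusters; variants split 3:1.

    The rank shift flattens the head so the most common name has a
    realistic frequency (a few percent, like the most common real
    forenames/surnames) rather than dominating the table.
    """
    weights = np.array([1.0 / (rank + 1 + shift) for rank in range(len(clusters))])
    weights = weights / weights.sum() * total_mass
    entries: dict[tuple[str, str], float] = {}
    for cluster, mass in zip(clusters, weights):
        shares = np.array([3.0 ** -i for i in range(len(cluster))])
        shares = shares / shares.sum()
        for name, share in zip(cluster, shares):
            entries[(name, gender)] = float(mass * share)
    return entries


def demo_frequency_model(n_sectors: int = 40, units_per_sector: int = 8,
                         oa_mean_population: float = 310.0,
                         postcodes_per_oa: int = 10,
                         total_population: int = 100_000,
                         f_min: float = 5e-6,
                         p_female_given_fm: float = 0.51) -> FrequencyModel:
    """A fully synthetic frequency model for tests and demos.

    Name tables combine hand-written phonetic spelling clusters (so
    metaphone-level confusions exist) with a generated Zipf tail, scaled so
    the most common forename has frequency ~0.03 and the most common
    surname ~0.013 — the scale real national name tables exhibit.
    Forename tables are gender-specific; the surname table is shared
    between genders.  The postcode model is a toy geography with UK-like
    unit populations (~31 people per postcode unit).
    """
    rng = np.random.default_rng(20_24)  # internal: tables are fixed artifacts
    taken: set[str] = {n for c in _FORENAME_CLUSTERS_F + _FORENAME_CLUSTERS_M
                       + _SURNAME_CLUSTERS for n in c}
    clusters_f = _FORENAME_CLUSTERS_F + [[n] for n in
                                         _tail_names(140, _SYL_FORENAME_END_F, taken, rng)]
    clusters_m = _FORENAME_CLUSTERS_M + [[n] for n in
                                         _tail_names(140, _SYL_FORENAME_END_M, taken, rng)]
    clusters_s = _SURNAME_CLUSTERS + [[n] for n in
                                      _tail_names(270, _SYL_SURNAME_END, taken, rng)]
    forename_entries = {**_zipf_table(clusters_f, GENDER_FEMALE, shift=12),
                        **_zipf_table(clusters_m, GENDER_MALE, shift=12)}
    surname_entries = {}
    for gender in (GENDER_FEMALE, GENDER_MALE):
        surname_entries.update(_zipf_table(clusters_s, gender, shift=25))
    forenames = NameFrequencyTable(forename_entries, f_min=f_min,
                                   p_female_given_fm=p_female_given_fm)
    surnames = NameFrequencyTable(surname_entries, f_min=f_min,
                                  p_female_given_fm=p_female_given_fm)

    letters = string.ascii_uppercase
    units = []
    oas_per_sector = max(1, round(total_population / (n_sectors * oa_mean_population)))
    for s in range(n_sectors):
        area = "CB" if s % 2 == 0 else "PE"
        sector = f"{area}{s // 2 + 1}{s % 10}"
        for u in range(units_per_sector):
            unit = f"{sector}{letters[u]}{letters[(u * 7 + s) % 26]}"
            units.append(PostcodeUnitInfo(
                unit=unit, sector=sector, oa_id=f"OA{s:03d}{u // postcodes_per_oa}",
                oa_mean_population=oa_mean_population,
                postcodes_per_oa=postcodes_per_oa,
                oas_per_sector=oas_per_sector))
    postcodes = PostcodeModel(units, total_population=total_population)
    return FrequencyModel(forenames=forenames, surnames=surnames,
                          postcodes=postcodes)


@dataclass(frozen=True)
class ErrorProfile:
    """Identifier error rates injected between the two copies of a person.

    Defaults are the empirically measured inter-database discrepancy rates
    used for validation; a zeroed profile reproduces records exactly.
    """
    forename_errors: NameErrorRates = field(
        default_factory=lambda: MatchConfig().forename_errors)
    surname_errors: NameErrorRates = field(
        default_factory=lambda: MatchConfig().surname_errors)
    p_u_forename: float = 0.00191
    p_ep_dob: float = 0.00459
    p_en_dob: float = 0.00033   # the measured rate; the matcher may assume 0
    p_e_gender: float = 0.0033
    p_ep_postcode: float = 0.0097
    p_en_postcode: float = 0.300
    p_female_given_fm: float = 0.51

    @classmethod
    def zero(cls) -> "ErrorProfile":
        zero_rates = NameErrorRates(p_ep1=GenderedRates(0.0, 0.0),
                                    p_ep2np1=GenderedRates(0.0, 0.0),
                                    p_en=GenderedRates(0.0, 0.0))
        return cls(forename_errors=zero_rates, surname_errors=zero_rates,
                   p_u_forename=0.0, p_ep_dob=0.0, p_en_dob=0.0,
                   p_e_gender=0.0, p_ep_postcode=0.0, p_en_postcode=0.0)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _draw_name(rng: np.random.Generator, names: list[str],
               weights: np.ndarray) -> str:
    return names[int(rng.choice(len(names), p=weights))]


def _gender_name_pool(model: FrequencyModel, table: str,
                      gender: str) -> tuple[list[str], np.ndarray]:
    freq_table = model.forenames if table == "forename" else model.surnames
    if gender in (GENDER_FEMALE, GENDER_MALE):
        names = freq_table.names(gender)
    else:
        female = freq_table.names(GENDER_FEMALE)
        male = freq_table.names(GENDER_MALE)
        names = {n: 0.51 * female.get(n, 0) + 0.49 * male.get(n, 0)
                 for n in set(female) | set(male)}
    keys = sorted(names)
    weights = np.array([names[k] for k in keys])
    return keys, weights / weights.sum()


def generate_population(n: int, model: FrequencyModel, config: MatchConfig,
                        seed: int, start_year: int = 1960) -> list[PersonRecord]:
    """Draw n synthetic people, reproducibly for a fixed seed.

    Gender follows the composed priors; forename count is 1–2, surname
    count 1–2 (second surnames occasionally compound), postcode count 0–3;
    DOBs are uniform over a b-year window from ``start_year``;
    pseudopostcodes appear at rate p_pseudopostcode_unit.
    """
    rng = np.random.default_rng(seed)
    known_units = model.postcodes.known_units()
    gender_probs = [config.gender_prior(g) for g in
                    (GENDER_FEMALE, GENDER_MALE, GENDER_OTHER)]
    gender_probs = np.array(gender_probs) / sum(gender_probs)
    pools: dict[tuple[str, str], tuple[list[str], np.ndarray]] = {}
    records = []
    dob_window_days = max(1, int(round(config.b * 365.25)))
    for i in range(n):
        gender = (GENDER_FEMALE, GENDER_MALE, GENDER_OTHER)[
            int(rng.choice(3, p=gender_probs))]
        pool_key = ("forename", gender)
        if pool_key not in pools:
            pools[pool_key] = _gender_name_pool(model, "forename", gender)
        fore_names, fore_weights = pools[pool_key]
        pool_key = ("surname", gender)
        if pool_key not in pools:
            pools[pool_key] = _gender_name_pool(model, "surname", gender)
        sur_names, sur_weights = pools[pool_key]

        n_forenames = 1 + int(rng.random() < 0.35)
        forenames = []
        while len(forenames) < n_forenames:
            name = _draw_name(rng, fore_names, fore_weights)
            if name not in forenames:
                forenames.append(name)

        n_surnames = 1 + int(rng.random() < 0.08)
        surnames = []
        while len(surnames) < n_surnames:
            name = _draw_name(rng, sur_names, sur_weights)
            if rng.random() < 0.05:  # compound surname
                other = _draw_name(rng, sur_names, sur_weights)
                if other != name:
                    name = f"{name}-{other}"
            if name not in surnames:
                surnames.append(name)

        dob = date(start_year, 1, 1) + timedelta(days=int(rng.integers(dob_window_days)))

        n_postcodes = int(rng.choice(4, p=[0.05, 0.70, 0.20, 0.05]))
        postcodes = []
        for _ in range(n_postcodes):
            if rng.random() < config.p_pseudopostcode_unit:
                postcodes.append(NFA_PSEUDOPOSTCODE)
            else:
                postcodes.append(known_units[int(rng.integers(len(known_units)))])

        records.append(PersonRecord(
            local_id=f"P{i:06d}",
            forenames=[DatedValue(v) for v in forenames],
            surnames=[DatedValue(v) for v in surnames],
            dob=dob, gender=gender,
            postcodes=[DatedValue(v) for v in postcodes]))
    return records


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

_VOWEL_SET = "AEIOU"
_CONSONANTS = "".join(c for c in string.ascii_uppercase if c not in _VOWEL_SET)


def _single_char_edits(name: str, rng: np.random.Generator, tries: int):
    for _ in range(tries):
        kind = int(rng.integers(3))
        pos = int(rng.integers(len(name)))
        if kind == 0:  # substitute a vowel with another vowel
            vowel_positions = [i for i, c in enumerate(name) if c in _VOWEL_SET]
            if not vowel_positions:
                continue
            pos = vowel_positions[int(rng.integers(len(vowel_positions)))]
            new = _VOWEL_SET[int(rng.integers(5))]
            yield name[:pos] + new + name[pos + 1:]
        elif kind == 1:  # duplicate a letter
            yield name[:pos + 1] + name[pos] + name[pos + 1:]
        else:  # insert a vowel
            new = _VOWEL_SET[int(rng.integers(5))]
            yield name[:pos + 1] + new + name[pos + 1:]


def _metaphone_preserving_edit(name: str, rng: np.random.Generator,
                               neighbours: dict[str, list[str]]) -> str:
    """A different spelling with the same metaphone.

    Rejection-samples single-character edits; falls back to a
    same-metaphone dictionary neighbour; as a last resort leaves the name
    unchanged (no error recorded).
    """
    target = metaphone(name)
    for edited in _single_char_edits(name, rng, tries=30):
        if edited != name and metaphone(edited) == target:
            return edited
    options = [n for n in neighbours.get(target, ()) if n != name]
    if options:
        return options[int(rng.integers(len(options)))]
    return name


def _f2c_preserving_edit(name: str, rng: np.random.Generator) -> str:
    """Same first two characters, different metaphone and name."""
    target = metaphone(name)
    f2c = name[:2]
    for _ in range(30):
        tail_len = int(rng.integers(2, 6))
        tail = "".join(_CONSONANTS[int(rng.integers(len(_CONSONANTS)))] if k % 2 else
                       _VOWEL_SET[int(rng.integers(5))] for k in range(tail_len))
        candidate = f2c + tail
        if candidate != name and candidate[:2] == f2c and metaphone(candidate) != target:
            return candidate
    return name


def _complete_replacement(name: str, rng: np.random.Generator,
                          pool: list[str]) -> str:
    """A name agreeing at no tier (different name, metaphone, and F2C)."""
    target_meta, target_f2c = metaphone(name), name[:2]
    for _ in range(50):
        candidate = pool[int(rng.integers(len(pool)))]
        if (candidate != name and metaphone(candidate) != target_meta
                and candidate[:2] != target_f2c):
            return candidate
    return name


def _mutate_dob_partial(dob: date, rng: np.random.Generator) -> date:
    component = int(rng.integers(3))
    for _ in range(30):
        if component == 0:  # year
            new = dob.replace(year=dob.year + int(rng.integers(1, 6)) *
                              (1 if rng.random() < 0.5 else -1))
        elif component == 1:  # month
            month = 1 + int(rng.integers(12))
            if month == dob.month:
                continue
            try:
                new = dob.replace(month=month)
            except ValueError:
                continue
        else:  # day
            day = 1 + int(rng.integers(28))
            if day == dob.day:
                continue
            new = dob.replace(day=day)
        if new != dob:
            return new
    return dob


def _mutate_dob_complete(dob: date, rng: np.random.Generator) -> date:
    from .identifiers import compare_dob
    for _ in range(50):
        new = date(dob.year - 10, 1, 1) + timedelta(days=int(rng.integers(7300)))
        if compare_dob(dob, new) == "none":
            return new
    return dob


def _inject_errors(record: PersonRecord, profile: ErrorProfile,
                   model: FrequencyModel, rng: np.random.Generator,
                   neighbours: dict[str, dict[str, list[str]]],
                   pools: dict[str, list[str]]) -> PersonRecord:
    gender = record.gender
    w = profile.p_female_given_fm

    def mutate_name(value: str, errors: NameErrorRates, table: str) -> str:
        ep1, ep2np1, en = errors.resolve(gender, w)
        u = rng.random()
        if u < ep1:
            return _metaphone_preserving_edit(value, rng, neighbours[table])
        if u < ep1 + ep2np1:
            return _f2c_preserving_edit(value, rng)
        if u < ep1 + ep2np1 + en:
            return _complete_replacement(value, rng, pools[table])
        return value

    forenames = [replace(dv, value=mutate_name(dv.value, profile.forename_errors,
                                               "forename"))
                 for dv in record.forenames]
    if len(forenames) >= 2 and rng.random() < profile.p_u_forename:
        forenames = list(reversed(forenames))

    surnames = [replace(dv, value=mutate_name(dv.value, profile.surname_errors,
                                              "surname"))
                for dv in record.surnames]

    dob = record.dob
    if dob is not None:
        u = rng.random()
        if u < profile.p_ep_dob:
            dob = _mutate_dob_partial(dob, rng)
        elif u < profile.p_ep_dob + profile.p_en_dob:
            dob = _mutate_dob_complete(dob, rng)

    new_gender = gender
    if gender is not None and rng.random() < profile.p_e_gender:
        others = [g for g in (GENDER_FEMALE, GENDER_MALE, GENDER_OTHER) if g != gender]
        new_gender = others[int(rng.integers(len(others)))]

    known_units = model.postcodes.known_units()
    sectors: dict[str, list[str]] = {}
    for unit in known_units:
        from .frequencies import postcode_sector
        sectors.setdefault(postcode_sector(unit), []).append(unit)

    postcodes = []
    for dv in record.postcodes:
        value = dv.value
        u = rng.random()
        if u < profile.p_ep_postcode:
            from .frequencies import postcode_sector
            siblings = [p for p in sectors.get(postcode_sector(value), ())
                        if p != value]
            if siblings:
                value = siblings[int(rng.integers(len(siblings)))]
        elif u < profile.p_ep_postcode + profile.p_en_postcode:
            from .frequencies import postcode_sector
            strangers = [p for p in known_units
                         if postcode_sector(p) != postcode_sector(value)]
            if strangers:
                value = strangers[int(rng.integers(len(strangers)))]
        postcodes.append(replace(dv, value=value))

    return PersonRecord(local_id=record.local_id, forenames=forenames,
                        surnames=surnames, dob=dob, gender=new_gender,
                        postcodes=postcodes, perfect_ids=dict(record.perfect_ids),
                        payload=record.payload)


def derive_sample_with_errors(
    population: list[PersonRecord],
    overlap_fraction: float,
    profile: ErrorProfile,
    model: FrequencyModel,
    seed: int,
) -> tuple[list[PersonRecord], list[PersonRecord], dict[str, str | None]]:
    """Split a population into an error-injected proband/sample file pair.

    Every population member becomes a proband; a fraction
    ``overlap_fraction`` also appears in the sample.  Both copies of an
    overlapping person receive independently injected errors at the
    profile's rates.  The truth map sends each proband local ID to its
    sample local ID, or None when the proband is not in the sample.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    membership_rng, proband_rng, sample_rng = (
        np.random.default_rng(s) for s in root.spawn(3))

    neighbours: dict[str, dict[str, list[str]]] = {}
    pools: dict[str, list[str]] = {}
    for table_name, table in (("forename", model.forenames),
                              ("surname", model.surnames)):
        names = sorted(set(table.names("F")) | set(table.names("M")))
        pools[table_name] = names
        by_meta: dict[str, list[str]] = {}
        for name in names:
            by_meta.setdefault(metaphone(name), []).append(name)
        neighbours[table_name] = by_meta

    probands: list[PersonRecord] = []
    sample: list[PersonRecord] = []
    truth: dict[str, str | None] = {}
    in_sample = membership_rng.random(len(population)) < overlap_fraction
    for member, record in zip(in_sample, population):
        proband_id = f"A-{record.local_id}"
        proband = _inject_errors(record, profile, model, proband_rng,
                                 neighbours, pools)
        proband = replace_local_id(proband, proband_id)
        probands.append(proband)
        if member:
            sample_id = f"B-{record.local_id}"
            copy = _inject_errors(record, profile, model, sample_rng,
                                  neighbours, pools)
            sample.append(replace_local_id(copy, sample_id))
            truth[proband_id] = sample_id
        else:
            truth[proband_id] = None
    return probands, sample, truth


def replace_local_id(record: PersonRecord, local_id: str) -> PersonRecord:
    return PersonRecord(local_id=local_id, forenames=record.forenames,
                        surnames=record.surnames, dob=record.dob,
                        gender=record.gender, postcodes=record.postcodes,
                        perfect_ids=dict(record.perfect_ids),
                        payload=record.payload)
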