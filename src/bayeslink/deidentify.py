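"""Conversion of plaintext person records into hashed linkage records.

Every identifier and fuzzy tier is replaced by a keyed cryptographic
digest (HMAC), so that two organisations sharing a secret key can compare
identities without exchanging plaintext: equal digests mean equal inputs
(collisions are treated as impossible), but digests are infeasible to
invert without the key.  Proband-mode records additionally carry the
population frequency of each hashed token, rounded to a configured number
of significant figures, which is what allows the full Bayesian comparison
to run on digests alone.
"""

from __future__ import annotations

import hashlib
import hmac
from dataclasses import dataclass

from .config import MatchConfig
from .frequencies import (
    FrequencyModel,
    normalize_postcode,
    postcode_sector,
    round_sig,
)
from .identifiers import ComparableDob, fragment_surname, fuzzy_tiers, standardize_name
from .records import (
    HashedDob,
    HashedGender,
    HashedName,
    HashedPersonRecord,
    HashedPostcode,
    HashedSurname,
    PersonRecord,
)

__all__ = ["HashSpec", "hash_token", "hash_person", "hash_file"]

_ALGORITHMS = {
    "HMAC-MD5": hashlib.md5,
    "HMAC-SHA-256": hashlib.sha256,
    "HMAC-SHA-512": hashlib.sha512,
}


@dataclass(frozen=True)
class HashSpec:
    """Hash algorithm and secret keys.

    ``identifier_key`` protects all identifiers; ``local_id_key`` (if set)
    hashes the local ID with a *separate* secret so it need not be shared
    with the other organisation; None passes local IDs through unmodified
    (e.g. if pre-hashed elsewhere).
    """
    algorithm: str = "HMAC-MD5"
    identifier_key: str = ""
    local_id_key: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {sorted(_ALGORITHMS)}")
        if not self.identifier_key:
            raise ValueError("identifier_key must be a non-empty secret")


def hash_token(spec: HashSpec, token: str, key: str | None = None) -> str:
    """Deterministic keyed digest of a canonical token, lowercase hex."""
    secret = spec.identifier_key if key is None else key
    return hmac.new(secret.encode("utf-8"), token.encode("utf-8"),
                    _ALGORITHMS[spec.algorithm]).hexdigest()


def _hash_name(spec: HashSpec, canonical: str, frequencies, start, end) -> HashedName:
    meta, f2c = fuzzy_tiers(canonical)
    name_freq = metaphone_freq = f2c_freq = None
    if frequencies is not None:
        name_freq, metaphone_freq, f2c_freq = frequencies
    return HashedName(
        name=hash_token(spec, canonical),
        metaphone=hash_token(spec, meta),
        f2c=hash_token(spec, f2c),
        name_freq=name_freq, metaphone_freq=metaphone_freq, f2c_freq=f2c_freq,
        start_date=start, end_date=end,
    )


def hash_person(record: PersonRecord, spec: HashSpec, config: MatchConfig,
                model: FrequencyModel | None = None,
                mode: str = "proband") -> HashedPersonRecord:
    """De-identify one person record.

    In proband mode a frequency model is required: each hashed token gets
    its (gender-conditional, floored) population frequency attached,
    rounded to ``config.rounding_sf`` significant figures, plus the
    gender-resolved name error-rate triples.  In sample mode only digests
    are emitted.  Start/end dates and the payload stay in plaintext.
    """
    if mode not in ("proband", "sample"):
        raise ValueError(f"mode must be 'proband' or 'sample', got {mode!r}")
    proband_mode = mode == "proband"
    if proband_mode and model is None:
        raise ValueError("proband-mode hashing requires a frequency model")

    sf = config.rounding_sf

    def rounded(freqs):
        return tuple(round_sig(f, sf) for f in freqs)

    forenames = []
    for dv in record.forenames:
        canonical = standardize_name(dv.value)
        if not canonical:
            continue
        freqs = None
        if proband_mode:
            freqs = rounded(model.forename_tier_frequencies(canonical, record.gender))
        forenames.append(_hash_name(spec, canonical, freqs, dv.start_date, dv.end_date))

    surnames = []
    for dv in record.surnames:
        fragments = fragment_surname(dv.value)
        if not fragments:
            continue
        hashed_fragments = []
        for fragment in fragments:
            freqs = None
            if proband_mode:
                freqs = rounded(model.surname_tier_frequencies(fragment, record.gender))
            hashed_fragments.append(_hash_name(spec, fragment, freqs, None, None))
        surnames.append(HashedSurname(fragments=tuple(hashed_fragments),
                                      start_date=dv.start_date, end_date=dv.end_date))

    hashed_dob = None
    if record.dob is not None:
        keys = ComparableDob.from_date(record.dob)
        hashed_dob = HashedDob(
            full=hash_token(spec, keys.full),
            year_month=hash_token(spec, keys.year_month),
            month_day=hash_token(spec, keys.month_day),
            year_day=hash_token(spec, keys.year_day),
        )

    hashed_gender = None
    if record.gender is not None:
        freq = round_sig(config.gender_prior(record.gender), sf) if proband_mode else None
        hashed_gender = HashedGender(digest=hash_token(spec, record.gender),
                                     frequency=freq)

    postcodes = []
    for dv in record.postcodes:
        unit = normalize_postcode(dv.value)
        if not unit:
            continue
        sector = postcode_sector(unit)
        pseudo = True
        unit_freq = sector_freq = None
        if model is not None:
            pseudo = model.postcodes.is_pseudo_or_unknown(unit)
            if proband_mode and not pseudo:
                unit_freq = round_sig(model.postcodes.unit_frequency(unit), sf)
                sector_freq = round_sig(model.postcodes.sector_frequency(unit), sf)
        postcodes.append(HashedPostcode(
            unit=hash_token(spec, unit), sector=hash_token(spec, sector),
            pseudo=pseudo, unit_freq=unit_freq, sector_freq=sector_freq,
            start_date=dv.start_date, end_date=dv.end_date))

    perfect_ids = {name: hash_token(spec, value)
                   for name, value in record.perfect_ids.items()}

    local_id = record.local_id
    if spec.local_id_key is not None:
        local_id = hash_token(spec, record.local_id, key=spec.local_id_key)

    forename_rates = surname_rates = None
    if proband_mode:
        w = config.p_female_given_fm
        forename_rates = tuple(round_sig(r, sf) for r in
                               config.forename_errors.resolve(record.gender, w))
        surname_rates = tuple(round_sig(r, sf) for r in
                              config.surname_errors.resolve(record.gender, w))

    return HashedPersonRecord(
        local_id=local_id, mode=mode,
        forenames=forenames, surnames=surnames, dob=hashed_dob,
        gender=hashed_gender, postcodes=postcodes, perfect_ids=perfect_ids,
        payload=record.payload,
        forename_error_rates=forename_rates, surname_error_rates=surname_rates,
    )


def hash_file(records: list[PersonRecord], spec: HashSpec, config: MatchConfig,
              model: FrequencyModel | None = None,
              mode: str = "proband") -> list[HashedPersonRecord]:
    """De-identify a whole person file (one hashed record per input record)."""
    return [hash_person(r, spec, config, model=model, mode=mode) for r in records]
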