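"""Linkage configuration: every tunable parameter of the matcher.

Defaults reproduce the settings validated against linked UK mental-health
records: empirical identifier error rates, national name-frequency floors,
the birth-year range parameter b, UK-population postcode scaling, and the
decision thresholds θ (consideration) and δ (leader advantage) chosen to
minimise a weighted performance metric FNR + w_MID·MID with w_MID = 20.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

__all__ = ["GenderedRates", "NameErrorRates", "MatchConfig", "DEFAULT_CONFIG"]

GENDER_FEMALE = "F"
GENDER_MALE = "M"
GENDER_OTHER = "X"
GENDERS = (GENDER_FEMALE, GENDER_MALE, GENDER_OTHER)


@dataclass(frozen=True)
class GenderedRates:
    """A probability recorded separately for female and male probands.

    For probands of gender X or unknown gender, the whole-population
    weighted mean of the F/M values is used, with weight
    P(female | female or male).
    """
    female: float
    male: float

    def resolve(self, gender: str | None, p_female_given_fm: float) -> float:
        if gender == GENDER_FEMALE:
            return self.female
        if gender == GENDER_MALE:
            return self.male
        return p_female_given_fm * self.female + (1 - p_female_given_fm) * self.male


@dataclass(frozen=True)
class NameErrorRates:
    """Four-state error probabilities for one name class (given same person)."""
    p_ep1: GenderedRates     # metaphone-but-not-name match
    p_ep2np1: GenderedRates  # F2C-but-not-metaphone-or-name match
    p_en: GenderedRates      # no match at all

    def resolve(self, gender: str | None, p_female_given_fm: float) -> tuple[float, float, float]:
        return (self.p_ep1.resolve(gender, p_female_given_fm),
                self.p_ep2np1.resolve(gender, p_female_given_fm),
                self.p_en.resolve(gender, p_female_given_fm))


# UK 2017 population, used to scale national postcode frequencies to a
# local population via k_postcode = n_uk / n_p.
UK_POPULATION_2017 = 66_040_000


@dataclass(frozen=True)
class MatchConfig:
    """All comparison-time and proband-file-encoded settings.

    Attributes are grouped as in the validated configuration: population
    priors, per-identifier error rates, postcode scaling, frequency
    floors/rounding, and the two decision thresholds.
    """

    # -- population priors ------------------------------------------------
    n_p: int = 852_523                 # population size (Cambridgeshire & Peterborough, 2018)
    b: float = 30.0                    # birth-year range parameter (years)
    p_female_given_fm: float = 0.51    # P(female | female or male)
    p_gender_x: float = 0.004          # P(gender not female or male)

    # -- frequency handling -----------------------------------------------
    f_min_forename: float = 5e-6       # floor for unknown/rare forenames
    f_min_surname: float = 5e-6        # floor for unknown/rare surnames
    rounding_sf: int = 5               # significant figures for frequencies in hashed files

    # -- postcode model ---------------------------------------------------
    k_postcode: float = UK_POPULATION_2017 / 852_523
    p_pseudopostcode_unit: float = 0.00201   # P(pseudopostcode or unknown unit)
    k_pseudopostcode: float = 1.83           # sector multiple; must be > 1

    # -- error rates (given proband and candidate are the same person) ----
    forename_errors: NameErrorRates = field(default_factory=lambda: NameErrorRates(
        p_ep1=GenderedRates(female=0.00894, male=0.00840),
        p_ep2np1=GenderedRates(female=0.00881, male=0.00688),
        p_en=GenderedRates(female=0.00572, male=0.00625),
    ))
    surname_errors: NameErrorRates = field(default_factory=lambda: NameErrorRates(
        p_ep1=GenderedRates(female=0.00551, male=0.00471),
        p_ep2np1=GenderedRates(female=0.00378, male=0.00247),
        p_en=GenderedRates(female=0.0567, male=0.0134),
    ))
    p_u_forename: float = 0.00191      # P(forename order shuffled | >= 2 forenames)
    p_ep_dob: float = 0.00459          # single-component DOB error
    p_en_dob: float = 0.0              # complete DOB mismatch (0 enables the DOB pre-filter)
    p_e_gender: float = 0.0033         # gender mismatch
    p_ep_postcode: float = 0.0097      # sector-only postcode match
    p_en_postcode: float = 0.300       # complete postcode mismatch

    # -- decision thresholds ----------------------------------------------
    theta: float = 5.0                 # consideration threshold (log odds), inclusive (>=)
    delta: float = 0.0                 # leader advantage threshold (log odds), inclusive
    w_mid: float = 20.0                # misidentification weight in the WPM

    def __post_init__(self) -> None:
        if self.n_p < 2:
            raise ValueError("n_p must be >= 2")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.k_pseudopostcode <= 1:
            raise ValueError("k_pseudopostcode must be > 1 (else the sector-only "
                             "pseudopostcode tier has zero chance probability)")

    @property
    def p_pseudopostcode_sector(self) -> float:
        return self.k_pseudopostcode * self.p_pseudopostcode_unit

    def gender_prior(self, gender: str) -> float:
        """Composed prior P(gender) over {F, M, X}."""
        if gender == GENDER_FEMALE:
            return self.p_female_given_fm * (1 - self.p_gender_x)
        if gender == GENDER_MALE:
            return (1 - self.p_female_given_fm) * (1 - self.p_gender_x)
        if gender == GENDER_OTHER:
            return self.p_gender_x
        raise ValueError(f"unknown gender code {gender!r}")

    # -- (de)serialisation: the comparison-time settings file --------------

    _COMPARISON_TIME_KEYS = ("n_p", "b", "k_postcode", "p_pseudopostcode_unit",
                             "k_pseudopostcode", "theta", "delta")

    def with_settings_file(self, path: str | Path) -> "MatchConfig":
        """Override the comparison-time subset from a key/value JSON file."""
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        unknown = set(data) - set(self._COMPARISON_TIME_KEYS)
        if unknown:
            raise ValueError(f"unknown comparison-time settings: {sorted(unknown)}")
        return replace(self, **data)

    def write_settings_file(self, path: str | Path) -> None:
        full = asdict(self)
        subset = {k: full[k] for k in self._COMPARISON_TIME_KEYS}
        Path(path).write_text(json.dumps(subset, indent=2) + "\n", encoding="utf-8")


DEFAULT_CONFIG = MatchConfig()
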