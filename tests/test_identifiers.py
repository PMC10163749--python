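"""Identifier standardization, fuzzy tiers, and per-class comparisons."""

import math
from datetime import date

import pytest

from bayeslink.config import MatchConfig
from bayeslink.identifiers import (
    ComparableName,
    ComparablePostcode,
    ComparableSurname,
    compare_dob,
    compare_forename_pair,
    compare_forenames,
    compare_gender,
    compare_postcodes,
    compare_surnames,
    fragment_surname,
    fuzzy_tiers,
    standardize_name,
    transliterate_variants,
)

class TestStandardization:
    @pytest.mark.parametrize("raw,expected", [
        ("L'Estrange", "LESTRANGE"),
        ("smith", "SMITH"),
        ("  Mary Jane ", "MARYJANE"),
        ("Müller", "MULLER"),
    ])
    def test_canonical_form(self, raw, expected):
        assert standardize_name(raw) == expected

    def test_transliteration_variants(self):
        assert transliterate_variants("Müller") == ["MULLER", "MUELLER"]
        assert transliterate_variants("Smith") == ["SMITH"]

    def test_punctuation_only_is_missing(self):
        assert standardize_name("--") == ""


class TestFuzzyTiers:
    @pytest.mark.parametrize("name,meta", [
        ("RUDOLF", "RTLF"), ("RUDOLPH", "RTLF"),
        ("JONATHAN", "JN0N"), ("JONATHON", "JN0N"),
    ])
    def test_phonetic_spelling_clusters(self, name, meta):
        assert fuzzy_tiers(name)[0] == meta

    def test_f2c_of_short_token(self):
        assert fuzzy_tiers("AB")[1] == "AB"

    def test_null_metaphone_still_comparable(self):
        meta, f2c = fuzzy_tiers("A")
        assert meta == "A" or isinstance(meta, str)


class TestSurnameFragmentation:
    def test_compound_surname(self):
        assert fragment_surname("Mozart-Smith") == ["MOZARTSMITH", "MOZART", "SMITH"]

    def test_nobiliary_particle_dropped(self):
        assert fragment_surname("van Beethoven") == ["VANBEETHOVEN", "BEETHOVEN"]

    def test_simple_surname(self):
        assert fragment_surname("Smith") == ["SMITH"]

    def test_accented_surname_keeps_both_variants(self):
        fragments = fragment_surname("Müller")
        assert "MULLER" in fragments and "MUELLER" in fragments


class TestDobComparison:
    def test_identical(self):
        assert compare_dob(date(1980, 6, 15), date(1980, 6, 15)) == "full"

    @pytest.mark.parametrize("other", [
        date(1980, 6, 16),   # day differs
        date(1980, 7, 15),   # month differs
        date(1981, 6, 15),   # year differs
    ])
    def test_single_component_mismatch_is_partial(self, other):
        assert compare_dob(date(1980, 6, 15), other) == "partial1"

    def test_two_component_mismatch_is_none(self):
        assert compare_dob(date(1980, 6, 15), date(1981, 7, 15)) == "none"

    def test_symmetric(self):
        a, b = date(1980, 6, 15), date(1980, 7, 15)
        assert compare_dob(a, b) == compare_dob(b, a)


class TestGenderComparison:
    def test_match_at_defaults(self):
        llr = compare_gender("F", "F", 0.50796, 0.0033)
        assert llr == pytest.approx(math.log((1 - 0.0033) / 0.50796))

    def test_mismatch(self):
        llr = compare_gender("F", "M", 0.50796, 0.0033)
        assert llr == pytest.approx(math.log(0.0033 / (1 - 0.50796)))

    def test_absent_gender_contributes_nothing(self):
        assert compare_gender("F", None, 0.50796, 0.0033) == 0.0
        assert compare_gender(None, "F", None, 0.0033) == 0.0


def _name(token, freqs=None, start=None, end=None):
    meta, f2c = fuzzy_tiers(token)
    return ComparableName(token, meta, f2c, freqs, start, end)


# Worked-example frequencies: male forename JAMES (p_f 0.0295, metaphone
# frequency p_f + 0.000133) and the weighted-mean ALLEN surname parameters.
JAMES_FREQS = (0.0295, 0.0295 + 0.000133, 0.0295 + 0.000133 + 0.01)
MALE_FORENAME_RATES = (0.0084, 0.00688, 0.00625)
ALLEN_FREQS = (0.0028, 0.003, 0.113)
ALLEN_RATES = (0.00510, 0.00314, 0.0355)


class TestForenamePair:
    def test_metaphone_match_worked_example(self):
        outcome = compare_forename_pair(_name("JAMES", JAMES_FREQS),
                                        _name("JAIMES"),
                                        MALE_FORENAME_RATES, 5e-6)
        assert outcome.tier == "partial1"
        assert outcome.llr == pytest.approx(4.15, abs=0.005)

    def test_full_match_worked_example(self):
        outcome = compare_forename_pair(_name("JAMES", JAMES_FREQS),
                                        _name("JAMES"),
                                        MALE_FORENAME_RATES, 5e-6)
        assert outcome.tier == "full"
        assert outcome.llr == pytest.approx(3.50, abs=0.005)

    def test_f2c_match_worked_example(self):
        outcome = compare_forename_pair(_name("ALLEN", ALLEN_FREQS),
                                        _name("ALLARDYCE"),
                                        ALLEN_RATES, 5e-6)
        assert outcome.tier == "partial2"
        assert outcome.llr == pytest.approx(-3.56, abs=0.005)

    def test_weighted_mean_rates_reproduce_worked_example(self):
        """The ALLEN parameters are the F/M-weighted default surname rates."""
        config = MatchConfig()
        resolved = config.surname_errors.resolve("X", config.p_female_given_fm)
        assert resolved[1] == pytest.approx(0.00314, abs=2e-5)
        assert resolved[2] == pytest.approx(0.0355, abs=2e-4)

    def test_tier_is_symmetric(self):
        from bayeslink.identifiers import name_tier
        a, b = _name("RUDOLF", JAMES_FREQS), _name("RUDOLPH")
        assert name_tier(a, b) == name_tier(b, a) == "partial1"


class TestForenameLists:
    def test_empty_side_contributes_nothing(self):
        assert compare_forenames([_name("ANNA", JAMES_FREQS)], [],
                                 MALE_FORENAME_RATES, 5e-6, 0.00191) == 0.0
        assert compare_forenames([], [_name("ANNA")],
                                 MALE_FORENAME_RATES, 5e-6, 0.00191) == 0.0

    def test_strict_order_adds_log_p_o(self):
        probands = [_name("ANNA", JAMES_FREQS), _name("MARIE", JAMES_FREQS)]
        candidates = [_name("ANNA"), _name("MARIE")]
        pairwise = sum(compare_forename_pair(p, c, MALE_FORENAME_RATES, 5e-6).llr
                       for p, c in zip(probands, candidates))
        total = compare_forenames(probands, candidates,
                                  MALE_FORENAME_RATES, 5e-6, 0.00191)
        assert total == pytest.approx(pairwise + math.log(1 - 0.00191))

    def test_order_mismatch_pays_p_u(self):
        probands = [_name("MARIE", JAMES_FREQS), _name("ANNA", JAMES_FREQS)]
        candidates = [_name("ANNA"), _name("MARIE")]
        pairwise = (compare_forename_pair(probands[0], candidates[1],
                                          MALE_FORENAME_RATES, 5e-6).llr
                    + compare_forename_pair(probands[1], candidates[0],
                                            MALE_FORENAME_RATES, 5e-6).llr)
        total = compare_forenames(probands, candidates,
                                  MALE_FORENAME_RATES, 5e-6, 0.00191)
        # Table 1E mismatch branch: + ln(p_u) - ln(2*1 - 1)
        assert total == pytest.approx(pairwise + math.log(0.00191))

    def test_temporal_nonoverlap_excludes_pair(self):
        old = _name("ANNA", JAMES_FREQS, end=date(2000, 1, 1))
        new = _name("ANNA", start=date(2010, 1, 1))
        assert compare_forenames([old], [new],
                                 MALE_FORENAME_RATES, 5e-6, 0.00191) == 0.0


def _surname(raw, freq_for, start=None, end=None):
    fragments = tuple(_name(f, freq_for(f)) for f in fragment_surname(raw))
    return ComparableSurname(fragments, start, end)


class TestSurnameComparison:
    @staticmethod
    def freq_for(fragment):
        table = {"SMITH": 0.01, "MOZART": 0.0005, "MOZARTSMITH": 5e-6,
                 "JONES": 0.012}
        base = table.get(fragment, 5e-6)
        return (base, base * 1.3, base * 1.3 + 0.02)

    def test_compound_vs_compound_matches_joined_form(self):
        p = _surname("Mozart-Smith", self.freq_for)
        c = _surname("Mozart-Smith", self.freq_for)
        from bayeslink.identifiers import surname_pair_outcome
        outcome = surname_pair_outcome(p, c, ALLEN_RATES, 5e-6)
        assert outcome.tier == "full"
        # most informative fragment: the whole joined form, not SMITH
        expected = math.log((1 - sum(ALLEN_RATES)) / 5e-6)
        assert outcome.llr == pytest.approx(expected)

    def test_compound_vs_component_uses_matching_fragment_frequency(self):
        p = _surname("Mozart-Smith", self.freq_for)
        c = _surname("Smith", self.freq_for)
        from bayeslink.identifiers import surname_pair_outcome
        outcome = surname_pair_outcome(p, c, ALLEN_RATES, 5e-6)
        assert outcome.tier == "full"
        expected = math.log((1 - sum(ALLEN_RATES)) / 0.01)
        assert outcome.llr == pytest.approx(expected)

    def test_complete_mismatch_scored_once(self):
        total = compare_surnames([_surname("Smith", self.freq_for)],
                                 [_surname("Jones", self.freq_for)],
                                 ALLEN_RATES, 5e-6)
        from bayeslink.identifiers import four_state_params
        expected = four_state_params(self.freq_for("SMITH"), ALLEN_RATES,
                                     5e-6).llr("none")
        assert total == pytest.approx(expected)

    def test_multiple_surnames_pay_unordered_correction(self):
        p = [_surname("Smith", self.freq_for)]
        c = [_surname("Smith", self.freq_for), _surname("Jones", self.freq_for)]
        single = compare_surnames(p, [_surname("Smith", self.freq_for)],
                                  ALLEN_RATES, 5e-6)
        total = compare_surnames(p, c, ALLEN_RATES, 5e-6)
        assert total == pytest.approx(single - math.log(2))


def _postcode(unit, p_f=None, p_p=None, start=None, end=None):
    from bayeslink.frequencies import postcode_sector
    return ComparablePostcode(unit, postcode_sector(unit), p_f, p_p, start, end)


class TestPostcodeComparison:
    def test_tiers(self):
        from bayeslink.identifiers import postcode_tier
        assert postcode_tier(_postcode("CB20AH"), _postcode("CB20AH")) == "full"
        assert postcode_tier(_postcode("CB20AH"), _postcode("CB20XY")) == "partial1"
        assert postcode_tier(_postcode("CB20AH"), _postcode("PE11AA")) == "none"

    def test_temporal_nonoverlap_skipped_equals_removed(self):
        active = _postcode("CB20AH", 0.001, 0.01)
        stale_candidate = _postcode("CB20AH", start=date(2015, 1, 1))
        proband_old = _postcode("CB20AH", 0.001, 0.01, end=date(2010, 1, 1))
        other = _postcode("PE11AA")
        with_skip = compare_postcodes([proband_old], [stale_candidate, other],
                                      0.0097, 0.300)
        removed = compare_postcodes([proband_old], [other], 0.0097, 0.300)
        assert with_skip == pytest.approx(removed)

    def test_mismatch_is_weak_negative_evidence(self):
        llr = compare_postcodes([_postcode("CB20AH", 0.001, 0.01)],
                                [_postcode("PE11AA")], 0.0097, 0.300)
        assert -1.5 < llr < 0


def test_self_comparison_yields_only_full_tiers(model, config, population):
    """Error-free records agree with themselves at the full tier everywhere."""
    from bayeslink.engine import build_comparable
    from bayeslink.identifiers import dob_tier, name_tier, postcode_tier
    for record in population[:40]:
        proband = build_comparable(record, config, model, proband_side=True)
        candidate = build_comparable(record, config, model, proband_side=False)
        if proband.dob is not None:
            assert dob_tier(proband.dob, candidate.dob) == "full"
        for p, c in zip(proband.forenames, candidate.forenames):
            assert name_tier(p, c) == "full"
        for p, c in zip(proband.postcodes, candidate.postcodes):
            assert postcode_tier(p, c) == "full"
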