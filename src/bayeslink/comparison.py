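"""Generic full/partial comparison systems expressed as log likelihood ratios.

Each identifier comparison is modelled as a small discrete system: given
data D (the observed agreement tier between a proband and a candidate
value), the hypothesis H that the two records belong to the same person is
updated by the log likelihood ratio ln[P(D|H) / P(D|¬H)].  Three system
sizes are supported:

* two-state (match / no match), e.g. gender;
* three-state (full / partial / no match), e.g. date of birth, postcode;
* four-state (full / partial-1 / partial-2 / no match), e.g. names, where
  partial-1 is a phonetic (metaphone) match and partial-2 a
  first-two-characters match.

In each system the P(D|H) column is driven by error probabilities (the
chance that the same person's identifier is mis-recorded to the given
degree) and the P(D|¬H) column by population frequencies (the chance that
a random other person agrees to that degree).  Both columns sum to one.

The module also provides the corrections applied when several identifiers
of one class are compared at once (pick-the-best over multiple surnames,
ordered forename lists), which would otherwise inflate the chance of a
spurious match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "NEG_INF",
    "InvalidComparisonParameter",
    "TwoStateParams",
    "ThreeStateParams",
    "FourStateParams",
    "ComparisonOutcome",
    "MultiComparisonContext",
    "llr_two_state",
    "llr_three_state",
    "llr_four_state",
    "best_pairing_unordered",
    "unordered_correction",
    "ordered_correction",
    "check_comparison_ordering",
]

#: Sentinel for impossible-under-H outcomes.  ``float("-inf")`` is absorbing
#: under addition and sorts below every finite value, which is exactly the
#: behaviour required of a cumulative log-odds term for a ruled-out match.
NEG_INF = float("-inf")

# Tier names, from best to worst agreement.
TIER_FULL = "full"
TIER_PARTIAL1 = "partial1"
TIER_PARTIAL2 = "partial2"
TIER_NONE = "none"

_TIER_RANK = {TIER_NONE: 0, TIER_PARTIAL2: 1, TIER_PARTIAL1: 2, TIER_FULL: 3}


class InvalidComparisonParameter(ValueError):
    """A probability parameter is outside its admissible range."""


def _log_ratio(numerator: float, denominator: float) -> float:
    """ln(numerator/denominator) with 0 numerators mapping to −∞.

    A zero numerator means the observed data are impossible under H, which
    legitimately rules the candidate out.  A nonpositive denominator with a
    positive numerator would mean infinite support for H from a single
    identifier, which is never acceptable: it signals a misconfigured
    frequency model.
    """
    if numerator < 0 or denominator < 0:
        raise InvalidComparisonParameter(
            f"negative probability in ratio {numerator}/{denominator}")
    if numerator == 0:
        if denominator <= 0:
            raise InvalidComparisonParameter("0/0 likelihood ratio")
        return NEG_INF
    if denominator <= 0:
        raise InvalidComparisonParameter(
            f"positive numerator {numerator} over nonpositive denominator")
    return math.log(numerator / denominator)


def tier_rank(tier: str) -> int:
    """Rank of an agreement tier; higher is better agreement."""
    return _TIER_RANK[tier]


@dataclass(frozen=True)
class TwoStateParams:
    """Match / no-match comparison.

    p_e: P(mismatch | same person) — the error probability.
    p_f: P(match | different person) — the population frequency of the
         proband's value.
    """
    p_e: float
    p_f: float

    def __post_init__(self) -> None:
        if not 0 < self.p_f < 1:
            raise InvalidComparisonParameter(f"p_f={self.p_f} must be in (0,1)")
        if not 0 <= self.p_e <= 1:
            raise InvalidComparisonParameter(f"p_e={self.p_e} must be in [0,1]")

    @property
    def p_c(self) -> float:
        return 1.0 - self.p_e

    @property
    def p_n(self) -> float:
        return 1.0 - self.p_f

    def llr(self, tier: str) -> float:
        if tier == TIER_FULL:
            return _log_ratio(self.p_c, self.p_f)
        if tier == TIER_NONE:
            return _log_ratio(self.p_e, self.p_n)
        raise ValueError(f"two-state system has no tier {tier!r}")


@dataclass(frozen=True)
class ThreeStateParams:
    """Full / partial / no-match comparison.

    p_ep:  P(partial-only match | same person)
    p_en:  P(no match | same person)
    p_f:   P(full match | different person)
    p_pnf: P(partial but not full match | different person)
    """
    p_ep: float
    p_en: float
    p_f: float
    p_pnf: float

    def __post_init__(self) -> None:
        if not 0 < self.p_f < 1:
            raise InvalidComparisonParameter(f"p_f={self.p_f} must be in (0,1)")
        if self.p_ep < 0 or self.p_en < 0 or self.p_ep + self.p_en > 1:
            raise InvalidComparisonParameter("error probabilities must be in [0,1] and sum to <=1")
        if self.p_pnf <= 0 and self.p_ep > 0:
            # would give an infinite LLR for an erroneous partial match
            raise InvalidComparisonParameter(
                f"p_pnf={self.p_pnf} must be > 0 when p_ep > 0")
        if self.p_f + self.p_pnf > 1:
            raise InvalidComparisonParameter("p_f + p_pnf must be <= 1")

    @property
    def p_c(self) -> float:
        return 1.0 - self.p_ep - self.p_en

    @property
    def p_n(self) -> float:
        return 1.0 - self.p_f - self.p_pnf

    def llr(self, tier: str) -> float:
        if tier == TIER_FULL:
            return _log_ratio(self.p_c, self.p_f)
        if tier == TIER_PARTIAL1:
            return _log_ratio(self.p_ep, self.p_pnf)
        if tier == TIER_NONE:
            return _log_ratio(self.p_en, self.p_n)
        raise ValueError(f"three-state system has no tier {tier!r}")


@dataclass(frozen=True)
class FourStateParams:
    """Full / partial-1 / partial-2 / no-match comparison (names).

    Error column (given same person): p_ep1 partial-1 only, p_ep2np1
    partial-2 only, p_en complete mismatch.  Chance column (given different
    person): p_f full, p_p1nf partial-1-not-full, p_p2np1
    partial-2-not-partial-1.
    """
    p_ep1: float
    p_ep2np1: float
    p_en: float
    p_f: float
    p_p1nf: float
    p_p2np1: float

    def __post_init__(self) -> None:
        if not 0 < self.p_f < 1:
            raise InvalidComparisonParameter(f"p_f={self.p_f} must be in (0,1)")
        errors = (self.p_ep1, self.p_ep2np1, self.p_en)
        if any(e < 0 for e in errors) or sum(errors) > 1:
            raise InvalidComparisonParameter("error probabilities must be in [0,1] and sum to <=1")
        for name, num, den in (("p_p1nf", self.p_ep1, self.p_p1nf),
                               ("p_p2np1", self.p_ep2np1, self.p_p2np1)):
            if den <= 0 and num > 0:
                raise InvalidComparisonParameter(
                    f"{name}={den} must be > 0 when its error probability is > 0")
        if self.p_f + self.p_p1nf + self.p_p2np1 > 1:
            raise InvalidComparisonParameter("chance-match probabilities must sum to <=1")

    @property
    def p_c(self) -> float:
        return 1.0 - self.p_ep1 - self.p_ep2np1 - self.p_en

    @property
    def p_n(self) -> float:
        return 1.0 - self.p_f - self.p_p1nf - self.p_p2np1

    def llr(self, tier: str) -> float:
        if tier == TIER_FULL:
            return _log_ratio(self.p_c, self.p_f)
        if tier == TIER_PARTIAL1:
            return _log_ratio(self.p_ep1, self.p_p1nf)
        if tier == TIER_PARTIAL2:
            return _log_ratio(self.p_ep2np1, self.p_p2np1)
        if tier == TIER_NONE:
            return _log_ratio(self.p_en, self.p_n)
        raise ValueError(f"four-state system has no tier {tier!r}")


@dataclass(frozen=True)
class ComparisonOutcome:
    """Agreement tier of one identifier pair plus its LLR contribution."""
    tier: str
    llr: float

    @property
    def is_positive(self) -> bool:
        return self.llr > 0


@dataclass(frozen=True)
class MultiComparisonContext:
    """Bookkeeping for a multi-identifier comparison of one class.

    n, m: number of proband / candidate identifiers; c: number of selected
    pairings with LLR > 0; ordered: whether sequence matters (forenames);
    strict_order: whether every positive pairing matched index-for-index;
    p_o: P(order preserved | same person) when >= 2 orderings exist.
    """
    n: int
    m: int
    c: int
    ordered: bool = False
    strict_order: bool = False
    p_o: float = 1.0

    @property
    def p_u(self) -> float:
        return 1.0 - self.p_o


def llr_two_state(matched: bool, params: TwoStateParams) -> float:
    return params.llr(TIER_FULL if matched else TIER_NONE)


def llr_three_state(tier: str, params: ThreeStateParams) -> float:
    return params.llr(tier)


def llr_four_state(tier: str, params: FourStateParams) -> float:
    return params.llr(tier)


def best_pairing_unordered(
    pairwise_llrs: Sequence[Sequence[float | None]],
) -> tuple[list[tuple[int, int, float]], int]:
    """Greedy pick-the-best pairing of proband and candidate identifiers.

    ``pairwise_llrs[i][j]`` is the LLR of comparing proband identifier i
    with candidate identifier j; ``None`` marks pairs that must not be
    compared at all (e.g. explicit temporal non-overlap).  Pairs are taken
    in descending LLR order, ties broken by (proband index, candidate
    index) ascending for determinism, and each identifier may be used at
    most once.

    Returns (selected pairs as (i, j, llr), c) where c counts the selected
    pairs with LLR > 0 ("positive" comparisons).
    """
    candidates: list[tuple[float, int, int]] = []
    for i, row in enumerate(pairwise_llrs):
        for j, llr in enumerate(row):
            if llr is not None:
                candidates.append((llr, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    selected: list[tuple[int, int, float]] = []
    for llr, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        selected.append((i, j, llr))
    selected.sort()
    c = sum(1 for _, _, llr in selected if llr > 0)
    return selected, c


def unordered_correction(c: int, m: int) -> float:
    """Multiple-comparison penalty −ln(m·(m−1)·…) for c positive pairings.

    Picking the best of several candidate identifiers inflates the chance
    that a random person matches; the Bonferroni-style factor m(m−1)… (one
    term per positive pairing) is divided out of P(D|¬H), i.e. subtracted
    from the log odds.  No correction applies to pure non-matches (c = 0),
    nor when only a single comparison was possible.
    """
    if c == 0:
        return 0.0
    if not 1 <= c <= m:
        raise InvalidComparisonParameter(f"need 1 <= c <= m, got c={c}, m={m}")
    product = 1
    for i in range(c):
        product *= m - i
    return -math.log(product)


def ordered_correction(context: MultiComparisonContext) -> float:
    """Correction for ordered multi-identifier comparisons (forenames).

    When the best pairing preserves the recorded order, P(D|H) is weighted
    by p_o (only one ordering achieves this, so P(D|¬H) needs no
    correction).  When matches occurred out of order, P(D|H) is weighted by
    p_u = 1 − p_o and P(D|¬H) by the unordered product minus one (the
    strictly ordered arrangement).
    """
    if context.c < 1 or context.m <= 1:
        return 0.0
    if context.strict_order:
        if context.p_o <= 0:
            raise InvalidComparisonParameter("p_o must be > 0 for an ordered match")
        return math.log(context.p_o)
    if not 0 < context.p_o < 1:
        raise InvalidComparisonParameter(
            f"p_o={context.p_o} must be in (0,1) when an order mismatch occurred")
    product = 1
    for i in range(context.c):
        product *= context.m - i
    return math.log(context.p_u) - math.log(product - 1)


def check_comparison_ordering(
    params: TwoStateParams | ThreeStateParams | FourStateParams,
    label: str = "",
) -> list[str]:
    """Warn when tier LLRs deviate from none <= partial(s) <= full.

    The intuitive ordering is not guaranteed: a very name-specific
    metaphone can make a phonetic match stronger evidence than an exact
    match, and a very common F2C can make that partial tier weaker evidence
    than an outright mismatch.  Returns human-readable warnings; never
    raises.
    """
    if isinstance(params, TwoStateParams):
        tiers = [TIER_NONE, TIER_FULL]
    elif isinstance(params, ThreeStateParams):
        tiers = [TIER_NONE, TIER_PARTIAL1, TIER_FULL]
    else:
        tiers = [TIER_NONE, TIER_PARTIAL2, TIER_PARTIAL1, TIER_FULL]
    warnings: list[str] = []
    prefix = f"{label}: " if label else ""
    try:
        llrs = [(t, params.llr(t)) for t in tiers]
    except InvalidComparisonParameter as exc:
        return [f"{prefix}could not evaluate tiers: {exc}"]
    for (t_lo, llr_lo), (t_hi, llr_hi) in zip(llrs, llrs[1:]):
        if llr_lo > llr_hi:
            warnings.append(
                f"{prefix}tier ordering violated: {t_lo} ({llr_lo:+.2f}) > "
                f"{t_hi} ({llr_hi:+.2f})")
    return warnings
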