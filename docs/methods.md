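# Methods

## The matching model

`bayeslink` decides, for each *proband* (a person of interest from
organisation A), whether any *candidate* in a *sample* (organisation B's
file) is the same person.  Let H be the hypothesis that a given candidate
is the proband.  Starting from the population prior P(H) = 1/n_p, where
n_p is the size of the population both files are drawn from, the log odds
are updated once per identifier class:

    log(posterior odds) = −ln(n_p − 1) + LLR_DOB + LLR_gender
                          + LLR_forename + LLR_surname + LLR_postcode

with each LLR = ln[P(D|H)/P(D|¬H)] for the observed agreement tier D.
Identifiers missing on either side contribute nothing (missing at random).
Identifier classes are assumed conditionally independent given H, except
that all forename frequencies and name error rates are conditioned on the
proband's gender (names and gender are strongly dependent).

Each identifier class uses a small discrete comparison system whose two
probability columns each sum to one:

* **Gender** — two-state (match/no match).  P(D|¬H) for a match is the
  composed prior of the proband's gender: P(F) = 0.51·(1−0.004),
  P(M) = 0.49·(1−0.004), P(X) = 0.004.  The published settings give the
  conditional P(female|F or M) = 0.51 and the X mass separately; the
  product composition is this package's (natural) choice of joint.
* **Date of birth** — three-state: full match; partial = exactly one of
  year/month/day differing; otherwise none.  Chance probabilities are
  closed forms in the birth-year-range parameter b:
  p_f = 1/(365.25·b) and p_pnf = (16b + 631)/(5844b).  29 February is
  treated like every other day.
* **Forename** — four-state per name pair: exact canonical match;
  metaphone match (primary Double Metaphone code); first-two-characters
  (F2C) match; none.  Chance probabilities come from gender-conditional
  frequency tables.
* **Surname** — as forename, but each recorded surname is first split
  into fragments (joined form, components, transliteration variants,
  minus nobiliary particles) and the best fragment pair is scored,
  preferring higher tiers and then the most informative (lowest-frequency)
  matching fragment, whose frequency is the one used.
* **Postcode** — three-state: unit match, sector match, none; a mismatch
  is deliberately weak negative evidence (p_en = 0.30: people move).

**Multi-identifier corrections.**  When a class holds several values, all
pairs are compared and a greedy pick-the-best pairing is taken (descending
LLR, each value used once; ties break by index for determinism).  Picking
the best of m candidate values inflates the chance of a spurious match, so
for c positive (LLR > 0) pairings, ln(m·(m−1)·…) (c factors) is subtracted
from the log odds — a Bonferroni-style correction, slightly conservative
(mq ≥ 1 − (1−q)^m) but composable in a cumulative log-odds system.
Surnames and postcodes are unordered; forename lists are ordered: a
strictly index-aligned best pairing multiplies P(D|H) by p_o, an
out-of-order one by p_u = 1 − p_o with the unordered ¬H correction minus
the single ordered arrangement.  Greedy pairing is not optimal assignment;
on small instances an independent exhaustive pick-the-best oracle verifies
it, and a test documents that it never exceeds the optimal-assignment
total.  Unpaired proband values that had at least one comparable partner
contribute their own no-match LLR once each (the published procedure does
not say; this is the package's choice, and it keeps mismatch evidence
symmetric with the single-value case).

**Decision rule.**  The leading candidate is declared the match iff its
log odds reach the consideration threshold θ *and* lead the runner-up by
at least δ (both inclusive — "exceeds" is read as ≥ so that δ = 0 can
declare matches; ties at δ = 0 go to the first candidate in file order,
which also makes duplicate detection possible).  The runner-up is the
second-best candidate overall, not the second-best above θ.  Probands are
decided independently; there is no one-to-one (bipartite) constraint.  A
shared "perfect" identifier (e.g. NHS number) short-circuits the
probabilistic path entirely, with a translation map for differing field
names.

**−∞ handling.**  A tier with zero probability under H (e.g. a complete
DOB mismatch when p_en_dob = 0) contributes −∞, which is absorbing under
addition and sorts below all finite scores.  A zero/negative denominator
with positive numerator (infinite support from one identifier) is always a
configuration error and raises.  When p_en_dob = 0, candidates are
pre-filtered via hash indexes on the full DOB and its three two-component
projections; ruled-out candidates would score −∞ and can never win, so
the filter is exact, and with evenly spread birthdays it reduces work by
5844b/(16b + 647) (~155× at b = 30), with a further (16b + 647)/16 (~140×
at b = 100) if p_ep_dob = 0 too.

## De-identified mode

Both organisations share a secret key and hash every identifier and fuzzy
tier with HMAC (MD5 by default; SHA-256/SHA-512 available), lowercase hex.
Equal digests are treated as equal plaintext (collisions assumed away).
The proband file also carries, per token, its population frequency rounded
to 5 significant figures (round-half-even), which is all the Bayesian
update needs; sample files carry digests only.  Dates and the opaque
payload stay plaintext; the local ID may be passed through or hashed with
a separate key.

Design choices the published description leaves open, resolved here:

* **Fuzzy DOB representation** — the full-DOB digest plus digests of the
  three two-component projections (year-month, month-day, year-day).
  Exactly one projection survives a single-component error, and two
  projections can only agree when the full DOB agrees, so the plaintext
  partial-match definition is recovered exactly from digests.
* **Gender-conditional error rates** — the proband record carries the
  resolved (p_ep1, p_ep2np1, p_en) triples for forenames and surnames.
  The attached gender frequency already identifies the gender category, so
  this leaks nothing further, and it makes hashed decisions bit-compatible
  with plaintext ones up to frequency rounding.
* Tokens are hashed after standardization, so transliteration variants
  (MULLER, MUELLER) hash separately and match exactly as in plaintext.

The defining property, tested end to end, is that hashed-mode linkage
reproduces plaintext decisions exactly on synthetic data, with leader log
odds equal to within the rounding perturbation (< 0.01).

## Frequency models

* **Names.**  Tables map (name, gender) → frequency; metaphone and F2C
  frequencies are derived by summing over contributing names, so a fuzzy
  tier is never rarer than any name it covers.  Lookups are floored at
  f_min = 5×10⁻⁶ (unfloored rare frequencies would let a single name add
  up to ln(1/f) and overwhelm the prior); no renormalization is applied
  after flooring.  Gender-X/unknown lookups take the 0.51/0.49 weighted
  mean of the floored F/M values.  The four-state chance column is built
  from the three attached marginals as p_p1nf = p_meta − p_name and
  p_p2np1 = p_f2c − p_meta, clamped below at f_min because the tiers are
  not strictly nested in probability for unusual names (a name's F2C
  population can be smaller than its metaphone population); the clamp
  keeps every denominator positive.
* **Postcodes.**  Unit population = mean Output Area (OA) population ÷
  postcodes per OA; sector population = mean OA population × OAs per
  sector; national frequencies divide by the national population and are
  scaled by k_postcode (≈ n_UK/n_p for a geographically concentrated local
  population, ≈ 1 for a dispersed one) and weighted by
  (1 − p_pseudopostcode_sector).  Pseudopostcodes (ZZ99…, e.g. ZZ99 3VZ =
  no fixed abode) and units unknown to the model get
  p_f = p_pseudopostcode_unit = 0.00201 and sector probability
  k_pseudopostcode = 1.83 times that; k_pseudopostcode must exceed 1 or a
  sector-only pseudopostcode match would have zero chance probability.
* **Tier ordering checks.**  Because parameters are user-configurable,
  the package can evaluate all tiers of a comparison and warn when the
  LLRs deviate from none ≤ partial(s) ≤ full — inversions are legitimate
  (JAMES's metaphone is more specific than the name itself) but worth
  surfacing.

## Default settings

All defaults are the validated configuration: n_p = 852,523; b = 30
(empirical, reflecting a subsampled age composition rather than the full
population age range); gender priors 0.51/0.004; f_min = 5×10⁻⁶ for both
name classes; 5 significant figures of frequency rounding; k_postcode =
66,040,000/852,523; pseudopostcode parameters 0.00201 and 1.83; the
gendered forename/surname error-rate triples; p_u_forename = 0.00191;
p_ep_dob = 0.00459 with p_en_dob = 0 (the measured complete-mismatch rate
is 0.00033, but zero enables the exact pre-filter); p_e_gender = 0.0033;
postcode rates 0.0097/0.300; θ = 5, δ = 0 (the WPM optimum, see below);
w_MID = 20.

## The synthetic validation harness

Real validation used gold-standard NHS-number-linked records, which cannot
ship.  The harness instead generates populations with the statistical
structure the matcher assumes and re-runs the same evaluation:

* **Generator.**  Gender from the composed priors; 1–2 forenames drawn
  gender-conditionally and 1–2 surnames (occasionally compound) from
  synthetic tables; DOBs uniform over a b-year window; 0–3 postcodes from
  a synthetic unit/sector geography with UK-like unit populations (~31
  people), plus pseudopostcodes at the configured 0.00201.  The name
  tables combine hand-written phonetic spelling clusters (RUDOLF/RUDOLPH,
  STEPHEN/STEVEN, …) with a generated syllable-based Zipf tail, scaled so
  the most common forename has frequency ≈ 0.03 and the most common
  surname ≈ 0.013 — the scale real national tables exhibit (the published
  worked examples use JAMES at 0.0295 and SMITH-like surnames near 0.01).
* **Error injection.**  Each overlapping person appears in both files
  with independently injected errors at the default (empirically measured)
  rates: metaphone-preserving single-character edits (rejection-sampled,
  falling back to a same-metaphone dictionary neighbour), F2C-preserving
  metaphone-breaking edits, complete name replacements, single-component
  DOB edits, complete DOB replacements at their small real rate (0.00033,
  even though the matcher assumes zero — deliberately, so the study
  conditions include the model's own approximation), gender flips,
  sector-preserving and complete postcode changes, and forename order
  shuffles at p_u.  Membership and each file's error stream use separate
  substreams of one seeded generator.
* **Evaluation.**  TP/TN/FP/FN classify detection ("declared" vs "in
  sample"; a declared match to the *wrong* person still counts as TP for
  detection), MID = P(wrong person | declared) is tracked separately, and
  WPM = FNR + 20·MID summarises the preference for accuracy over
  coverage.  Scores are threshold-independent, so one linkage run supports
  the whole θ/δ ∈ {0..15}² sweep.  AUROC uses leader log odds with −∞
  replaced by −10⁵ and midrank tie handling.

What passing synthetic tests shows — and what it does not.  The harness
exercises every code path (fuzzy tiers, corrections, hashing, pre-filter,
thresholds) under known truth, and reaches TPR ≈ 0.96 with MID < 0.001 at
the default thresholds on a 10,000-person world (problem size chosen so
the whole suite runs in well under a minute of linkage time).  It cannot
certify real-data accuracy: real names are not conditionally independent
of age or geography, real error processes include transpositions and
aliasing the injector does not model, and real frequency tables are
estimated rather than known.  The published real-data figures (AUROC
0.997–0.999, TPR 0.965, MID 0.0025) required the gold-standard clinical
databases.

## Numerical choices

* Natural logarithms throughout; log odds at full double precision;
  winner comparisons use exact floating-point order, no tolerance.
* Frequency rounding is `%g`-style, ties to even, idempotent.
* Pairing ties break by (proband index, candidate index); results are
  invariant to sample-file permutation except exact ties at δ = 0, which
  follow the documented first-wins order.
* θ and δ comparisons are inclusive (≥); a single candidate has an
  implicit runner-up of −∞; a leader at −∞ never matches.

## Known limitations

* No forename/surname transposition handling, no continuous string
  distances (Bloom filters, edit distance), no bipartite one-to-one
  matching, no use of shared-postcode duration — all deliberately out of
  scope, matching the method being implemented.
* The Double Metaphone encoder is an original implementation of the
  published algorithm; it matches the published codes for the documented
  examples and standard test names, but obscure edge cases may differ
  from other implementations.  Both files in a linkage must therefore be
  prepared with this package (true of any fuzzy-hashing scheme).
* Frequency tables floored at f_min are not renormalized, so extremely
  long-tailed tables slightly overstate total probability mass.
* The pseudopostcode unit probability is a single pooled estimate for all
  unknown units; localities with many invalid postcodes may need a larger
  value.
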