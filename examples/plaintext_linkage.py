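"""Link a small plaintext proband file against a sample file.

Builds six people by hand — including a spelling discrepancy, a changed
postcode, and someone absent from the sample — scores every
proband-candidate pair by cumulative log likelihood ratio, and prints the
declared matches.  Positive leader log odds mean the leading candidate is
more likely than not the same person; a match needs log odds >= theta (5
by default) and a lead of >= delta over the runner-up.
"""

from dataclasses import replace
from datetime import date

import bayeslink as bl

model = bl.demo_frequency_model(total_population=10_000)
config = replace(bl.MatchConfig(), n_p=10_000, k_postcode=1.0)

probands = [
    bl.PersonRecord("A1", forenames=[bl.DatedValue("Stephen")],
                    surnames=[bl.DatedValue("Clarke")],
                    dob=date(1964, 3, 2), gender="M",
                    postcodes=[bl.DatedValue("CB10 AG")]),
    bl.PersonRecord("A2", forenames=[bl.DatedValue("Anna"), bl.DatedValue("Marie")],
                    surnames=[bl.DatedValue("Mozart-Smith")],
                    dob=date(1988, 11, 23), gender="F",
                    postcodes=[bl.DatedValue("PE30 1AB")]),
    bl.PersonRecord("A3", forenames=[bl.DatedValue("Rudolf")],
                    surnames=[bl.DatedValue("Taylor")],
                    dob=date(1975, 7, 14), gender="M"),
]
sample = [
    # Stephen recorded as Steven (same metaphone), same address
    bl.PersonRecord("B1", forenames=[bl.DatedValue("Steven")],
                    surnames=[bl.DatedValue("Clark")],
                    dob=date(1964, 3, 2), gender="M",
                    postcodes=[bl.DatedValue("CB10 AG")]),
    # Anna recorded under the component surname only, DOB day off by one
    bl.PersonRecord("B2", forenames=[bl.DatedValue("Anna"), bl.DatedValue("Marie")],
                    surnames=[bl.DatedValue("Smith")],
                    dob=date(1988, 11, 24), gender="F",
                    postcodes=[bl.DatedValue("PE30 1AB")]),
    # an unrelated person sharing Rudolf's DOB
    bl.PersonRecord("B3", forenames=[bl.DatedValue("George")],
                    surnames=[bl.DatedValue("Hill")],
                    dob=date(1975, 7, 14), gender="M"),
]

results = bl.link_datasets(probands, sample, config, model=model)
print(f"theta={config.theta}, delta={config.delta}, "
      f"prior log odds={bl.prior_log_odds(config.n_p):+.2f}\n")
for r in results:
    leader = "-inf" if r.leader_log_odds == bl.NEG_INF else f"{r.leader_log_odds:+.2f}"
    print(f"proband {r.proband_local_id}: match={r.match_local_id or 'none':5s} "
          f"leader={r.leader_local_id} log_odds={leader} basis={r.basis}")
print("\nA1 and A2 link despite fuzzy-tier discrepancies; A3's only "
      "DOB-compatible candidate has the wrong name, so no match is declared.")
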