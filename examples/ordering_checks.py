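"""Check that tier LLRs follow the intuitive none <= partial <= full order.

Not guaranteed: a name whose metaphone is rarely produced by *other* names
can make a phonetic match stronger evidence than an exact match, and a
very common first-two-characters tier can be weaker evidence than an
outright mismatch.  Two real-name parameter sets demonstrate both
inversions; the DOB comparison at default settings is well ordered.
"""

from bayeslink import check_comparison_ordering, dob_probabilities
from bayeslink.comparison import FourStateParams, ThreeStateParams

james = FourStateParams(p_ep1=0.0084, p_ep2np1=0.00688, p_en=0.00625,
                        p_f=0.0295, p_p1nf=0.000133, p_p2np1=0.01)
allen = FourStateParams(p_ep1=0.00510, p_ep2np1=0.00314, p_en=0.0355,
                        p_f=0.0028, p_p1nf=0.0002, p_p2np1=0.110)
p_f, p_pnf, _ = dob_probabilities(30.0)
dob = ThreeStateParams(p_ep=0.00459, p_en=0.0, p_f=p_f, p_pnf=p_pnf)

for label, params in [("male forename JAMES", james),
                      ("surname ALLEN", allen),
                      ("DOB at defaults", dob)]:
    warnings = check_comparison_ordering(params, label=label)
    if warnings:
        for warning in warnings:
            print("WARN", warning)
    else:
        print(f"ok   {label}: tiers well ordered")

print("\nJAMES: almost nothing but JAMES maps to metaphone JMS, so a "
      "metaphone-not-name match (e.g. JAIMES) outweighs an exact match.")
print("ALLEN: many names start 'AL', so an AL-only match is weaker evidence "
      "than a complete mismatch.")
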