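"""De-identified linkage: identical decisions without any plaintext.

Generates a synthetic population, injects realistic identifier errors into
the two copies of each overlapping person, hashes both files with a shared
secret key (HMAC-MD5 digests of every identifier and fuzzy tier, with
rounded population frequencies attached on the proband side), and shows
that linking the hashed files reproduces the plaintext decisions exactly.
"""

from dataclasses import replace

import bayeslink as bl

n = 1500
model = bl.demo_frequency_model(total_population=n)
config = replace(bl.MatchConfig(), n_p=n, k_postcode=1.0)

population = bl.generate_population(n, model, config, seed=7)
probands, sample, truth = bl.derive_sample_with_errors(
    population, overlap_fraction=0.5, profile=bl.ErrorProfile(),
    model=model, seed=8)

plain = bl.link_datasets(probands, sample, config, model=model)

spec = bl.HashSpec(algorithm="HMAC-MD5", identifier_key="shared-secret-key")
hashed_probands = bl.hash_file(probands, spec, config, model=model, mode="proband")
hashed_sample = bl.hash_file(sample, spec, config, model=model, mode="sample")
hashed = bl.link_datasets(hashed_probands, hashed_sample, config)

example = hashed_probands[0].forenames[0]
print("a hashed forename entry (digests + rounded frequencies):")
print(f"  name={example.name[:12]}... metaphone={example.metaphone[:12]}... "
      f"f2c={example.f2c[:12]}...")
print(f"  frequencies: name={example.name_freq} metaphone={example.metaphone_freq} "
      f"f2c={example.f2c_freq}\n")

agree = sum(1 for p, h in zip(plain, hashed)
            if p.match_local_id == h.match_local_id)
counts = bl.classify_outcomes(hashed, truth)
print(f"decisions identical in {agree}/{len(plain)} probands")
print(f"hashed-mode accuracy: TPR={counts.tpr:.3f} MID={counts.mid:.5f}")
print("\nEqual digests mean equal plaintext, and the proband file carries the "
      "frequencies, so the Bayesian update is unchanged by hashing.")
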