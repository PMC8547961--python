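"""Build a covariate-balanced cohort by optimal matching.

Simulates a confounded cohort (cases older, heavier and more often male
than the reference pool), then matches 1:1 with Mahalanobis distance inside
propensity-score calipers and prints the standardized mean differences
before and after.
"""

from oncospectra import SimConfig, generate_cohort, match_cohort

cfg = SimConfig(n_cases=100, n_refs=200, seed=3,
                age_shift=5.0, bmi_shift=1.5,
                male_fraction_case=0.65, male_fraction_ref=0.45)
cohort, _ = generate_cohort(cfg)

match, balance = match_cohort(cohort.meta)
print(f"matched {len(match.pairs)} of {cfg.n_cases} cases "
      f"({len(match.unmatched)} outside the caliper of "
      f"{match.caliper:.3f} logits)")
print(balance.round(3))
print("-> |SMD| well below 0.1 after matching means the groups are "
      "clinically comparable on age, sex and BMI.")
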