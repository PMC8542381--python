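"""Simulate a calibrated synthetic cohort and run the full validation.

The generator reproduces the published marginal sign prevalences and
per-stratum case-fatality ratios of the 2-59-month validation cohort; the
pipeline then filters, scores, and reports discrimination exactly as an
external validation would.
"""

from pneumorisk import default_params, run_validation, simulate_cohort

params = default_params("risc_malawi_waz", seed=1)   # published n = 17 864
cohort = simulate_cohort(params)
print(f"simulated {len(cohort)} children, "
      f"{sum(r.died for r in cohort)} deaths "
      f"(CFR {100 * sum(r.died for r in cohort) / len(cohort):.1f}%)")

report = run_validation(cohort, ["risc_malawi_waz"], seed=1)
sr = report.per_score["risc_malawi_waz"]

e = sr.eligibility
print(f"eligible {e.n_eligible}/{e.n_input} "
      f"({e.n_excluded_age} excluded by age, {e.n_excluded_missing} missing)")
print(f"AUC {sr.auc.auc:.2f} (95% CI {sr.auc.ci_low:.2f}-{sr.auc.ci_high:.2f})"
      f" -> {sr.label} discrimination")
print(f"recommended cut-points (sens 60-80%, spec >= 40%): "
      f"{sr.recommended_cutpoints}")
for c in sr.recommended_cutpoints:
    row = next(r for r in sr.cutpoints.rows if r.cutpoint == c)
    print(f"  score >= {c}: sensitivity {row.sensitivity.pct:.1f}%, "
          f"specificity {row.specificity.pct:.1f}%, "
          f"LR+ {row.lr_pos.value:.2f}, LR- {row.lr_neg.value:.2f}")
print("\nA cut-point flags a child as high risk when their score is at or "
      "above it; the listed\ncut-points balance catching most deaths "
      "against not flagging most survivors.")
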