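"""Risk predictiveness curve: how mortality risk concentrates in the cohort.

The curve plots each child's predicted risk (the empirical CFR at their
exact score) against the cumulative fraction of the population, sorted by
risk.  A flat curve means the score does not separate risk; a late, steep
rise means most deaths concentrate in a small high-scoring group.
"""

from pneumorisk import (
    default_params, filter_eligible, get_spec, predictiveness_curve,
    score_cohort, simulate_cohort,
)

cohort = simulate_cohort(default_params("risc_malawi_waz", n=8000, seed=3))
eligible, _ = filter_eligible(cohort, get_spec("risc_malawi_waz"))
totals = [r.total for r in score_cohort(eligible, "risc_malawi_waz")]
outcomes = [r.died for r in eligible]

curve = predictiveness_curve(totals, outcomes)
print(f"overall cohort risk: {100 * curve.overall_risk:.1f}%")
print("cumulative fraction -> predicted risk")
for frac, risk in curve.points:
    bar = "#" * round(60 * risk)
    print(f"  {frac:6.1%}  {100 * risk:5.1f}%  {bar}")
print(f"\nfraction-weighted mean of the curve = {100 * curve.mean_risk():.2f}%"
      " (equals the overall risk by construction)")
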