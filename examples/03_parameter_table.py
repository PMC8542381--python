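"""Build the per-parameter summary table (n, %, deaths, CFR with 95% CI).

This is the classic descriptive table of an external validation: for each
score parameter, how many children had the finding and what fraction of
them died.  Strata overlap — a child appears in every row it satisfies.
"""

from pneumorisk import (
    build_parameter_table, default_params, filter_eligible, get_spec,
    simulate_cohort,
)
from pneumorisk.metrics import format_parameter_table

spec = get_spec("risc_hiv_negative")
cohort = simulate_cohort(default_params("risc_hiv_negative", seed=7))
eligible, _ = filter_eligible(cohort, spec)

table = format_parameter_table(build_parameter_table(eligible, spec))
print(table.to_string(index=False))
print("\ncfr_pct is deaths/n within the stratum; the interval is the exact "
      "(Clopper-Pearson)\n95% CI. The Total row is the whole eligible cohort.")
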