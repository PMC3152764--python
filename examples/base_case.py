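"""The base case: screen a cohort once at 70 and treat on a positive.

Runs the paired no-screening/screening microsimulation (common random
numbers) at a desk-scale cohort of 20,000 and prints the per-1000 comparison
table plus the number-needed-to-screen/treat.  The full-scale published
figures use 100,000 patients; at 20,000 expect a few percent of Monte Carlo
wobble.
"""

from adscreensim import SimulationConfig, comparison_table, simulate_cohort
from adscreensim.outcomes import compare_result

config = SimulationConfig(cohort_size=20_000, seed=1)
result = simulate_cohort(config)
cmp = compare_result(result)

print(comparison_table(cmp).to_string(index=False))
print(
    f"\nComplete avoiders took {cmp.avoider_share:.0%} of the incremental AD-free years; "
    f"the rest went to patients whose onset was delayed but still occurred."
)

# Reading: screening trades ~2,600 person-years of preventive therapy per
# 1000 screened for ~20 avoided AD cases and ~150 extra AD-free years; about
# 51 people must be screened (12 treated) to avoid one case.
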