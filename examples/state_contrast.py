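"""Discriminate epileptogenic states by median nodal strength.

Simulates a cohort whose network coupling follows the epileptogenic
hierarchy (ictal > post-ictal > interictal-with-spikes > pre-ictal >
interictal-without-spikes) and tests all state pairs with the paired
Wilcoxon signed-rank test, FDR-corrected across the band x pair family.
"""

from ictalgraph import cohort_strengths, simulate_cohort, state_study_spec
from ictalgraph.states import compare_states

cohort = simulate_cohort(
    n_good=10, n_poor=0, template=state_study_spec(n_channels=12), rng_seed=3
)
table = cohort_strengths(cohort, measures=("AEC",))
results = compare_states(table, "AEC")

print("ictal vs pre-ictal, AEC nodal strength (n=10 patients):")
for r in results:
    if r.state_a == "ictal" and r.state_b == "pre_ictal":
        mark = "*" if r.p_fdr < 0.05 else " "
        print(
            f"  {r.band:10s} diff={r.percent_difference:+6.1f}%  "
            f"p_raw={r.p_raw:.4f}  p_fdr={r.p_fdr:.4f} {mark}"
        )
print()
print("A positive difference with FDR p < 0.05 (*) recovers the planted rise")
print("of network synchronization from the pre-ictal to the ictal state.")
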