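"""Plant epileptogenic hubs in a synthetic cohort and recover them by ROC.

Simulates a small good-outcome cohort in which 6 of 20 contacts form a
strongly coupled hub set lying inside the resection, computes AEC/oAEC/PLV
nodal strength for the ictal state, and asks how well strength separates
resected (epileptogenic) from non-resected contacts.
"""

from ictalgraph import cohort_strengths, hub_study_spec, simulate_cohort
from ictalgraph.nodes import classify_nodes

cohort = simulate_cohort(
    n_good=4, n_poor=0, template=hub_study_spec(n_channels=20, n_hubs=6),
    rng_seed=7, states=("ictal",),
)
table = cohort_strengths(cohort, states=("ictal",))
rocs = classify_nodes(table)

print("best ictal-band ROC per connectivity measure (pooled electrodes):")
for measure in ("AEC", "oAEC", "PLV"):
    best = max(
        (r for (m, _, _), r in rocs.items() if m == measure), key=lambda r: r.auc
    )
    print(
        f"  {measure:5s} band={best.band:10s} AUC={best.auc:.3f} "
        f"max Youden J={best.youden_j_max:.2f} at threshold {best.optimal_threshold:.1f}"
    )
print()
print("AUC near 1 means normalized nodal strength almost perfectly ranks the")
print("planted (resected) hub contacts above the rest; the max-J threshold is")
print("the operating point later used to define hubs for outcome prediction.")
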