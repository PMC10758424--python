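"""Edge-wise group comparison: find the connection that differs.

Simulates control and patient cohorts whose generating models differ in a
single edge weight, estimates each subject's connectome, and ranks edges
by the one-sided Welch t-test p-value for greater patient weight — the
boosted edge should top the table.
"""

from causalfc import (
    SubjectCFCSet,
    TPCParams,
    edge_density,
    edgewise_comparison,
    make_ground_truth,
    run_tpc,
    simulate_cohort,
    top_k_edges,
)

model = make_ground_truth(
    8, 0.08, contemp_fraction=0.25, seed=5,
    group_deltas={"patient": ((0, 1, 0.3),)},
)
cohort = simulate_cohort(
    model, {"control": 15, "patient": 15}, n_timepoints=600, seed=5
)

entries = []
for sid, group, ts in cohort.subjects:
    cfc = run_tpc(ts, TPCParams(tau=1, alpha_ci=0.001))
    entries.append((sid, group, cfc))
cfcs = SubjectCFCSet(tuple(entries))

dens = [edge_density(cfc) for _, _, cfc in entries]
print(f"mean CFC edge density: {sum(dens) / len(dens):.4f} (sparse by design)")

table = edgewise_comparison(cfcs, "control", "patient", direction="g2>g1")
print("\ntop 10 edges, patient > control (ascending one-sided p):")
print(top_k_edges(table, 10).to_string(index=False))

lab = model.region_labels
boosted = (lab[0], lab[1])
first = (table.iloc[0]["source"], table.iloc[0]["target"])
print(f"\nboosted edge {boosted[0]} -> {boosted[1]} "
      f"{'ranks first' if first == boosted else f'ranked behind {first}'}")
# The p column is exploratory (no multiple-testing correction); the point
# is the ranking, not a significance claim.
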