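"""Classify diet-responsive promoter interactions: rewired vs preformed.

The two-category model: (1) rewired interactions whose contact frequency
itself changes between conditions (exact NB test, p < 0.001); (2) preformed
interactions whose contacts are stable but whose distal end carries a
differential acetylation peak — the enhancer activates inside a pre-existing
loop.  Everything else is static.
"""

import pandas as pd

import chromdyn as cd

truth = cd.make_genome(cd.SimulationConfig(seed=1))
cap = cd.simulate_capture(truth)
truth = cd.simulate_peaks_expression_cage(truth)
for cond in ("A", "B"):
    cap[f"count_{cond}"] = cap[f"count_{cond}1"] + cap[f"count_{cond}2"]
sig = (
    cd.score_capture_interactions(cap, truth.fragments, count_col="count_A")["significant"]
    | cd.score_capture_interactions(cap, truth.fragments, count_col="count_B")["significant"]
)
called = cap[sig.to_numpy()].reset_index(drop=True)

idiff = cd.nb_count_test(
    called[["count_A1", "count_A2", "count_B1", "count_B2"]].to_numpy(),
    ["A", "A", "B", "B"], kind="interaction",
    unit_ids=called["unit_id"].to_numpy(),
)
ac = truth.acetyl_peaks
pdiff = cd.nb_count_test(
    ac[[f"count_{c}{r}" for c in ("A", "B") for r in (1, 2, 3)]].to_numpy(),
    ["A"] * 3 + ["B"] * 3, kind="peak", unit_ids=ac["peak_id"].to_numpy(),
).merge(ac[["peak_id", "chrom", "start", "end"]],
        left_on="unit_id", right_on="peak_id")

records = cd.classify_loop_dynamics(called, idiff, pdiff, truth.fragments)
print("class counts:")
print(records["loop_class"].value_counts().to_string())
planted = records[records["true_class"] != "background"]
acc = (planted["loop_class"] == planted["true_class"]).mean()
print(f"\nagreement with planted labels: {100 * acc:.1f}%")

genes = cd.link_dynamics_to_genes(records)
print(f"genes linked to a dynamic loop class: "
      f"{genes[genes['loop_class'] != 'static']['gene_id'].nunique()}")
# Rewired interactions change contact frequency (p < 0.001); preformed ones
# keep stable contacts but gain or lose acetylation at the distal enhancer;
# the linkage table maps each class back to the bait gene.
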