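"""Fold-change DEP detection and reproducibility frequency across experiments.

24 experiments are simulated on one shared ground truth containing a single
always-differential protein. Per experiment, proteins with a replicate-mean
fold change strictly above 2 between any group pair are recorded; their
occurrence frequency over the 24 experiments is binned into low (1-9),
medium (10-18) and high (19-24) reproducibility, and records reproduced in
every experiment with a consistent direction are reported.
"""

import proteoqc as pq

config = pq.SimulationConfig(
    n_proteins=400, dep_fraction=1 / 400, specific_fraction=0.0,
    dep_fc_log2_range=(3.0, 3.5),
    cv_profile={"low": 0.25, "medium": 0.2, "high": 0.15},
    detection_midpoint_log10=-float("inf"), seed=5)

truth, records = None, []
for e in range(24):
    matrix, metadata, truth = pq.simulate_experiment(
        config, experiment_seed=100 + e, experiment_id=f"E{e + 1}",
        truth=truth)
    records.extend(pq.detect_deps(pq.ibaq_to_fot(matrix), metadata,
                                  experiment_id=f"E{e + 1}"))

table = pq.dep_reproducibility(records, 24)
print("frequency bins at E=24:", pq.frequency_bins(24))
print("records per bin:", table["bin"].value_counts().to_dict())

hits = pq.consistent_trend_deps(table, 24)
planted = truth.dep_flags["protein_id"].iloc[0]
print(f"consistent-trend proteins: {sorted(set(hits['protein_id']))} "
      f"(planted: {planted})")
print("a protein recovered in all 24 experiments with one direction is a "
      "benchmark-grade differential indicator")
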