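#!/usr/bin/env python
"""Microarray screen: detection filter, differential expression, clustering.

Runs the background-tagging / mean+2SD threshold / 80%-of-animals detection
chain on the simulated two-group matrix from 01, tests retained probes with
the pooled-variance Student's t at p <= 0.05, ranks absolute differences
and fold changes, and clusters samples by UPGMA on 1 - Spearman correlation.
"""

from dcquant import expression, io

DATA, OUT = "results/data", "results"

m = io.read_expression_matrix(f"{DATA}/expression_matrix.tsv",
                              f"{DATA}/expression_groups.tsv")
truth = io.read_json(f"{DATA}/expression_matrix.truth.json")

det = expression.detect(m)
n_true = len(truth["params"]["expressed_probe_ids"])
overlap = len(set(det.retained_probes) & set(truth["params"]["expressed_probe_ids"]))
print(f"detection filter: {len(det.retained_probes)} / {m.values.shape[0]} "
      f"probes retained ({overlap}/{n_true} planted expressed probes recovered)")

de = expression.differential_expression(m, det.retained_probes, alpha=0.05)
io.write_table(de, f"{OUT}/differential_expression.tsv")
true_de = set(truth["params"]["de_probe_ids"])
hit = len(true_de & set(de["probe_id"]))
print(f"differential expression: {len(de)} probes at p <= 0.05 "
      f"({hit}/{len(true_de)} planted 4-fold changes recovered)")

report = expression.expression_report(m, det, de)
io.write_table(report["by_absolute_difference"].head(50),
               f"{OUT}/top_absolute_differences.tsv")
io.write_table(report["by_fold_change"].head(50), f"{OUT}/top_fold_changes.tsv")
top = report["by_fold_change"].iloc[0]
print(f"largest fold change: {top['probe_id']} "
      f"({top['fold_change']:.2f}x, {top['direction']})")

dendro = expression.cluster_samples(m, det.retained_probes)
with open(f"{OUT}/sample_tree.nwk", "w") as fh:
    fh.write(dendro.newick + "\n")
final_groups = {dendro.merges[-1][0], dendro.merges[-1][1]}
print(f"clustering: last merge joins clusters led by {sorted(final_groups)} "
      f"at height {dendro.merges[-1][2]:.3f} -> {OUT}/sample_tree.nwk")
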