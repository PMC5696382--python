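#!/usr/bin/env python
"""Phagosome maturation scoring: fusion, ROS, pH, degradation, export.

Scores the five assay tables from 01 with their respective indices and
writes tidy per-object and summary outputs.
"""

from dcquant import assays, io

DATA, OUT = "results/data", "results"

fusion = io.read_table(f"{DATA}/assay_fusion.tsv", "fusion_objects")
per_obj, fusion_mean = assays.pl_fusion_index(fusion)
io.write_table(per_obj, f"{OUT}/fusion_indices.tsv")
print(f"P-L fusion index: mean {fusion_mean:.0f} over {len(per_obj)} phagosomes")

ros = io.read_table(f"{DATA}/assay_ros.tsv", "ros_objects")
_, ros_mean = assays.phagosomal_ros_index(ros)
print(f"phagosomal ROS index: mean {ros_mean:.2f}")

stacks = io.read_table(f"{DATA}/assay_ph_calibration.tsv", "ph_calibration")
calib = assays.fit_ratio_ph_calibration(stacks)
io.write_json(
    {"bottom": calib.bottom, "top": calib.top, "ph50": calib.ph50,
     "slope": calib.slope, "levels": calib.levels.tolist(),
     "mean_ratios": calib.mean_ratios.tolist()},
    f"{OUT}/ph_calibration.json",
)
probe_ratio = float(calib.predict(5.5))
print(f"pH calibration: pH50 {calib.ph50:.2f}; a phagosome at ratio "
      f"{probe_ratio:.3f} reads pH {assays.ratio_to_ph(probe_ratio, calib):.2f}")

deg = io.read_table(f"{DATA}/assay_degradation.tsv", "mfi_series")
t0 = float(deg.loc[deg["chase_min"].idxmin(), "mfi"])
table = assays.ova_degradation_percent(deg["chase_min"], deg["mfi"], t0)
io.write_table(table, f"{OUT}/ova_degradation.tsv")
last = table.iloc[-1]
print(f"OVA degradation: {last['degraded_percent']:.0f}% by "
      f"{last['chase_min']:.0f} min chase (t0 reference = pulse-only MFI)")

cells = io.read_table(f"{DATA}/assay_export.tsv", "export_cells")
pct, thr = assays.cytosol_export_percent(cells, control_quantile=0.99)
io.write_json({"export_percent": pct, "threshold": thr,
               "control_quantile": 0.99}, f"{OUT}/cytosol_export.json")
print(f"antigen export to cytosol: {pct:.1f}% of treated cells above the "
      f"99th-percentile control score ({thr:.3f})")
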