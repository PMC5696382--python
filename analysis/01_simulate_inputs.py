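#!/usr/bin/env python
"""Generate every synthetic input the analyses consume, with truth sidecars.

Writes per-cell three-cube FRET intensities, a FRET time course, paired
TG/control plate-reader calcium traces, a ratio image with phagosome masks,
the five phagosome assay tables, and a two-group microarray matrix into
results/data/, each with its ground-truth JSON next to it.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dcquant import io, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)


def save(name, table, truth):
    io.write_table(table, OUT / f"{name}.tsv")
    io.write_json(truth.to_dict(), OUT / f"{name}.truth.json")


cells, truth = synthetic.gen_three_cube_dataset(
    true_e=0.25, a=0.1, d=0.3, g=2.0, n_cells=85, noise_sd=0.01, seed=SEED
)
save("fret_cells", cells, truth)

pre, post, truth = synthetic.gen_photobleach_pair(
    0.25, 0.1, 0.3, 2.0, n_cells=85, noise_sd=0.01, seed=SEED + 1
)
save("fret_bleach_pre", pre, truth)
io.write_table(post, OUT / "fret_bleach_post.tsv")

trace, truth = synthetic.gen_fret_timecourse(
    bottom=1.0, top=1.4, v50=120.0, slope=30.0, noise_sd=0.02, seed=SEED + 2
)
save("fret_trace",
     pd.DataFrame({"time_s": trace.times, "efficiency": trace.values}), truth)

for name, kwargs in [
    ("calcium_tg", dict(er_release_amp=80.0, influx_amp=300.0, with_tg=True)),
    ("calcium_control", dict(er_release_amp=0.0, influx_amp=100.0, with_tg=False)),
]:
    tr, truth = synthetic.gen_calcium_plate(**kwargs, seed=SEED + 3, well_id=name)
    save(name, pd.DataFrame({"well_id": name, "time_s": tr.times, "F": tr.f}), truth)
    io.write_json(tr.events, OUT / f"{name}.events.json")

img, truth = synthetic.gen_ratio_image(
    shape=(64, 64), n_phagosomes=8, hotspot_fraction=0.5, seed=SEED + 4
)
np.savetxt(OUT / "ratio_image.txt", img.ratio, fmt="%.6g")
np.savetxt(OUT / "ratio_labels.txt", img.labels, fmt="%d")
io.write_json(truth.to_dict(), OUT / "ratio_image.truth.json")

for kind, params in [
    ("fusion", {"planted_index": 2000.0}),
    ("ros", {"planted_index": 1.5}),
    ("ph_calibration", {}),
    ("degradation", {}),
    ("export", {"n_positive": 30}),
]:
    table, truth = synthetic.gen_assay_objects(kind, params, seed=SEED + 5)
    save(f"assay_{kind}", table, truth)

matrix, truth = synthetic.gen_microarray(
    n_probes=2000, n_per_group=4, frac_expressed=0.8, fold=4.0, seed=SEED + 6
)
io.write_expression_matrix(matrix, OUT / "expression_matrix.tsv",
                           OUT / "expression_groups.tsv")
io.write_json(truth.to_dict(), OUT / "expression_matrix.truth.json")

print(f"wrote synthetic inputs (seed {SEED}) to {OUT}/")
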