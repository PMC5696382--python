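# dcquant

Quantification pipeline for the cell-biological readouts used to study
antigen cross-presentation in dendritic cells: how efficiently phagosomes
mature (fusion with lysosomes, reactive-oxygen production, luminal pH,
antigen degradation, antigen export to the cytosol), how store-operated
Ca²⁺ entry (SOCE) behaves, how fast the ER Ca²⁺ sensor STIM1 oligomerizes
after store depletion, and which genes separate mutant from wild-type
spleens on a two-group microarray. Every estimator is paired with a seeded
synthetic-data generator carrying its ground truth, so the whole chain is
testable without microscopes, plate readers, or array scanners.

## What it computes

**Three-cube E-FRET** (`dcquant.fret`). Apparent FRET efficiency from
donor/acceptor/FRET-channel intensities

    E = (I_DA − a·I_AA − d·I_DD) / (I_DA − a·I_AA + (G − d)·I_DD)

with bleed-through slopes *a* (I_DA on I_AA, acceptor-only cells) and *d*
(I_DA on I_DD, donor-only cells) from linear regression over ~85 cells, and
the G factor from complete acceptor photobleaching,
G = (Fc_pre − Fc_post)/(I_DD_post − I_DD_pre) with Fc = I_DA − a·I_AA − d·I_DD.
Time courses are normalized to the last minute of pre-stimulus baseline,
smoothed with a 2nd-order 4-neighbor (9-point local quadratic) filter, and
fitted to a Boltzmann sigmoid; **V50** is the time-to-half-maximum
efficiency — the oligomerization-speed readout.

**Calcium** (`dcquant.calcium`). Single-wavelength fluo-4 calibration
[Ca²⁺] = Kd·(F − Fmin)/(Fmax − F) with Kd = 345 nM and per-well Fmax from
digitonin; SOCE decomposition of paired thapsigargin (TG) / no-TG wells
(release AUC in Ca²⁺-free medium; total, constitutive and store-operated
entry after Ca²⁺ add-back); periphagosomal hotspot calling on
cytosol-normalized ratio images (mean ratio over a 2-px annulus ≥ 1.5).

**Phagosome indices** (`dcquant.assays`). P-L fusion index
((FRET/bead − basal)/HA_total × 10,000), phagosomal ROS index
(OxyBurst/Alexa-568 minus external-particle basal), intracellular ROS
(max / first-6-min baseline), ratiometric pH calibration (sigmoid over
pH 4.0–9.0 buffers, five stacks per level) and inversion, percent antigen
degradation (1 − MFI/MFI_t0), and percent cytosolic antigen export
(450/535 nm score above a control quantile).

**Microarray screen** (`dcquant.expression`). Per-array background = the
lowest 20% of probe intensities; detection threshold = background mean +
2 SD; a probe is analyzed if it exceeds the threshold in ≥ 80% of the
animals of ≥ 1 group; two-sided Student's t (pooled variance) filtered at
p ≤ 0.05; linear fold changes and absolute differences; UPGMA clustering
of samples on 1 − Spearman correlation with Newick export.

`dcquant.synthetic` generates all of the above inputs with planted truth;
`dcquant.io` holds the TSV/JSON schemas plus the ellipsoid tumor-volume
helper V = (4/3)·π·r1·r2·r3; `dcquant.pipeline` runs the full
simulate → analyze chain with materialized config and provenance.

## Worked example

The numbered scripts under `analysis/` run the whole study chain on
synthetic data (optionally pass a seed to `01`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fret_kinetics.py
python analysis/03_calcium_soce.py
python analysis/04_phagosome_indices.py
python analysis/05_expression_screen.py
```

With the default seed this prints:

```
bleed-through: a = 0.0999 (R2 0.9993, n=85), d = 0.2990 (R2 0.9994)
G factor (donor dequenching): 1.9925
double-labeled cells: mean E = 0.2512 (sd 0.0040, n=85)
Boltzmann fit: V50 = 119.0 s after stimulus, TOP = 1.397 (fold of baseline)
ER release (AUC under TG response): 6000 a.u.*s
total entry 300 - constitutive 100 = SOCE 200 a.u.
periphagosomal hotspots: 50% of 8 phagosomes (threshold 1.5x cytosol, 2 px annulus)
P-L fusion index: mean 2000 over 20 phagosomes
OVA degradation: 80% by 240 min chase (t0 reference = pulse-only MFI)
antigen export to cytosol: 30.0% of treated cells above the 99th-percentile control score (0.164)
detection filter: 1600 / 2000 probes retained (1600/1600 planted expressed probes recovered)
differential expression: 219 probes at p <= 0.05 (160/160 planted 4-fold changes recovered)
```

The planted truths were a = 0.1, d = 0.3, G = 2.0, E = 0.25, V50 = 120 s,
release AUC 6000, SOCE 200, 50% hotspots, fusion index 2000, 30% export,
1600 expressed and 160 differentially expressed probes — each estimator
recovers its generator's truth at the simulated noise levels. A `dcquant`
CLI exposes the same operations (`dcquant fret fit-v50 …`,
`dcquant calcium soce …`, `dcquant array de …`, `dcquant volume 10 8 6`).

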