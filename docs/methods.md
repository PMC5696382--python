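# Methods

This note records the models implemented in `dcquant`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the procedure descriptions left the design
open.

## Three-cube E-FRET

The apparent-efficiency estimator corrects the FRET-channel signal I_DA
for acceptor bleed-through (a·I_AA) and donor bleed-through (d·I_DD), and
converts the remaining sensitized emission Fc = I_DA − a·I_AA − d·I_DD to
an efficiency using the instrument factor G:

E = Fc / (Fc + G·I_DD).

Assumptions: intensities are background-subtracted, bleed-through is
linear in the respective single-label channel, and G is constant across
cells for a fixed optical configuration.

* **Bleed-through regression orientation.** The protocol phrase
  "I_AA vs. I_DA" is implemented as I_DA regressed on I_AA (and I_DD for
  d): that is the only orientation in which the slope carries the units of
  a bleed-through coefficient that multiplies I_AA in the efficiency
  formula. Diagnostics (R², n, slope standard error) are returned with
  each estimate.
* **G-factor denominator.** The standard donor-dequenching form
  (I_DD_post − I_DD_pre) is the default. Some write-ups transcribe the
  denominator as (I_DA_post − I_DD_pre); that variant is kept behind
  `denominator_mode="as_printed"` rather than silently corrected, because
  the two give different (even opposite-signed) values and a user
  comparing against legacy numbers needs both. G is pooled over cells as
  a ratio of sums, weighting cells by their dequenching. Bleach
  completeness is checked (default: residual acceptor < 5% of pre-bleach)
  and violations warn rather than abort, since a biased G is diagnosable
  while a hard failure is not.
* **Trace conditioning.** Normalization is division by the mean over the
  last 60 s before the stimulus (baseline → 1), matching fold-style FRET
  traces; at the 12-s frame interval that window holds 5 frames.
  "2nd-order, 4-neighbor" smoothing is a 9-point moving local quadratic
  least-squares fit evaluated at the window center — the Savitzky–Golay
  idea, but with shrunken one-sided windows at the edges so the trace
  keeps its length and any exact quadratic (hence any constant) passes
  through unchanged. A uniform grid is required (checked to 1e-6
  relative).
* **Boltzmann fit.** f(t) = bottom + (top − bottom)/(1 + exp((v50 − t)/slope)),
  t measured from the stimulus. Five deterministic starts with v50 at the
  20/35/50/65/80% quantiles of the post-stimulus window; parameter
  tolerance 1e-10; negative-slope solutions are mapped to the equivalent
  canonical curve (plateaus swapped); inverted fits (top < bottom) are
  rejected. V50 is reported on the post-stimulus clock. TOP is reported on
  whichever scale the input trace is on; the CLI emits both the
  normalized TOP and its product with the raw baseline, since which of
  the two a legacy report means is ambiguous.

## Calcium

[Ca²⁺] = Kd·(F − Fmin)/(Fmax − F), Kd = 345 nM for fluo-4. Fmax is the
per-well maximum after digitonin permeabilization; Fmin is the dye-free
well at matched cell density. F ≥ Fmax is a saturation error; F < Fmin
clamps to 0 nM with a warning.

SOCE decomposition assumes the standard protocol ordering
TG (Ca²⁺-free) → Ca²⁺ add-back → digitonin. The release AUC is the
trapezoidal area of (F − pre-TG baseline) over [tg_add, ca_add), with
negative excursions truncated at zero (release is a magnitude); samples
at or after the add-back are excluded because they already reflect entry.
Entry amplitudes are peak-minus-immediately-pre-add, the peak sought in a
configurable 120-s window after add-back — peak rather than plateau mean
because entry transients decay under extrusion. SOCE = total −
constitutive exactly, by construction. Adding a constant to a whole trace
changes nothing (everything is baseline-referenced).

Hotspot calling: a phagosome is a hotspot iff the mean cytosol-normalized
ratio over its periphagosomal annulus (mask dilated by `annulus_width`,
minus the mask, minus other phagosomes) is ≥ `threshold_ratio`. The
imaging protocol pins neither number, so both are explicit, mandatory
parameters echoed into every output (defaults 2 px and 1.5; at these
settings planted hotspots at ratio 3 on unit background are recovered
exactly). The comparison is ≥, so annuli exactly at threshold count.
Phagosomes whose annulus would leave the image are excluded from the
denominator with a warning naming them. Coordinates are row-major,
0-based; masks are explicit labeled pixels, never reconstructed from
centroids.

## Phagosome indices

* Fusion: basal = mean FRET/bead over external (uningested) beads; index =
  ((FRET/bead − basal)/HA_total) × 10,000; zero-bead objects are excluded
  with a warning. Invariant to rescaling both channels of every object.
* ROS: OxyBurst/Alexa-568 minus the external-particle mean ratio.
  Intracellular ROS: max over the course divided by the mean over the
  first 6 min, endpoints inclusive (with the 2-min cadence the baseline
  is t = 0, 2, 4, 6).
* pH: sigmoid ratio(pH) fitted on per-level mean ratios (replicate stacks
  are averaged, mirroring five-stack averaging; scatter kept as residual
  diagnostics). Non-monotone means abort with the offending level pairs
  named — a non-monotone standard curve cannot be inverted. The inverse
  is analytic; ratios outside the calibrated mean-ratio range are refused
  unless extrapolation is explicitly allowed. The same machinery serves
  endosomal dual-dextran calibration with user-supplied standards.
* Degradation: percent(t) = 100·(1 − MFI(t)/MFI_t0), clipped to [0, 100].
  The reference is the pulse-only (zero-chase) MFI — without a stated
  reference the percent is undefined, so the choice is configurable and
  recorded in output metadata.
* Export: per-cell score = 450 nm/(535 nm + 1e-9); threshold = the 0.99
  quantile of the probe-only control scores; the readout is the percent
  of treated cells above it. Scores are ratios rather than gated quadrant
  counts (flow gating is out of scope here). Under the null
  (treated ≡ control) the expected positive fraction is
  (1 − quantile)·100, which the tests verify by simulation.

## Microarray screen

Per array, exactly floor(0.20·n_probes) lowest-intensity probes are
tagged as background (stable ranking, ties broken by probe order);
threshold = tagged mean + 2·SD; a probe is analyzed if it strictly
exceeds the threshold in ≥ 80% of the animals of at least one group
(3/4 fails, 4/4 passes at the study's group size of four). "Standard
deviations" is read as the sample SD (n − 1): background sets are small
and that is the conventional reading; the population form is available
by flag. The t-test defaults to pooled variance ("Student's" as opposed
to Welch, which is available by flag), two-sided, df = n1 + n2 − 2,
filtered at raw p ≤ 0.05 with no multiple-testing correction — that is
the screening procedure being reproduced; FDR can be reported alongside
but never filters. Fold changes are linear-scale group2/group1 means,
computed on retained probes. Zero-variance probes are excluded with a
warning rather than given p = 0.

Clustering is UPGMA on 1 − Spearman rank correlation between sample
columns. The agglomeration is implemented in-package because the contract
here is a deterministic merge sequence: among equal-minimum pairs the
lexicographically smallest cluster-label pair merges first, and each
cluster is labeled by its lexicographically smallest member. Distance
updates use the size-weighted average-linkage recurrence, equivalent to
re-averaging all original pairwise distances (the tests check this
against both a brute-force re-averaging oracle and scipy's average
linkage). Trees serialize to Newick with each child's branch length equal
to parent merge height minus child merge height (leaves at height 0);
merge heights are cophenetic distances, not halved.

## Synthetic data

Generators are pure functions of (parameters, seed) — same seed, byte-
identical output — and each records a truth object sufficient to compute
the expected downstream estimate in closed form, asserted by round-trip
tests at zero noise.

Noise model: multiplicative Gaussian for intensities (fluorescence scales
with expression, and relative noise keeps ratio estimators unbiased at
low noise), additive Gaussian for efficiencies and ratios; intensities
are clipped at zero after noise, with clip counts warned. The acquisition
noise magnitudes are free parameters, not claims about real data;
defaults (1% channel noise for calibration populations, 0.02 additive on
efficiency traces) exercise the estimators in a regime where their
tolerances are meaningful.

Study-condition defaults baked into the generators: ~85 cells of
~10-fold-varying expression for bleed-through calibration; 12-s frames,
2 min baseline + 10 min post-stimulus for FRET time courses; two groups
of four arrays with up to 80% of probes truly expressed (the analysis
itself assumes at most 80% are expressed — and at exactly 80% the tagged
background coincides with the truly unexpressed set, the regime where
detection can be exact); five replicate stacks per pH buffer across
pH 4.0–9.0. The calcium generator shapes the TG transient as a sin²
pulse of 150 s so its area is exactly amp·75 s even under trapezoidal
integration on the sampling grid, giving a closed-form AUC truth.
Phagosome masks are disks and hotspot regions annuli of default width
2 px — the simplest geometry exercising annulus-based calling; there is
no point-spread function, photobleaching (beyond the G protocol), or
other photorealism, so passing tests certify the estimators' arithmetic
and statistical behavior, not robustness to real microscopy artifacts.
The export generator plants positives above, and negatives strictly
below, the whole control score range, so a planted positive count maps
exactly to the reported percentage.

## Problem sizes

The default test and analysis runs use 2,000-probe matrices (12,500 for
the null-calibration check, so ≥ 10,000 probes survive detection),
50-trace V50 ensembles, 200-rep export null simulations at 1,000 cells
per arm, and 100 random 6-sample matrices for the clustering oracle —
sizes at which every stochastic tolerance in the tests is comfortably
resolved while the full suite stays fast.

## Known limitations

Single-cell tracking/registration, pixel-level FRET, spectral unmixing,
array normalization, probe-to-gene annotation and pathway analysis are
out of scope; masks and per-object tables are inputs, not products of
segmentation. The hotspot threshold and annulus width, the degradation
reference, and the G denominator mode are explicit decisions surfaced as
parameters rather than recovered facts; conclusions that depend on them
should cite the configured values, which every output echoes.

## Tumor volume

V = (4/3)·π·r1·r2·r3 over semi-axes. Caliper length/width/depth are
treated as diameters and halved by default (the formula needs radii);
`measures_are_radii` disables halving for data already recorded as
semi-axes, since practice varies and the two differ by 8×.
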