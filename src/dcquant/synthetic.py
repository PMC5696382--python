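"""Synthetic-data generators with embedded ground truth.

Every generator is a pure function of its parameters and a seed, emulating
the study's raw inputs — per-cell three-cube FRET intensities, plate-reader
calcium traces, per-phagosome assay object tables, cytosol-normalized ratio
images with phagosome masks, and two-group microarray intensity matrices —
so the downstream estimators can be exercised and validated without any
microscopy or array data.

Noise conventions: fluorescence intensities receive multiplicative Gaussian
noise (fluorescence scales with expression level, so relative noise keeps
ratio estimators unbiased at low noise) and are clipped at zero afterwards;
efficiencies and ratios receive additive Gaussian noise. At ``noise_sd = 0``
every generated dataset maps exactly (closed form) onto the expected output
of its downstream estimator, which is what the round-trip tests assert.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    CalciumTrace,
    DomainError,
    FretTrace,
    RatioImage,
    SyntheticTruth,
)

__all__ = [
    "gen_three_cube_dataset",
    "gen_photobleach_pair",
    "gen_fret_timecourse",
    "gen_calcium_plate",
    "gen_microarray",
    "gen_ratio_image",
    "gen_assay_objects",
]

# duration of the synthetic store-release transient (sin^2 pulse), seconds;
# trapezoidal AUC of the pulse on a commensurate grid is exactly amp * width/2
TG_PULSE_WIDTH_S = 150.0


def _mult_noise(rng: np.random.Generator, arr: np.ndarray, sd: float) -> np.ndarray:
    """Multiplicative Gaussian noise, clipped at 0; clip count logged via warning."""
    if sd == 0:
        return arr
    noisy = arr * (1.0 + rng.normal(0.0, sd, size=arr.shape))
    n_clip = int(np.sum(noisy < 0))
    if n_clip:
        warnings.warn(f"{n_clip} intensity values clipped at 0 after noise")
    return np.clip(noisy, 0.0, None)


def gen_three_cube_dataset(
    true_e: float,
    a: float,
    d: float,
    g: float,
    n_cells: int = 85,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate per-cell three-cube intensities for the E-FRET calibration.

    Emits three cell classes mirroring the calibration protocol: donor-only
    cells (acceptor bleed-through absent), acceptor-only cells, and
    double-labeled cells carrying the planted FRET efficiency ``true_e``.
    Cells span an order of magnitude of expression ("varying expression
    levels"), which gives the bleed-through regressions leverage.

    For double-labeled cells, before noise::

        S    = G * I_DD * E / (1 - E)          (sensitized emission)
        I_DA = a * I_AA + d * I_DD + S

    so the E-FRET estimator recovers ``true_e`` exactly at zero noise.
    """
    if not (0 <= true_e < 1) or not np.isfinite(true_e):
        raise DomainError(f"true_e must be in [0, 1), got {true_e}")
    if a < 0 or d < 0 or g <= 0 or not all(map(np.isfinite, (a, d, g))):
        raise DomainError("require a, d >= 0 and G > 0, all finite")
    if n_cells < 3:
        raise DomainError("n_cells >= 3 required per cell class")
    rng = np.random.default_rng(seed)

    rows = []
    for label in ("donor_only", "acceptor_only", "double"):
        # log-uniform expression spread, ~10x range
        expr = 10 ** rng.uniform(1.5, 2.5, size=n_cells)
        if label == "donor_only":
            idd = expr
            iaa = np.zeros(n_cells)
            ida = d * idd
        elif label == "acceptor_only":
            idd = np.zeros(n_cells)
            iaa = expr
            ida = a * iaa
        else:
            idd = expr
            iaa = expr * rng.uniform(0.5, 1.5, size=n_cells)
            s = g * idd * true_e / (1.0 - true_e)
            ida = a * iaa + d * idd + s
        idd = _mult_noise(rng, idd, noise_sd)
        iaa = _mult_noise(rng, iaa, noise_sd)
        ida = _mult_noise(rng, ida, noise_sd)
        for i in range(n_cells):
            rows.append(
                {
                    "cell_id": f"{label}_{i:03d}",
                    "I_DD": idd[i],
                    "I_AA": iaa[i],
                    "I_DA": ida[i],
                    "label": label,
                }
            )
    table = pd.DataFrame(rows, columns=["cell_id", "I_DD", "I_AA", "I_DA", "label"])
    truth = SyntheticTruth(
        "gen_three_cube_dataset",
        seed,
        {"true_E": true_e, "true_a": a, "true_d": d, "true_G": g,
         "n_cells": n_cells, "noise_sd": noise_sd},
    )
    return table, truth


def gen_photobleach_pair(
    true_e: float,
    a: float,
    d: float,
    g: float,
    n_cells: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    residual_acceptor: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate complete acceptor photobleaching for G-factor estimation.

    Pre-bleach cells are double-labeled with planted efficiency ``true_e``.
    After a complete bleach the sensitized emission vanishes, the acceptor
    channel drops to ``residual_acceptor`` of its pre-bleach value, and the
    donor dequenches fully: I_DD_post = I_DD_pre / (1 - E). With that
    construction (Fc_pre - Fc_post)/(I_DD_post - I_DD_pre) = G exactly.
    """
    pre, _ = gen_three_cube_dataset(true_e, a, d, g, n_cells, 0.0, seed)
    pre = pre[pre["label"] == "double"].reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])

    idd_post = pre["I_DD"].to_numpy() / (1.0 - true_e)
    iaa_post = pre["I_AA"].to_numpy() * residual_acceptor
    ida_post = a * iaa_post + d * idd_post  # no sensitized emission left
    post = pd.DataFrame(
        {
            "cell_id": pre["cell_id"],
            "I_DD": _mult_noise(rng, idd_post, noise_sd),
            "I_AA": _mult_noise(rng, iaa_post, noise_sd),
            "I_DA": _mult_noise(rng, ida_post, noise_sd),
            "label": "double",
        }
    )
    if noise_sd > 0:
        for col in ("I_DD", "I_AA", "I_DA"):
            pre[col] = _mult_noise(rng, pre[col].to_numpy(), noise_sd)
    truth = SyntheticTruth(
        "gen_photobleach_pair",
        seed,
        {"true_E": true_e, "true_a": a, "true_d": d, "true_G": g,
         "noise_sd": noise_sd, "residual_acceptor": residual_acceptor},
    )
    return pre, post, truth


def gen_fret_timecourse(
    bottom: float,
    top: float,
    v50: float,
    slope: float,
    t_stim: float = 120.0,
    dt: float = 12.0,
    duration: float = 720.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FretTrace, SyntheticTruth]:
    """Boltzmann-shaped FRET efficiency time course around a TG stimulus.

    Defaults mirror the acquisition protocol: one frame every 12 s, 2 min of
    baseline before stimulation, 10 min after. E(t) = bottom before the
    stimulus and bottom + (top-bottom)/(1+exp((v50-(t-t_stim))/slope))
    afterwards, with additive Gaussian noise.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    if slope == 0:
        raise DomainError("slope must be nonzero")
    if top < bottom:
        raise DomainError("top must be >= bottom")
    if duration < t_stim + 2 * dt:
        raise DomainError("duration must cover the post-stimulus window")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    rel = times - t_stim
    values = np.where(
        rel < 0,
        bottom,
        bottom + (top - bottom) / (1.0 + np.exp((v50 - rel) / slope)),
    )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    trace = FretTrace(times=times, values=values, stim_time=t_stim)
    truth = SyntheticTruth(
        "gen_fret_timecourse",
        seed,
        {"bottom": bottom, "top": top, "true_V50": v50, "slope": slope,
         "t_stim": t_stim, "dt": dt, "noise_sd": noise_sd},
    )
    return trace, truth


def gen_calcium_plate(
    baseline_f: float = 100.0,
    er_release_amp: float = 80.0,
    influx_amp: float = 200.0,
    fmin: float = 20.0,
    fmax: float = 1000.0,
    with_tg: bool = True,
    dt: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    well_id: str = "well",
) -> tuple[CalciumTrace, SyntheticTruth]:
    """Plate-reader fluo-4 trace through the SOCE protocol phases.

    Phases: baseline in Ca2+-free medium; TG addition at 200 s releasing ER
    stores as a sin^2 transient of height ``er_release_amp`` (area exactly
    amp * 75 s); CaCl2 add-back at 600 s producing an entry plateau of
    height ``influx_amp`` (total entry if TG was present, constitutive
    otherwise); digitonin at 900 s pinning the signal at ``fmax`` for
    calibration.
    """
    if not (fmin < baseline_f < fmax):
        raise DomainError("require fmin < baseline_F < fmax")
    peak = baseline_f + max(er_release_amp if with_tg else 0.0, 0.0) + max(influx_amp, 0.0)
    if peak >= fmax:
        raise DomainError("amplitudes push F to/beyond Fmax before digitonin")
    if er_release_amp < 0 or influx_amp < 0:
        raise DomainError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    tg_add, ca_add, dig_add, duration = 200.0, 600.0, 900.0, 1100.0
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    f = np.full_like(times, baseline_f)

    if with_tg:
        s = times - tg_add
        in_pulse = (s >= 0) & (s <= TG_PULSE_WIDTH_S)
        f[in_pulse] += er_release_amp * np.sin(np.pi * s[in_pulse] / TG_PULSE_WIDTH_S) ** 2
    f[times >= ca_add] = baseline_f + influx_amp
    f[times >= dig_add] = fmax
    if noise_sd > 0:
        pre_dig = times < dig_add
        f[pre_dig] = f[pre_dig] * (1.0 + rng.normal(0.0, noise_sd, size=pre_dig.sum()))
    events = {"ca_add": ca_add, "digitonin_add": dig_add}
    if with_tg:
        events["tg_add"] = tg_add
    trace = CalciumTrace(times=times, f=f, events=events, well_id=well_id)
    truth = SyntheticTruth(
        "gen_calcium_plate",
        seed,
        {"baseline_F": baseline_f, "er_release_amp": er_release_amp,
         "influx_amp": influx_amp, "fmin": fmin, "fmax": fmax,
         "with_tg": with_tg, "noise_sd": noise_sd,
         "true_auc_tg": (er_release_amp * TG_PULSE_WIDTH_S / 2.0) if with_tg else 0.0},
    )
    return trace, truth


def gen_microarray(
    n_probes: int = 10000,
    n_per_group: int = 4,
    frac_expressed: float = 0.8,
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    expr_mean: float = 1000.0,
    de_fraction: float = 0.1,
    fold: float = 2.0,
    seed: int = 0,
) -> tuple["ExpressionMatrix", SyntheticTruth]:
    """Two-group microarray intensity matrix with planted expressed/DE probes.

    Mirrors the study's design: two groups of ``n_per_group`` arrays (4 vs 4
    in the deposited series), a minority... up to 80% of probes truly
    expressed (the analysis itself assumes at most 80% of genes are
    expressed on any array), the rest drawn from an array-level background
    N(bg_mean, bg_sd). Expressed probes get probe-specific means around
    ``expr_mean`` (log-normal spread); a ``de_fraction`` of them carries a
    between-group fold change of ``fold`` (group2 = fold * group1).
    """
    from .datatypes import ExpressionMatrix

    if not (0 < frac_expressed <= 0.8):
        raise DomainError("frac_expressed must be in (0, 0.8]")
    if n_per_group < 2:
        raise DomainError("n_per_group >= 2 required")
    if expr_mean <= bg_mean + 2 * bg_sd:
        raise DomainError(
            "expr_mean must exceed bg_mean + 2*bg_sd; planted truth would be "
            "undetectable by construction"
        )
    rng = np.random.default_rng(seed)
    n_expressed = int(round(frac_expressed * n_probes))
    probe_ids = [f"probe_{i:06d}" for i in range(n_probes)]
    expressed_idx = np.sort(rng.choice(n_probes, size=n_expressed, replace=False))
    expressed_ids = [probe_ids[i] for i in expressed_idx]

    n_de = int(round(de_fraction * n_expressed)) if fold != 1.0 else 0
    de_idx = np.sort(rng.choice(expressed_idx, size=n_de, replace=False)) if n_de else np.array([], dtype=int)
    de_ids = [probe_ids[i] for i in de_idx]

    samples = [f"g1_s{i}" for i in range(n_per_group)] + [f"g2_s{i}" for i in range(n_per_group)]
    groups = {s: ("group1" if s.startswith("g1") else "group2") for s in samples}

    # background for everyone, then overwrite expressed probes
    vals = rng.normal(bg_mean, bg_sd, size=(n_probes, 2 * n_per_group))
    probe_level = expr_mean * np.exp(rng.normal(0.0, 0.25, size=n_expressed))
    rel_noise = 0.05  # within-group biological/technical scatter
    expr_vals = probe_level[:, None] * (
        1.0 + rng.normal(0.0, rel_noise, size=(n_expressed, 2 * n_per_group))
    )
    vals[expressed_idx, :] = expr_vals
    if n_de:
        de_pos = np.searchsorted(expressed_idx, de_idx)
        vals[de_idx, n_per_group:] = (
            fold * probe_level[de_pos][:, None]
            * (1.0 + rng.normal(0.0, rel_noise, size=(n_de, n_per_group)))
        )
    vals = np.clip(vals, 1e-6, None)  # intensities stay positive

    df = pd.DataFrame(vals, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    matrix = ExpressionMatrix(values=df, groups=groups)
    truth = SyntheticTruth(
        "gen_microarray",
        seed,
        {"n_probes": n_probes, "n_per_group": n_per_group,
         "frac_expressed": frac_expressed, "bg_mean": bg_mean, "bg_sd": bg_sd,
         "expr_mean": expr_mean, "de_fraction": de_fraction, "fold": fold,
         "expressed_probe_ids": expressed_ids, "de_probe_ids": de_ids},
    )
    return matrix, truth


def gen_ratio_image(
    shape: tuple[int, int] = (64, 64),
    n_phagosomes: int = 8,
    hotspot_fraction: float = 0.5,
    hotspot_ratio: float = 3.0,
    background_ratio: float = 1.0,
    disk_radius: int = 4,
    annulus_width: int = 2,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[RatioImage, SyntheticTruth]:
    """Cytosol-normalized ratio image with disk phagosomes and hotspot rings.

    The grid is uniform at ``background_ratio`` (unit background after
    cytosol normalization); phagosome masks are non-overlapping disks whose
    interiors sit at 0.8x background (dye-poor particle); a truth-selected
    ``hotspot_fraction`` of phagosomes carries a periphagosomal annulus of
    width ``annulus_width`` at ``hotspot_ratio``. Annuli of distinct
    phagosomes never overlap and stay inside the image.
    """
    if hotspot_ratio <= background_ratio:
        raise DomainError("hotspot_ratio must exceed background_ratio")
    if n_phagosomes < 1:
        raise DomainError("n_phagosomes >= 1 required")
    n_hot = int(round(hotspot_fraction * n_phagosomes))
    if abs(n_hot - hotspot_fraction * n_phagosomes) > 1e-9:
        warnings.warn(
            "hotspot_fraction * n_phagosomes is not an integer; rounding to "
            f"{n_hot} hotspot phagosomes"
        )
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = disk_radius + annulus_width + 1
    if 2 * margin >= min(h, w):
        raise DomainError("grid too small for the requested disk geometry")

    yy, xx = np.mgrid[0:h, 0:w]
    centers: list[tuple[int, int]] = []
    min_sep = 2 * (disk_radius + annulus_width) + 1
    tries = 0
    while len(centers) < n_phagosomes:
        tries += 1
        if tries > max_tries:
            raise DomainError(
                f"could not place {n_phagosomes} non-overlapping phagosomes "
                f"in {shape} after {max_tries} tries"
            )
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))

    ratio = np.full(shape, background_ratio, dtype=float)
    labels = np.zeros(shape, dtype=int)
    hot_flags = np.zeros(n_phagosomes, dtype=bool)
    hot_flags[rng.choice(n_phagosomes, size=n_hot, replace=False)] = True
    for i, (cy, cx) in enumerate(centers):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = r2 <= disk_radius**2
        labels[disk] = i + 1
        ratio[disk] = 0.8 * background_ratio
        if hot_flags[i]:
            ring = (r2 > disk_radius**2) & (r2 <= (disk_radius + annulus_width) ** 2)
            ratio[ring] = hotspot_ratio
    cytosol = labels == 0
    img = RatioImage(ratio=ratio, labels=labels, cytosol_mask=cytosol)
    truth = SyntheticTruth(
        "gen_ratio_image",
        seed,
        {"n_phagosomes": n_phagosomes, "hotspot_fraction": hotspot_fraction,
         "hotspot_ratio": hotspot_ratio, "background_ratio": background_ratio,
         "disk_radius": disk_radius, "annulus_width": annulus_width,
         "hotspot_labels": [i + 1 for i in range(n_phagosomes) if hot_flags[i]]},
    )
    return img, truth


def _gen_fusion(params: dict, rng: np.random.Generator) -> pd.DataFrame:
    n_int = int(params.get("n_internal", 20))
    n_ext = int(params.get("n_external", 10))
    basal = float(params.get("basal_ratio", 0.1))
    h = float(params.get("cell_ha_total", 2.0))
    bead = float(params.get("bead_mean", 100.0))
    noise = float(params.get("noise_sd", 0.0))
    planted = np.atleast_1d(np.asarray(params.get("planted_index", 2000.0), dtype=float))
    idx = np.resize(planted, n_int)
    rows = []
    beads_e = _mult_noise(rng, np.full(n_ext, bead), noise)
    for i in range(n_ext):
        rows.append({"object_id": f"ext_{i:03d}", "fret": basal * beads_e[i],
                     "bead": beads_e[i], "cell_ha_total": h, "is_external": True})
    beads_i = _mult_noise(rng, np.full(n_int, bead), noise)
    for i in range(n_int):
        ratio = basal + idx[i] * h / 10_000.0
        rows.append({"object_id": f"int_{i:03d}", "fret": ratio * beads_i[i],
                     "bead": beads_i[i], "cell_ha_total": h, "is_external": False})
    return pd.DataFrame(rows)


def _gen_ros(params: dict, rng: np.random.Generator) -> pd.DataFrame:
    n_int = int(params.get("n_internal", 20))
    n_ext = int(params.get("n_external", 10))
    basal = float(params.get("basal_ratio", 0.5))
    alexa = float(params.get("alexa_mean", 100.0))
    noise = float(params.get("noise_sd", 0.0))
    planted = np.atleast_1d(np.asarray(params.get("planted_index", 1.0), dtype=float))
    idx = np.resize(planted, n_int)
    rows = []
    al_e = _mult_noise(rng, np.full(n_ext, alexa), noise)
    for i in range(n_ext):
        rows.append({"object_id": f"ext_{i:03d}", "oxyburst": basal * al_e[i],
                     "alexa568": al_e[i], "is_external": True})
    al_i = _mult_noise(rng, np.full(n_int, alexa), noise)
    for i in range(n_int):
        rows.append({"object_id": f"int_{i:03d}",
                     "oxyburst": (basal + idx[i]) * al_i[i],
                     "alexa568": al_i[i], "is_external": False})
    return pd.DataFrame(rows)


def _gen_ph_calibration(params: dict, rng: np.random.Generator) -> pd.DataFrame:
    levels = np.asarray(params.get("levels", [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]), dtype=float)
    n_stacks = int(params.get("n_stacks", 5))  # five stacks per buffer
    bottom = float(params.get("bottom", 0.2))
    top = float(params.get("top", 2.0))
    ph50 = float(params.get("ph50", 6.5))
    slope = float(params.get("slope", 0.8))
    noise = float(params.get("noise_sd", 0.0))
    rows = []
    for ph in levels:
        r = bottom + (top - bottom) / (1.0 + np.exp((ph50 - ph) / slope))
        reps = r + (rng.normal(0.0, noise, size=n_stacks) if noise > 0 else np.zeros(n_stacks))
        for s, val in enumerate(reps):
            rows.append({"ph": ph, "stack_id": s, "ratio": val})
    return pd.DataFrame(rows)


def _gen_degradation(params: dict, rng: np.random.Generator) -> pd.DataFrame:
    chase = np.asarray(params.get("chase_min", [0, 30, 60, 120, 240]), dtype=float)
    t0 = float(params.get("t0_reference", 1000.0))
    pct = np.asarray(params.get("true_percent", [0, 20, 40, 60, 80]), dtype=float)
    noise = float(params.get("noise_sd", 0.0))
    mfi = t0 * (1.0 - pct / 100.0)
    mfi = _mult_noise(rng, mfi, noise)
    return pd.DataFrame({"chase_min": chase, "mfi": mfi})


def _gen_export(params: dict, rng: np.random.Generator) -> pd.DataFrame:
    n_treated = int(params.get("n_treated", 100))
    n_control = int(params.get("n_control", 100))
    n_positive = int(params.get("n_positive", 30))
    green = float(params.get("green_mean", 100.0))
    if n_positive > n_treated:
        raise DomainError("n_positive cannot exceed n_treated")
    # control blue/green scores ~ lognormal around 0.1
    ctrl_scores = 0.1 * np.exp(rng.normal(0.0, 0.3, size=n_control))
    rows = [
        {"cell_id": f"ctrl_{i:04d}", "blue": s * green, "green": green,
         "condition": "probe_only_control"}
        for i, s in enumerate(ctrl_scores)
    ]
    # positives planted far above the control range, negatives strictly below
    # the control minimum so any control quantile separates them exactly
    pos_scores = ctrl_scores.max() * rng.uniform(5.0, 10.0, size=n_positive)
    neg_scores = ctrl_scores.min() * rng.uniform(0.1, 0.5, size=n_treated - n_positive)
    treated = np.concatenate([pos_scores, neg_scores])
    rng.shuffle(treated)
    rows += [
        {"cell_id": f"trt_{i:04d}", "blue": s * green, "green": green,
         "condition": "treated"}
        for i, s in enumerate(treated)
    ]
    return pd.DataFrame(rows)


_ASSAY_GENERATORS = {
    "fusion": _gen_fusion,
    "ros": _gen_ros,
    "ph_calibration": _gen_ph_calibration,
    "degradation": _gen_degradation,
    "export": _gen_export,
}


def gen_assay_objects(
    kind: str, params: dict | None = None, seed: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate per-object tables for the phagosome scoring assays.

    ``kind`` selects the assay: ``fusion`` (per-phagosome FRET/bead/HA
    channels with an external-bead basal population), ``ros``
    (OxyBurst/Alexa-568 pairs), ``ph_calibration`` (buffer ratio stacks
    across pH 4.0-9.0, five stacks per level, plus unknowns), ``degradation``
    (MFI per chase time) or ``export`` (per-cell 450/535 nm pairs for
    treated and probe-only control populations).
    """
    if kind not in _ASSAY_GENERATORS:
        raise DomainError(
            f"unknown assay kind {kind!r}; expected one of {sorted(_ASSAY_GENERATORS)}"
        )
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    table = _ASSAY_GENERATORS[kind](params, rng)
    truth = SyntheticTruth(f"gen_assay_objects[{kind}]", seed, params)
    return table, truth
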