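"""Phagosome biology scoring indices.

Covers the per-object quantifications of phagosomal maturation:

* phago-lysosome fusion index — basal-corrected FRET/bead-channel ratio
  normalized to the cell's total lysosomal-dye (Alexa-594-HA) fluorescence
  and scaled by 10,000;
* phagosomal ROS index — OxyBurst/Alexa-568 ratio minus the external
  (uningested) particle ratio;
* intracellular ROS — maximum fluorescence over the time course normalized
  to the mean over the first minutes of baseline;
* ratiometric pH — sigmoid calibration over buffer standards (pH 4.0-9.0)
  and its inverse;
* phagosomal antigen degradation — percent loss of anti-OVA stain relative
  to the pulse-only reference;
* antigen export to the cytosol — percent of treated cells whose
  450/535 nm (cleaved/intact CCF4) score exceeds a control quantile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import DomainError, RatioCalibration

__all__ = [
    "pl_fusion_index",
    "phagosomal_ros_index",
    "intracellular_ros_summary",
    "fit_ratio_ph_calibration",
    "ratio_to_ph",
    "ova_degradation_percent",
    "cytosol_export_percent",
]

FUSION_SCALE = 10_000.0  # final P-L fusion index scale factor
EXPORT_EPS = 1e-9  # guard on the 535 nm denominator of the CCF4 score


def _split_objects(objs: pd.DataFrame, assay: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    internal = objs[~objs["is_external"].astype(bool)]
    external = objs[objs["is_external"].astype(bool)]
    if external.empty:
        raise DomainError(f"{assay}: no external objects; basal ratio undefined")
    if internal.empty:
        raise DomainError(f"{assay}: no internal objects to score")
    return internal, external


def pl_fusion_index(objs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Phago-lysosome fusion index per internal phagosome, plus the mean.

    basal = mean(fret/bead) over external (uningested) beads;
    index  = ((fret/bead - basal) / cell_ha_total) * 10,000.

    Objects with a zero bead channel cannot be ratioed and are excluded
    with a warning.
    """
    zero_bead = objs["bead"] == 0
    if zero_bead.any():
        warnings.warn(
            f"{int(zero_bead.sum())} object(s) with zero bead channel excluded"
        )
        objs = objs[~zero_bead]
    internal, external = _split_objects(objs, "P-L fusion")
    basal = float((external["fret"] / external["bead"]).mean())
    ratio = internal["fret"] / internal["bead"]
    index = (ratio - basal) / internal["cell_ha_total"] * FUSION_SCALE
    per_obj = pd.DataFrame(
        {"object_id": internal["object_id"], "fret_bead_ratio": ratio,
         "basal_ratio": basal, "fusion_index": index}
    ).reset_index(drop=True)
    return per_obj, float(index.mean())


def phagosomal_ros_index(objs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Phagosomal ROS index: OxyBurst/Alexa-568 ratio minus the external
    (basal) ratio, per internal phagosome, plus the mean."""
    zero = objs["alexa568"] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} object(s) with zero Alexa-568 channel excluded"
        )
        objs = objs[~zero]
    internal, external = _split_objects(objs, "phagosomal ROS")
    basal = float((external["oxyburst"] / external["alexa568"]).mean())
    index = internal["oxyburst"] / internal["alexa568"] - basal
    per_obj = pd.DataFrame(
        {"object_id": internal["object_id"], "basal_ratio": basal,
         "ros_index": index}
    ).reset_index(drop=True)
    return per_obj, float(index.mean())


def intracellular_ros_summary(
    times_min, fluorescence, baseline_span: float = 6.0
) -> float:
    """Whole-cell ROS readout: max fluorescence over the course normalized
    to the mean over the first ``baseline_span`` minutes (endpoint
    inclusive, so a 2-min cadence contributes t = 0, 2, 4, 6)."""
    t = np.asarray(times_min, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise DomainError("times and fluorescence must be matching 1-D arrays")
    sel = t <= baseline_span
    if sel.sum() < 2:
        raise DomainError("need >= 2 samples within the baseline span")
    baseline = f[sel].mean()
    if baseline <= 0:
        raise DomainError("baseline mean must be > 0")
    return float(f.max() / baseline)


def _sigmoid(ph, bottom, top, ph50, slope):
    return bottom + (top - bottom) / (1.0 + np.exp((ph50 - ph) / slope))


def fit_ratio_ph_calibration(
    buffer_stacks: pd.DataFrame, monotone_tol: float = 0.0
) -> RatioCalibration:
    """Fit the pH-vs-ratio sigmoid over calibration buffer stacks.

    ``buffer_stacks`` has columns ``ph``, ``stack_id``, ``ratio``; the fit
    is on per-level mean ratios (replicate stacks are averaged, their
    scatter kept as residual diagnostics). Mean ratios must be monotone in
    pH within ``monotone_tol``; violations abort with the offending levels
    named, since a non-monotone standard curve cannot be inverted.
    """
    grouped = buffer_stacks.groupby("ph")["ratio"]
    levels = np.array(sorted(grouped.groups))
    if levels.size < 4:
        raise DomainError("need >= 4 pH levels for calibration")
    counts = grouped.count()
    if (counts < 2).any():
        raise DomainError("need >= 2 replicate stacks per pH level")
    means = grouped.mean().loc[levels].to_numpy(float)

    diffs = np.diff(means)
    sign = np.sign(diffs[np.abs(diffs) > monotone_tol])
    if sign.size and not (np.all(sign >= 0) or np.all(sign <= 0)):
        bad = [
            f"pH {levels[i]:g}->{levels[i + 1]:g}"
            for i in range(diffs.size)
            if np.sign(diffs[i]) != sign[0] and abs(diffs[i]) > monotone_tol
        ]
        raise DomainError(
            "mean calibration ratios are not monotone in pH at: " + ", ".join(bad)
        )

    span = levels[-1] - levels[0]
    p0 = (float(means[0]), float(means[-1]), float(levels.mean()), span / 6.0)
    popt, _ = optimize.curve_fit(_sigmoid, levels, means, p0=p0, maxfev=20000)
    bottom, top, ph50, slope = (float(p) for p in popt)
    if slope < 0:  # same curve, canonical parameterization
        bottom, top, slope = top, bottom, -slope
    resid = means - _sigmoid(levels, bottom, top, ph50, slope)
    return RatioCalibration(
        levels=levels, mean_ratios=means,
        bottom=bottom, top=top, ph50=ph50, slope=slope, residuals=resid,
    )


def ratio_to_ph(
    ratio, calib: RatioCalibration, allow_extrapolation: bool = False
):
    """Invert the fitted pH sigmoid: ratio -> pH, monotone on the
    calibrated range. Ratios outside the calibrated mean-ratio range are
    refused unless ``allow_extrapolation``."""
    r = np.asarray(ratio, dtype=float)
    lo = min(calib.mean_ratios.min(), calib.mean_ratios.max())
    hi = max(calib.mean_ratios.min(), calib.mean_ratios.max())
    if not allow_extrapolation and (np.any(r < lo) or np.any(r > hi)):
        raise DomainError(
            f"ratio outside calibrated range [{lo:.4g}, {hi:.4g}]; "
            "pass allow_extrapolation=True to override"
        )
    span = calib.top - calib.bottom
    x = span / (r - calib.bottom) - 1.0
    if np.any(x <= 0):
        raise DomainError("ratio outside the open range of the fitted sigmoid")
    ph = calib.ph50 - calib.slope * np.log(x)
    return float(ph) if ph.ndim == 0 else ph


def ova_degradation_percent(
    chase_times, mfi, t0_reference: float
) -> pd.DataFrame:
    """Percent antigen degradation per chase time.

    percent(t) = 100 * (1 - MFI(t)/MFI_t0), clipped to [0, 100], with the
    pulse-only (zero-chase) stain intensity as the reference.
    """
    if t0_reference <= 0:
        raise DomainError("t0 reference MFI must be > 0")
    t = np.asarray(chase_times, dtype=float)
    m = np.asarray(mfi, dtype=float)
    pct = np.clip(100.0 * (1.0 - m / t0_reference), 0.0, 100.0)
    return pd.DataFrame({"chase_min": t, "mfi": m, "degraded_percent": pct})


def cytosol_export_percent(
    cells: pd.DataFrame, control_quantile: float = 0.99
) -> tuple[float, float]:
    """Percent of treated cells scored positive for cytosolic antigen export.

    Each cell's score is blue/(green + eps) — the cleaved (450 nm) over
    intact (535 nm) CCF4 emission. The positivity threshold is the
    ``control_quantile`` of the probe-only control population's scores;
    returns (percent positive among treated, threshold).
    """
    if not (0 < control_quantile <= 1):
        raise DomainError("control_quantile must be in (0, 1]")
    ctrl = cells[cells["condition"] == "probe_only_control"]
    treated = cells[cells["condition"] == "treated"]
    if treated.empty:
        raise DomainError("no treated cells")
    if len(ctrl) < 20:
        raise DomainError(f"control population has {len(ctrl)} cells; >= 20 required")
    score = lambda df: df["blue"].to_numpy(float) / (
        df["green"].to_numpy(float) + EXPORT_EPS
    )
    ctrl_scores = score(ctrl)
    if np.ptp(ctrl_scores) == 0:
        warnings.warn("degenerate control: all control scores identical")
    threshold = float(np.quantile(ctrl_scores, control_quantile))
    percent = 100.0 * float(np.mean(score(treated) > threshold))
    return percent, threshold
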