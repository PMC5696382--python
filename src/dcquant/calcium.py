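"""Fluo-4 calibration, SOCE decomposition, and periphagosomal hotspot calling.

Store-operated Ca2+ entry (SOCE) is quantified with the classic Ca2+
re-addition protocol: ER stores are depleted with thapsigargin (TG) in
Ca2+-free medium (the transient's area reports ER release), then external
CaCl2 is added and the entry amplitude is read; SOCE is the total entry
(TG well) minus the constitutive entry (no-TG well). Fluorescence is
converted to [Ca2+] with the single-wavelength equation
Kd*(F - Fmin)/(Fmax - F), Fmax pinned per well by digitonin.

Periphagosomal Ca2+ hotspots are called on cytosol-normalized ratio images:
a phagosome is a hotspot when the mean ratio over its surrounding annulus
reaches a threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate
from skimage.morphology import dilation, disk

from .datatypes import (
    CalciumCalibration,
    CalciumTrace,
    DomainError,
    RatioImage,
    SoceSummary,
)

__all__ = [
    "calibrate_fluo4",
    "calibration_bounds",
    "quantify_soce",
    "detect_hotspots",
]

# defaults for hotspot calling; the imaging protocol does not pin these, so
# they are explicit, mandatory knobs echoed into output metadata
DEFAULT_HOTSPOT_THRESHOLD = 1.5
DEFAULT_ANNULUS_WIDTH = 2
PEAK_WINDOW_S = 120.0  # window after Ca2+ add-back in which the entry peak is sought


def calibrate_fluo4(f, calib: CalciumCalibration):
    """[Ca2+] in nM from fluo-4 fluorescence: Kd*(F - Fmin)/(Fmax - F).

    Strictly increasing in F on [Fmin, Fmax). F at or above Fmax is a
    saturated signal (error); F below Fmin is clamped to 0 nM with a
    warning (sub-background readings carry no concentration information).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f >= calib.fmax):
        raise DomainError("saturated signal: F >= Fmax, concentration undefined")
    below = f < calib.fmin
    if np.any(below):
        warnings.warn(
            f"{int(np.sum(below))} reading(s) below Fmin clamped to 0 nM"
        )
    conc = calib.kd * (f - calib.fmin) / (calib.fmax - f)
    conc = np.where(below, 0.0, conc)
    return float(conc) if conc.ndim == 0 else conc


def calibration_bounds(
    trace: CalciumTrace, dye_free_reference: float
) -> CalciumCalibration:
    """Per-well calibration bounds from the digitonin segment.

    Fmax is the maximum fluorescence after digitonin addition; Fmin is the
    dye-free well reference measured at the same cell density.
    """
    dig = trace.events.get("digitonin_add")
    if dig is None:
        raise DomainError("trace has no digitonin_add event; Fmax undefined")
    sel = trace.times >= dig
    if sel.sum() < 3:
        raise DomainError("need >= 3 post-digitonin samples for Fmax")
    fmax = float(trace.f[sel].max())
    if dye_free_reference >= fmax:
        raise DomainError(
            f"dye-free reference ({dye_free_reference}) is not below the "
            f"post-digitonin maximum ({fmax})"
        )
    return CalciumCalibration(fmin=float(dye_free_reference), fmax=fmax)


def _baseline(trace: CalciumTrace, before: float) -> float:
    sel = trace.times < before
    if not sel.any():
        raise DomainError("no samples before the stimulus; baseline undefined")
    return float(trace.f[sel].mean())


def _entry_amplitude(trace: CalciumTrace, peak_window: float) -> float:
    """Entry amplitude: post-add-back peak minus the immediately-pre-add level."""
    ca = trace.events.get("ca_add")
    if ca is None:
        raise DomainError("trace has no ca_add event")
    pre = trace.times < ca
    if not pre.any():
        raise DomainError("no samples before ca_add")
    pre_level = float(trace.f[pre][-1])
    win = (trace.times >= ca) & (trace.times <= ca + peak_window)
    if not win.any():
        raise DomainError("no samples in the post-ca_add peak window")
    return float(trace.f[win].max() - pre_level)


def quantify_soce(
    tg_trace: CalciumTrace,
    control_trace: CalciumTrace,
    peak_window: float = PEAK_WINDOW_S,
    influx_reference: float | None = None,
) -> SoceSummary:
    """Decompose a paired TG / no-TG well into release AUC and SOCE.

    ``auc_tg``: trapezoidal area of (F - pre-TG baseline) over
    [tg_add, ca_add] on the TG well, negative excursions truncated at 0
    (store release is a magnitude). ``total_entry`` and
    ``constitutive_entry``: add-back peak minus the immediately-pre-add
    level on the TG and control wells; ``soce`` is their difference.
    ``influx_reference``, when given, expresses total entry as a percent of
    that caller-supplied reference (e.g. a paired wild-type mean).
    """
    tg = tg_trace.events.get("tg_add")
    ca = tg_trace.events.get("ca_add")
    if tg is None or ca is None:
        raise DomainError("TG trace must carry tg_add and ca_add events")
    if ca <= tg:
        raise DomainError("ca_add must come after tg_add")
    baseline = _baseline(tg_trace, before=tg)
    # samples at/after ca_add already reflect add-back, not store release
    sel = (tg_trace.times >= tg) & (tg_trace.times < ca)
    resp = np.clip(tg_trace.f[sel] - baseline, 0.0, None)
    auc = float(integrate.trapezoid(resp, tg_trace.times[sel]))

    total = _entry_amplitude(tg_trace, peak_window)
    constitutive = _entry_amplitude(control_trace, peak_window)
    soce = total - constitutive
    pct = None
    if influx_reference is not None:
        if influx_reference == 0:
            raise DomainError("influx reference must be nonzero")
        pct = 100.0 * total / influx_reference
    return SoceSummary(
        auc_tg=auc,
        total_entry=total,
        constitutive_entry=constitutive,
        soce=soce,
        influx_percent=pct,
    )


def detect_hotspots(
    img: RatioImage,
    annulus_width: int = DEFAULT_ANNULUS_WIDTH,
    threshold_ratio: float = DEFAULT_HOTSPOT_THRESHOLD,
) -> tuple[dict, float]:
    """Call periphagosomal hotspots on a cytosol-normalized ratio image.

    For each phagosome the annulus is its mask dilated by ``annulus_width``
    pixels minus the mask itself; the phagosome is a hotspot iff the mean
    ratio over the annulus is >= ``threshold_ratio``. Phagosomes whose
    annulus would extend past the image border are excluded from the
    denominator, with a warning naming them. Returns (per-phagosome flags
    keyed by label, hotspot percentage over scored phagosomes).
    """
    n = img.n_phagosomes
    if n < 1:
        raise DomainError("image contains no phagosome masks")
    if annulus_width < 1:
        raise DomainError("annulus_width must be >= 1 pixel")
    selem = disk(annulus_width)
    h, w = img.ratio.shape
    flags: dict[int, bool] = {}
    excluded = []
    for label in range(1, n + 1):
        mask = img.labels == label
        if not mask.any():
            raise DomainError(f"phagosome label {label} has an empty mask")
        ys, xs = np.nonzero(mask)
        if (
            ys.min() < annulus_width
            or xs.min() < annulus_width
            or ys.max() >= h - annulus_width
            or xs.max() >= w - annulus_width
        ):
            excluded.append(label)
            continue
        annulus = dilation(mask, selem) & ~mask & (img.labels == 0)
        if not annulus.any():
            raise DomainError(f"phagosome {label}: empty annulus")
        flags[label] = bool(img.ratio[annulus].mean() >= threshold_ratio)
    if excluded:
        warnings.warn(
            f"{len(excluded)} phagosome(s) excluded (annulus outside image "
            f"bounds): labels {excluded}"
        )
    if not flags:
        raise DomainError("no phagosome could be scored (all annuli out of bounds)")
    percent = 100.0 * sum(flags.values()) / len(flags)
    return flags, percent
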