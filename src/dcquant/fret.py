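"""Three-cube E-FRET calibration and STIM1-oligomerization kinetics.

Implements the intensity-based (sensitized emission) FRET workflow used to
read out STIM1 oligomerization speed: bleed-through calibration from
single-labeled cells, G-factor estimation from complete acceptor
photobleaching, the apparent-efficiency formula

    E = (I_DA - a*I_AA - d*I_DD) / (I_DA - a*I_AA + (G - d)*I_DD),

trace normalization to the pre-stimulus baseline, local-quadratic
("2nd order, 4 neighbors") smoothing, and Boltzmann sigmoid fitting whose
V50 parameter is the time-to-half-maximum efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import BoltzmannFit, DomainError, FretCalibration, FretTrace

__all__ = [
    "efret",
    "estimate_bleedthrough",
    "estimate_g_factor",
    "normalize_fret_trace",
    "smooth_trace",
    "fit_boltzmann",
    "BleedthroughEstimate",
]


def efret(
    i_dd,
    i_aa,
    i_da,
    calib: FretCalibration,
    eps: float = 1e-12,
):
    """Apparent FRET efficiency from three-cube intensities.

    Accepts scalars or arrays. Measurements whose corrected denominator
    ``I_DA - a*I_AA + (G-d)*I_DD`` has magnitude below ``eps`` are flagged:
    the result is NaN and a warning reports how many were undefined (never
    a silent NaN).
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_aa = np.asarray(i_aa, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    if np.any(~np.isfinite(i_dd)) or np.any(~np.isfinite(i_aa)) or np.any(~np.isfinite(i_da)):
        raise DomainError("intensities must be finite")
    fc = i_da - calib.a * i_aa - calib.d * i_dd
    den = fc + calib.g * i_dd
    bad = np.abs(den) < eps
    n_bad = int(np.sum(bad))
    if n_bad:
        warnings.warn(
            f"{n_bad} measurement(s) have near-zero E-FRET denominator "
            f"(|den| < {eps}); efficiency undefined, returned as NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(bad, np.nan, fc / np.where(bad, 1.0, den))
    return float(e) if e.ndim == 0 else e


@dataclass(frozen=True)
class BleedthroughEstimate:
    """Bleed-through slope with its regression diagnostics."""

    value: float
    r_squared: float
    n: int
    stderr: float


def _slope(x: np.ndarray, y: np.ndarray, channel: str) -> BleedthroughEstimate:
    if x.size < 3:
        raise DomainError(f"need >= 3 cells to regress I_DA on {channel}")
    if np.ptp(x) == 0:
        raise DomainError(f"{channel} values are constant; slope undefined")
    res = stats.linregress(x, y)
    return BleedthroughEstimate(
        value=float(res.slope),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        stderr=float(res.stderr),
    )


def estimate_bleedthrough(
    acceptor_only: pd.DataFrame, donor_only: pd.DataFrame
) -> tuple[BleedthroughEstimate, BleedthroughEstimate]:
    """Bleed-through coefficients from single-labeled cell populations.

    ``a`` is the least-squares slope of I_DA on I_AA over acceptor-only
    cells; ``d`` the slope of I_DA on I_DD over donor-only cells —
    the only regression orientation in which each slope has the units of a
    bleed-through coefficient in the efficiency formula.
    """
    a = _slope(
        acceptor_only["I_AA"].to_numpy(float),
        acceptor_only["I_DA"].to_numpy(float),
        "I_AA",
    )
    d = _slope(
        donor_only["I_DD"].to_numpy(float),
        donor_only["I_DA"].to_numpy(float),
        "I_DD",
    )
    return a, d


def estimate_g_factor(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    a: float,
    d: float,
    denominator_mode: str = "standard",
    bleach_completeness: float = 0.05,
) -> float:
    """G factor from pre/post complete-acceptor-photobleach intensities.

    With Fc = I_DA - a*I_AA - d*I_DD, the standard donor-dequenching form is

        G = (Fc_pre - Fc_post) / (I_DD_post - I_DD_pre),

    pooled over cells as a ratio of sums (cells with more dequenching weigh
    more). ``denominator_mode="as_printed"`` instead uses the denominator
    (I_DA_post - I_DD_pre) as transcribed in some protocol write-ups; it is
    kept selectable rather than silently corrected.

    A bleach leaving more than ``bleach_completeness`` of the pre-bleach
    acceptor signal triggers a warning (the estimate is then biased).
    """
    if denominator_mode not in ("standard", "as_printed"):
        raise DomainError(f"unknown denominator_mode {denominator_mode!r}")
    pre_dd = pre["I_DD"].to_numpy(float)
    pre_aa = pre["I_AA"].to_numpy(float)
    pre_da = pre["I_DA"].to_numpy(float)
    post_dd = post["I_DD"].to_numpy(float)
    post_aa = post["I_AA"].to_numpy(float)
    post_da = post["I_DA"].to_numpy(float)
    if pre_dd.shape != post_dd.shape:
        raise DomainError("pre and post tables must pair the same cells")

    pre_aa_tot, post_aa_tot = pre_aa.sum(), post_aa.sum()
    if pre_aa_tot > 0 and post_aa_tot > bleach_completeness * pre_aa_tot:
        warnings.warn(
            f"incomplete photobleach: residual acceptor signal is "
            f"{100 * post_aa_tot / pre_aa_tot:.1f}% of pre-bleach "
            f"(limit {100 * bleach_completeness:.1f}%); G estimate is biased"
        )
    fc_pre = pre_da - a * pre_aa - d * pre_dd
    fc_post = post_da - a * post_aa - d * post_dd
    num = np.sum(fc_pre - fc_post)
    if denominator_mode == "standard":
        den = np.sum(post_dd - pre_dd)
    else:
        den = np.sum(post_da - pre_dd)
    if abs(den) < 1e-12:
        raise DomainError("no donor dequenching: G denominator is zero")
    return float(num / den)


def normalize_fret_trace(trace: FretTrace, baseline_window: float = 60.0) -> FretTrace:
    """Divide a trace by its mean over the last ``baseline_window`` seconds
    before the stimulus, so the pre-stimulus baseline averages exactly 1."""
    sel = (trace.times >= trace.stim_time - baseline_window) & (
        trace.times < trace.stim_time
    )
    if sel.sum() < 2:
        raise DomainError(
            f"fewer than 2 samples in baseline window "
            f"[{trace.stim_time - baseline_window}, {trace.stim_time})"
        )
    baseline = trace.values[sel].mean()
    if baseline == 0:
        raise DomainError("baseline mean is zero; cannot normalize")
    return FretTrace(
        times=trace.times.copy(),
        values=trace.values / baseline,
        stim_time=trace.stim_time,
    )


def smooth_trace(trace: FretTrace, rel_tol: float = 1e-6) -> FretTrace:
    """Second-order, 4-neighbor smoothing.

    Each point is replaced by the center value of the least-squares
    quadratic fitted over the 9-point window (4 neighbors on each side);
    near the edges the window shrinks to whatever neighbors exist. Any
    quadratic input is reproduced exactly; on white noise the interior
    variance strictly decreases. Requires a uniform sampling grid (checked
    to relative tolerance ``rel_tol``).
    """
    n = len(trace)
    if n < 9:
        raise DomainError("smoothing needs >= 9 samples (4 neighbors each side)")
    dts = np.diff(trace.times)
    if np.ptp(dts) > rel_tol * np.abs(dts.mean()):
        raise DomainError("non-uniform sampling grid; smoothing undefined")
    out = np.empty(n)
    t, v = trace.times, trace.values
    for i in range(n):
        lo, hi = max(0, i - 4), min(n, i + 5)
        tw = t[lo:hi] - t[i]  # center at the evaluation point
        coeffs = np.polynomial.polynomial.polyfit(tw, v[lo:hi], deg=2)
        out[i] = coeffs[0]
    return FretTrace(times=t.copy(), values=out, stim_time=trace.stim_time)


def _boltzmann(t, bottom, top, v50, slope):
    z = np.clip((v50 - t) / slope, -700.0, 700.0)  # avoid exp overflow mid-search
    return bottom + (top - bottom) / (1.0 + np.exp(z))


def fit_boltzmann(
    trace: FretTrace,
    xtol: float = 1e-10,
    max_nfev: int = 20000,
) -> BoltzmannFit:
    """Fit the post-stimulus trace to a Boltzmann sigmoid.

    Time is measured from the stimulus; V50 is the time-to-half-maximum and
    TOP the plateau efficiency. Five deterministic initializations (V50
    guesses at the 20/35/50/65/80% quantiles of the post-stimulus window)
    are tried and the lowest-RSS convergent fit with top >= bottom wins.
    """
    sel = trace.times >= trace.stim_time
    t = trace.times[sel] - trace.stim_time
    y = trace.values[sel]
    if t.size < 5:
        raise DomainError("need >= 5 post-stimulus samples to fit")
    if np.ptp(y) == 0:
        raise DomainError("constant trace; Boltzmann fit undefined")

    b0, t0 = float(y.min()), float(y.max())
    span = float(t[-1] - t[0])
    slope0 = max(span / 10.0, 1e-6)
    best = None
    diagnostics = []
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        p0 = (b0, t0, float(t[0] + q * span), slope0)
        try:
            popt, _ = optimize.curve_fit(
                _boltzmann, t, y, p0=p0, xtol=xtol, maxfev=max_nfev
            )
        except RuntimeError as exc:
            diagnostics.append(f"init q={q}: {exc}")
            continue
        resid = y - _boltzmann(t, *popt)
        rss = float(resid @ resid)
        bottom, top, v50, slope = (float(p) for p in popt)
        if slope < 0:  # equivalent curve with swapped plateaus; canonicalize
            bottom, top, slope = top, bottom, -slope
        if top < bottom:
            diagnostics.append(f"init q={q}: inverted fit (top < bottom)")
            continue
        if best is None or rss < best.rss:
            best = BoltzmannFit(bottom=bottom, top=top, v50=v50, slope=slope, rss=rss)
    if best is None:
        raise DomainError(
            "Boltzmann fit failed for all initializations: " + "; ".join(diagnostics)
        )
    return best
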