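"""Shared domain containers for the quantification pipeline.

Tabular collections (per-cell three-cube intensities, assay object tables,
expression matrices) travel as pandas DataFrames with the column schemas
registered in :mod:`dcquant.io`; the small calibration/result bundles below
are plain dataclasses so they can be serialized to JSON and echoed into run
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FretCalibration",
    "FretTrace",
    "BoltzmannFit",
    "CalciumCalibration",
    "CalciumTrace",
    "SoceSummary",
    "RatioImage",
    "RatioCalibration",
    "ExpressionMatrix",
    "SyntheticTruth",
]


class DomainError(ValueError):
    """Invalid input for a quantification operation."""


@dataclass(frozen=True)
class FretCalibration:
    """Three-cube FRET calibration: bleed-through slopes and G factor.

    ``a`` is the acceptor bleed-through into the FRET channel (slope of
    I_DA on I_AA over acceptor-only cells), ``d`` the donor bleed-through
    (slope of I_DA on I_DD over donor-only cells), and ``g`` the
    sensitized-emission-to-donor-dequenching conversion factor from
    complete acceptor photobleaching.
    """

    a: float
    d: float
    g: float

    def __post_init__(self) -> None:
        for name in ("a", "d", "g"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"FretCalibration.{name} must be finite, got {v!r}")
        if self.a < 0 or self.d < 0:
            raise DomainError("bleed-through coefficients a, d must be >= 0")
        if self.g <= 0:
            raise DomainError("G factor must be > 0")

    def to_dict(self) -> dict:
        return {"a": self.a, "d": self.d, "G": self.g}

    @classmethod
    def from_dict(cls, d: dict) -> "FretCalibration":
        return cls(a=float(d["a"]), d=float(d["d"]), g=float(d["G"]))


@dataclass
class FretTrace:
    """Single-cell FRET efficiency time course around a stimulus."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # efficiency, dimensionless
    stim_time: float  # seconds

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise DomainError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("trace values must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann sigmoid fit f(t) = bottom + (top-bottom)/(1+exp((v50-t)/slope)).

    ``v50`` is the time-to-half-maximum measured from the stimulus; ``top``
    the plateau (maximum FRET efficiency); ``rss`` the residual sum of
    squares of the accepted fit.
    """

    bottom: float
    top: float
    v50: float
    slope: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + np.exp((self.v50 - t) / self.slope)
        )


@dataclass(frozen=True)
class CalciumCalibration:
    """Fluo-4 single-wavelength calibration bounds.

    Kd defaults to 345 nM, the fluo-4/Ca2+ dissociation constant used for
    plate-reader calibration; Fmax is the ionomycin/digitonin-saturated
    fluorescence, Fmin the dye-free background at matched cell density.
    """

    fmin: float
    fmax: float
    kd: float = 345.0  # nM

    def __post_init__(self) -> None:
        if not (self.fmin < self.fmax):
            raise DomainError(f"Fmin ({self.fmin}) must be < Fmax ({self.fmax})")
        if self.kd <= 0:
            raise DomainError("Kd must be > 0")


@dataclass
class CalciumTrace:
    """Well fluorescence time course with stimulus-event markers.

    ``events`` maps event names (``tg_add``, ``ca_add``, ``digitonin_add``)
    to times in seconds; ``tg_add`` and ``digitonin_add`` are optional
    (control wells have no TG, imaging wells no digitonin).
    """

    times: np.ndarray
    f: np.ndarray
    events: dict
    well_id: str = "well"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.times.shape != self.f.shape or self.times.ndim != 1:
            raise DomainError("times and F must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")
        t0, t1 = self.times[0], self.times[-1]
        ordered = [self.events.get(k) for k in ("tg_add", "ca_add", "digitonin_add")]
        present = [t for t in ordered if t is not None]
        for t in present:
            if not (t0 <= t <= t1):
                raise DomainError(f"event time {t} outside trace span [{t0}, {t1}]")
        if any(b <= a for a, b in zip(present, present[1:])):
            raise DomainError(
                "event times must be ordered tg_add < ca_add < digitonin_add"
            )


@dataclass
class SoceSummary:
    """SOCE decomposition of a paired TG/control well.

    ``soce`` is always ``total_entry - constitutive_entry``; ``auc_tg`` the
    trapezoidal area of the store-release transient in Ca2+-free medium.
    """

    auc_tg: float  # a.u. * s
    total_entry: float  # a.u.
    constitutive_entry: float  # a.u.
    soce: float  # a.u.
    influx_percent: Optional[float] = None  # % of caller-supplied reference


@dataclass
class RatioImage:
    """Cytosol-normalized 2-D ratio grid with labeled phagosome masks.

    ``labels`` is an integer image of the same shape: 0 outside phagosomes,
    1..n inside phagosome n. ``cytosol_mask`` marks cytosolic pixels used
    for normalization diagnostics.
    """

    ratio: np.ndarray
    labels: np.ndarray
    cytosol_mask: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.cytosol_mask = np.asarray(self.cytosol_mask, dtype=bool)
        if self.ratio.ndim != 2:
            raise DomainError("ratio must be a 2-D grid")
        if self.labels.shape != self.ratio.shape or self.cytosol_mask.shape != self.ratio.shape:
            raise DomainError("labels and cytosol_mask must match ratio shape")
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio < 0):
            raise DomainError("ratio grid must be finite and >= 0")
        if not self.cytosol_mask.any():
            raise DomainError("cytosol mask is empty")

    @property
    def n_phagosomes(self) -> int:
        return int(self.labels.max())


@dataclass
class RatioCalibration:
    """Ratiometric pH calibration: per-level mean ratios plus sigmoid fit."""

    levels: np.ndarray  # pH
    mean_ratios: np.ndarray
    bottom: float
    top: float
    ph50: float
    slope: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, ph: np.ndarray) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + np.exp((self.ph50 - ph) / self.slope)
        )


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with a two-group design.

    ``values``: DataFrame indexed by probe_id with sample_id columns;
    ``groups``: mapping sample_id -> group label (exactly two groups,
    >= 2 samples each).
    """

    values: pd.DataFrame
    groups: dict

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise DomainError("expression matrix contains missing intensities")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise DomainError(f"samples without group assignment: {sorted(missing)}")
        labels = sorted({self.groups[s] for s in self.values.columns})
        if len(labels) != 2:
            raise DomainError(f"expected exactly 2 groups, got {labels}")
        for g in labels:
            n = sum(1 for s in self.values.columns if self.groups[s] == g)
            if n < 2:
                raise DomainError(f"group {g!r} has {n} samples; >= 2 required")

    @property
    def group_labels(self) -> list:
        return sorted({self.groups[s] for s in self.values.columns})

    def samples_in(self, group: str) -> list:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class SyntheticTruth:
    """Ground-truth record attached to every synthetic dataset."""

    generator_name: str
    seed: int
    params: dict

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "generator_name": self.generator_name,
            "seed": int(self.seed),
            "params": {k: _clean(v) for k, v in self.params.items()},
        }
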