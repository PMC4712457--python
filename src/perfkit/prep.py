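"""Signal preparation: baseline, normalization, trimming, ROI curves, AIF.

Raw dynamic MRI signal is converted to an analyzable concentration surrogate
in four steps: (1) estimate the pre-contrast baseline S0 as the mean of the
first ``baseline_n`` time points; (2) normalize, by default as relative
enhancement (S - S0)/S0; (3) optionally trim the time series and restrict the
slice range; (4) average curves over an ROI.  An arterial ROI yields the
blood concentration c_a,b, which is converted to the plasma concentration
c_a = c_a,b / (1 - Hct_a) with the arterial haematocrit (default 0.45).

ROI curves are computed by averaging the enclosed voxels' signal first and
normalizing the averaged curve (the per-voxel alternative is noted in the
methods documentation).  All time and slice indices are 0-based; ranges are
inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import TimeGrid, TimeSeriesCurve
from .errors import ConfigError, NormalizationError, RoiError
from .volume import Dynamic4D

NORMALIZATION_MODES = ("relative_enhancement", "subtraction", "none")


@dataclass
class PrepConfig:
    """Signal-preparation settings.

    Parameters
    ----------
    normalization : {"relative_enhancement", "subtraction", "none"}
        Signal-to-concentration-surrogate transform.
    baseline_n : int
        Number of leading time points averaged into the baseline S0 (>= 1).
    trim : (first, last) or None
        Inclusive 0-based time-point window; None keeps the full series.
    slice_range : (first, last) or None
        Inclusive 0-based slice window; None keeps all slices.
    hct_a : float
        Arterial haematocrit fraction in [0, 1); 0.45 is the customary
        standard value when no subject-specific measurement exists.
    hct_t : float
        Tissue-blood haematocrit; carried for completeness, used in no
        computation.
    """

    normalization: str = "relative_enhancement"
    baseline_n: int = 1
    trim: tuple[int, int] | None = None
    slice_range: tuple[int, int] | None = None
    hct_a: float = 0.45
    hct_t: float = 0.25

    def __post_init__(self):
        if self.normalization not in NORMALIZATION_MODES:
            raise ConfigError(
                f"unknown normalization {self.normalization!r}; choose from {NORMALIZATION_MODES}"
            )
        if int(self.baseline_n) < 1:
            raise ConfigError("baseline_n must be >= 1")
        self.baseline_n = int(self.baseline_n)
        if not (0.0 <= self.hct_a < 1.0):
            raise ConfigError(f"hct_a must lie in [0, 1), got {self.hct_a}")
        for name in ("trim", "slice_range"):
            rng = getattr(self, name)
            if rng is not None:
                first, last = int(rng[0]), int(rng[1])
                if first < 0 or last < first:
                    raise ConfigError(f"{name} must satisfy 0 <= first <= last, got {rng}")
                setattr(self, name, (first, last))

    def to_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "baseline_n": self.baseline_n,
            "trim": list(self.trim) if self.trim else None,
            "slice_range": list(self.slice_range) if self.slice_range else None,
            "hct_a": self.hct_a,
            "hct_t": self.hct_t,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrepConfig":
        kw = dict(d)
        for name in ("trim", "slice_range"):
            if kw.get(name) is not None:
                kw[name] = tuple(kw[name])
        return cls(**kw)


@dataclass
class RoiMask:
    """A 2D region on one slice, as a boolean mask or rectangle corners."""

    label: str
    slice_index: int
    mask: np.ndarray | None = None
    rect: tuple[int, int, int, int] | None = None  # x0, y0, x1, y1 inclusive
    voxel_count: int = field(init=False, default=0)

    def resolve(self, shape_xy: tuple[int, int]) -> np.ndarray:
        """Boolean mask of shape (nx, ny); validates bounds and non-emptiness."""
        nx, ny = shape_xy
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (nx, ny):
                raise RoiError(
                    f"ROI {self.label!r}: mask shape {m.shape} does not match image {(nx, ny)}"
                )
        elif self.rect is not None:
            x0, y0, x1, y1 = self.rect
            if not (0 <= x0 <= x1 < nx and 0 <= y0 <= y1 < ny):
                raise RoiError(f"ROI {self.label!r}: rectangle {self.rect} outside image {(nx, ny)}")
            m = np.zeros((nx, ny), dtype=bool)
            m[x0 : x1 + 1, y0 : y1 + 1] = True
        else:
            raise RoiError(f"ROI {self.label!r}: neither mask nor rectangle given")
        if not m.any():
            raise RoiError(f"ROI {self.label!r} is empty")
        self.voxel_count = int(m.sum())
        return m


def baseline_value(curve: TimeSeriesCurve, baseline_n: int) -> float:
    """Mean of the first ``baseline_n`` samples (the pre-contrast signal S0)."""
    n = curve.grid.n
    if not (1 <= baseline_n <= n):
        raise ConfigError(f"baseline_n must be in [1, {n}], got {baseline_n}")
    return float(np.mean(curve.values[: int(baseline_n)]))


def normalize(curve: TimeSeriesCurve, s0: float, mode: str) -> TimeSeriesCurve:
    """Apply the chosen signal normalization against baseline ``s0``."""
    if mode == "relative_enhancement":
        if s0 <= 0:
            raise NormalizationError(
                f"relative enhancement needs a positive baseline, got S0={s0}"
            )
        return curve.with_values((curve.values - s0) / s0)
    if mode == "subtraction":
        return curve.with_values(curve.values - s0)
    if mode == "none":
        return curve
    raise ConfigError(f"unknown normalization mode {mode!r}")


def prepare_curve(curve: TimeSeriesCurve, config: PrepConfig) -> TimeSeriesCurve:
    """Baseline estimation + normalization with the curve's own S0."""
    s0 = baseline_value(curve, config.baseline_n)
    return normalize(curve, s0, config.normalization)


def roi_mean_curve(volume: Dynamic4D, roi: RoiMask) -> TimeSeriesCurve:
    """Per-time-point mean of the signal over the ROI's voxels.

    The enclosed voxel count is recorded on the ROI for the report.
    """
    nx, ny, nz, _ = volume.shape
    if not (0 <= roi.slice_index < nz):
        raise RoiError(f"ROI {roi.label!r}: slice {roi.slice_index} outside [0, {nz - 1}]")
    m = roi.resolve((nx, ny))
    vals = volume.data[:, :, roi.slice_index, :][m].mean(axis=0)
    return TimeSeriesCurve(volume.grid, vals, label=roi.label)


def blood_to_plasma(aif_blood: TimeSeriesCurve, hct_a: float) -> TimeSeriesCurve:
    """Convert an arterial blood curve to plasma: c_a = c_a,b / (1 - Hct_a)."""
    if not (0.0 <= hct_a < 1.0):
        raise ConfigError(f"hct_a must lie in [0, 1), got {hct_a}")
    return aif_blood.with_values(aif_blood.values / (1.0 - hct_a))


def trim_and_slice(volume: Dynamic4D, config: PrepConfig) -> Dynamic4D:
    """Crop the time window and slice range; the time vector is re-zeroed."""
    nx, ny, nz, nt = volume.shape
    t0, t1 = config.trim if config.trim is not None else (0, nt - 1)
    z0, z1 = config.slice_range if config.slice_range is not None else (0, nz - 1)
    if t1 >= nt:
        raise ConfigError(f"trim {config.trim} exceeds {nt} time points")
    if z1 >= nz:
        raise ConfigError(f"slice_range {config.slice_range} exceeds {nz} slices")
    if t1 - t0 + 1 < 3:
        raise ConfigError("trim window must keep at least 3 time points")
    data = volume.data[:, :, z0 : z1 + 1, t0 : t1 + 1]
    grid = TimeGrid(volume.grid.t[t0 : t1 + 1]).rezeroed()
    meta = dict(volume.meta)
    meta["trim"] = [t0, t1]
    meta["slice_range"] = [z0, z1]
    return Dynamic4D(data.copy(), grid, volume.spacing, meta)
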