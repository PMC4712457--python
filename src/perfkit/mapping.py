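"""Voxelwise parametric mapping inside a rectangular bounding box.

Map mode fits the chosen model independently to every voxel curve inside a
user-supplied rectangle propagated through the slice stack.  Each voxel is
normalized against its own leading-sample baseline, so the semantics match
ROI mode applied voxelwise.  Outputs are one 3D map per display parameter of
the model plus chi-square and AICc maps and a convergence mask.

Voxels outside the box carry NaN; voxels inside the box whose fit fails
(e.g. an all-zero background voxel with relative-enhancement normalization)
are recorded as unconverged with zero-valued parameters, keeping every
in-box map value finite.  Fits are independent per voxel, so results do not
depend on evaluation order or chunking.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigError, PerfkitError
from .fitting import FitConfig, aicc, fit_curve, ranking_chi2_floor, resolve_aif
from .kinetics import MODELS
from .prep import PrepConfig, prepare_curve
from .volume import Dynamic4D


@dataclass
class BoundingBox:
    """Inclusive rectangle (x0, y0, x1, y1) propagated through all slices."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x0 > self.x1 or self.y0 > self.y1 or self.x0 < 0 or self.y0 < 0:
            raise ConfigError(f"malformed bounding box {self}")

    def validate(self, shape_xy: tuple[int, int]) -> None:
        nx, ny = shape_xy
        if self.x1 >= nx or self.y1 >= ny:
            raise ConfigError(f"bounding box {self} outside image {(nx, ny)}")

    def to_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass
class ParametricMapSet:
    """One 3D map per output parameter, plus goodness-of-fit maps."""

    model: str
    maps: dict[str, np.ndarray]
    chi2_map: np.ndarray
    aicc_map: np.ndarray
    converged_mask: np.ndarray
    bbox: BoundingBox
    units: dict[str, str] = field(default_factory=dict)

    def map_names(self) -> list[str]:
        return list(self.maps)


class VoxelwiseMapper(BaseEstimator):
    """Fit a kinetic model voxelwise inside a bounding box.

    Parameters mirror :class:`~perfkit.fitting.KineticCurveFit` at the
    analysis level: a model name, the preparation settings applied per voxel,
    and the shared fit configuration.

    Attributes
    ----------
    maps_ : ParametricMapSet
        Parametric, chi-square and AICc maps plus the convergence mask.
    """

    def __init__(self, model: str = "2CXM", bbox: BoundingBox | tuple | None = None,
                 prep: PrepConfig | None = None, fit_config: FitConfig | None = None):
        self.model = model
        self.bbox = bbox
        self.prep = prep
        self.fit_config = fit_config

    def fit(self, volume: Dynamic4D, aif) -> "VoxelwiseMapper":
        self.maps_ = fit_maps(
            volume,
            self.bbox,
            self.model,
            aif,
            self.prep or PrepConfig(),
            self.fit_config or FitConfig(),
        )
        return self

    def transform(self, volume: Dynamic4D | None = None) -> dict[str, np.ndarray]:
        if not hasattr(self, "maps_"):
            raise ConfigError("mapper is not fitted yet")
        return self.maps_.maps


def _as_bbox(bbox) -> BoundingBox:
    if isinstance(bbox, BoundingBox):
        return bbox
    if bbox is None:
        raise ConfigError("map mode requires a rectangular bounding box")
    return BoundingBox(*bbox)


def fit_maps(volume: Dynamic4D, bbox, model: str, aif,
             prep: PrepConfig | None = None,
             fit_config: FitConfig | None = None) -> ParametricMapSet:
    """Voxelwise fit of one model inside the propagated bounding box."""
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}")
    prep = prep or PrepConfig()
    fit_config = fit_config or FitConfig()
    box = _as_bbox(bbox)
    nx, ny, nz, _ = volume.shape
    box.validate((nx, ny))
    aif_curve = resolve_aif(volume, aif, prep)

    # the map layout (parameter names/units) follows the model's output row
    from .kinetics import derive_parameters

    layout = derive_parameters(model, fit_config.params_for(model))
    names = list(layout.values)
    units = dict(layout.units)

    shape3 = (nx, ny, nz)
    maps = {n: np.full(shape3, np.nan) for n in names}
    chi2_map = np.full(shape3, np.nan)
    aicc_map = np.full(shape3, np.nan)
    converged = np.zeros(shape3, dtype=bool)

    for z in range(nz):
        for x in range(box.x0, box.x1 + 1):
            for y in range(box.y0, box.y1 + 1):
                curve = volume.voxel_curve(x, y, z)
                try:
                    tissue = prepare_curve(curve, prep)
                    r = fit_curve(model, tissue, aif_curve, fit_config)
                except PerfkitError:
                    for n in names:
                        maps[n][x, y, z] = 0.0
                    chi2_map[x, y, z] = 0.0
                    aicc_map[x, y, z] = np.nan
                    continue
                for n in names:
                    v = r.derived.values[n]
                    maps[n][x, y, z] = v if math.isfinite(v) else 0.0
                chi2_map[x, y, z] = r.chi2
                aicc_map[x, y, z] = r.aicc
                converged[x, y, z] = r.converged
    return ParametricMapSet(model=model, maps=maps, chi2_map=chi2_map,
                            aicc_map=aicc_map, converged_mask=converged,
                            bbox=box, units=units)


def compare_models_maps(volume: Dynamic4D, bbox, models, aif,
                        prep: PrepConfig | None = None,
                        fit_config: FitConfig | None = None):
    """Per-model map sets plus a per-voxel best-model label map.

    The label map holds the index (into ``models``) of the AICc-minimizing
    model per voxel, with the same numerical-floor tie-break as ROI-mode
    model comparison: equal fits go to the model with fewer free parameters,
    then to model-name order.  Voxels outside the box are -1.
    """
    models = list(models)
    if len(models) < 2:
        raise ConfigError("model comparison needs at least 2 models")
    prep = prep or PrepConfig()
    fit_config = fit_config or FitConfig()
    box = _as_bbox(bbox)
    map_sets = {m: fit_maps(volume, box, m, aif, prep, fit_config) for m in models}

    nx, ny, nz, _ = volume.shape
    label = np.full((nx, ny, nz), -1, dtype=int)
    k_free = {m: fit_config.params_for(m).n_free for m in models}

    for z in range(nz):
        for x in range(box.x0, box.x1 + 1):
            for y in range(box.y0, box.y1 + 1):
                try:
                    tissue = prepare_curve(volume.voxel_curve(x, y, z), prep)
                    floor = ranking_chi2_floor(tissue.values)
                except PerfkitError:
                    floor = 0.0
                best = None
                for idx, m in enumerate(models):
                    chi2 = map_sets[m].chi2_map[x, y, z]
                    k = k_free[m]
                    n = volume.grid.n
                    a = aicc(max(chi2, floor), n, k) if math.isfinite(chi2) else float("inf")
                    if math.isnan(a):
                        a = float("inf")
                    key = (a, k, m)
                    if best is None or key < best[0]:
                        best = (key, idx)
                label[x, y, z] = best[1]
    return map_sets, label
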