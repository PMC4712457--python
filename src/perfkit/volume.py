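"""4D dynamic volume container shared by I/O, preparation and mapping."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import TimeGrid, TimeSeriesCurve
from .errors import GridError


@dataclass
class Dynamic4D:
    """A dynamic series: voxel array (x, y, slice, time) plus its time vector.

    ``meta`` records provenance -- vendor dialect, the DICOM tags actually
    used for timing, spatial spacing -- and travels into the analysis report.
    """

    data: np.ndarray
    grid: TimeGrid
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise GridError(f"expected a 4D (x, y, slice, time) array, got ndim={self.data.ndim}")
        if self.data.shape[3] != self.grid.n:
            raise GridError(
                f"array has {self.data.shape[3]} time points but grid has {self.grid.n}"
            )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def voxel_curve(self, x: int, y: int, z: int) -> TimeSeriesCurve:
        return TimeSeriesCurve(self.grid, self.data[x, y, z, :], label=f"voxel ({x},{y},{z})")
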