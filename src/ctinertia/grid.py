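"""In-memory volume containers.

A :class:`VoxelGrid` is the single representation of a CT volume used by
every stage: a rank-3 array of scanner grey-values (or, after calibration,
densities) with anisotropic voxel spacing and a world origin, both in
millimetres. Array axes are ordered ``(slice, row, col)``; anatomical
meaning is assigned by the user (via axis specifications or a board-plane
fit), never assumed from scan orientation.

Voxel *centers* carry the material: the world position of the center of
voxel ``(i, j, k)`` is ``origin + (index + 1/2) * spacing``. Centering makes
discretised mass/inertia integrals second-order accurate in voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DimensionMismatchError


@dataclass
class VoxelGrid:
    """A 3D scalar volume with voxel geometry.

    Parameters
    ----------
    values
        Rank-3 array, axis order ``(slice, row, col)``. Grey-values in
        scanner units, or densities (kg m^-3) after calibration.
    spacing
        Millimetres per voxel along each array axis; strictly positive.
    origin
        World position (mm) of the *corner* of voxel ``(0, 0, 0)``.
    axis_labels
        Names for the three array axes, recording anatomical correspondence
        where known.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    axis_labels: tuple = ("slice", "row", "col")

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionMismatchError(
                f"volume must be rank 3, got rank {self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise DimensionMismatchError("all three dimensions must be >= 1")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis_labels = tuple(self.axis_labels)
        if len(self.axis_labels) != 3:
            raise ValueError("axis_labels must name exactly three axes")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel *centers* for integer indices.

        Accepts a single index triple or an ``(n, 3)`` array.
        """
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx + 0.5) * self.spacing

    def world_to_index(self, world) -> np.ndarray:
        """Integer voxel index containing a world point (mm); inverse of
        :meth:`index_to_world` on voxel centers."""
        w = np.asarray(world, dtype=float)
        return np.floor((w - self.origin) / self.spacing).astype(np.int64)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Center coordinates (mm, world) of all voxels along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """Same geometry, different values (e.g. grey -> density)."""
        if np.shape(values) != self.values.shape:
            raise DimensionMismatchError("replacement values must match grid shape")
        return VoxelGrid(
            values=np.asarray(values),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            axis_labels=self.axis_labels,
        )


@dataclass
class LabelVolume:
    """Integer segment labels for virtual dissection.

    Label 0 is reserved for background/unassigned; every nonzero label in
    ``labels`` must be named in ``segment_names``.
    """

    labels: np.ndarray
    segment_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionMismatchError("label volume must be rank 3")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.segment_names = dict(self.segment_names)
        if 0 in self.segment_names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.segment_names)
        if missing:
            raise ValueError(f"labels present but unnamed: {sorted(missing)}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def check_companion(self, grid: VoxelGrid) -> None:
        if self.labels.shape != grid.values.shape:
            raise DimensionMismatchError(
                f"label shape {self.labels.shape} != grid shape {grid.values.shape}"
            )

    def name_of(self, label: int) -> str:
        if label == 0:
            return "unassigned"
        return self.segment_names[label]
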