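"""Grey-value to density calibration.

A CT scanner reports each voxel as a grey-value proportional to X-ray
attenuation. Scanning tissue-characterisation phantom rods of known density
(plus a region of air) alongside the specimen gives a set of
(mean grey-value, known density) pairs; an ordinary least-squares line
through them converts the whole volume to absolute density (kg m^-3).
Because fields of view and scanner state vary, the calibration is per-scan:
a fit from one scan must not be reused on another.

Two convenience maps for working in Hounsfield units are included:
``HU = 1000 (mu - mu_water) / mu_water`` from attenuation coefficients, and
the uncalibrated approximation ``rho = HU + 1000`` anchored at water
(0 HU -> 1000 kg m^-3) and air (-1000 HU -> 0 kg m^-3). Both are affine, so
a calibration fitted on raw grey-values and one fitted on HU are equivalent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import AIR_DENSITY, fsum
from .errors import DegenerateFitError, DomainError, EmptyRoiError, InsufficientDataError
from .grid import VoxelGrid

__all__ = [
    "PhantomSample",
    "DensityCalibration",
    "RoiSpec",
    "sample_phantom",
    "fit_calibration",
    "hounsfield_from_attenuation",
    "density_from_hu",
    "apply_calibration",
    "AIR_DENSITY",
]


@dataclass
class PhantomSample:
    """Mean grey-value of one calibration material of known density."""

    name: str
    known_density: float  # kg m^-3
    mean_grey: float  # scanner units
    n_voxels: int

    def __post_init__(self):
        if self.known_density < 0:
            raise ValueError("known_density must be >= 0")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass
class RoiSpec:
    """An elliptical region of interest on one plane of the stack.

    ``plane_fraction`` in (0, 1) selects the slice along the designated
    plane axis (e.g. 0.25/0.50/0.75 for the quarter planes of a rod).
    ``center`` and ``semi_axes`` are in-plane world mm; ``rotation`` rotates
    the ellipse axes by the given angle (radians) in the plane.
    """

    plane_fraction: float
    center: tuple  # (mm, mm) along the two in-plane axes
    semi_axes: tuple  # (mm, mm), strictly positive
    rotation: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.plane_fraction < 1.0:
            raise ValueError("plane_fraction must lie in (0, 1)")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be strictly positive")

    def slice_index(self, n_slices: int) -> int:
        # floor(f*n) maps (0,1) onto valid indices 0..n-1
        return min(int(self.plane_fraction * n_slices), n_slices - 1)


@dataclass
class DensityCalibration:
    """Linear grey -> density map: ``rho = slope * grey + intercept``."""

    slope: float  # kg m^-3 per grey unit
    intercept: float  # kg m^-3
    r_squared: float
    samples: list = field(default_factory=list)

    def __post_init__(self):
        if not self.slope > 0:
            raise DegenerateFitError(
                f"calibration slope must be positive (denser material attenuates "
                f"more), got {self.slope}"
            )
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, grey):
        """Density (kg m^-3) for grey-values (scalar or array)."""
        return self.slope * np.asarray(grey, dtype=float) + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "samples": [
                {
                    "name": s.name,
                    "known_density": s.known_density,
                    "mean_grey": s.mean_grey,
                    "n_voxels": s.n_voxels,
                }
                for s in self.samples
            ],
        }
        with open(Path(path), "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DensityCalibration":
        with open(Path(path)) as fh:
            d = json.load(fh)
        samples = [PhantomSample(**s) for s in d["samples"]]
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            samples=samples,
        )


def _roi_voxel_values(grid: VoxelGrid, roi: RoiSpec, plane_axis: int) -> np.ndarray:
    """Grey-values of voxels whose centers fall strictly inside the ellipse."""
    in_plane = [ax for ax in range(3) if ax != plane_axis]
    u = grid.axis_centers(in_plane[0])
    v = grid.axis_centers(in_plane[1])
    uu, vv = np.meshgrid(u, v, indexing="ij")
    du = uu - roi.center[0]
    dv = vv - roi.center[1]
    c, s = np.cos(roi.rotation), np.sin(roi.rotation)
    # coordinates in the ellipse frame
    pu = c * du + s * dv
    pv = -s * du + c * dv
    inside = (pu / roi.semi_axes[0]) ** 2 + (pv / roi.semi_axes[1]) ** 2 < 1.0

    k = roi.slice_index(grid.values.shape[plane_axis])
    plane = np.take(grid.values, k, axis=plane_axis)
    return np.asarray(plane, dtype=float)[inside]


def sample_phantom(
    grid: VoxelGrid,
    rois: Sequence[RoiSpec],
    known_density: float,
    name: str,
    plane_axis: int = 0,
) -> PhantomSample:
    """Pool the grey-values inside elliptical ROIs (one per sampling plane).

    Voxel membership is by the strict voxel-center-inside-ellipse test:
    partially covered boundary voxels are excluded, avoiding partial-volume
    contamination of the phantom mean. Values from all planes are pooled
    into a single mean.
    """
    if not rois:
        raise EmptyRoiError(f"phantom '{name}': no ROIs supplied")
    pools = []
    for i, roi in enumerate(rois):
        vals = _roi_voxel_values(grid, roi, plane_axis)
        if vals.size == 0:
            raise EmptyRoiError(
                f"phantom '{name}': ROI {i} (plane_fraction={roi.plane_fraction}) "
                f"contains no voxel centers"
            )
        pools.append(vals)
    pooled = np.concatenate(pools)
    return PhantomSample(
        name=name,
        known_density=float(known_density),
        mean_grey=fsum(pooled) / pooled.size,
        n_voxels=int(pooled.size),
    )


def fit_calibration(
    samples: Sequence[PhantomSample],
    air_sample: PhantomSample | None = None,
) -> DensityCalibration:
    """Ordinary least squares of known density on mean grey-value.

    The regression direction matches how the calibration is applied (density
    predicted from the measured grey); samples are unweighted. Passing
    ``air_sample`` adds the air region as a true calibration point at its
    physical density (~1.2 kg m^-3 at room conditions, not 0).
    """
    pts = list(samples)
    if air_sample is not None:
        pts = pts + [air_sample]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need at least 2 phantom samples to fit a line, got {len(pts)}"
        )
    grey = np.array([s.mean_grey for s in pts], dtype=float)
    dens = np.array([s.known_density for s in pts], dtype=float)
    if np.ptp(grey) == 0:
        raise DegenerateFitError("all samples share one grey-value; fit is degenerate")
    res = stats.linregress(grey, dens)
    if np.ptp(dens) == 0:
        r2 = 1.0  # perfectly flat data lie exactly on the fitted line
    else:
        r2 = float(res.rvalue) ** 2
    return DensityCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        samples=pts,
    )


def hounsfield_from_attenuation(mu_voxel, mu_water: float):
    """Hounsfield units from linear attenuation coefficients.

    ``HU = 1000 (mu_voxel - mu_water) / mu_water``: water defines 0 HU and
    vanishing attenuation (air) -1000 HU.
    """
    if not mu_water > 0:
        raise DomainError(f"mu_water must be positive, got {mu_water}")
    return 1000.0 * (np.asarray(mu_voxel, dtype=float) - mu_water) / mu_water


def density_from_hu(hu):
    """Uncalibrated HU -> density approximation for biological material.

    Linear through the two physical anchors: water (0 HU -> 1000 kg m^-3)
    and air (-1000 HU -> 0 kg m^-3), extrapolated beyond them.
    """
    return np.asarray(hu, dtype=float) + 1000.0


def apply_calibration(grid: VoxelGrid, cal: DensityCalibration) -> VoxelGrid:
    """Map a grey-value volume to a density volume (kg m^-3), same geometry."""
    return grid.with_values(cal.predict(grid.values))
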