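"""Reading and writing volumes and result reports.

CT volumes arrive either as an ordered multi-file TIFF stack (one 2D image
per slice, 16-bit, uncompressed) with spacing supplied by the user, or as a
DICOM series whose geometry is taken from the headers. Results leave as a
JSON report (machine-readable, full double precision) plus a CSV segment
table. Label volumes round-trip as integer TIFF stacks.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    AmbiguousSeriesError,
    DimensionMismatchError,
    EmptyInputError,
    MetadataError,
)
from .grid import LabelVolume, VoxelGrid

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_dicom_series",
    "read_label_stack",
    "write_label_stack",
    "write_results",
    "read_results",
]


def read_tiff_stack(paths: Sequence, spacing, origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    """Read an ordered list of single-slice TIFF files into a volume.

    Slice order follows the order of ``paths`` (axis 0 of the result).
    Grey-values are preserved bit-exactly; ``spacing`` and ``origin`` are in
    mm, axis order ``(slice, row, col)``.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise EmptyInputError("no TIFF paths given")
    slices = []
    for p in paths:
        img = tifffile.imread(p)
        if img.ndim != 2:
            raise DimensionMismatchError(f"{p} is not a single 2D slice (ndim={img.ndim})")
        if slices and img.shape != slices[0].shape:
            raise DimensionMismatchError(
                f"slice {p} has shape {img.shape}, expected {slices[0].shape}"
            )
        if slices and img.dtype != slices[0].dtype:
            raise DimensionMismatchError(
                f"slice {p} has dtype {img.dtype}, expected {slices[0].dtype}"
            )
        slices.append(img)
    return VoxelGrid(values=np.stack(slices, axis=0), spacing=spacing, origin=origin)


def write_tiff_stack(grid: VoxelGrid, directory, prefix: str = "slice") -> list:
    """Write a volume as one uncompressed TIFF per slice; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    n = grid.values.shape[0]
    width = max(4, len(str(n)))
    for i in range(n):
        p = directory / f"{prefix}_{i:0{width}d}.tif"
        tifffile.imwrite(p, grid.values[i])
        paths.append(p)
    return paths


def _is_dicom(path: Path) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_dicom_series(directory) -> VoxelGrid:
    """Read one coherent DICOM series from a directory.

    Slices are sorted by their position along the slice direction (image
    orientation normal), not by filename, and the rescale slope/intercept
    from the headers is applied so values are in the scanner's output units.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and _is_dicom(p))
    if not files:
        raise EmptyInputError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]

    series_uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series_uids) > 1:
        raise AmbiguousSeriesError(
            f"directory {directory} contains {len(series_uids)} series; expected one"
        )

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise MetadataError("DICOM series lacks PixelSpacing")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)

    # Sort by position projected on the slice normal; fall back to InstanceNumber.
    if hasattr(first, "ImagePositionPatient"):
        if hasattr(first, "ImageOrientationPatient"):
            iop = np.asarray([float(v) for v in first.ImageOrientationPatient])
            normal = np.cross(iop[:3], iop[3:])
        else:
            normal = np.array([0.0, 0.0, 1.0])
        keys = [
            float(np.dot(normal, [float(v) for v in ds.ImagePositionPatient]))
            for ds in datasets
        ]
    elif hasattr(first, "InstanceNumber"):
        keys = [int(ds.InstanceNumber) for ds in datasets]
    else:
        raise MetadataError("DICOM series lacks slice position information")
    order = np.argsort(keys)
    datasets = [datasets[i] for i in order]
    keys = [keys[i] for i in order]

    if len(datasets) > 1:
        slice_mm = float(np.median(np.diff(keys)))
        if slice_mm <= 0:
            raise MetadataError("could not determine positive slice separation")
    else:
        slice_mm = float(
            getattr(first, "SpacingBetweenSlices", getattr(first, "SliceThickness", 0))
        )
        if slice_mm <= 0:
            raise MetadataError("single slice with no SliceThickness/SpacingBetweenSlices")

    arrays = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
        if arr.shape != arrays[0].shape:
            raise DimensionMismatchError("DICOM slices disagree on shape")

    pos0 = np.asarray(
        [float(v) for v in getattr(datasets[0], "ImagePositionPatient", (0, 0, 0))]
    )
    # Origin is the voxel-(0,0,0) corner: header positions are pixel centers.
    spacing = (slice_mm, row_mm, col_mm)
    origin = (
        float(pos0[2]) - 0.5 * slice_mm,
        float(pos0[1]) - 0.5 * row_mm,
        float(pos0[0]) - 0.5 * col_mm,
    )
    return VoxelGrid(values=np.stack(arrays, axis=0), spacing=spacing, origin=origin)


def write_label_stack(labels: LabelVolume, directory, prefix: str = "label") -> list:
    """Write a label volume as integer TIFF slices plus a JSON name map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = VoxelGrid(labels.labels.astype(np.int32), spacing=(1, 1, 1))
    paths = write_tiff_stack(grid, directory, prefix=prefix)
    names_path = directory / f"{prefix}_names.json"
    with open(names_path, "w") as fh:
        json.dump({str(k): v for k, v in labels.segment_names.items()}, fh, indent=2)
    return paths


def read_label_stack(paths: Sequence, names_path) -> LabelVolume:
    grid = read_tiff_stack(paths, spacing=(1, 1, 1))
    with open(names_path) as fh:
        names = {int(k): v for k, v in json.load(fh).items()}
    return LabelVolume(labels=grid.values.astype(np.int64), segment_names=names)


def _props_to_dict(props) -> dict:
    return {
        "mass_kg": float(props.mass),
        "com_m": [float(v) for v in props.com],
        "origin_m": [float(v) for v in props.origin],
        "tensor_kg_m2": [[float(v) for v in row] for row in props.tensor],
        "principal_moments_kg_m2": [float(v) for v in props.principal_moments],
        "principal_axes_columns": [[float(v) for v in row] for row in props.principal_axes],
    }


def write_results(props, segments: pd.DataFrame | None, path) -> dict:
    """Write an inertial-properties report.

    ``path`` is the JSON report path; the segment table (if any) is written
    alongside as ``<stem>_segments.csv``. Floats are serialised at full
    double precision so a read-back reproduces them to better than 1e-12
    relative.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = {"inertial_properties": _props_to_dict(props)}
    if segments is None:
        segments = pd.DataFrame()
    csv_path = path.with_name(path.stem + "_segments.csv")
    segments.to_csv(csv_path, index=False)
    report["segments"] = segments.to_dict(orient="records")
    report["segment_table_csv"] = os.fspath(csv_path.name)
    try:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write report to {path}: {exc}") from exc
    return report


def read_results(path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
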