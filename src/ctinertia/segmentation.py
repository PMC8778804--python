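"""Specimen isolation and virtual dissection.

The specimen is separated from surrounding air (and scanner fixtures, via a
user-supplied exclusion mask) by grey-value thresholding. Rather than
picking the threshold by eye, it is optimised so that the calibrated total
mass of the retained voxels matches the specimen's balance-measured mass:
the mass-vs-threshold curve is non-increasing (raising the threshold only
removes non-negative voxel masses), so a bisection converges and the
residual mass error is bounded by the tolerance — by default 0.1 g, the
resolution of a laboratory balance.

Virtual dissection then splits the retained voxels by an integer label
volume (anatomical segments traced by the user) and reports per-segment
masses and fractions, with compensated sums so segment masses add up to the
total to within rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import fsum
from .calibration import DensityCalibration
from .errors import BracketError, DimensionMismatchError, DomainError
from .grid import LabelVolume, VoxelGrid
from .inertial import MassModel

__all__ = [
    "ThresholdResult",
    "apply_threshold",
    "optimise_threshold",
    "virtual_dissect",
]

#: Default mass tolerance for threshold optimisation: 0.1 g, the balance
#: resolution the measured target mass itself carries.
DEFAULT_MASS_TOLERANCE_KG = 1e-4


@dataclass
class ThresholdResult:
    """Outcome of mass-matched threshold optimisation."""

    threshold: float  # grey units
    estimated_mass: float  # kg
    target_mass: float  # kg
    mass_error: float  # kg, signed: estimated - target
    n_voxels_retained: int
    iterations: int
    monotone: bool = True  # certified non-increasing at every probed level

    def __post_init__(self):
        if abs(abs(self.mass_error) - abs(self.estimated_mass - self.target_mass)) > 1e-15:
            raise ValueError("mass_error inconsistent with estimated/target masses")


def apply_threshold(
    grid: VoxelGrid,
    threshold: float,
    exclusion_mask: np.ndarray | LabelVolume | None = None,
) -> np.ndarray:
    """Binary specimen mask: grey >= threshold and not excluded.

    ``exclusion_mask`` (boolean array or a label volume whose nonzero voxels
    are excluded) models the manual removal of scanner parts, mounting board
    and calibration phantoms. An empty result is permitted.
    """
    mask = np.asarray(grid.values) >= threshold
    if exclusion_mask is not None:
        if isinstance(exclusion_mask, LabelVolume):
            excl = exclusion_mask.labels != 0
        else:
            excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != mask.shape:
            raise DimensionMismatchError("exclusion mask shape must match grid shape")
        mask &= ~excl
    return mask


def _mass_at(values, cal, voxel_volume_m3, threshold, clamp_negative):
    """Fast (pairwise-summed) calibrated mass of voxels >= threshold."""
    rho = cal.predict(values[values >= threshold])
    if clamp_negative:
        rho = np.maximum(rho, 0.0)
    return float(rho.sum()) * voxel_volume_m3, int(rho.size)


def optimise_threshold(
    grid: VoxelGrid,
    cal: DensityCalibration,
    target_mass: float,
    bounds: tuple,
    tolerance: float = DEFAULT_MASS_TOLERANCE_KG,
    exclusion_mask: np.ndarray | LabelVolume | None = None,
    integer_levels: bool = True,
    clamp_negative: bool = True,
) -> ThresholdResult:
    """Bisection for the threshold whose calibrated mass matches the target.

    Preconditions: ``target_mass > 0`` and the target bracketed, i.e.
    mass(lower bound) >= target >= mass(upper bound). Bisection runs until
    ``|mass error| <= tolerance`` or the interval collapses to one
    representable grey level (one integer level by default); ties prefer the
    lower threshold. Monotonicity of the probed mass curve is certified as
    the search proceeds; a violation (possible only with negative calibrated
    densities left unclamped) triggers a warning and a fallback grid scan
    over integer levels choosing the minimum |mass error|.
    """
    if not target_mass > 0:
        raise DomainError("target_mass must be positive")
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise DomainError(f"bounds must be a nonempty interval, got {bounds}")
    if integer_levels:
        lo, hi = np.floor(lo), np.ceil(hi)

    if exclusion_mask is not None:
        keep = ~(
            exclusion_mask.labels != 0
            if isinstance(exclusion_mask, LabelVolume)
            else np.asarray(exclusion_mask, dtype=bool)
        )
        if keep.shape != grid.values.shape:
            raise DimensionMismatchError("exclusion mask shape must match grid shape")
        values = np.asarray(grid.values)[keep]
    else:
        values = np.asarray(grid.values).ravel()
    vvol = grid.voxel_volume_m3

    probed: dict[float, tuple] = {}

    def mass(thr):
        if thr not in probed:
            probed[thr] = _mass_at(values, cal, vvol, thr, clamp_negative)
        return probed[thr][0]

    m_lo, m_hi = mass(lo), mass(hi)
    iterations = 1  # the bracket evaluation counts as the first iteration
    if m_lo < target_mass - tolerance or m_hi > target_mass + tolerance:
        raise BracketError(
            f"target mass {target_mass:.6g} kg not bracketed: mass at lower "
            f"bound {lo:g} is {m_lo:.6g} kg, at upper bound {hi:g} is "
            f"{m_hi:.6g} kg"
        )

    # endpoint satisfaction (lower endpoint preferred on tie)
    best = lo if abs(m_lo - target_mass) <= abs(m_hi - target_mass) else hi
    if abs(mass(best) - target_mass) <= tolerance:
        thr = best
    else:
        min_step = 1.0 if integer_levels else 0.0
        while hi - lo > min_step and abs(hi - lo) > 1e-9 * max(abs(hi), 1.0):
            mid = 0.5 * (lo + hi)
            if integer_levels:
                mid = np.floor(mid)
                if mid <= lo:
                    break
            m_mid = mass(mid)
            iterations += 1
            if abs(m_mid - target_mass) <= tolerance:
                lo = hi = mid
                break
            if m_mid > target_mass:
                lo = mid
            else:
                hi = mid
        # interval collapsed: pick the endpoint with the smaller |error|,
        # lower threshold on ties
        if lo == hi:
            thr = lo
        else:
            thr = lo if abs(mass(lo) - target_mass) <= abs(mass(hi) - target_mass) else hi

    monotone = _certify_monotone(probed)
    if not monotone:
        warnings.warn(
            "mass-vs-threshold curve non-monotone at probed levels; falling back "
            "to a grid scan over integer grey levels",
            RuntimeWarning,
        )
        lo0, hi0 = np.floor(float(bounds[0])), np.ceil(float(bounds[1]))
        levels = np.arange(lo0, hi0 + 1.0)
        errs = [abs(mass(t) - target_mass) for t in levels]
        iterations += len(levels)
        thr = float(levels[int(np.argmin(errs))])

    est, n_vox = probed[thr]
    # definitive estimate with compensated summation
    rho = cal.predict(values[values >= thr])
    if clamp_negative:
        rho = np.maximum(rho, 0.0)
    est = fsum(rho) * vvol
    return ThresholdResult(
        threshold=float(thr),
        estimated_mass=est,
        target_mass=float(target_mass),
        mass_error=est - float(target_mass),
        n_voxels_retained=n_vox,
        iterations=iterations,
        monotone=monotone,
    )


def _certify_monotone(probed: dict) -> bool:
    thr = sorted(probed)
    masses = [probed[t][0] for t in thr]
    return all(masses[i] >= masses[i + 1] - 1e-12 for i in range(len(masses) - 1))


def virtual_dissect(model: MassModel, labels: LabelVolume) -> pd.DataFrame:
    """Per-segment mass table from a labelled mass model.

    Returns a DataFrame with columns ``segment, label, mass_kg,
    mass_fraction, n_voxels``; voxels labelled 0 appear as ``unassigned``.
    Per-segment masses are compensated sums, and the fraction denominator is
    the compensated sum of the segment masses, so the table conserves the
    total retained mass to rounding.
    """
    if model.indices is None:
        raise ValueError("mass model carries no voxel indices; rebuild with indices")
    if np.any(model.indices.max(axis=0) >= np.array(labels.shape)):
        raise DimensionMismatchError("label volume too small for model voxel indices")
    vox_labels = labels.labels[tuple(model.indices.T)]
    rows = []
    for lab in np.unique(vox_labels):
        sel = vox_labels == lab
        rows.append(
            {
                "segment": labels.name_of(int(lab)),
                "label": int(lab),
                "mass_kg": fsum(model.masses[sel]),
                "n_voxels": int(sel.sum()),
            }
        )
    df = pd.DataFrame(rows)
    total = fsum(df["mass_kg"].to_numpy())
    df["mass_fraction"] = df["mass_kg"] / total if total > 0 else 0.0
    return df[["segment", "label", "mass_kg", "mass_fraction", "n_voxels"]]
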