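"""Ground-truthed synthetic inputs.

No CT scan ships with this package, so every pipeline stage is exercised
against scenes whose mass properties are known in closed form: collections
of homogeneous primitives (cuboids, spheres, cylinders, ellipsoids, thin
plates) rasterised into a CT-like grey-value volume, with the grey scale an
affine map of density (the convention the calibration module fits) plus
seeded Gaussian noise. The analytic ground truth — total and per-label
mass, CoM and inertia tensor, composed by the parallel-axis theorem — is
computed from the primitives, never from voxels, so pipeline-vs-truth
discrepancies measure discretisation and noise, nothing else.

Scene geometry follows clinical scanner output: 512x512 slices separated by
1.25 mm with sub-millimetre in-plane pixels, tissue-characterisation rods
spanning 450-1820 kg m^-3, and a bird-like articulated specimen whose thin
distal wing plates make the MoI share of the hand wing far exceed its mass
share. A trifilar-pendulum trace simulator integrating the exact
(large-angle) equation of motion closes the loop for the pendulum module.

Rasterisation samples voxel centers only (no anti-aliasing): a voxel
belongs to the last-listed shape containing its center. Partial-volume
effects at material boundaries are therefore absent; see the methods note
for what that implies about feather-like structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._util import AIR_DENSITY, fsum
from .calibration import RoiSpec
from .errors import DomainError, LayoutError
from .grid import LabelVolume, VoxelGrid
from .pendulum import OscillationTrace, PendulumRig

__all__ = [
    "Shape",
    "SceneSpec",
    "GroundTruth",
    "rasterize_scene",
    "make_phantom_rods",
    "make_bird_like_scene",
    "simulate_pendulum_trace",
    "small_angle_period",
    "compose_inertia",
]

#: Densities (kg m^-3) of an eight-rod tissue-characterisation phantom set
#: spanning lung-equivalent to cortical-bone-equivalent materials.
PHANTOM_DENSITIES = (450.0, 920.0, 980.0, 1000.0, 1060.0, 1120.0, 1340.0, 1820.0)

_PRIMITIVES = ("cuboid", "plate", "sphere", "cylinder", "ellipsoid")


@dataclass
class Shape:
    """One homogeneous primitive.

    ``center`` is in metres, world axes ordered like the grid axes
    ``(slice, row, col)``. ``dims`` (m) depend on the primitive: full edge
    lengths for ``cuboid``/``plate``, ``(radius,)`` for ``sphere``,
    ``(radius, height)`` for ``cylinder`` (height along ``axis``), semi-axes
    for ``ellipsoid``. ``rotation`` (3x3, optional) poses the local frame in
    the world.
    """

    primitive: str
    center: tuple
    dims: tuple
    density: float
    label: int
    name: str = ""
    axis: int = 0
    rotation: np.ndarray | None = None

    def __post_init__(self):
        if self.primitive not in _PRIMITIVES:
            raise ValueError(f"unknown primitive {self.primitive!r}")
        self.center = tuple(float(c) for c in self.center)
        self.dims = tuple(float(d) for d in self.dims)
        if min(self.dims) <= 0:
            raise ValueError(f"shape {self.name!r}: degenerate dimensions {self.dims}")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)

    # ---- analytic properties -------------------------------------------
    @property
    def volume(self) -> float:
        if self.primitive in ("cuboid", "plate"):
            a, b, c = self.dims
            return a * b * c
        if self.primitive == "sphere":
            return 4.0 / 3.0 * np.pi * self.dims[0] ** 3
        if self.primitive == "cylinder":
            r, h = self.dims
            return np.pi * r**2 * h
        a, b, c = self.dims  # ellipsoid semi-axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def mass(self) -> float:
        return self.density * self.volume

    def tensor_about_com(self) -> np.ndarray:
        """Closed-form inertia tensor about the shape's CoM, world frame."""
        m = self.mass
        if self.primitive in ("cuboid", "plate"):
            a, b, c = self.dims
            local = m / 12.0 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        elif self.primitive == "sphere":
            local = 2.0 / 5.0 * m * self.dims[0] ** 2 * np.eye(3)
        elif self.primitive == "cylinder":
            r, h = self.dims
            perp = m * (3 * r * r + h * h) / 12.0
            diag = [perp, perp, perp]
            diag[self.axis] = m * r * r / 2.0
            local = np.diag(diag)
        else:  # ellipsoid
            a, b, c = self.dims
            local = m / 5.0 * np.diag([b * b + c * c, a * a + c * c, a * a + b * b])
        if self.rotation is not None:
            local = self.rotation @ local @ self.rotation.T
        return local

    # ---- rasterisation helpers -----------------------------------------
    def half_extent(self) -> np.ndarray:
        """Conservative world-frame half extent (m) for bounding boxes."""
        if self.primitive in ("cuboid", "plate"):
            h = np.asarray(self.dims) / 2.0
        elif self.primitive == "sphere":
            h = np.full(3, self.dims[0])
        elif self.primitive == "cylinder":
            r, length = self.dims
            h = np.full(3, r)
            h[self.axis] = length / 2.0
        else:
            h = np.asarray(self.dims, dtype=float)
        if self.rotation is not None:
            h = np.abs(self.rotation) @ h  # AABB of the rotated box
        return h

    def contains(self, p0, p1, p2) -> np.ndarray:
        """Membership test for broadcastable world coordinates (m)."""
        d0 = p0 - self.center[0]
        d1 = p1 - self.center[1]
        d2 = p2 - self.center[2]
        if self.rotation is not None:
            rt = self.rotation.T
            l0 = rt[0, 0] * d0 + rt[0, 1] * d1 + rt[0, 2] * d2
            l1 = rt[1, 0] * d0 + rt[1, 1] * d1 + rt[1, 2] * d2
            l2 = rt[2, 0] * d0 + rt[2, 1] * d1 + rt[2, 2] * d2
        else:
            l0, l1, l2 = d0, d1, d2
        if self.primitive in ("cuboid", "plate"):
            a, b, c = self.dims
            # half-open boxes make grid-aligned faces sample exactly
            return (
                (-a / 2 <= l0) & (l0 < a / 2)
                & (-b / 2 <= l1) & (l1 < b / 2)
                & (-c / 2 <= l2) & (l2 < c / 2)
            )
        if self.primitive == "sphere":
            return l0 * l0 + l1 * l1 + l2 * l2 <= self.dims[0] ** 2
        if self.primitive == "cylinder":
            r, h = self.dims
            axial = (l0, l1, l2)[self.axis]
            radial = [l0, l1, l2]
            radial.pop(self.axis)
            return (radial[0] ** 2 + radial[1] ** 2 <= r * r) & (
                np.abs(axial) <= h / 2
            )
        a, b, c = self.dims
        return (l0 / a) ** 2 + (l1 / b) ** 2 + (l2 / c) ** 2 <= 1.0


@dataclass
class SceneSpec:
    """A full synthetic study: shapes, grey scale, geometry, noise, seed."""

    shapes: list
    calibration_truth: tuple = (1.0, -1000.0)  # (slope, intercept): rho = s*G + i
    noise_sigma: float = 0.0  # grey units
    spacing: tuple = (1.25, 0.98, 0.98)  # mm
    volume_shape: tuple = (64, 512, 512)
    origin: tuple = (0.0, 0.0, 0.0)  # mm
    seed: int = 0

    def segment_names(self) -> dict:
        return {s.label: (s.name or f"label_{s.label}") for s in self.shapes}


def compose_inertia(parts):
    """Combine (mass, com, tensor_about_com) parts via the parallel axis.

    Returns the composite ``(mass, com, tensor_about_com)``; exact for
    disjoint bodies.
    """
    parts = list(parts)
    total = fsum([p[0] for p in parts])
    if total <= 0:
        return 0.0, np.zeros(3), np.zeros((3, 3))
    com = sum(p[0] * np.asarray(p[1], dtype=float) for p in parts) / total
    tensor = np.zeros((3, 3))
    for m, c, t in parts:
        d = np.asarray(c, dtype=float) - com
        tensor += np.asarray(t, dtype=float) + m * (float(d @ d) * np.eye(3) - np.outer(d, d))
    return total, com, tensor


@dataclass
class GroundTruth:
    """Analytic mass properties of a scene (never computed from voxels)."""

    total_mass: float
    com: np.ndarray  # m
    tensor_about_com: np.ndarray  # kg m^2
    per_label: dict = field(default_factory=dict)  # label -> dict

    @classmethod
    def from_shapes(cls, shapes) -> "GroundTruth":
        per_label: dict[int, dict] = {}
        for lab in sorted({s.label for s in shapes}):
            members = [s for s in shapes if s.label == lab]
            m, c, t = compose_inertia(
                [(s.mass, np.asarray(s.center), s.tensor_about_com()) for s in members]
            )
            per_label[lab] = {
                "name": members[0].name or f"label_{lab}",
                "mass": m,
                "com": c,
                "tensor_about_com": t,
            }
        m, c, t = compose_inertia(
            [(s.mass, np.asarray(s.center), s.tensor_about_com()) for s in shapes]
        )
        return cls(total_mass=m, com=c, tensor_about_com=t, per_label=per_label)

    def subset(self, labels) -> tuple:
        """Composite (mass, com, tensor_about_com) of a subset of labels."""
        return compose_inertia(
            [
                (d["mass"], d["com"], d["tensor_about_com"])
                for lab, d in self.per_label.items()
                if lab in set(labels)
            ]
        )


def rasterize_scene(spec: SceneSpec):
    """Rasterise a scene into ``(VoxelGrid, LabelVolume, GroundTruth)``.

    Per-voxel density is that of the (last-listed) shape containing the
    voxel center, air (1.2 kg m^-3) elsewhere; grey-values invert the
    scene's density calibration ``rho = slope*G + intercept`` and carry
    seeded Gaussian noise. Raises if any shape extends outside the volume.
    Overlapping shapes trigger a warning because the analytic ground truth
    assumes disjoint bodies.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    shape = tuple(int(n) for n in spec.volume_shape)
    extent_lo = origin * 1e-3
    extent_hi = (origin + spacing * np.asarray(shape)) * 1e-3

    density = np.full(shape, AIR_DENSITY, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)

    centers_m = [
        (origin[ax] + (np.arange(shape[ax]) + 0.5) * spacing[ax]) * 1e-3
        for ax in range(3)
    ]

    overlap = 0
    for s in spec.shapes:
        h = s.half_extent()
        lo = np.asarray(s.center) - h
        hi = np.asarray(s.center) + h
        if np.any(lo < extent_lo - 1e-12) or np.any(hi > extent_hi + 1e-12):
            raise LayoutError(
                f"shape {s.name!r} spans [{lo}, {hi}] m, outside volume "
                f"[{extent_lo}, {extent_hi}] m"
            )
        # restrict the membership test to the shape's bounding box
        sl = []
        for ax in range(3):
            inside = np.nonzero(
                (centers_m[ax] >= lo[ax] - 1e-12) & (centers_m[ax] <= hi[ax] + 1e-12)
            )[0]
            if inside.size == 0:
                sl = None
                break
            sl.append(slice(inside[0], inside[-1] + 1))
        if sl is None:
            continue
        sub = tuple(sl)
        p0 = centers_m[0][sub[0]][:, None, None]
        p1 = centers_m[1][sub[1]][None, :, None]
        p2 = centers_m[2][sub[2]][None, None, :]
        mask = s.contains(p0, p1, p2)
        overlap += int((labels[sub][mask] != 0).sum())
        density[sub][mask] = s.density
        labels[sub][mask] = s.label

    if overlap:
        warnings.warn(
            f"{overlap} voxels claimed by more than one shape; analytic ground "
            f"truth assumes disjoint bodies",
            RuntimeWarning,
        )

    slope, intercept = spec.calibration_truth
    grey = (density - intercept) / slope
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.noise_sigma, size=shape)

    grid = VoxelGrid(values=grey, spacing=spacing, origin=origin)
    label_volume = LabelVolume(labels=labels, segment_names=spec.segment_names())
    return grid, label_volume, GroundTruth.from_shapes(spec.shapes)


def make_phantom_rods(
    densities=PHANTOM_DENSITIES,
    volume_shape=(64, 512, 512),
    spacing=(1.25, 0.98, 0.98),
    origin=(0.0, 0.0, 0.0),
    radius_mm: float = 10.0,
    row_axis1_mm: float | None = None,
    roi_fraction: float = 0.6,
    label_start: int = 101,
):
    """Parallel calibration rods plus matched elliptical ROIs.

    Rods run along axis 0 (the slice axis), arranged in a row across axis 2
    at the in-plane position ``row_axis1_mm`` (defaults to 80% of the axis-1
    extent). Returns ``(shapes, rois, air_roi)`` where ``rois`` maps rod
    name -> three RoiSpec at the 25/50/75% planes with semi-axes
    ``roi_fraction * radius`` (strictly inside the rod), and ``air_roi``
    samples an empty corner for the air calibration point.
    """
    densities = list(densities)
    if len(densities) < 2:
        raise DomainError("need at least 2 rod densities")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    extent = spacing * np.asarray(volume_shape)
    if row_axis1_mm is None:
        row_axis1_mm = origin[1] + 0.8 * extent[1]
    length_mm = 0.9 * extent[0]
    z_mm = origin[0] + 0.5 * extent[0]

    n = len(densities)
    pitch = (extent[2] - 4 * radius_mm) / n
    if pitch < 2.5 * radius_mm:
        raise LayoutError(
            f"{n} rods of radius {radius_mm} mm do not fit across {extent[2]:.0f} mm"
        )
    starts = origin[2] + 2 * radius_mm + pitch * (np.arange(n) + 0.5)

    shapes, rois = [], {}
    for k, (rho, x2) in enumerate(zip(densities, starts)):
        name = f"rod_{k}"
        shapes.append(
            Shape(
                primitive="cylinder",
                center=(z_mm * 1e-3, row_axis1_mm * 1e-3, x2 * 1e-3),
                dims=(radius_mm * 1e-3, length_mm * 1e-3),
                density=float(rho),
                label=label_start + k,
                name=name,
                axis=0,
            )
        )
        rois[name] = [
            RoiSpec(
                plane_fraction=f,
                center=(row_axis1_mm, x2),
                semi_axes=(roi_fraction * radius_mm, roi_fraction * radius_mm),
            )
            for f in (0.25, 0.50, 0.75)
        ]
    air_roi = [
        RoiSpec(
            plane_fraction=f,
            center=(origin[1] + 25.0, origin[2] + 25.0),
            semi_axes=(15.0, 15.0),
        )
        for f in (0.25, 0.50, 0.75)
    ]
    return shapes, rois, air_roi


#: Specimen segment labels used by the bird-like scene.
BIRD_SEGMENTS = {
    1: "head",
    2: "torso",
    3: "humerus_left",
    4: "radius_ulna_left",
    5: "manus_left",
    6: "humerus_right",
    7: "radius_ulna_right",
    8: "manus_right",
    9: "tibiotarsus_left",
    10: "tibiotarsus_right",
    11: "tail",
}

#: Labels of scanner fixtures (board, phantom rods) in the full study scene.
FIXTURE_BOARD_LABEL = 120


def make_bird_like_scene(
    spacing=(1.25, 0.98, 0.98),
    volume_shape=(64, 512, 512),
    noise_sigma: float = 5.0,
    seed: int = 0,
    calibration_truth=(1.0, -1000.0),
    retracted: bool = False,
    fixtures: bool = True,
) -> SceneSpec:
    """A bird-of-prey analogue on scanner-like geometry.

    Axis 0 is dorsoventral (slices), axis 1 anteroposterior, axis 2
    mediolateral. The specimen is mirror-symmetric about the mediolateral
    midplane: an ellipsoidal torso, spherical head, three thin wing plates
    per side whose density falls distally (flesh-and-bone inner wing to
    feather-dominated hand wing), cylindrical legs and a light tail plate.
    ``retracted=True`` folds the wing plates inboard at twice the thickness
    (per-segment masses conserved), mimicking a second scan with the wings
    drawn in. With ``fixtures=True`` the mounting board and an eight-rod
    phantom set are added (labels >= 100), to be excluded from the specimen
    by mask just as scanner furniture is removed by hand in practice.

    Wing-plate faces are aligned to voxel boundaries so that center
    sampling rasterises the plates without mass bias.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(v) for v in volume_shape)
    extent = spacing * np.asarray(shape)
    c1 = 0.5 * extent[1]
    c2 = 0.5 * extent[2]

    def mm(*v):
        return tuple(x * 1e-3 for x in v)

    dz = spacing[0]
    # wing plate: 5 slices thick, faces on voxel boundaries
    z_lo = 28 * dz
    thick = 5 * dz
    z_mid = z_lo + thick / 2.0
    body_z = 0.5 * extent[0]

    shapes = [
        Shape("sphere", mm(body_z, c1 + 115.0, c2), mm(25.0), 1050.0, 1, "head"),
        Shape("ellipsoid", mm(body_z, c1, c2), mm(25.0, 75.0, 40.0), 950.0, 2, "torso"),
    ]

    if not retracted:
        sections = [  # (span from, span to, density, base name)
            (45.0, 110.0, 900.0, "humerus"),
            (110.0, 175.0, 700.0, "radius_ulna"),
            (175.0, 235.0, 350.0, "manus"),
        ]
        wing_thick = thick
    else:
        sections = [
            (45.0, 77.5, 900.0, "humerus"),
            (77.5, 110.0, 700.0, "radius_ulna"),
            (110.0, 140.0, 350.0, "manus"),
        ]
        wing_thick = 2 * thick
    label_of = {v: k for k, v in BIRD_SEGMENTS.items()}
    for side, sign in (("left", -1.0), ("right", +1.0)):
        for lo, hi, rho, base in sections:
            name = f"{base}_{side}"
            shapes.append(
                Shape(
                    "plate",
                    mm(z_lo + wing_thick / 2.0, c1, c2 + sign * (lo + hi) / 2.0),
                    mm(wing_thick, 90.0, hi - lo),
                    rho,
                    label_of[name],
                    name,
                )
            )
    for side, sign in (("left", -1.0), ("right", +1.0)):
        shapes.append(
            Shape(
                "cylinder",
                mm(body_z, c1 - 110.0, c2 + sign * 25.0),
                mm(8.0, 70.0),
                1100.0,
                label_of[f"tibiotarsus_{side}"],
                f"tibiotarsus_{side}",
                axis=1,
            )
        )
    shapes.append(
        Shape("plate", mm(z_mid, c1 - 195.0, c2), mm(thick, 80.0, 60.0), 400.0, 11, "tail")
    )

    if fixtures:
        rod_shapes, _, _ = make_phantom_rods(
            volume_shape=shape, spacing=tuple(spacing), row_axis1_mm=c1 + 190.0
        )
        shapes.extend(rod_shapes)
        board_z = 3 * dz  # resting plane, below the specimen
        shapes.append(
            Shape(
                "plate",
                mm(board_z, c1 - 45.0, c2),
                mm(3 * dz, 410.0, 490.0),
                600.0,
                FIXTURE_BOARD_LABEL,
                "board",
            )
        )

    return SceneSpec(
        shapes=shapes,
        calibration_truth=tuple(calibration_truth),
        noise_sigma=noise_sigma,
        spacing=tuple(spacing),
        volume_shape=shape,
        seed=seed,
    )


def make_bird_study(
    spacing=(1.25, 0.98, 0.98),
    volume_shape=(64, 512, 512),
    noise_sigma: float = 5.0,
    seed: int = 0,
    calibration_truth=(1.0, -1000.0),
    retracted: bool = False,
):
    """Bird scene *with* fixtures plus the phantom ROI specs needed to
    calibrate it: returns ``(SceneSpec, rois, air_roi, rod_densities)``
    where ``rois`` maps rod name -> RoiSpec list in rod order."""
    scene = make_bird_like_scene(
        spacing=spacing,
        volume_shape=volume_shape,
        noise_sigma=noise_sigma,
        seed=seed,
        calibration_truth=calibration_truth,
        retracted=retracted,
        fixtures=True,
    )
    extent1 = spacing[1] * volume_shape[1]
    _, rois, air_roi = make_phantom_rods(
        volume_shape=volume_shape,
        spacing=spacing,
        row_axis1_mm=0.5 * extent1 + 190.0,
    )
    return scene, rois, air_roi, list(PHANTOM_DENSITIES)


def small_angle_period(I: float, m: float, rig: PendulumRig) -> float:
    """Small-angle trifilar period ``2 pi sqrt(I L / (m g R^2))``."""
    return 2 * np.pi * np.sqrt(I * rig.L / (m * rig.g * rig.R**2))


def simulate_pendulum_trace(
    I_total: float,
    rig: PendulumRig,
    zeta: float = 0.0,
    amplitude: float = np.deg2rad(2.0),
    duration: float = 180.0,
    rate: float = 70.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    suspended_mass: float | None = None,
) -> OscillationTrace:
    """Integrate the exact trifilar equation of motion; return the gyro trace.

    The restoring torque follows the true thread geometry,
    ``T = -m g R^2 sin(theta) / sqrt(L^2 - 4 R^2 sin^2(theta/2))``, not the
    small-angle approximation, so small-angle modelling error is measurable
    rather than assumed. Damping is linear viscous with ratio ``zeta``
    defined against the small-angle natural frequency. ``suspended_mass``
    defaults to the bare rig mass; pass rig + specimen mass for a loaded
    run. Angular velocity is sampled at ``rate`` Hz with seeded Gaussian
    noise of ``noise_sigma`` rad s^-1.
    """
    m = rig.m_p if suspended_mass is None else float(suspended_mass)
    if not I_total > 0:
        raise DomainError("I_total must be positive")
    if not 0.0 <= zeta < 1.0:
        raise DomainError("zeta must lie in [0, 1)")
    max_amp = 2.0 * np.arcsin(min(1.0, rig.L / (2.0 * rig.R)))
    if not 0.0 < amplitude < max_amp:
        raise DomainError(
            f"amplitude {amplitude:.3f} rad outside the suspension's geometric "
            f"range (0, {max_amp:.3f})"
        )
    omega_n = np.sqrt(m * rig.g * rig.R**2 / (rig.L * I_total))
    c = 2.0 * zeta * I_total * omega_n

    def rhs(_t, y):
        theta, theta_dot = y
        sin_half = np.sin(0.5 * theta)
        drop = np.sqrt(rig.L**2 - 4.0 * rig.R**2 * sin_half**2)
        torque = -m * rig.g * rig.R**2 * np.sin(theta) / drop - c * theta_dot
        return (theta_dot, torque / I_total)

    t_eval = np.arange(0.0, duration, 1.0 / rate)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        (float(amplitude), 0.0),
        method="DOP853",
        t_eval=t_eval,
        rtol=1e-11,
        atol=1e-13,
        max_step=0.25 * 2 * np.pi / omega_n,
    )
    if not sol.success:
        raise RuntimeError(f"trifilar integration failed: {sol.message}")
    omega = sol.y[1]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        omega = omega + rng.normal(0.0, noise_sigma, size=omega.shape)
    return OscillationTrace(t=t_eval, omega=omega)
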