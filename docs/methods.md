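# Methods

This note documents the models implemented in `ctinertia`, the choices made
where the underlying experimental procedure leaves freedom, and what the
synthetic test fixtures do and do not demonstrate.

## Voxel model and units

A CT volume is a rank-3 array in `(slice, row, col)` order with per-axis
spacing and a world origin in millimetres; anatomical axis meaning is never
inferred from scan orientation but assigned by the user (or by the
board-plane fit, below). Mass is carried by **voxel centers**: the center of
voxel `(i, j, k)` sits at `origin + (index + ½)·spacing`. Center placement
makes the discretised mass, CoM and inertia integrals second-order accurate
in voxel size, which the oracle tests measure directly. All analytics run in
SI (kg, m, kg m²); millimetres appear only at the I/O boundary.

## Density calibration

Known densities are regressed on measured mean grey-values — the same
direction in which the calibration is later applied — by unweighted ordinary
least squares (`scipy.stats.linregress`). Design choices:

* **Per-scan calibration is mandatory.** Scanner state and field of view
  shift the grey scale between scans, so a fitted calibration carries its
  samples with it and is never silently reused.
* **ROI membership is strict center-inside-ellipse.** Partially covered
  boundary voxels are excluded so partial-volume averaging cannot bias the
  phantom means; the three sampling planes are pooled into a single mean
  (pooling vs per-plane averaging is a free choice; pooling weights every
  voxel equally).
* **Air is a true calibration point at 1.2 kg m⁻³**, not zero — physically
  correct, numerically almost indistinguishable.
* Raw grey-values and Hounsfield units are affine-equivalent here, so the
  calibration accepts either; the HU helpers exist for interoperability.

## Mass-matched thresholding

The specimen/air threshold is the grey level at which the calibrated mass of
retained voxels equals the balance-measured mass. Because every voxel
contributes non-negative mass (negative calibrated densities — noise below
the air line — are clamped to zero, with the count logged), the
mass-vs-threshold curve is non-increasing and bisection is robust and
deterministic. Defaults: tolerance 0.1 g (the balance resolution that the
target mass itself carries), integer grey levels (16-bit scanners emit
integers), lower threshold on ties. The search certifies monotonicity at
every probed level; a violation (possible only with clamping disabled) falls
back to an exhaustive scan over integer levels. Scanner fixtures (board,
phantom rods) are excluded by a user-supplied mask, mirroring the manual
clean-up step of a real scan; there is no automatic fixture detection.

At coarse voxelisations the mass quantum of a single grey level can exceed
the tolerance; the threshold may then be made continuous
(`integer_levels=False`), which the reduced-resolution test configurations
use.

## Inertia tensor conventions

Products of inertia are stored as tensor entries `I_xy = −Σ m x y` — the
tensor satisfying `L = I ω`. Some biomechanics tables list positive products
`+Σ m x y`; negate the off-diagonals to convert. Principal moments are
sorted ascending; axis columns are sign-fixed so each column's
largest-magnitude component is positive, then the third column is flipped if
needed to keep the frame right-handed (det +1). For degenerate (repeated)
moments only the moments are contractual; any orthonormal basis of the
eigenplane may be returned. Anatomical labelling of principal axes
(roll/pitch/yaw) is deliberately left to the user: automatic assignment from
scan orientation is unreliable, so the pipeline derives the dorsoventral
axis from a total-least-squares plane fit to the scanned mounting board
(smallest singular vector of the centered board points, oriented toward the
specimen CoM) and takes a user hint for the in-plane roll direction.

Summations use compensated (exactly rounded) accumulation via `math.fsum`,
so conservation identities — segment masses vs total, projection-map and
spanwise-profile totals vs their parent quantities, parallel-axis round
trips — hold at the 1e-12 relative level and are asserted at 1e-10 in tests.
Inside the threshold bisection, where the mass curve is probed dozens of
times on multi-million-voxel arrays, pairwise `np.sum` is used for speed and
the final estimate is recomputed with the compensated sum.

## Uniform-density comparison

To quantify what the calibration buys, the pipeline can re-run the full
analysis with every retained voxel assigned `total_mass / n` (density =
specimen mass / specimen volume). Total mass is preserved exactly by
construction; on any specimen with a dense core and light periphery (a
feathered bird being the extreme case) the uniform assumption moves mass
outward and inflates the moments of inertia — the sign of that bias is
asserted in tests, its magnitude is specimen-dependent.

## Trifilar pendulum

The rig is modelled as a single-degree-of-freedom torsional oscillator:
platform of mass `m` hung on three threads of length `L` at radius `R`.
Small-angle MoI from the period: `I = m g R² τ² / (4π² L)`. The fit target
is **angular velocity** — the gyroscope observable — so the damped-oscillator
displacement model is differentiated before fitting:

    x'(t) = X e^(−ζωₙt) [ω_d cos(ω_d t + φ) − ζωₙ sin(ω_d t + φ)],
    ω_d = ωₙ √(1 − ζ²).

Fitting uses the trailing 60 s of the trace (configurable) to avoid release
transients, with initial guesses from the discrete-spectrum peak (ω_d), the
logarithmic decrement of successive extrema (ζ) and a linear solve for
amplitude/phase; `scipy.optimize.curve_fit` refines all four parameters with
ζ bounded to [0, 1). Amplitude and phase are referenced to the window start.
Repeated measurements aggregate as unweighted means.

A specimen placed with its CoM a horizontal distance `D` from the platform
axis still twists about that axis, so the combined measurement contains the
parallel-axis term; the corrected specimen MoI about its own CoM-through,
board-normal axis is

    I_dv = (m_b + m_p) g R² τ² / (4π² L) − I_p − m_b D²,

which reduces exactly to the uncorrected difference at `D = 0`. Thread mass
and elasticity are neglected (nylon line), and no large-angle estimation is
attempted — instead the validity envelope is *measured*: the test oracle
integrates the exact geometric equation of motion,

    I θ̈ = −m g R² sin θ / √(L² − 4R² sin²(θ/2)) − c θ̇,

with a high-order adaptive integrator, so the small-angle error of Eq-style
analysis is observable (≈0.01 % at 2° amplitude, growing monotonically with
amplitude) rather than assumed away.

## Synthetic scenes: what they emulate, and what they don't

`synthetic` rasterises homogeneous primitives (cuboid/plate, sphere,
cylinder, ellipsoid; optional rigid pose) into scanner-like volumes —
512×512 in-plane, 1.25 mm slice separation, sub-millimetre pixels, grey =
(ρ − b)/a with seeded Gaussian noise (default σ = 5 grey units) — and
computes ground truth *analytically* (closed-form tensors composed by the
parallel-axis theorem, never from voxels). The default bird-like scene is
mirror-symmetric: ellipsoidal torso (950 kg m⁻³), spherical head (1050),
per-side wing plates whose density falls distally (900 → 700 → 350,
emulating flesh-and-bone inner wing to feather-dominated hand wing),
cylindrical legs (1100) and a light tail plate (400), about 0.55 kg in
total — between a barn owl and a peregrine falcon. A mounting board and the
eight-rod phantom set are included as fixtures (labels ≥ 100) so the
exclusion-mask and board-plane workflows run exactly as on a real scan. A
retracted-wing variant folds the plates inboard at conserved segment mass.
Wing-plate faces are aligned to voxel boundaries so center sampling
rasterises them without mass bias — a deliberate choice that keeps the
scene's discretisation error in the smooth second-order regime.

Limitations of the emulation, hence of what green tests prove about real
data: rasterisation is center-sampling only, so **partial-volume mixing at
material boundaries is absent** — precisely the effect that makes per-voxel
*density* (as opposed to mass) unreliable in feathers; grey-values are
exactly affine in density, so beam hardening, scatter and other scanner
nonlinearities are not represented; and anatomical segment boundaries are
exact, whereas physical dissection cuts are not. Passing tests demonstrate
correctness of the computational chain, not robustness to those physical
artefacts.

### Oracle-test problem sizes and the convergence check

Primitive-oracle tests run at 64³ and 128³ (the voxel counts at which the
closed-form comparison is both fast and already sub-percent); the chained
pipeline tests run the full 64×512×512 default scene, and
reduced-in-plane-resolution variants (256² or 128² at proportionally larger
pixels — the same physical scene) where repetition matters. The convergence
assertion compares the *family-wise maximum* component error across the
three primitives between resolutions: that maximum is dominated by the
deterministic second-order quadrature (center-lumping) error, which shrinks
exactly 4× per halving, while the lattice boundary-counting error on curved
surfaces — which fluctuates rather than decays smoothly — stays below it.
The test cylinder is tilted a few degrees off-lattice so its circular
cross-section is not replicated coherently slice after slice.

## Pipeline and reproducibility

`run_pipeline` chains simulate → calibrate → threshold → inertia → dissect →
project → spanwise → pendulum on a validated configuration (pydantic,
unknown keys rejected, fail-fast before any computation). Every stochastic
element (scene noise, trace noise) descends from the single config seed, and
the report embeds a manifest (config dump, SHA-256 config hash, package and
numpy versions) sufficient to reproduce a run bit for bit. Stage outputs are
recomputed rather than cached: at the scene sizes the package supports a
full rerun costs seconds, and a content cache would add a staleness failure
mode with no measurable benefit.
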