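"""Numeric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np

#: Density of air at room conditions, kg m^-3. Used as the "known density"
#: of air regions included in phantom calibrations.
AIR_DENSITY = 1.2

#: Standard gravitational acceleration, m s^-2.
STANDARD_GRAVITY = 9.81


def fsum(values) -> float:
    """Exactly-rounded (compensated) sum of an array of floats.

    Wraps :func:`math.fsum` so conservation identities (segment masses
    summing to the total, profile bins summing to the parent moment) hold to
    one unit in the last place rather than accumulating with n.
    """
    arr = np.asarray(values, dtype=float)
    return math.fsum(arr.ravel().tolist())


def weighted_mean(weights: np.ndarray, values: np.ndarray) -> float:
    """Compensated weighted mean ``sum(w*v)/sum(w)``."""
    return fsum(np.asarray(weights) * np.asarray(values)) / fsum(weights)


def as_unit_vector(v, tol: float = 1e-12) -> np.ndarray:
    """Return ``v`` normalised to unit length; raise if near-zero."""
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < tol:
        raise ValueError("direction vector has (near-)zero length")
    return v / n


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed proper rotation (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q
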