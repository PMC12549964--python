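"""Uniform SO(3) sampling, quaternion algebra and relative-orientation statistics.

Orientations are represented as unit quaternions ``q = (w, x, y, z)``.  The
relative orientation between two rigid-body orientations ``R_i`` and ``R_j``
is the magnitude of the single axis-angle rotation mapping one onto the
other,

    theta = 2 * arccos(|Re[R_i R_j^{-1}]|),

where the real part of the relative quaternion is simply the 4-vector dot
product of the two unit quaternions.  The absolute value folds the q <-> -q
double cover so theta always lands in [0, pi].

For two *independent* Haar-uniform rotations the relative angle follows the
density p(theta) = (2/pi) sin^2(theta/2) on [0, pi], with mean
pi/2 + 2/pi ~= 2.2074 rad.  This is why orientation errors of any method
"saturate" around 2.2 rad: that is the mean angle between totally random
orientations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize

__all__ = [
    "Rotation",
    "sample_uniform_rotations",
    "sample_uniform_rotation",
    "relative_angle",
    "pairwise_relative_angles",
    "angle_pdf",
    "angle_cdf",
    "angle_distribution_stats",
    "SO3_MEAN_ANGLE",
    "UNNORMALIZED_PDF_FACTOR",
]

#: Closed-form mean relative angle between independent uniform rotations.
SO3_MEAN_ANGLE = math.pi / 2 + 2 / math.pi

#: The angle density is sometimes quoted as (1/2) sin^2(theta/2); that form
#: integrates to pi/4 over [0, pi].  Multiplying the normalized density
#: returned by :func:`angle_pdf` by this factor recovers it.
UNNORMALIZED_PDF_FACTOR = math.pi / 4

_UNIT_TOL = 1e-9


class Rotation:
    """A 3D rotation stored as a unit quaternion ``(w, x, y, z)``.

    The constructor normalizes its input; after construction ``|q| = 1``
    to within 1e-12.  ``q`` and ``-q`` describe the same rotation and all
    operations in this module are invariant to that sign flip.
    """

    __slots__ = ("q",)

    def __init__(self, q, *, normalize: bool = True):
        q = np.asarray(q, dtype=np.float64)
        if q.shape != (4,):
            raise ValueError(f"quaternion must have shape (4,), got {q.shape}")
        norm = float(np.linalg.norm(q))
        if norm < 1e-12:
            raise ValueError("zero quaternion does not define a rotation")
        if normalize:
            q = q / norm
        elif abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"quaternion norm {norm} deviates from 1 beyond tolerance")
        self.q = q

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), normalize=False)

    @classmethod
    def from_axis_angle(cls, axis, angle: float) -> "Rotation":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        half = 0.5 * float(angle)
        return cls(np.concatenate(([math.cos(half)], math.sin(half) * axis)))

    @classmethod
    def random(cls, rng) -> "Rotation":
        """One Haar-uniform rotation drawn from ``rng`` (Generator or seed)."""
        return cls(sample_uniform_rotations(1, rng)[0], normalize=False)

    # -- algebra -----------------------------------------------------------
    def __mul__(self, other: "Rotation") -> "Rotation":
        w1, x1, y1, z1 = self.q
        w2, x2, y2, z2 = other.q
        return Rotation(
            np.array(
                [
                    w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                    w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                    w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                    w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
                ]
            )
        )

    def inv(self) -> "Rotation":
        w, x, y, z = self.q
        return Rotation(np.array([w, -x, -y, -z]), normalize=False)

    def as_matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on column vectors."""
        w, x, y, z = self.q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate an (N, 3) array (or single 3-vector) of coordinates."""
        vectors = np.asarray(vectors, dtype=np.float64)
        return vectors @ self.as_matrix().T

    def __repr__(self) -> str:  # pragma: no cover
        w, x, y, z = self.q
        return f"Rotation(w={w:.6f}, x={x:.6f}, y={y:.6f}, z={z:.6f})"


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_uniform_rotations(n: int, rng_seed) -> np.ndarray:
    """Draw ``n`` Haar-uniform unit quaternions as an (n, 4) array.

    A 4D standard normal vector, normalized to the unit 3-sphere, is uniform
    on S^3 and therefore Haar-uniform on SO(3) under the double cover.
    """
    rng = _as_rng(rng_seed)
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return q


def sample_uniform_rotation(rng_seed) -> Rotation:
    """Draw a single Haar-uniform :class:`Rotation`."""
    return Rotation.random(_as_rng(rng_seed))


def _check_unit(q: np.ndarray) -> None:
    norms = np.linalg.norm(np.atleast_2d(q), axis=-1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError("non-unit quaternion passed to relative-angle computation")


def relative_angle(Ri: Rotation, Rj: Rotation) -> float:
    """Minimal rotation angle mapping orientation ``Ri`` onto ``Rj``, in [0, pi].

    Computed as ``2 * arccos(|Re[Ri Rj^-1]|)``; the real part of the relative
    quaternion equals the 4-vector dot product of the two unit quaternions.
    Symmetric in its arguments and invariant to quaternion sign flips.
    """
    qi = Ri.q if isinstance(Ri, Rotation) else np.asarray(Ri, dtype=np.float64)
    qj = Rj.q if isinstance(Rj, Rotation) else np.asarray(Rj, dtype=np.float64)
    _check_unit(qi)
    _check_unit(qj)
    a = abs(float(np.dot(qi, qj)))
    return 2.0 * math.acos(min(a, 1.0))


def pairwise_relative_angles(quats: np.ndarray) -> np.ndarray:
    """Relative angles for all i<j pairs of an (N, 4) unit-quaternion array.

    Returns a condensed vector of length N(N-1)/2 ordered like
    :func:`scipy.spatial.distance.pdist` (row-major over the upper triangle).
    """
    quats = np.asarray(quats, dtype=np.float64)
    _check_unit(quats)
    gram = np.abs(quats @ quats.T)
    iu, ju = np.triu_indices(len(quats), k=1)
    return 2.0 * np.arccos(np.clip(gram[iu, ju], -1.0, 1.0))


def angle_pdf(theta) -> np.ndarray:
    """Normalized density of the relative angle between uniform rotations.

    ``p(theta) = (2/pi) sin^2(theta/2)`` on [0, pi]; integrates to 1.
    Multiply by :data:`UNNORMALIZED_PDF_FACTOR` for the (1/2) sin^2(theta/2)
    convention.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if np.any((theta < 0) | (theta > math.pi)):
        raise ValueError("theta must lie in [0, pi]")
    return (2.0 / math.pi) * np.sin(theta / 2.0) ** 2


def angle_cdf(theta) -> np.ndarray:
    """CDF of the relative-angle distribution: F(theta) = (theta - sin theta)/pi."""
    theta = np.asarray(theta, dtype=np.float64)
    if np.any((theta < 0) | (theta > math.pi)):
        raise ValueError("theta must lie in [0, pi]")
    return (theta - np.sin(theta)) / math.pi


def angle_distribution_stats() -> tuple[float, float]:
    """(mean, median) of the relative-angle distribution, in radians.

    The mean has the closed form pi/2 + 2/pi.  The median solves
    F(theta) = (theta - sin theta)/pi = 1/2 and is found by a bracketing
    root-finder to 1e-10.
    """
    median = optimize.brentq(
        lambda t: (t - math.sin(t)) / math.pi - 0.5, 0.0, math.pi, xtol=1e-10
    )
    return SO3_MEAN_ANGLE, float(median)
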