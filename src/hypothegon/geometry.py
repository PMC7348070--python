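"""Geometry of the ternary hypothesis space.

The hypothesis space for the diagnostic task is the 2-simplex of probability
distributions over three mutually exclusive decimal-comparison misconceptions
(WN, ID, SL), drawn as an equilateral triangle.  This module provides
validation of probability triples, the affine map between barycentric
coordinates and the drawing plane, distances between belief states, and a
triangular-lattice discretization of the simplex.

Distances are always taken between the 3-component probability vectors, not
between their 2-D plane images (the plane image of a unit-side triangle
shrinks all distances by a constant factor 1/sqrt(2), which would silently
rescale every kernel bandwidth downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, MalformedJudgmentError, OutOfSimplexError

#: Hypothesis labels, in canonical component order.
HYPOTHESES = ("WN", "ID", "SL")

#: Tolerance for simplex membership / normalization checks on internal values.
NORMALIZATION_TOL = 1e-9

#: Looser tolerance applied when cleaning user-supplied (hand-entered) triples.
INPUT_CLEANUP_TOL = 1e-6

# Drawing convention: WN bottom-left, ID bottom-right, SL top; unit side length.
TRIANGLE_VERTICES = np.array(
    [[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3.0) / 2.0]]
)

# Orthonormal basis of the sum-zero plane embedded in R^3. Coordinates in this
# basis are isometric to the 3-component Euclidean metric used throughout.
SIMPLEX_PLANE_BASIS = np.array(
    [
        [1.0 / math.sqrt(2.0), 1.0 / math.sqrt(6.0)],
        [-1.0 / math.sqrt(2.0), 1.0 / math.sqrt(6.0)],
        [0.0, -2.0 / math.sqrt(6.0)],
    ]
)


def validate_probability_vector(
    raw, tolerance: float = NORMALIZATION_TOL
) -> np.ndarray:
    """Validate and normalize a probability triple.

    Parameters
    ----------
    raw
        Three reals intended as probabilities over (WN, ID, SL).
    tolerance
        Maximum tolerated deviation of the component sum from 1, and the
        largest negative excursion that is clipped to zero rather than
        rejected.

    Returns
    -------
    numpy.ndarray
        The normalized vector (components >= 0, summing to 1 exactly).

    Raises
    ------
    MalformedJudgmentError
        If the triple has the wrong length, a component below ``-tolerance``,
        or a sum deviating from 1 by more than ``tolerance``.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.shape != (3,):
        raise MalformedJudgmentError(
            f"expected a probability triple, got shape {arr.shape}: {raw!r}"
        )
    if not np.all(np.isfinite(arr)):
        raise MalformedJudgmentError(f"non-finite component in {tuple(arr)!r}")
    if np.any(arr < -tolerance):
        raise MalformedJudgmentError(
            f"negative probability component in {tuple(arr)!r}"
        )
    total = float(arr.sum())
    if abs(total - 1.0) > tolerance:
        raise MalformedJudgmentError(
            f"components of {tuple(arr)!r} sum to {total:.6g}, not 1 "
            f"(tolerance {tolerance:g})"
        )
    arr = np.clip(arr, 0.0, None)
    total = float(arr.sum())
    if abs(total - 1.0) > 1e-12:  # leave near-exact triples untouched
        arr = arr / total
    return arr


def barycentric_to_cartesian(p) -> np.ndarray:
    """Map barycentric coordinates to the drawing plane.

    Accepts a single triple or an array of shape (..., 3); returns the
    matching (..., 2) array of plane coordinates on the unit-side triangle
    with WN bottom-left, ID bottom-right, SL top.
    """
    p = np.asarray(p, dtype=float)
    return p @ TRIANGLE_VERTICES


def cartesian_to_barycentric(q, tolerance: float = NORMALIZATION_TOL) -> np.ndarray:
    """Invert :func:`barycentric_to_cartesian`.

    Raises
    ------
    OutOfSimplexError
        If the point lies outside the reference triangle by more than
        ``tolerance`` (measured on the barycentric components).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (2,):
        raise OutOfSimplexError(f"expected a plane point, got shape {q.shape}")
    p_sl = q[1] / TRIANGLE_VERTICES[2, 1]
    p_id = q[0] - 0.5 * p_sl
    p_wn = 1.0 - p_id - p_sl
    p = np.array([p_wn, p_id, p_sl])
    if np.any(p < -tolerance) or np.any(p > 1.0 + tolerance):
        raise OutOfSimplexError(
            f"plane point {tuple(q)!r} maps outside the simplex: {tuple(p)!r}"
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def simplex_distance(p, q) -> float:
    """Euclidean distance between two belief states in probability space."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


@dataclass(frozen=True)
class Lattice:
    """Triangular-lattice discretization of the simplex.

    ``points`` has shape (n, 3); for subdivision level m the point count is
    (m + 1)(m + 2) / 2 (or (m - 1)(m - 2) / 2 interior-only).
    """

    resolution: int
    points: np.ndarray

    def __len__(self) -> int:
        return self.points.shape[0]


def generate_lattice(resolution: int, interior_only: bool = False) -> Lattice:
    """All barycentric triples (i, j, k)/m with i + j + k = m.

    Parameters
    ----------
    resolution
        Subdivision level m >= 1.
    interior_only
        Restrict to strictly positive components (i, j, k >= 1).
    """
    if not isinstance(resolution, (int, np.integer)) or resolution < 1:
        raise ConfigurationError(
            f"lattice resolution must be a positive integer, got {resolution!r}"
        )
    m = int(resolution)
    lo = 1 if interior_only else 0
    pts = [
        (i, j, m - i - j)
        for i in range(lo, m + 1 - 2 * lo)
        for j in range(lo, m + 1 - i - lo)
    ]
    points = np.array(pts, dtype=float) / m
    if points.size == 0:
        points = points.reshape(0, 3)
    return Lattice(resolution=m, points=points)


def snap_to_lattice(p, lattice: Lattice) -> np.ndarray:
    """Nearest lattice point to ``p`` in probability-space distance."""
    p = np.asarray(p, dtype=float)
    idx = int(np.argmin(np.sum((lattice.points - p) ** 2, axis=1)))
    return lattice.points[idx]
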