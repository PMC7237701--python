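"""Source-orientation reconstruction for ring and tandem applicator channels.

A stepping source travelling inside a ring applicator points along the local
tangent of the ring, not along the chord to the next dwell.  The tangent
method implemented here recovers orientations in two steps:

1. fit the ring plane — enumerate candidate plane normals from triples of
   dwell positions, score each candidate by the RMSE of point-to-plane
   distances, keep the best, then least-squares fit the circle (centre,
   radius) to the dwells projected into that plane;
2. orient each dwell along the tangent of the fitted circle at its position,
   signed to advance with the channel's delivery order.

The simpler chained method (orient each dwell along the chord to the next
dwell) is provided as the baseline it improves on: for dwells equally spaced
by an angular step ``dphi`` on a circle, chained directions deviate from the
true tangent by exactly ``dphi / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ConfigurationError, GeometryError

#: a position triple is rejected as collinear below this triangle area (mm^2)
COLLINEAR_AREA_MM2 = 1e-6

#: use all C(n,3) triples up to this many positions, then a stride subsample
MAX_EXHAUSTIVE_POSITIONS = 12
SUBSAMPLE_TRIPLES = 220


@dataclass(frozen=True)
class RingFit:
    """A fitted ring: plane normal (unit), circle centre (mm), radius (mm),
    and the RMSE (mm) of the dwell positions against the selected plane."""

    plane_normal: np.ndarray
    center_mm: np.ndarray
    radius_mm: float
    rmse_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "plane_normal", np.asarray(self.plane_normal, float))
        object.__setattr__(self, "center_mm", np.asarray(self.center_mm, float))
        if abs(np.linalg.norm(self.plane_normal) - 1.0) > 1e-9:
            raise GeometryError("ring plane normal must be a unit vector")
        if not self.radius_mm > 0:
            raise GeometryError("ring radius must be > 0")
        if self.rmse_mm < 0:
            raise GeometryError("ring RMSE must be >= 0")


def _canonical_hemisphere(n: np.ndarray) -> np.ndarray:
    """Flip a unit normal so its first non-zero component is positive."""
    for c in n:
        if abs(c) > 1e-12:
            return n if c > 0 else -n
    return n


def candidate_planes(positions_mm: np.ndarray) -> np.ndarray:
    """Unit plane normals from non-degenerate triples of dwell positions.

    All C(n,3) triples are used for n <= 12; above that a deterministic
    stride subsample of at most 220 triples bounds the cost.
    """
    pos = np.asarray(positions_mm, dtype=float)
    n = len(pos)
    if n < 3:
        raise GeometryError(f"need >= 3 positions to define candidate planes, got {n}")
    triples = list(combinations(range(n), 3))
    if n > MAX_EXHAUSTIVE_POSITIONS:
        stride = max(1, len(triples) // SUBSAMPLE_TRIPLES)
        triples = triples[::stride][:SUBSAMPLE_TRIPLES]
    normals = []
    for i, j, k in triples:
        cross = np.cross(pos[j] - pos[i], pos[k] - pos[i])
        area = 0.5 * np.linalg.norm(cross)
        if area < COLLINEAR_AREA_MM2:
            continue  # degenerate (collinear) triple
        normals.append(_canonical_hemisphere(cross / np.linalg.norm(cross)))
    if not normals:
        raise GeometryError("all position triples are collinear; no ring plane exists")
    return np.asarray(normals)


def _plane_rmse(positions: np.ndarray, normal: np.ndarray) -> float:
    d = positions @ normal
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def _in_plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _fit_circle_2d(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (centre, radius)."""
    A = np.column_stack([2.0 * xy[:, 0], 2.0 * xy[:, 1], np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(c + cx ** 2 + cy ** 2))
    return np.array([cx, cy]), radius


def select_plane(positions_mm: np.ndarray, candidates: np.ndarray | None = None) -> RingFit:
    """Pick the candidate plane with minimal point-to-plane RMSE and fit the
    in-plane circle to the projected dwell positions."""
    pos = np.asarray(positions_mm, dtype=float)
    if candidates is None:
        candidates = candidate_planes(pos)
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if len(candidates) == 0:
        raise GeometryError("no candidate planes supplied")
    rmses = [_plane_rmse(pos, n) for n in candidates]
    best = int(np.argmin(rmses))
    normal = _canonical_hemisphere(candidates[best] / np.linalg.norm(candidates[best]))

    plane_point = normal * float((pos @ normal).mean())
    u, v = _in_plane_basis(normal)
    rel = pos - plane_point
    xy = np.column_stack([rel @ u, rel @ v])
    c2d, radius = _fit_circle_2d(xy)
    center = plane_point + c2d[0] * u + c2d[1] * v
    return RingFit(plane_normal=normal, center_mm=center, radius_mm=radius,
                   rmse_mm=rmses[best])


def tangent_directions(fit: RingFit, positions_mm: np.ndarray) -> np.ndarray:
    """Unit tangents of the fitted ring at each dwell position.

    The tangent is ``normal x (p - centre)`` normalized; its sign is chosen so
    each direction advances along the channel's dwell ordering (positive dot
    product with the chord to the next dwell; the last dwell uses the chord
    from its predecessor).
    """
    pos = np.asarray(positions_mm, dtype=float)
    radial = pos - fit.center_mm
    norms = np.linalg.norm(np.cross(fit.plane_normal, radial), axis=-1)
    if np.any(norms < 1e-12):
        idx = int(np.argmin(norms))
        raise GeometryError(f"dwell {idx} sits at the ring centre; tangent undefined")
    t = np.cross(fit.plane_normal, radial)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    n = len(pos)
    if n >= 2:
        chords = np.empty_like(pos)
        chords[:-1] = pos[1:] - pos[:-1]
        chords[-1] = pos[-1] - pos[-2]
        flip = np.einsum("ij,ij->i", t, chords) < 0
        t[flip] *= -1.0
    return t


def chained_directions(positions_mm: np.ndarray) -> np.ndarray:
    """Baseline orientations: chord to the next dwell, last dwell reuses the
    previous chord."""
    pos = np.asarray(positions_mm, dtype=float)
    if len(pos) < 2:
        raise GeometryError("chained directions require >= 2 positions")
    chords = pos[1:] - pos[:-1]
    lengths = np.linalg.norm(chords, axis=-1)
    if np.any(lengths == 0):
        idx = int(np.argmin(lengths))
        raise GeometryError(f"duplicate consecutive dwell positions at index {idx}")
    dirs = np.empty_like(pos)
    dirs[:-1] = chords / lengths[:, None]
    dirs[-1] = dirs[-2]
    return dirs


def assign_directions(positions_mm: np.ndarray, applicator_type: str
                      ) -> tuple[np.ndarray, str, RingFit | None]:
    """Dispatch orientation reconstruction by applicator type.

    ``ring`` channels get the tangent method; ``tandem`` and ``generic``
    channels the chained baseline.  Returns ``(directions, method, ring_fit)``
    with ``ring_fit`` None for non-ring channels.
    """
    if applicator_type == "ring":
        fit = select_plane(positions_mm)
        return tangent_directions(fit, positions_mm), "tangent", fit
    if applicator_type in ("tandem", "generic"):
        return chained_directions(positions_mm), "chained", None
    raise ConfigurationError(
        f"unknown applicator type {applicator_type!r}; expected ring|tandem|generic"
    )
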