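"""Full Procrustes matching with scaling and combinatorial vertex assignment.

Coordination geometry is compared metal-at-origin: translation is removed by
anchoring the metal at the origin of both point sets (the metal itself is not
a vertex), not by centroid subtraction — a single long bond must not shift
the frame.  For a fixed vertex correspondence the rotation and scale have the
standard closed-form orthogonal solution; the correspondence itself is found
by exhaustive permutation search up to ``EXHAUSTIVE_CAP`` vertices and by a
seeded assignment/refinement heuristic above it.

The reported distance is the normalized full Procrustes distance

    d = sqrt( sum_i || s R x_i - y_perm(i) ||^2 / sum_i || y_i ||^2 )

with the denominator over the *reference* shape, whose vertices are unit
length in the packaged class library — so the acceptance threshold is
directly comparable across coordination numbers.  The measure is therefore
asymmetric (scale freedom sits on the observed side only); all consumers use
the observed-vs-reference direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

EXHAUSTIVE_CAP = 8
DISTANCE_ATOL = 1e-9


class DegenerateShapeError(ValueError):
    pass


@dataclass(frozen=True)
class Shape:
    """A metal environment as vertices about the origin (the metal)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(pts) < 2:
            raise ValueError("a shape needs at least 2 points")
        norms = np.linalg.norm(pts, axis=1)
        if np.any(norms < 1e-12):
            raise DegenerateShapeError("no vertex may sit on the metal (origin)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ProcrustesMatch:
    """Result of matching an observed shape against a reference class."""

    class_name: str
    permutation: tuple[int, ...]  # observed vertex i -> reference vertex perm[i]
    rotation: np.ndarray
    scale: float
    distance: float
    reflected: bool = field(default=False)


def _as_points(shape) -> np.ndarray:
    if isinstance(shape, Shape):
        return shape.points
    return Shape(np.asarray(shape, dtype=float)).points


def _reference_of(candidate) -> tuple[str, np.ndarray]:
    """Accept a CoordinationClass-like object or a bare Shape/array."""
    if hasattr(candidate, "reference_coords"):
        return candidate.name, np.asarray(candidate.reference_coords, dtype=float)
    return getattr(candidate, "name", ""), _as_points(candidate)


def procrustes_fit(observed, reference, permutation, allow_reflection: bool = True):
    """Optimal rotation/scale for a fixed correspondence.

    ``permutation[i]`` is the reference vertex paired with observed vertex i.
    Returns ``(rotation, scale, distance)`` where ``scale * rotation @ x_i``
    best approximates ``y_perm[i]``.
    """
    X = _as_points(observed)
    _, Y = _reference_of(reference)
    perm = np.asarray(permutation, dtype=int)
    if len(X) != len(Y):
        raise ValueError("point counts differ")
    if sorted(perm.tolist()) != list(range(len(Y))):
        raise ValueError("permutation is not a bijection")
    Yp = Y[perm]
    # maximize tr(R M) with M = X^T Yp; R = V D U^T from M = U S V^T
    M = X.T @ Yp
    U, sig, Vt = np.linalg.svd(M)
    D = np.eye(3)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    trace = float((sig * np.diag(D)).sum())
    ssq_x = float((X * X).sum())
    scale = trace / ssq_x
    if scale <= 0:
        raise DegenerateShapeError("optimal scale is not positive")
    resid = scale * (X @ R.T) - Yp
    distance = float(np.sqrt((resid * resid).sum() / (Y * Y).sum()))
    return R, scale, distance


# ---------------------------------------------------------------------------
# exhaustive search (vectorized over all permutations)

_PERM_CACHE: dict[int, np.ndarray] = {}


def _permutation_table(n: int) -> np.ndarray:
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.intp
        )
    return _PERM_CACHE[n]


def _sym3_eigvals(B: np.ndarray) -> np.ndarray:
    """Closed-form (Cardano) eigenvalues of stacked symmetric 3x3 matrices."""
    a00, a01, a02 = B[..., 0, 0], B[..., 0, 1], B[..., 0, 2]
    a11, a12, a22 = B[..., 1, 1], B[..., 1, 2], B[..., 2, 2]
    p1 = a01**2 + a02**2 + a12**2
    q = (a00 + a11 + a22) / 3.0
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    pn = np.where(p > 0, p, 1.0)
    b00, b11, b22 = (a00 - q) / pn, (a11 - q) / pn, (a22 - q) / pn
    b01, b02, b12 = a01 / pn, a02 / pn, a12 / pn
    det_b = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    phi = np.arccos(np.clip(det_b / 2.0, -1.0, 1.0)) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return np.stack([e1, e2, e3], axis=-1)


def _det3(A: np.ndarray) -> np.ndarray:
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _exhaustive_permutation(X: np.ndarray, Y: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Permutation maximizing the (det-corrected) singular-value trace."""
    n = len(X)
    P = _permutation_table(n)
    # A_k = X^T Y[P_k] for each permutation k
    A = np.einsum("ni,knj->kij", X, Y[P])
    sig = np.sqrt(np.clip(_sym3_eigvals(np.einsum("kji,kjl->kil", A, A)), 0.0, None))
    if allow_reflection:
        trace = sig.sum(axis=-1)
    else:
        trace = sig.sum(axis=-1) - np.where(_det3(A) < 0, 2.0 * sig.min(axis=-1), 0.0)
    return P[int(np.argmax(trace))]


# ---------------------------------------------------------------------------
# heuristic search for large coordination numbers

def _frame(v1: np.ndarray, v2: np.ndarray, flip: bool) -> np.ndarray | None:
    f1 = v1 / np.linalg.norm(v1)
    c = np.cross(v1, v2)
    nc = np.linalg.norm(c)
    if nc < 1e-8:
        return None
    f3 = c / nc
    if flip:
        f3 = -f3
    f2 = np.cross(f3, f1)
    return np.stack([f1, f2, f3], axis=1)  # columns


def _heuristic_permutation(X: np.ndarray, Y: np.ndarray, allow_reflection: bool) -> np.ndarray:
    n = len(X)
    Xu = X / np.linalg.norm(X, axis=1, keepdims=True)
    Yu = Y / np.linalg.norm(Y, axis=1, keepdims=True)
    i1 = 0
    cross_norms = np.linalg.norm(np.cross(Xu[i1], Xu), axis=1)
    i2 = int(np.argmax(cross_norms))
    Fx = _frame(Xu[i1], Xu[i2], flip=False)
    best_perm, best_d = None, np.inf
    flips = (False, True) if allow_reflection else (False,)
    for j1 in range(n):
        for j2 in range(n):
            if j1 == j2:
                continue
            for flip in flips:
                Fy = _frame(Yu[j1], Yu[j2], flip=flip)
                if Fx is None or Fy is None:
                    continue
                R = Fy @ Fx.T  # may be improper when flip=True
                # first assignment on directions only (no scale yet), then
                # alternate closed-form fit <-> metric re-assignment
                XRu = (R @ Xu.T).T
                cost = ((XRu[:, None, :] - Yu[None, :, :]) ** 2).sum(-1)
                perm = None
                for _ in range(40):
                    rows, cols = linear_sum_assignment(cost)
                    new_perm = np.empty(n, dtype=int)
                    new_perm[rows] = cols
                    if perm is not None and np.array_equal(new_perm, perm):
                        break
                    perm = new_perm
                    R, s, _ = procrustes_fit(X, Y, perm, allow_reflection)
                    XR = s * (R @ X.T).T
                    cost = ((XR[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
                _, _, d = procrustes_fit(X, Y, perm, allow_reflection)
                if d < best_d - 1e-15:
                    best_d, best_perm = d, perm
    if best_perm is None:  # all reference pairs collinear: fall back to identity
        best_perm = np.arange(n)
    return np.asarray(best_perm)


def best_match(observed, candidate, allow_reflection: bool = True) -> ProcrustesMatch:
    """Best correspondence between an observed shape and a reference class.

    Exhaustive over all n! permutations for n <= ``EXHAUSTIVE_CAP``; above
    that, rotation seeds from reference vertex pairs are completed by
    minimum-cost bipartite assignment and refined by alternating fit and
    re-assignment.
    """
    name, Y = _reference_of(candidate)
    X = _as_points(observed)
    if len(X) != len(Y):
        raise ValueError(
            f"point-count mismatch: observed {len(X)} vs reference {len(Y)}"
        )
    if len(X) <= EXHAUSTIVE_CAP:
        perm = _exhaustive_permutation(X, Y, allow_reflection)
    else:
        perm = _heuristic_permutation(X, Y, allow_reflection)
    R, s, d = procrustes_fit(X, Y, perm, allow_reflection)
    return ProcrustesMatch(
        class_name=name,
        permutation=tuple(int(p) for p in perm),
        rotation=R,
        scale=s,
        distance=d,
        reflected=bool(np.linalg.det(R) < 0),
    )


def brute_force_match(observed, candidate, allow_reflection: bool = True) -> ProcrustesMatch:
    """Test oracle: plain-loop exhaustive enumeration of all permutations.

    Independent of the vectorized search path: each permutation is fitted
    with the closed-form solution and the residual is measured directly on
    the transformed coordinates.
    """
    name, Y = _reference_of(candidate)
    X = _as_points(observed)
    if len(X) != len(Y):
        raise ValueError("point-count mismatch")
    if len(X) > EXHAUSTIVE_CAP:
        raise ValueError(f"brute force capped at {EXHAUSTIVE_CAP} vertices")
    best = None
    for perm in itertools.permutations(range(len(X))):
        R, s, d = procrustes_fit(X, Y, perm, allow_reflection)
        if best is None or d < best.distance:
            best = ProcrustesMatch(
                class_name=name,
                permutation=perm,
                rotation=R,
                scale=s,
                distance=d,
                reflected=bool(np.linalg.det(R) < 0),
            )
    return best
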