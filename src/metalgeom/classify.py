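"""Coordination-class assignment by iterative bond-capture descent.

An environment is offered at the three capture radii alpha = 1.3, 1.2, 1.1
(nested neighbour sets).  The widest radius is tried first, so a site is
always assigned to the class with the highest possible coordination number;
only when no class of matching coordination comes in under the (strict)
Procrustes threshold does the classifier descend to the next radius — this
is what lets a stretched octahedron fall back to square-planar when two
opposite vertices drop out of capture range.

Post-hoc review statistics (low coordination, small class, bond-length
outliers) are surfaced as flags for human inspection, never as automated
re-decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .config import DEFAULTS
from .crystal import MetalEnvironment
from .library import ClassLibrary, classes_by_coordination
from .procrustes import Shape, best_match


@dataclass(frozen=True)
class RankedMatch:
    class_name: str
    coordination_number: int
    distance: float
    alpha: float
    neighbor_indices: tuple[int, ...]  # indices into that alpha's environment
    permutation: tuple[int, ...]
    passed: bool


@dataclass
class ClassificationResult:
    environment_id: str
    matches: list[RankedMatch] = field(default_factory=list)
    accepted: bool = False
    threshold: float = DEFAULTS.procrustes_threshold
    alphas_tried: list[float] = field(default_factory=list)
    reason: str = ""

    @property
    def best(self) -> RankedMatch | None:
        return self.matches[0] if self.matches else None

    @property
    def alpha_used(self) -> float | None:
        return self.best.alpha if self.best else None


def _rank_key(m: RankedMatch):
    # highest coordination first, then smallest distance, then name
    return (-m.coordination_number, m.distance, m.class_name)


def _cap_neighbors(
    env: MetalEnvironment, max_coordination: int | None
) -> tuple[int, ...]:
    """Neighbour indices kept after the -c cap (longest normalized bonds
    dropped first, distance measured in units of d12 / (r1 + r2))."""
    idx = list(range(len(env.neighbors)))
    if max_coordination is None or len(idx) <= max_coordination:
        return tuple(idx)
    r1 = chem.covalent_radius(env.metal_element)
    norm = [
        env.neighbors[i].distance
        / (r1 + chem.covalent_radius(env.neighbors[i].element))
        for i in idx
    ]
    order = sorted(idx, key=lambda i: (norm[i], env.neighbors[i].label))
    return tuple(sorted(order[:max_coordination]))


def classify_environment(
    env_by_alpha: dict[float, MetalEnvironment],
    library: ClassLibrary,
    threshold: float = DEFAULTS.procrustes_threshold,
    max_coordination: int | None = None,
    allow_reflection: bool = DEFAULTS.allow_reflection,
) -> ClassificationResult:
    """Assign a metal environment to a coordination class.

    ``env_by_alpha`` maps each capture multiplier to the (hydrogen-free)
    environment extracted at that multiplier; the multipliers are tried in
    descending order.  Acceptance requires a Procrustes distance strictly
    below *threshold* against a class whose coordination number equals the
    (possibly capped) neighbour count.
    """
    alphas = sorted(env_by_alpha, reverse=True)
    env0 = env_by_alpha[alphas[0]]
    result = ClassificationResult(
        environment_id=f"{env0.source_id}:{env0.metal_label}",
        threshold=threshold,
    )
    all_matches: list[RankedMatch] = []
    for alpha in alphas:
        env = env_by_alpha[alpha]
        result.alphas_tried.append(alpha)
        subset = _cap_neighbors(env, max_coordination)
        n = len(subset)
        if n == 0:
            continue
        candidates = classes_by_coordination(library, n, used_only=True)
        if not candidates or n < 2:
            continue
        points = env.neighbor_points()[list(subset)]
        alpha_matches = []
        for cand in candidates:
            m = best_match(Shape(points), cand, allow_reflection=allow_reflection)
            alpha_matches.append(
                RankedMatch(
                    class_name=cand.name,
                    coordination_number=cand.coordination_number,
                    distance=m.distance,
                    alpha=alpha,
                    neighbor_indices=subset,
                    permutation=m.permutation,
                    passed=m.distance < threshold,
                )
            )
        all_matches.extend(alpha_matches)
        if any(m.passed for m in alpha_matches):
            # success at this capture radius: no smaller alpha is consulted
            passing = sorted([m for m in all_matches if m.passed], key=_rank_key)
            failing = sorted([m for m in all_matches if not m.passed], key=_rank_key)
            result.matches = passing + failing
            result.accepted = True
            return result
    result.matches = sorted(all_matches, key=_rank_key)
    result.accepted = False
    result.reason = "no neighbors" if not all_matches else "no class below threshold"
    return result


def small_class_flag(n_class: int, n_metal: int) -> bool:
    """Small-class review rule: N_class <= min(30, 0.05 * N_metal)."""
    if n_class < 0 or n_metal < 0:
        raise ValueError("counts must be non-negative")
    if n_metal < n_class:
        raise ValueError("n_metal must be >= n_class")
    return n_class <= min(30.0, 0.05 * n_metal)


def iqr_outliers(values) -> np.ndarray:
    """Upper-tail outlier flags: value > q3 + 1.5 * IQR.

    Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("insufficient data: need at least 4 values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return v > q3 + 1.5 * (q3 - q1)


def low_coordination_flag(result: ClassificationResult) -> bool:
    """True for an accepted assignment with coordination number <= 4."""
    if not result.accepted or result.best is None:
        return False
    return result.best.coordination_number <= 4


@dataclass(frozen=True)
class ReviewFlags:
    low_coordination: bool = False
    small_class: bool = False
    bond_outlier: bool = False
    review_band: bool = False  # distance in (review_band, threshold)


def review_flags(
    result: ClassificationResult,
    n_class: int | None = None,
    n_metal: int | None = None,
    bond_outlier: bool = False,
    review_band: float = DEFAULTS.review_band,
) -> ReviewFlags:
    """Assemble the post-classification review flags for one site."""
    if not result.accepted or result.best is None:
        return ReviewFlags()
    small = (
        small_class_flag(n_class, n_metal)
        if n_class is not None and n_metal is not None
        else False
    )
    return ReviewFlags(
        low_coordination=low_coordination_flag(result),
        small_class=small,
        bond_outlier=bond_outlier,
        review_band=review_band < result.best.distance < result.threshold,
    )
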