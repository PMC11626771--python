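"""Package-wide defaults.

All tunables that the pipeline consults live here so that a run is fully
described by a :class:`RunDefaults` instance plus explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunDefaults:
    """Default knobs for mining, classification and statistics.

    alphas
        Bond-capture multipliers of the covalent-radius sum, tried in
        descending order during classification.
    procrustes_threshold
        Strict upper bound on the accepted Procrustes distance.
    review_band
        Distances above this (but below the threshold) are flagged for
        manual review.
    translation_range
        Lattice translations used during symmetry expansion: all integer
        shifts in ``[-translation_range, +translation_range]`` per axis.
    merge_tolerance
        Cartesian distance (A) below which two symmetry images of the same
        element are considered duplicates.
    bond_sd_floor / angle_sd_floor
        Minimal esds written to restraints when data are degenerate.
    """

    alphas: tuple[float, ...] = (1.3, 1.2, 1.1)
    procrustes_threshold: float = 0.3
    review_band: float = 0.2
    allow_reflection: bool = True
    exhaustive_permutation_cap: int = 8
    translation_range: int = 1
    merge_tolerance: float = 0.1
    resolution_cutoff: float = 0.82
    r_factor_cutoff: float = 0.1
    bond_sd_floor: float = 0.02
    angle_sd_floor: float = 3.0
    max_modes: int = 3
    min_mode_weight: float = 0.05
    seed: int = 20406
    radius_overrides: dict[str, float] = field(default_factory=dict)


DEFAULTS = RunDefaults()
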