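"""Restraint statistics: multimodal bond lengths and folded-normal angles.

Bond lengths for a (metal element, ligand element, class) population are
often multimodal (spin states, oxidation states, bridging vs terminal
ligands), so they are summarized by a small Gaussian mixture whose component
count is chosen by BIC, guarded by a minimum component weight and a minimum
separation (components closer than one pooled standard deviation are
pooled).  Angles live on the half-circle [0, 180] deg: a plain normal fit
misbehaves near the linear limit, so the likelihood used is the von Mises
density folded about 0/180 — mass near 180 deg stays at 180 deg instead of
wrapping.  The derived esd is deg(1/sqrt(kappa)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e
from sklearn.mixture import GaussianMixture

from .classify import ClassificationResult
from .config import DEFAULTS
from .crystal import MetalEnvironment

KAPPA_CAP = 1.0e6
MIN_SAMPLES = 5


@dataclass(frozen=True)
class Mode:
    mean: float
    sd: float
    count: int


@dataclass(frozen=True)
class BondLengthModes:
    modes: tuple[Mode, ...]
    most_probable: int
    low_data: bool = False

    @property
    def top(self) -> Mode:
        return self.modes[self.most_probable]

    @property
    def n(self) -> int:
        return sum(m.count for m in self.modes)


@dataclass(frozen=True)
class AngleStats:
    mu: float      # degrees in [0, 180]
    kappa: float
    n: int
    low_data: bool = False

    @property
    def sd(self) -> float:
        """Esd in degrees, floored for degenerate concentrations."""
        return max(DEFAULTS.angle_sd_floor, math.degrees(1.0 / math.sqrt(self.kappa)))


def detect_modes(
    samples,
    max_modes: int = DEFAULTS.max_modes,
    seed: int = DEFAULTS.seed,
    min_weight: float = DEFAULTS.min_mode_weight,
    sd_floor: float = DEFAULTS.bond_sd_floor,
) -> BondLengthModes:
    """Summarize a bond-length sample as 1..max_modes Gaussian components."""
    x = np.asarray(samples, dtype=float)
    if np.any(x <= 0):
        raise ValueError("bond lengths must be positive")
    if x.size < MIN_SAMPLES:
        mean = float(x.mean()) if x.size else 0.0
        sd = max(float(x.std(ddof=1)) if x.size > 1 else 0.0, sd_floor)
        return BondLengthModes(
            modes=(Mode(mean, sd, int(x.size)),), most_probable=0, low_data=True
        )
    X = x.reshape(-1, 1)
    best_k, best_bic, best_gm = 1, np.inf, None
    for k in range(1, min(max_modes, x.size // 2) + 1):
        gm = GaussianMixture(
            n_components=k, random_state=seed, n_init=3, reg_covar=1e-8
        ).fit(X)
        if k > 1 and gm.weights_.min() < min_weight:
            continue
        bic = gm.bic(X)
        if bic < best_bic:
            best_k, best_bic, best_gm = k, bic, gm
    labels = best_gm.predict(X)
    groups = [x[labels == g] for g in range(best_k) if np.any(labels == g)]
    groups.sort(key=lambda g: g.mean())
    # pool components closer than one pooled sd
    merged: list[np.ndarray] = []
    for g in groups:
        if merged:
            prev = merged[-1]
            pooled = math.sqrt(
                (prev.var(ddof=0) * prev.size + g.var(ddof=0) * g.size)
                / (prev.size + g.size)
            )
            if abs(g.mean() - prev.mean()) < max(pooled, sd_floor):
                merged[-1] = np.concatenate([prev, g])
                continue
        merged.append(g)
    modes = tuple(
        Mode(
            mean=float(g.mean()),
            sd=max(float(g.std(ddof=1)) if g.size > 1 else 0.0, sd_floor),
            count=int(g.size),
        )
        for g in merged
    )
    most = max(range(len(modes)), key=lambda i: (modes[i].count, -i))
    return BondLengthModes(modes=modes, most_probable=most)


def _folded_vm_negll(params, t):
    """Negative log-likelihood of the folded von Mises on [0, pi]."""
    mu, log_kappa = params
    kappa = math.exp(min(log_kappa, math.log(KAPPA_CAP)))
    a = kappa * np.cos(t - mu)
    b = kappa * np.cos(t + mu)
    # log I0(kappa) = log i0e(kappa) + kappa  (overflow-safe)
    log_norm = math.log(2.0 * math.pi) + math.log(i0e(kappa)) + kappa
    return -(np.logaddexp(a, b).sum() - t.size * log_norm)


def fit_symmetrized_von_mises(angles) -> AngleStats:
    """Maximum-likelihood mu/kappa of the folded von Mises for angles in
    degrees on [0, 180]."""
    a = np.asarray(angles, dtype=float)
    if np.any((a < 0) | (a > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    t = np.radians(a)
    if a.size < MIN_SAMPLES:
        # circular mean of the folded sample as a fallback
        mu = float(np.degrees(np.arctan2(np.sin(t).mean(), np.cos(t).mean()))) % 360.0
        mu = min(abs(mu), abs(360.0 - mu))
        return AngleStats(mu=min(mu, 180.0), kappa=KAPPA_CAP, n=int(a.size), low_data=True)
    if t.std() < 1e-9:
        return AngleStats(mu=float(a.mean()), kappa=KAPPA_CAP, n=int(a.size))
    # coarse grid on mu, profile-ish start for kappa, then local refinement
    best = None
    r_bar = min(float(np.hypot(np.sin(2 * t).mean(), np.cos(2 * t).mean())), 0.999)
    kappa0 = max(r_bar * (2.0 - r_bar**2) / (1.0 - r_bar**2), 0.5)
    for mu0 in np.radians(np.arange(0.0, 180.1, 7.5)):
        nll = _folded_vm_negll((mu0, math.log(kappa0)), t)
        if best is None or nll < best[0]:
            best = (nll, mu0)
    res = minimize(
        _folded_vm_negll,
        x0=[best[1], math.log(kappa0)],
        args=(t,),
        method="L-BFGS-B",
        bounds=[(0.0, math.pi), (math.log(1e-3), math.log(KAPPA_CAP))],
    )
    mu = float(np.degrees(res.x[0]))
    kappa = float(math.exp(res.x[1]))
    return AngleStats(mu=min(max(mu, 0.0), 180.0), kappa=kappa, n=int(a.size))


# ---------------------------------------------------------------------------
# accumulation over a classified corpus

BondKey = tuple[str, str, str]          # (metal element, ligand element, class)
AngleKey = tuple[str, str, tuple[int, int]]  # (class, metal element, ref vertex pair)


@dataclass
class RestraintTable:
    """Per-key raw samples plus fitted summaries, keyed as the restraints
    are applied: bonds by (metal, ligand element, class), angles by the
    matched class's reference-vertex pair (so cis and trans octahedral
    angles are separate populations)."""

    bond_samples: dict[BondKey, list[float]] = field(default_factory=dict)
    angle_samples: dict[AngleKey, list[float]] = field(default_factory=dict)
    seed: int = DEFAULTS.seed

    def add_bond(self, key: BondKey, length: float) -> None:
        self.bond_samples.setdefault(key, []).append(float(length))

    def add_angle(self, key: AngleKey, angle_deg: float) -> None:
        self.angle_samples.setdefault(key, []).append(float(angle_deg))

    def bond_modes(self, key: BondKey) -> BondLengthModes:
        return detect_modes(self.bond_samples[key], seed=self.seed)

    def angle_stats(self, key: AngleKey) -> AngleStats:
        return fit_symmetrized_von_mises(self.angle_samples[key])

    def to_dict(self) -> dict:
        return {
            "bonds": {
                "|".join(k): sorted(v) for k, v in sorted(self.bond_samples.items())
            },
            "angles": {
                f"{k[0]}|{k[1]}|{k[2][0]}-{k[2][1]}": sorted(v)
                for k, v in sorted(self.angle_samples.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RestraintTable":
        table = cls()
        for key, vals in d.get("bonds", {}).items():
            m, l, c = key.split("|")
            table.bond_samples[(m, l, c)] = list(vals)
        for key, vals in d.get("angles", {}).items():
            c, m, pair = key.split("|")
            i, j = pair.split("-")
            table.angle_samples[(c, m, (int(i), int(j)))] = list(vals)
        return table


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def accumulate(
    classified: list[tuple[MetalEnvironment, ClassificationResult]],
    seed: int = DEFAULTS.seed,
) -> RestraintTable:
    """Build a RestraintTable from accepted classifications.

    Pure function of its input corpus: re-running on the same corpus yields
    an identical table.
    """
    table = RestraintTable(seed=seed)
    for env, result in classified:
        if not result.accepted or result.best is None:
            continue
        best = result.best
        subset = list(best.neighbor_indices)
        points = env.neighbor_points()[subset]
        for local_i, env_i in enumerate(subset):
            neigh = env.neighbors[env_i]
            table.add_bond(
                (env.metal_element, neigh.element, best.class_name), neigh.distance
            )
            for local_j in range(local_i + 1, len(subset)):
                ref_pair = tuple(
                    sorted(
                        (best.permutation[local_i], best.permutation[local_j])
                    )
                )
                table.add_angle(
                    (best.class_name, env.metal_element, ref_pair),
                    _angle_deg(points[local_i], points[local_j]),
                )
    return table
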