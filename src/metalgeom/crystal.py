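"""Small-molecule crystal handling: entry filters, symmetry expansion and
metal-environment extraction.

Structures come from crystallographic CIF files (cell, symmetry operators,
fractional coordinates, occupancies, quality metadata).  Mining keeps only
well-determined entries (sub-0.82 A resolution, R < 0.1, no partially
occupied non-H atoms, at least one metal), expands the asymmetric unit by
all symmetry operators over the +/-1 cell translations, and pulls every
atom with d12 <= alpha * (r1 + r2) around each metal of the asymmetric
unit, at alpha = 1.1, 1.2 and 1.3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np

from . import chem
from .config import DEFAULTS

DEFAULT_ALPHAS = DEFAULTS.alphas


@dataclass(frozen=True)
class AtomSite:
    label: str
    element: str
    fract: tuple[float, float, float]
    occupancy: float = 1.0


@dataclass
class CrystalStructure:
    name: str
    cell: tuple[float, float, float, float, float, float]  # a b c alpha beta gamma
    symops: list[str]
    sites: list[AtomSite]
    resolution: float | None = None
    r_factor: float | None = None

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0 < ang < 180 for ang in (al, be, ga)):
            raise ValueError("cell angles must lie in (0, 180)")
        if not any(gemmi.Op(op) == gemmi.Op("x,y,z") for op in self.symops):
            self.symops = ["x,y,z"] + list(self.symops)

    @property
    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def orth(self, fract) -> np.ndarray:
        p = self.unit_cell.orthogonalize(gemmi.Fractional(*fract))
        return np.array([p.x, p.y, p.z])


@dataclass(frozen=True)
class ExpandedAtom:
    element: str
    label: str
    position: np.ndarray  # Cartesian A
    site_index: int       # back-reference into CrystalStructure.sites


@dataclass(frozen=True)
class EnvironmentAtom:
    element: str
    label: str
    position: np.ndarray
    distance: float


@dataclass(frozen=True)
class MetalEnvironment:
    metal_element: str
    metal_label: str
    metal_position: np.ndarray
    neighbors: tuple[EnvironmentAtom, ...]
    alpha: float
    source_id: str = ""

    def neighbor_points(self) -> np.ndarray:
        return np.array([a.position - self.metal_position for a in self.neighbors])

    def neighbor_elements(self) -> list[str]:
        return [a.element for a in self.neighbors]


@dataclass(frozen=True)
class FilterVerdict:
    source_id: str
    passed: bool
    reason: str = ""


def read_crystal_cif(path: str | Path) -> CrystalStructure:
    """Read a small-molecule CIF (cell, symmetry, atom sites, quality tags)."""
    path = str(path)
    small = gemmi.read_small_structure(path)
    block = gemmi.cif.read(path).sole_block()

    def _num(*tags):
        for tag in tags:
            v = block.find_value(tag)
            if v is not None and v not in ("?", "."):
                try:
                    return float(v.strip("()").split("(")[0])
                except ValueError:
                    continue
        return None

    resolution = _num("_reflns_d_resolution_high", "_diffrn_reflns_resolution_high")
    if resolution is None:
        theta = _num("_diffrn_reflns_theta_max")
        wav = _num("_diffrn_radiation_wavelength")
        if theta and wav and 0 < theta < 90:
            resolution = wav / (2.0 * np.sin(np.radians(theta)))
    r_factor = _num("_refine_ls_R_factor_all", "_refine_ls_R_factor_gt")

    cell = small.cell
    sites = [
        AtomSite(
            label=s.label,
            element=s.element.name,
            fract=(s.fract.x, s.fract.y, s.fract.z),
            occupancy=s.occ if s.occ > 0 else 1.0,
        )
        for s in small.sites
    ]
    symops = list(small.symops) or ["x,y,z"]
    return CrystalStructure(
        name=small.name or Path(path).stem,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        symops=symops,
        sites=sites,
        resolution=resolution,
        r_factor=r_factor,
    )


def passes_entry_filters(
    structure: CrystalStructure,
    resolution_cutoff: float = DEFAULTS.resolution_cutoff,
    r_factor_cutoff: float = DEFAULTS.r_factor_cutoff,
) -> FilterVerdict:
    """Apply the entry-selection rules; always returns a verdict."""
    sid = structure.name
    if structure.resolution is None or structure.r_factor is None:
        return FilterVerdict(sid, False, "missing metadata")
    if not structure.resolution < resolution_cutoff:
        return FilterVerdict(sid, False, "resolution")
    if not structure.r_factor < r_factor_cutoff:
        return FilterVerdict(sid, False, "R factor")
    for site in structure.sites:
        if not chem.is_hydrogen(site.element) and abs(site.occupancy - 1.0) > 1e-6:
            return FilterVerdict(sid, False, "partial occupancy")
    if not any(chem.is_metal(s.element) for s in structure.sites
               if s.element in chem.covalent_radius_table()):
        return FilterVerdict(sid, False, "no metal")
    return FilterVerdict(sid, True, "")


def expand_symmetry(
    structure: CrystalStructure,
    translation_range: int = DEFAULTS.translation_range,
    merge_tolerance: float | None = DEFAULTS.merge_tolerance,
) -> list[ExpandedAtom]:
    """All symmetry images over the translation block, in Cartesian A.

    Images of the same element closer than *merge_tolerance* are merged,
    keeping the first by (site, operator, translation) order; pass
    ``merge_tolerance=None`` to keep every generated image.
    """
    cell = structure.unit_cell
    if cell.volume <= 0:
        raise ValueError("singular cell matrix")
    ops = [gemmi.Op(s) for s in structure.symops]
    shifts = [
        (i, j, k)
        for i in range(-translation_range, translation_range + 1)
        for j in range(-translation_range, translation_range + 1)
        for k in range(-translation_range, translation_range + 1)
    ]
    shifts.sort()
    atoms: list[ExpandedAtom] = []
    grid: dict[tuple, list[int]] = {}
    tol = merge_tolerance if merge_tolerance else 0.0

    def _is_duplicate(elem: str, pos: np.ndarray) -> bool:
        if not tol:
            return False
        key0 = tuple(np.floor(pos / tol).astype(int))
        for dk in np.ndindex(3, 3, 3):
            key = (key0[0] + dk[0] - 1, key0[1] + dk[1] - 1, key0[2] + dk[2] - 1)
            for idx in grid.get(key, ()):
                a = atoms[idx]
                if a.element == elem and np.linalg.norm(a.position - pos) < tol:
                    return True
        return False

    for si, site in enumerate(structure.sites):
        for op in ops:
            base = op.apply_to_xyz(list(site.fract))
            for shift in shifts:
                fr = (base[0] + shift[0], base[1] + shift[1], base[2] + shift[2])
                pos = structure.orth(fr)
                if _is_duplicate(site.element, pos):
                    continue
                atoms.append(
                    ExpandedAtom(site.element, site.label, pos, site_index=si)
                )
                if tol:
                    key = tuple(np.floor(pos / tol).astype(int))
                    grid.setdefault(key, []).append(len(atoms) - 1)
    return atoms


def asu_metal_atoms(structure: CrystalStructure) -> list[ExpandedAtom]:
    """Metal atoms of the asymmetric unit, in Cartesian coordinates."""
    out = []
    for i, site in enumerate(structure.sites):
        if site.element in chem.covalent_radius_table() and chem.is_metal(site.element):
            out.append(
                ExpandedAtom(site.element, site.label, structure.orth(site.fract), i)
            )
    return out


def extract_environment(
    metal: ExpandedAtom,
    expanded_atoms: list[ExpandedAtom],
    alpha: float,
    radius_overrides: dict[str, float] | None = None,
    source_id: str = "",
) -> MetalEnvironment:
    """All atoms with d12 <= alpha * (r1 + r2) around *metal*.

    The metal's own image (any atom coinciding with it) is excluded.
    """
    if alpha not in DEFAULT_ALPHAS:
        import warnings

        warnings.warn(f"non-standard alpha {alpha}", stacklevel=2)
    r1 = chem.covalent_radius(metal.element, radius_overrides)
    neighbors = []
    for atom in expanded_atoms:
        d = float(np.linalg.norm(atom.position - metal.position))
        if d < 1e-6:
            continue
        r2 = chem.covalent_radius(atom.element, radius_overrides)
        if d <= alpha * (r1 + r2):
            neighbors.append(
                EnvironmentAtom(atom.element, atom.label, atom.position, d)
            )
    neighbors.sort(key=lambda a: (a.distance, a.label))
    return MetalEnvironment(
        metal_element=metal.element,
        metal_label=metal.label,
        metal_position=metal.position,
        neighbors=tuple(neighbors),
        alpha=alpha,
        source_id=source_id,
    )


def extract_environments(
    structure: CrystalStructure,
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    translation_range: int = DEFAULTS.translation_range,
) -> dict[float, list[MetalEnvironment]]:
    """Per-alpha environments for every metal in the asymmetric unit."""
    expanded = expand_symmetry(structure, translation_range=translation_range)
    metals = asu_metal_atoms(structure)
    out: dict[float, list[MetalEnvironment]] = {}
    for alpha in alphas:
        out[alpha] = [
            extract_environment(m, expanded, alpha, source_id=structure.name)
            for m in metals
        ]
    return out


def partition_metal_metal(
    environments: list[MetalEnvironment],
) -> tuple[list[MetalEnvironment], list[MetalEnvironment]]:
    """Split environments into (no metal-metal bond, >=1 metal-metal bond)."""
    no_mm, mm = [], []
    for env in environments:
        has_mm = any(
            e in chem.covalent_radius_table() and chem.is_metal(e)
            for e in env.neighbor_elements()
        )
        (mm if has_mm else no_mm).append(env)
    return no_mm, mm


def strip_hydrogens(environment: MetalEnvironment) -> MetalEnvironment:
    """Drop H/D neighbours; everything else untouched."""
    kept = tuple(
        a for a in environment.neighbors if not chem.is_hydrogen(a.element)
    )
    return replace(environment, neighbors=kept)
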