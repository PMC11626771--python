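"""Idealized coordination-geometry classes and the packaged class library.

Every class stores reference ligand positions with the metal at the origin
and all metal-ligand distances normalized to exactly 1, so matching is
independent of the metal and ligand identities.  The packaged library is
regenerated from standard polyhedra constructions (documented per builder
below); sandwich classes place every ring atom at unit distance from the
metal with the ring polar angle fixed by a common chord convention.  The
library version tag records this regenerated provenance.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .procrustes import Shape, best_match

UNIT_TOL = 1e-9
LIBRARY_VERSION = "metalgeom-1 (regenerated from standard polyhedra; supplementary archive not vendored)"


class LibraryError(ValueError):
    pass


@dataclass(frozen=True)
class CoordinationClass:
    """A named ideal geometry with unit-normalized reference coordinates."""

    name: str
    coordination_number: int
    reference_coords: np.ndarray
    provenance: str = "pre-existing"  # "pre-existing" | "added[:COD code]"
    used: bool = True

    def __post_init__(self):
        pts = np.asarray(self.reference_coords, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise LibraryError(f"{self.name}: coordinates must be (n, 3)")
        if len(pts) != self.coordination_number:
            raise LibraryError(
                f"{self.name}: {len(pts)} points but coordination number "
                f"{self.coordination_number}"
            )
        norms = np.linalg.norm(pts, axis=1)
        if np.any(np.abs(norms - 1.0) > UNIT_TOL):
            raise LibraryError(f"{self.name}: reference points are not unit length")
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise LibraryError(f"{self.name}: coincident reference points")
        object.__setattr__(self, "reference_coords", pts)

    @property
    def shape(self) -> Shape:
        return Shape(self.reference_coords)


@dataclass
class ClassLibrary:
    classes: list[CoordinationClass] = field(default_factory=list)
    version: str = LIBRARY_VERSION

    def __post_init__(self):
        names = [c.name for c in self.classes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LibraryError(f"duplicate class names: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def get(self, name: str) -> CoordinationClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def register(self, cls: CoordinationClass) -> None:
        if any(c.name == cls.name for c in self.classes):
            raise LibraryError(f"class {cls.name!r} already registered")
        self.classes.append(cls)

    def coordination_numbers(self) -> list[int]:
        return sorted({c.coordination_number for c in self.classes})


def classes_by_coordination(
    library: ClassLibrary, n: int, used_only: bool = False
) -> list[CoordinationClass]:
    """All classes with coordination number *n*, sorted by name."""
    if n < 1:
        raise ValueError("coordination number must be >= 1")
    out = [
        c
        for c in library
        if c.coordination_number == n and (c.used or not used_only)
    ]
    return sorted(out, key=lambda c: c.name)


def make_ideal_class(
    points, name: str, provenance: str = "added", used: bool = True
) -> CoordinationClass:
    """Build a class from direction vectors, normalizing each to unit length."""
    pts = np.asarray(points, dtype=float)
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms < 1e-9):
        raise LibraryError(f"{name}: zero-length direction")
    unit = pts / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(cos, -1.0)
    if cos.max() > math.cos(math.radians(0.1)):
        raise LibraryError(f"{name}: duplicate directions within tolerance")
    return CoordinationClass(
        name=name,
        coordination_number=len(unit),
        reference_coords=unit,
        provenance=provenance,
        used=used,
    )


# ---------------------------------------------------------------------------
# constructions
#
# _polar(theta, phi): unit vector at polar angle theta from +z, azimuth phi.
# _ring(n, theta, offset): regular n-ring of unit vectors at polar theta.
# Ring chord convention for sandwich classes: the in-ring nearest-neighbour
# chord is 0.70 (roughly a 1.4 A C-C bond over a 2.0 A metal-carbon bond),
# which fixes sin(theta) = 0.35 / sin(pi/n) and makes every sandwich_n_m
# construction fully determined.

RING_CHORD = 0.70


def _polar(theta: float, phi: float) -> list[float]:
    return [
        math.sin(theta) * math.cos(phi),
        math.sin(theta) * math.sin(phi),
        math.cos(theta),
    ]


def _ring(n: int, theta: float, offset: float = 0.0) -> list[list[float]]:
    return [_polar(theta, offset + 2.0 * math.pi * k / n) for k in range(n)]


def _ring_theta(n: int) -> float:
    s = RING_CHORD / (2.0 * math.sin(math.pi / n)) if n > 1 else 0.0
    if s >= 1.0:
        raise LibraryError(f"ring of {n} atoms impossible under chord convention")
    return math.asin(s)


def _sandwich(n: int, m: int) -> list[list[float]]:
    """Two parallel rings (sizes n >= m) on opposite sides of the metal.

    m == 1 degenerates to a single axial cap at the south pole; m == 2 to a
    symmetric pair close to the south pole with the same chord convention.
    The smaller ring is staggered by half its azimuthal step.
    """
    pts = _ring(n, _ring_theta(n))
    if m == 1:
        pts.append([0.0, 0.0, -1.0])
    elif m == 2:
        th = math.asin(RING_CHORD / 2.0)
        pts += [_polar(math.pi - th, 0.0), _polar(math.pi - th, math.pi)]
    else:
        pts += _ring(m, math.pi - _ring_theta(m), offset=math.pi / m)
    return pts


_TETRA_ANGLE = math.acos(-1.0 / 3.0)  # 109.471 deg
_PRISM_THETA = math.atan(2.0 / math.sqrt(3.0))  # square-face trigonal prism
# square antiprism with equal square and inter-square edges
_ANTIPRISM_THETA = math.asin(math.sqrt(4.0 / (4.0 + math.sqrt(2.0))))
# D2d triangulated dodecahedron (Hoard-Silverton favourable angles)
_DODEC_A = math.radians(36.85)
_DODEC_B = math.radians(69.46)


def _dodecahedron() -> list[list[float]]:
    a, b = _DODEC_A, _DODEC_B
    return [
        _polar(a, 0.0),
        _polar(a, math.pi),
        _polar(math.pi - a, math.pi / 2),
        _polar(math.pi - a, 3 * math.pi / 2),
        _polar(b, math.pi / 2),
        _polar(b, 3 * math.pi / 2),
        _polar(math.pi - b, 0.0),
        _polar(math.pi - b, math.pi),
    ]


def _cube() -> list[list[float]]:
    r = 1.0 / math.sqrt(3.0)
    return [
        [sx * r, sy * r, sz * r]
        for sx in (1, -1)
        for sy in (1, -1)
        for sz in (1, -1)
    ]


_POLES = [[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]


def _constructions() -> list[tuple[str, str, bool, list[list[float]]]]:
    """(name, provenance, used, points) for every packaged class."""
    c: list[tuple[str, str, bool, list[list[float]]]] = []
    pre = "pre-existing"

    c.append(("Linear", pre, True, [_polar(0, 0), _polar(math.pi, 0)]))
    c.append(("Bent", pre, True, [_polar(0, 0), _polar(math.radians(120), 0)]))

    c.append(("Trigonal-planar", pre, True, _ring(3, math.pi / 2)))
    c.append(("Pyramid", pre, True, _ring(3, _TETRA_ANGLE)))
    c.append(("T-shape", pre, True,
              [_polar(0, 0), _polar(math.pi, 0), _polar(math.pi / 2, 0)]))

    c.append(("Tetrahedral", pre, True, [_polar(0, 0)] + _ring(3, _TETRA_ANGLE)))
    c.append(("Square-planar", pre, True, _ring(4, math.pi / 2)))
    c.append(("Trigonal-pyramid", pre, True, [_polar(0, 0)] + _ring(3, math.pi / 2)))

    c.append(("Square-pyramid", pre, True, [_polar(0, 0)] + _ring(4, math.pi / 2)))
    c.append(("Trigonal-bipyramid", pre, True, _POLES + _ring(3, math.pi / 2)))

    c.append(("Octahedral", pre, True, _POLES + _ring(4, math.pi / 2)))
    c.append(("Trigonal-prism", pre, True,
              _ring(3, _PRISM_THETA) + _ring(3, math.pi - _PRISM_THETA)))
    c.append(("Sandwich_4_2", "added:1558752", True, _sandwich(4, 2)))
    c.append(("Sandwich_5_1", "added:4110095", True, _sandwich(5, 1)))

    c.append(("Pentagonal-bipyramid", pre, True, _POLES + _ring(5, math.pi / 2)))
    c.append(("Sandwich_4_3", "added:4075391", True, _sandwich(4, 3)))
    c.append(("Sandwich_5_2", "added:7227676", True, _sandwich(5, 2)))

    c.append(("Cubic", pre, True, _cube()))
    c.append(("Dodecahedral", pre, True, _dodecahedron()))
    c.append(("Square-antiprismatic", pre, True,
              _ring(4, _ANTIPRISM_THETA)
              + _ring(4, math.pi - _ANTIPRISM_THETA, offset=math.pi / 4)))
    c.append(("Hexagonal-bipyramid", pre, True, _POLES + _ring(6, math.pi / 2)))
    c.append(("Sandwich_5_3", pre, True, _sandwich(5, 3)))
    c.append(("Sandwich_6_2", "added:4067378", True, _sandwich(6, 2)))

    c.append(("Sandwich_5_4", pre, True, _sandwich(5, 4)))
    c.append(("Sandwich_6_3", "added:7021276", True, _sandwich(6, 3)))

    c.append(("Sandwich_5_5", pre, True, _sandwich(5, 5)))
    c.append(("Sandwich_7_3", "added:4070696", True, _sandwich(7, 3)))

    c.append(("Sandwich_6_5", pre, True, _sandwich(6, 5)))
    c.append(("Sandwich_8_3", "added:4338644", True, _sandwich(8, 3)))

    c.append(("Sandwich_6_6", pre, False, _sandwich(6, 6)))
    c.append(("Sandwich_7_5", "added:4070477", True, _sandwich(7, 5)))

    c.append(("Sandwich_8_8", "added:2004620", True, _sandwich(8, 8)))
    return c


def build_default_library() -> ClassLibrary:
    """Regenerate the packaged library from the documented constructions."""
    lib = ClassLibrary(classes=[])
    for name, prov, used, pts in _constructions():
        lib.register(make_ideal_class(pts, name, provenance=prov, used=used))
    return lib


# ---------------------------------------------------------------------------
# plain-text class-definition format
#
#   class <name>
#   coordination <n>
#   provenance <pre-existing | added[:cod]>
#   used <yes|no>
#   <x> <y> <z>        (n lines)
#   end

def dump_library(library: ClassLibrary) -> str:
    lines = [f"# metalgeom class library | version: {library.version}"]
    for c in library:
        lines.append(f"class {c.name}")
        lines.append(f"coordination {c.coordination_number}")
        lines.append(f"provenance {c.provenance}")
        lines.append(f"used {'yes' if c.used else 'no'}")
        for p in c.reference_coords:
            lines.append(f"{p[0]:.15f} {p[1]:.15f} {p[2]:.15f}")
        lines.append("end")
    return "\n".join(lines) + "\n"


def parse_library(text: str) -> ClassLibrary:
    version = LIBRARY_VERSION
    classes: list[CoordinationClass] = []
    cur: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if line.startswith("#"):
            if "version:" in line:
                version = line.split("version:", 1)[1].strip()
            continue
        if not line:
            continue
        if line.startswith("class "):
            cur = {"name": line[6:].strip(), "points": []}
        elif cur is None:
            raise LibraryError(f"line {lineno}: content outside a class block")
        elif line.startswith("coordination "):
            cur["coordination"] = int(line.split()[1])
        elif line.startswith("provenance "):
            cur["provenance"] = line.split(None, 1)[1]
        elif line.startswith("used "):
            cur["used"] = line.split()[1] == "yes"
        elif line == "end":
            try:
                classes.append(
                    CoordinationClass(
                        name=cur["name"],
                        coordination_number=cur["coordination"],
                        reference_coords=np.array(cur["points"]),
                        provenance=cur.get("provenance", "pre-existing"),
                        used=cur.get("used", True),
                    )
                )
            except KeyError as exc:
                raise LibraryError(f"class {cur['name']}: missing field {exc}") from None
            cur = None
        else:
            cur["points"].append([float(v) for v in line.split()])
    if cur is not None:
        raise LibraryError(f"unterminated class block {cur['name']!r}")
    return ClassLibrary(classes=classes, version=version)


def load_class_library(source: str | Path | None = None) -> ClassLibrary:
    """Load the packaged default library, or one from a user path."""
    if source is None:
        text = (
            importlib.resources.files("metalgeom") / "data" / "coordination_classes.txt"
        ).read_text()
    else:
        text = Path(source).read_text()
    return parse_library(text)


def class_separation(a: CoordinationClass, b: CoordinationClass) -> float:
    """Procrustes distance between two classes of equal coordination."""
    return best_match(a.shape, b).distance
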