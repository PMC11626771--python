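"""Chemical reference tables: covalent radii, metal set, oxidation states.

The tables are shipped as plain TSV package data and loaded once at import.
Radii are single-bond covalent radii; for the spin-state ambiguous first-row
transition metals (Mn, Fe, Co) the packaged default is the high-spin (larger)
value, which makes neighbour capture permissive — the iterative bond-capture
descent in the classifier then tightens the selection.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache


class UnknownElementError(KeyError):
    """Raised for an element symbol absent from the reference tables."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown element: {self.symbol!r}"


def _data_text(name: str) -> str:
    return (importlib.resources.files("metalgeom") / "data" / name).read_text()


def _parse_rows(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def covalent_radius_table() -> dict[str, float]:
    """Element symbol -> covalent radius in Angstrom."""
    table = {}
    for row in _parse_rows(_data_text("covalent_radii.tsv")):
        symbol, radius = row[0], float(row[1])
        if radius <= 0:
            raise ValueError(f"non-positive radius for {symbol}")
        table[symbol] = radius
    return table


@lru_cache(maxsize=None)
def oxidation_state_table() -> dict[str, tuple[int, ...]]:
    """Metal symbol -> ascending tuple of common oxidation states."""
    table = {}
    for row in _parse_rows(_data_text("oxidation_states.tsv")):
        symbol, states = row[0], tuple(int(s) for s in row[1].split(","))
        if not states or list(states) != sorted(states):
            raise ValueError(f"bad oxidation-state row for {symbol}")
        table[symbol] = states
    return table


@lru_cache(maxsize=None)
def metal_elements() -> frozenset[str]:
    """The set of element symbols treated as metals.

    Defined as exactly the elements carrying an oxidation-state row, so the
    two tables can never disagree.
    """
    return frozenset(oxidation_state_table())


def _normalize(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        raise UnknownElementError(symbol)
    return s[0].upper() + s[1:].lower()


def covalent_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    """Covalent radius in Angstrom (case-insensitive symbol lookup)."""
    symbol = _normalize(element)
    if overrides and symbol in overrides:
        return overrides[symbol]
    try:
        return covalent_radius_table()[symbol]
    except KeyError:
        raise UnknownElementError(element) from None


def is_metal(element: str) -> bool:
    """True iff *element* belongs to the packaged metal set."""
    symbol = _normalize(element)
    if symbol not in covalent_radius_table():
        raise UnknownElementError(element)
    return symbol in metal_elements()


def common_oxidation_states(metal: str) -> list[int]:
    """Common oxidation states of *metal*, ascending."""
    symbol = _normalize(metal)
    if symbol not in metal_elements():
        raise UnknownElementError(metal)
    return list(oxidation_state_table()[symbol])


def is_hydrogen(element: str) -> bool:
    return _normalize(element) in ("H", "D", "T")
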