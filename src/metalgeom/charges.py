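"""Nominal charge assignment around metal atoms.

Ligand atoms get formal charges by valence bookkeeping (incident bond-order
sum against the element's default valences), with aromatic systems first
Kekulized so that, e.g., a cyclopentadienyl ring carries two double bonds
and a single carbanion — ring totals, not per-atom placement, are the
meaningful quantity.  Metal-ligand links are counted ionically: they do not
enter any ligand valence sum.  Each metal's charge is then chosen from its
common oxidation states so the total nominal charge of its bonded component
is as close to zero as possible, ties toward the smaller state; this keeps
metal charges chemically plausible, and adding an anionic ligand (the
protein context) can only push the chosen state up.

Hydrogens are not added here: graphs must arrive complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from . import chem

BOND_ORDERS = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5,
               "metal": 0.0, "deloc": 1.5}

# default valences; first entry is the preferred one
DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,), "B": (3,), "C": (4,), "N": (3,), "O": (2,), "F": (1,),
    "Si": (4,), "P": (3, 5), "S": (2, 4, 6), "Cl": (1,), "As": (3, 5),
    "Se": (2, 4, 6), "Br": (1,), "Te": (2, 4, 6), "I": (1,),
}

# hard ceilings on the incident bond-order sum (beyond is a valence error)
MAX_BONDSUM: dict[str, int] = {
    "H": 1, "B": 4, "C": 4, "N": 4, "O": 3, "F": 1, "Si": 4, "P": 5,
    "S": 6, "Cl": 3, "As": 5, "Se": 6, "Br": 3, "Te": 6, "I": 3,
}


class ValenceError(ValueError):
    pass


@dataclass(frozen=True)
class GraphAtom:
    name: str
    element: str


@dataclass(frozen=True)
class GraphBond:
    atom1: str
    atom2: str
    order: str = "single"       # single | double | triple | aromatic
    metal_link: bool = False    # ionic/dative metal-ligand link


@dataclass
class MolecularGraph:
    """Atoms plus covalent bonds and (separately marked) metal-ligand links."""

    atoms: list[GraphAtom] = field(default_factory=list)
    bonds: list[GraphBond] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate atom names")
        known = set(names)
        seen = set()
        for b in self.bonds:
            if b.atom1 not in known or b.atom2 not in known:
                raise ValueError(f"bond references unknown atom: {b.atom1}-{b.atom2}")
            if b.atom1 == b.atom2:
                raise ValueError(f"self-bond on {b.atom1}")
            key = frozenset((b.atom1, b.atom2))
            if key in seen:
                raise ValueError(f"duplicate bond {b.atom1}-{b.atom2}")
            seen.add(key)
            if b.order not in BOND_ORDERS:
                raise ValueError(f"invalid bond order {b.order!r}")

    def atom(self, name: str) -> GraphAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def element(self, name: str) -> str:
        return self.atom(name).element

    def is_metal_atom(self, name: str) -> bool:
        return chem.is_metal(self.element(name))

    def to_networkx(self, include_metal_links: bool = True) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.name, element=a.element)
        for b in self.bonds:
            if b.metal_link and not include_metal_links:
                continue
            g.add_edge(b.atom1, b.atom2, order=b.order, metal_link=b.metal_link)
        return g


def _kekulize(graph: MolecularGraph) -> dict[frozenset, float]:
    """Assign orders to aromatic bonds via maximum matching.

    Each Kekule-eligible atom takes at most one double bond; carbons are
    always eligible, nitrogens only when their sigma connectivity leaves
    room (pyridine-type), oxygen/sulfur contribute lone pairs instead.
    Any valid alternation is acceptable — ring totals are what downstream
    consumers use.
    """
    orders: dict[frozenset, float] = {}
    aromatic = [b for b in graph.bonds if b.order == "aromatic" and not b.metal_link]
    if not aromatic:
        return orders
    sigma_degree: dict[str, float] = {}
    for b in graph.bonds:
        if b.metal_link:
            continue
        for name in (b.atom1, b.atom2):
            sigma_degree[name] = sigma_degree.get(name, 0) + 1

    def eligible(name: str) -> bool:
        el = graph.element(name)
        if el == "C":
            return True
        if el in ("N", "P"):
            return sigma_degree.get(name, 0) <= 2
        return False

    sub = nx.Graph()
    for b in aromatic:
        orders[frozenset((b.atom1, b.atom2))] = 1.0
        if eligible(b.atom1) and eligible(b.atom2):
            sub.add_edge(b.atom1, b.atom2)
    for u, v in nx.max_weight_matching(sub, maxcardinality=True):
        orders[frozenset((u, v))] = 2.0
    return orders


def ligand_formal_charges(graph: MolecularGraph) -> dict[str, int]:
    """Formal charge of every nonmetal atom by valence bookkeeping."""
    kekule = _kekulize(graph)
    bondsum: dict[str, float] = {a.name: 0.0 for a in graph.atoms}
    for b in graph.bonds:
        if b.metal_link:
            continue  # ionic counting: metal links carry no ligand valence
        order = kekule.get(frozenset((b.atom1, b.atom2)), BOND_ORDERS[b.order])
        bondsum[b.atom1] += order
        bondsum[b.atom2] += order
    charges: dict[str, int] = {}
    for atom in graph.atoms:
        if chem.is_metal(atom.element):
            continue
        total = bondsum[atom.name]
        if abs(total - round(total)) > 1e-6:
            raise ValenceError(
                f"{atom.name}: non-integral bond-order sum {total} "
                "(unmatched aromatic system?)"
            )
        total = int(round(total))
        valences = DEFAULT_VALENCES.get(atom.element)
        if valences is None:
            raise ValenceError(f"{atom.name}: no default valence for {atom.element}")
        if total > MAX_BONDSUM.get(atom.element, max(valences)):
            raise ValenceError(
                f"{atom.name}: bond-order sum {total} exceeds the valence "
                f"capacity of {atom.element}"
            )
        # charge relative to the best-fitting default valence; ties resolve
        # to the negative (anionic) interpretation
        best = min(((abs(total - v), total - v) for v in valences))
        charges[atom.name] = best[1]
    return charges


@dataclass
class ChargeAssignment:
    atom_charges: dict[str, int]
    metal_states: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    @property
    def total_charge(self) -> int:
        return sum(self.atom_charges.values())

    def group_charge(self, names) -> int:
        return sum(self.atom_charges[n] for n in names)


def assign_metal_charges(graph: MolecularGraph) -> ChargeAssignment:
    """Choose metal oxidation states minimizing local net charge.

    For each connected component (covalent bonds plus metal links) the
    metals, taken in name order, pick the common oxidation state that
    brings the running total charge closest to zero; exact balance is the
    expectation and anything else is flagged.
    """
    ligand = ligand_formal_charges(graph)
    g = graph.to_networkx(include_metal_links=True)
    assignment = ChargeAssignment(atom_charges=dict(ligand), metal_states={})
    for component in nx.connected_components(g):
        metals = sorted(
            n for n in component if chem.is_metal(graph.element(n))
        )
        running = sum(ligand.get(n, 0) for n in component)
        for name in metals:
            states = chem.common_oxidation_states(graph.element(name))
            q = min(states, key=lambda s: (abs(running + s), s))
            if running + q != 0:
                assignment.warnings.append(
                    f"{name}: no common oxidation state of "
                    f"{graph.element(name)} balances the local charge "
                    f"({running:+d} + {q:+d} != 0)"
                )
            assignment.atom_charges[name] = q
            assignment.metal_states[name] = q
            running += q
    return assignment
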