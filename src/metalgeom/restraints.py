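"""Monomer restraint dictionaries, model sites and restraint JSON output.

Dictionaries use the CCP4 monomer-library mmCIF dialect
(``_chem_comp_atom``/``_chem_comp_bond``/``_chem_comp_angle`` with ideal
values and esds).  Parsing goes through gemmi's CIF reader; writing uses a
deterministic formatter so that an update touches only the rows it changes.

The metal bookkeeping mirrors how restraints are regenerated: metal atoms
and their bonds/angles are removed (with an exact reversal record kept),
the organic part is described elsewhere, and the metals are reinserted with
tentative positions at the mean of their bonding partners and tentative
bond lengths r1 + r2.  Updating replaces metal-involving bond and angle
ideals from classified statistics — the single most probable mode goes into
the dictionary, the full mode lists into a JSON document for downstream
restraint generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from . import chem
from .classify import ClassificationResult, _cap_neighbors
from .config import DEFAULTS
from .charges import GraphAtom, GraphBond, MolecularGraph
from .crystal import EnvironmentAtom, MetalEnvironment
from .stats import RestraintTable

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# monomer dictionary model

@dataclass(frozen=True)
class DictAtom:
    name: str
    element: str
    charge: float = 0.0


@dataclass(frozen=True)
class DictBond:
    atom1: str
    atom2: str
    order: str = "single"
    value: float | None = None   # ideal length, A
    esd: float | None = None

    def involves(self, names: set[str]) -> bool:
        return self.atom1 in names or self.atom2 in names


@dataclass(frozen=True)
class DictAngle:
    atom1: str
    atom2: str                   # vertex
    atom3: str
    value: float | None = None   # ideal angle, deg
    esd: float | None = None

    def involves(self, names: set[str]) -> bool:
        return bool({self.atom1, self.atom2, self.atom3} & names)


@dataclass
class MonomerDictionary:
    comp_id: str
    atoms: list[DictAtom] = field(default_factory=list)
    bonds: list[DictBond] = field(default_factory=list)
    angles: list[DictAngle] = field(default_factory=list)

    def __post_init__(self):
        if not self.comp_id:
            raise ValueError("component id must be non-empty")
        names = {a.name for a in self.atoms}
        if len(names) != len(self.atoms):
            raise ValueError("duplicate atom names")
        for b in self.bonds:
            if b.atom1 not in names or b.atom2 not in names:
                raise ValueError(f"bond references unknown atom {b.atom1}-{b.atom2}")
            if b.esd is not None and b.esd <= 0:
                raise ValueError(f"non-positive bond esd on {b.atom1}-{b.atom2}")
        for a in self.angles:
            if {a.atom1, a.atom2, a.atom3} - names:
                raise ValueError("angle references unknown atom")
            if a.esd is not None and a.esd <= 0:
                raise ValueError("non-positive angle esd")

    def element(self, name: str) -> str:
        for a in self.atoms:
            if a.name == name:
                return a.element
        raise KeyError(name)

    def metal_names(self) -> list[str]:
        return [a.name for a in self.atoms if chem.is_metal(a.element)]

    def to_molecular_graph(self) -> MolecularGraph:
        metals = set(self.metal_names())
        return MolecularGraph(
            atoms=[GraphAtom(a.name, a.element) for a in self.atoms],
            bonds=[
                GraphBond(
                    b.atom1,
                    b.atom2,
                    b.order,
                    metal_link=bool({b.atom1, b.atom2} & metals),
                )
                for b in self.bonds
            ],
        )


# ---------------------------------------------------------------------------
# mmCIF restraint dialect I/O

def parse_monomer_dictionary(text: str) -> MonomerDictionary:
    doc = gemmi.cif.read_string(text)
    block = None
    for b in doc:
        if b.find_loop("_chem_comp_atom.atom_id") or b.find_values(
            "_chem_comp_atom.atom_id"
        ):
            block = b
            break
    if block is None:
        raise ValueError("no _chem_comp_atom category found")

    def rows(prefix, tags):
        table = block.find(prefix, tags)
        return [[table[i][j] for j in range(len(tags))] for i in range(len(table))]

    atoms, comp_id = [], ""
    for comp, name, elem, charge in rows(
        "_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol", "?charge"]
    ):
        comp_id = comp
        q = float(charge) if charge not in (None, "?", ".", "") else 0.0
        atoms.append(DictAtom(name=name, element=elem.capitalize(), charge=q))

    def num(v):
        return None if v in (None, "?", ".", "") else float(v)

    bonds = [
        DictBond(a1, a2, order.lower(), num(val), num(esd))
        for _, a1, a2, order, val, esd in rows(
            "_chem_comp_bond.",
            ["comp_id", "atom_id_1", "atom_id_2", "?type", "?value_dist",
             "?value_dist_esd"],
        )
    ]
    angles = [
        DictAngle(a1, a2, a3, num(val), num(esd))
        for _, a1, a2, a3, val, esd in rows(
            "_chem_comp_angle.",
            ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "?value_angle",
             "?value_angle_esd"],
        )
    ]
    return MonomerDictionary(comp_id=comp_id, atoms=atoms, bonds=bonds, angles=angles)


def read_monomer_dictionary(path: str | Path) -> MonomerDictionary:
    return parse_monomer_dictionary(Path(path).read_text())


def _fmt(v, prec) -> str:
    return "." if v is None else f"{v:.{prec}f}"


def write_monomer_dictionary(d: MonomerDictionary) -> str:
    """Deterministic serialization (stable row order and formatting)."""
    out = [f"data_comp_{d.comp_id}", "#", "loop_"]
    out += [f"_chem_comp_atom.{t}" for t in ("comp_id", "atom_id", "type_symbol",
                                             "charge")]
    for a in d.atoms:
        out.append(f"{d.comp_id} {a.name} {a.element.upper()} {a.charge:.2f}")
    out += ["#", "loop_"]
    out += [f"_chem_comp_bond.{t}" for t in ("comp_id", "atom_id_1", "atom_id_2",
                                             "type", "value_dist",
                                             "value_dist_esd")]
    for b in d.bonds:
        out.append(
            f"{d.comp_id} {b.atom1} {b.atom2} {b.order} "
            f"{_fmt(b.value, 3)} {_fmt(b.esd, 3)}"
        )
    out += ["#", "loop_"]
    out += [f"_chem_comp_angle.{t}" for t in ("comp_id", "atom_id_1", "atom_id_2",
                                              "atom_id_3", "value_angle",
                                              "value_angle_esd")]
    for a in d.angles:
        out.append(
            f"{d.comp_id} {a.atom1} {a.atom2} {a.atom3} "
            f"{_fmt(a.value, 2)} {_fmt(a.esd, 2)}"
        )
    out.append("#")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# metal removal / reinsertion bookkeeping

@dataclass(frozen=True)
class RemovalRecord:
    """Everything needed to reverse strip_and_remember_metals exactly."""

    atoms: tuple[tuple[int, DictAtom], ...]
    bonds: tuple[tuple[int, DictBond], ...]
    angles: tuple[tuple[int, DictAngle], ...]

    @property
    def metal_names(self) -> list[str]:
        return [a.name for _, a in self.atoms]

    def partners(self, metal: str) -> list[str]:
        out = []
        for _, b in self.bonds:
            if b.atom1 == metal:
                out.append(b.atom2)
            elif b.atom2 == metal:
                out.append(b.atom1)
        return out


def strip_and_remember_metals(
    d: MonomerDictionary,
) -> tuple[MonomerDictionary, RemovalRecord]:
    """Remove metal atoms and every restraint touching them."""
    metals = set(d.metal_names())
    rec = RemovalRecord(
        atoms=tuple((i, a) for i, a in enumerate(d.atoms) if a.name in metals),
        bonds=tuple((i, b) for i, b in enumerate(d.bonds) if b.involves(metals)),
        angles=tuple((i, a) for i, a in enumerate(d.angles) if a.involves(metals)),
    )
    stripped = MonomerDictionary(
        comp_id=d.comp_id,
        atoms=[a for a in d.atoms if a.name not in metals],
        bonds=[b for b in d.bonds if not b.involves(metals)],
        angles=[a for a in d.angles if not a.involves(metals)],
    )
    return stripped, rec


def reinsert_metals(
    d: MonomerDictionary,
    record: RemovalRecord,
    coordinates: dict[str, np.ndarray] | None = None,
) -> tuple[MonomerDictionary, dict[str, np.ndarray], list[str]]:
    """Reverse the strip exactly; optionally compute tentative geometry.

    With *coordinates* (positions of the nonmetal atoms), each metal gets a
    tentative position at the arithmetic mean of its bonding partners and
    each restored metal bond a tentative length r1 + r2.  Returns the
    restored dictionary, the metal positions and degeneracy flags.
    """
    atoms = list(d.atoms)
    for i, a in sorted(record.atoms):
        atoms.insert(i, a)
    bonds = list(d.bonds)
    angles = list(d.angles)
    flags: list[str] = []
    positions: dict[str, np.ndarray] = {}
    restored_bonds = dict(record.bonds)
    if coordinates is not None:
        elements = {a.name: a.element for a in atoms}
        for _, metal_atom in record.atoms:
            partners = record.partners(metal_atom.name)
            missing = [p for p in partners if p not in coordinates]
            if missing:
                raise ValueError(
                    f"partner(s) without coordinates: {', '.join(missing)}"
                )
            if partners:
                positions[metal_atom.name] = np.mean(
                    [np.asarray(coordinates[p], float) for p in partners], axis=0
                )
            if len(partners) == 1:
                flags.append(f"{metal_atom.name}: single bonding partner")
        r = {
            i: replace(
                b,
                value=chem.covalent_radius(elements[b.atom1])
                + chem.covalent_radius(elements[b.atom2]),
            )
            for i, b in restored_bonds.items()
        }
        restored_bonds = r
    for i in sorted(restored_bonds):
        bonds.insert(i, restored_bonds[i])
    for i, a in sorted(record.angles):
        angles.insert(i, a)
    restored = MonomerDictionary(
        comp_id=d.comp_id, atoms=atoms, bonds=bonds, angles=angles
    )
    return restored, positions, flags


# ---------------------------------------------------------------------------
# macromolecular models

@dataclass(frozen=True)
class ModelInstance:
    chain: str
    seqid: int
    comp_id: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    positions: np.ndarray
    occupancies: tuple[float, ...]
    b_values: tuple[float, ...]

    @property
    def mean_occupancy(self) -> float:
        return float(np.mean(self.occupancies))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.b_values))


def read_model(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _instances(model: gemmi.Structure, comp_id: str) -> list[ModelInstance]:
    out = []
    for chain in model[0]:
        for res in chain:
            if res.name != comp_id:
                continue
            out.append(
                ModelInstance(
                    chain=chain.name,
                    seqid=res.seqid.num,
                    comp_id=comp_id,
                    atom_names=tuple(a.name for a in res),
                    elements=tuple(a.element.name for a in res),
                    positions=np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res]),
                    occupancies=tuple(a.occ for a in res),
                    b_values=tuple(a.b_iso for a in res),
                )
            )
    return out


def select_instance(model: gemmi.Structure, comp_id: str) -> ModelInstance:
    """Best-ordered instance: highest occupancy first, then smallest B."""
    instances = _instances(model, comp_id)
    if not instances:
        raise ValueError(f"component {comp_id!r} not present in the model")
    return min(
        instances,
        key=lambda r: (-r.mean_occupancy, r.mean_b, r.chain, r.seqid),
    )


def extract_site_from_model(
    model: gemmi.Structure,
    instance: ModelInstance,
    max_coordination: int | None = None,
    alphas: tuple[float, ...] = DEFAULTS.alphas,
) -> dict[str, dict[float, MetalEnvironment]]:
    """Per-metal environments of one component instance, from the whole model.

    Neighbours come from every atom in the model (protein and solvent
    included — the context matters), filtered by: hydrogens removed, other
    metals excluded from the ligand set, and the neighbour count capped at
    *max_coordination* by dropping the longest bonds in units of
    d12 / (r1 + r2).
    """
    all_atoms = []
    for chain in model[0]:
        for res in chain:
            for a in res:
                all_atoms.append(
                    (f"{chain.name}/{res.seqid.num}/{a.name}", a.element.name,
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                )
    sites: dict[str, dict[float, MetalEnvironment]] = {}
    for name, element, pos in zip(
        instance.atom_names, instance.elements, instance.positions
    ):
        if element not in chem.covalent_radius_table() or not chem.is_metal(element):
            continue
        r1 = chem.covalent_radius(element)
        per_alpha: dict[float, MetalEnvironment] = {}
        for alpha in alphas:
            neigh = []
            for label, el, p in all_atoms:
                if chem.is_hydrogen(el):
                    continue
                if el in chem.covalent_radius_table() and chem.is_metal(el):
                    continue
                dist = float(np.linalg.norm(p - pos))
                if dist < 1e-6:
                    continue
                if dist <= alpha * (r1 + chem.covalent_radius(el)):
                    neigh.append(EnvironmentAtom(el, label, p, dist))
            neigh.sort(key=lambda a: (a.distance, a.label))
            env = MetalEnvironment(
                metal_element=element,
                metal_label=name,
                metal_position=pos,
                neighbors=tuple(neigh),
                alpha=alpha,
                source_id=f"{instance.chain}/{instance.seqid}/{instance.comp_id}",
            )
            if max_coordination is not None:
                keep = _cap_neighbors(env, max_coordination)
                env = replace(env, neighbors=tuple(env.neighbors[i] for i in keep))
            per_alpha[alpha] = env
        sites[name] = per_alpha
    return sites


# ---------------------------------------------------------------------------
# dictionary update

@dataclass(frozen=True)
class RestraintChange:
    kind: str                  # "bond" | "angle"
    atoms: tuple[str, ...]
    old_value: float | None
    old_esd: float | None
    new_value: float
    new_esd: float


@dataclass
class UpdateReport:
    changes: list[RestraintChange] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def _pooled_bond_modes(table: RestraintTable, metal: str, ligand: str):
    samples: list[float] = []
    for (m, l, _cls), vals in table.bond_samples.items():
        if m == metal and l == ligand:
            samples.extend(vals)
    if not samples:
        return None
    from .stats import detect_modes

    return detect_modes(samples, seed=table.seed)


def update_dictionary(
    dictionary: MonomerDictionary,
    table: RestraintTable,
    classifications: dict[str, ClassificationResult],
    environments: dict[str, MetalEnvironment] | None = None,
) -> tuple[MonomerDictionary, UpdateReport]:
    """Replace metal-involving restraint ideals from classified statistics.

    *classifications* and *environments* are keyed by metal atom name (the
    environment is the one whose neighbour subset the accepted match used).
    Metal bonds get the most probable mode of the matching
    (metal, ligand element, class) record; metal-centred angles get the
    symmetrized von Mises summary of the class's reference-vertex pair.
    When no class matched, only bond lengths are updated (pooled over
    classes).  Everything not involving a metal is untouched.
    """
    report = UpdateReport()
    metals = set(dictionary.metal_names())
    if not metals:
        return dictionary, report
    environments = environments or {}
    elements = {a.name: a.element for a in dictionary.atoms}

    # map (metal name, dictionary atom name) -> reference vertex index
    ref_vertex: dict[tuple[str, str], int] = {}
    class_of: dict[str, str | None] = {}
    for metal, result in classifications.items():
        best = result.best if result.accepted else None
        class_of[metal] = best.class_name if best else None
        env = environments.get(metal)
        if best is None or env is None:
            continue
        for local_i, env_i in enumerate(best.neighbor_indices):
            label = env.neighbors[env_i].label
            short = label.rsplit("/", 1)[-1]
            ref_vertex[(metal, short)] = best.permutation[local_i]

    new_bonds = []
    for b in dictionary.bonds:
        metal = b.atom1 if b.atom1 in metals else (b.atom2 if b.atom2 in metals else None)
        if metal is None:
            new_bonds.append(b)
            continue
        other = b.atom2 if b.atom1 == metal else b.atom1
        cls = class_of.get(metal)
        if cls is not None:
            key = (elements[metal], elements[other], cls)
            modes = (
                table.bond_modes(key) if key in table.bond_samples else None
            )
        else:
            modes = _pooled_bond_modes(table, elements[metal], elements[other])
        if modes is None:
            report.skipped.append(f"bond {b.atom1}-{b.atom2}: no statistics")
            new_bonds.append(b)
            continue
        top = modes.top
        report.changes.append(
            RestraintChange("bond", (b.atom1, b.atom2), b.value, b.esd,
                            round(top.mean, 3), round(top.sd, 3))
        )
        new_bonds.append(replace(b, value=round(top.mean, 3), esd=round(top.sd, 3)))

    new_angles = []
    for a in dictionary.angles:
        if a.atom2 not in metals:
            new_angles.append(a)
            continue
        metal = a.atom2
        cls = class_of.get(metal)
        v1 = ref_vertex.get((metal, a.atom1))
        v2 = ref_vertex.get((metal, a.atom3))
        if cls is None or v1 is None or v2 is None:
            if cls is None:
                report.skipped.append(
                    f"angle {a.atom1}-{a.atom2}-{a.atom3}: no class matched"
                )
            else:
                report.skipped.append(
                    f"angle {a.atom1}-{a.atom2}-{a.atom3}: arm not in environment"
                )
            new_angles.append(a)
            continue
        key = (cls, elements[metal], tuple(sorted((v1, v2))))
        if key not in table.angle_samples:
            report.skipped.append(
                f"angle {a.atom1}-{a.atom2}-{a.atom3}: no statistics"
            )
            new_angles.append(a)
            continue
        st = table.angle_stats(key)
        report.changes.append(
            RestraintChange("angle", (a.atom1, a.atom2, a.atom3), a.value, a.esd,
                            round(st.mu, 2), round(st.sd, 2))
        )
        new_angles.append(replace(a, value=round(st.mu, 2), esd=round(st.sd, 2)))

    updated = MonomerDictionary(
        comp_id=dictionary.comp_id,
        atoms=list(dictionary.atoms),
        bonds=new_bonds,
        angles=new_angles,
    )
    return updated, report


# ---------------------------------------------------------------------------
# restraint JSON

def site_to_json(
    metal_label: str,
    metal_element: str,
    result: ClassificationResult,
    env_by_alpha: dict[float, MetalEnvironment],
    table: RestraintTable,
) -> dict:
    """One site block: every matched class ranked, with full mode lists."""
    classes = []
    for m in result.matches:
        if not m.passed:
            continue
        env = env_by_alpha[m.alpha]
        bonds = []
        seen_elements = []
        for env_i in m.neighbor_indices:
            el = env.neighbors[env_i].element
            if el in seen_elements:
                continue
            seen_elements.append(el)
            key = (metal_element, el, m.class_name)
            if key in table.bond_samples:
                modes = table.bond_modes(key)
                bonds.append(
                    {
                        "ligand_element": el,
                        "modes": [
                            {"mean": round(md.mean, 4), "sd": round(md.sd, 4),
                             "count": md.count}
                            for md in modes.modes
                        ],
                        "most_probable": modes.most_probable,
                    }
                )
        angles = []
        for (cls, met, pair), _samples in sorted(table.angle_samples.items()):
            if cls != m.class_name or met != metal_element:
                continue
            st = table.angle_stats((cls, met, pair))
            angles.append(
                {"vertex1": pair[0], "vertex2": pair[1],
                 "mean": round(st.mu, 3), "sd": round(st.sd, 3), "count": st.n}
            )
        classes.append(
            {
                "name": m.class_name,
                "coordination_number": m.coordination_number,
                "procrustes_distance": round(m.distance, 6),
                "alpha": m.alpha,
                "bonds": bonds,
                "angles": angles,
            }
        )
    return {
        "metal": metal_label,
        "element": metal_element,
        "accepted": result.accepted,
        "classes": classes,
    }


def emit_restraint_json(sites: list[dict]) -> dict:
    if not sites:
        raise ValueError("at least one site is required")
    doc = {"schema_version": SCHEMA_VERSION, "sites": sites}
    validate_restraint_json(doc)
    return doc


def validate_restraint_json(doc: dict) -> None:
    """Structural validation against the shipped schema (raises ValueError)."""

    def req(cond, msg):
        if not cond:
            raise ValueError(f"restraint JSON invalid: {msg}")

    req(isinstance(doc, dict), "document must be an object")
    req(doc.get("schema_version") == SCHEMA_VERSION, "bad schema_version")
    req(isinstance(doc.get("sites"), list) and doc["sites"], "sites must be a non-empty list")
    for s in doc["sites"]:
        req(isinstance(s.get("metal"), str) and s["metal"], "site.metal")
        req(isinstance(s.get("element"), str) and s["element"], "site.element")
        req(isinstance(s.get("accepted"), bool), "site.accepted")
        req(isinstance(s.get("classes"), list), "site.classes")
        for c in s["classes"]:
            req(isinstance(c.get("name"), str) and c["name"], "class.name")
            req(isinstance(c.get("coordination_number"), int)
                and c["coordination_number"] >= 1, "class.coordination_number")
            req(isinstance(c.get("procrustes_distance"), (int, float))
                and c["procrustes_distance"] >= 0, "class.procrustes_distance")
            req(isinstance(c.get("bonds"), list), "class.bonds")
            for b in c["bonds"]:
                req(isinstance(b.get("ligand_element"), str), "bond.ligand_element")
                req(isinstance(b.get("modes"), list) and b["modes"], "bond.modes")
                req(isinstance(b.get("most_probable"), int)
                    and 0 <= b["most_probable"] < len(b["modes"]),
                    "bond.most_probable")
                for md in b["modes"]:
                    req(md.get("sd", -1) > 0 and md.get("count", 0) >= 1
                        and md.get("mean", -1) > 0, "bond mode fields")
            req(isinstance(c.get("angles"), list), "class.angles")
            for a in c["angles"]:
                req(0 <= a.get("mean", -1) <= 180, "angle.mean")
                req(a.get("sd", -1) > 0, "angle.sd")


def write_restraint_json(doc: dict, path: str | Path) -> None:
    validate_restraint_json(doc)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_restraint_json(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_restraint_json(doc)
    return doc
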