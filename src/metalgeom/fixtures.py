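"""Synthetic inputs for testing and demonstration: noisy ideal coordination
sites, toy P1/P-1 crystals, toy monomer dictionaries and toy models.

Everything is a pure function of its arguments and an explicit seed, so the
full test corpus is regenerated at run time and never stored.  Angular and
radial noise are independent knobs: each ideal direction is perturbed by a
Gaussian step in its tangent plane and renormalized, then scaled by the
base bond length times a relative jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from . import chem
from .config import DEFAULTS
from .crystal import (
    CrystalStructure,
    EnvironmentAtom,
    MetalEnvironment,
    expand_symmetry,
)
from .library import ClassLibrary, load_class_library
from .restraints import DictAngle, DictAtom, DictBond, MonomerDictionary


# ---------------------------------------------------------------------------
# noisy ideal sites

@dataclass(frozen=True)
class SiteRecipe:
    """Recipe for one synthetic metal site."""

    class_name: str
    seed: int
    metal: str = "Zn"
    ligand: str = "O"
    ligands: tuple[str, ...] | None = None  # per-vertex override
    bond_length: float = 2.0
    sigma: float = 0.0        # angular noise, radians
    jitter: float = 0.0       # relative bond-length noise

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.jitter <= 0.2:
            raise ValueError("jitter must lie in [0, 0.2]")


def make_site(
    recipe: SiteRecipe, library: ClassLibrary | None = None
) -> MetalEnvironment:
    """Instantiate a noisy site from an ideal class at random orientation."""
    library = library or load_class_library()
    cls = library.get(recipe.class_name)  # KeyError for unknown class
    rng = np.random.default_rng(recipe.seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    dirs = cls.reference_coords @ rot.T
    n = len(dirs)
    ligands = recipe.ligands or (recipe.ligand,) * n
    if len(ligands) != n:
        raise ValueError("ligand list length must match coordination number")
    points = []
    for v in dirs:
        if recipe.sigma > 0:
            # Gaussian step in the tangent plane, then renormalize
            g = rng.normal(size=3)
            g -= np.dot(g, v) * v
            v = v + recipe.sigma * g
            v = v / np.linalg.norm(v)
        length = recipe.bond_length * (1.0 + recipe.jitter * rng.normal())
        points.append(length * v)
    neighbors = tuple(
        EnvironmentAtom(
            element=el,
            label=f"L{i}",
            position=np.asarray(p),
            distance=float(np.linalg.norm(p)),
        )
        for i, (el, p) in enumerate(zip(ligands, points))
    )
    return MetalEnvironment(
        metal_element=recipe.metal,
        metal_label="M1",
        metal_position=np.zeros(3),
        neighbors=neighbors,
        alpha=max(DEFAULTS.alphas),
        source_id=f"synthetic:{recipe.class_name}:{recipe.seed}",
    )


def site_environments(
    recipe: SiteRecipe,
    library: ClassLibrary | None = None,
    alphas: tuple[float, ...] = DEFAULTS.alphas,
) -> dict[float, MetalEnvironment]:
    """The same synthetic site filtered at each capture radius."""
    full = make_site(recipe, library)
    r1 = chem.covalent_radius(full.metal_element)
    out = {}
    for alpha in alphas:
        kept = tuple(
            a
            for a in full.neighbors
            if a.distance <= alpha * (r1 + chem.covalent_radius(a.element))
        )
        out[alpha] = MetalEnvironment(
            metal_element=full.metal_element,
            metal_label=full.metal_label,
            metal_position=full.metal_position,
            neighbors=kept,
            alpha=alpha,
            source_id=full.source_id,
        )
    return out


# ---------------------------------------------------------------------------
# toy crystals

def make_crystal(
    atoms: list[tuple[str, tuple[float, float, float]]],
    cell: tuple[float, float, float, float, float, float] = (10, 10, 10, 90, 90, 90),
    spacegroup: str = "P1",
    resolution: float | None = 0.75,
    r_factor: float | None = 0.05,
    occupancies: dict[str, float] | None = None,
    name: str = "toy",
) -> str:
    """Small-molecule CIF text for a list of (element, fractional xyz) atoms.

    Quality metadata is settable to pass or fail the entry filters; pass
    ``None`` to omit a datum.  Raises if symmetry expansion brings two
    different atoms closer than 0.5 A (overlapping fixture).
    """
    if spacegroup not in ("P1", "P-1"):
        raise ValueError("only P1 and P-1 toy crystals are supported")
    occupancies = occupancies or {}
    counters: dict[str, int] = {}
    labelled = []
    for el, fr in atoms:
        counters[el] = counters.get(el, 0) + 1
        labelled.append((f"{el}{counters[el]}", el, fr))
    lines = [
        f"data_{name}",
        f"_cell_length_a {cell[0]:.4f}",
        f"_cell_length_b {cell[1]:.4f}",
        f"_cell_length_c {cell[2]:.4f}",
        f"_cell_angle_alpha {cell[3]:.3f}",
        f"_cell_angle_beta {cell[4]:.3f}",
        f"_cell_angle_gamma {cell[5]:.3f}",
        f"_symmetry_space_group_name_H-M '{'P 1' if spacegroup == 'P1' else 'P -1'}'",
    ]
    if resolution is not None:
        lines.append(f"_reflns_d_resolution_high {resolution:.3f}")
    if r_factor is not None:
        lines.append(f"_refine_ls_R_factor_all {r_factor:.4f}")
    lines += ["loop_", "_symmetry_equiv_pos_as_xyz", "'x,y,z'"]
    if spacegroup == "P-1":
        lines.append("'-x,-y,-z'")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for label, el, fr in labelled:
        occ = occupancies.get(label, 1.0)
        lines.append(
            f"{label} {el} {fr[0]:.5f} {fr[1]:.5f} {fr[2]:.5f} {occ:.3f}"
        )
    text = "\n".join(lines) + "\n"

    check = CrystalStructure(
        name=name,
        cell=cell,
        symops=["x,y,z"] + (["-x,-y,-z"] if spacegroup == "P-1" else []),
        sites=[],
    )
    from .crystal import AtomSite

    check.sites = [AtomSite(lbl, el, fr) for lbl, el, fr in labelled]
    expanded = expand_symmetry(check)
    for i in range(len(expanded)):
        for j in range(i + 1, len(expanded)):
            if expanded[i].site_index == expanded[j].site_index:
                continue
            d = float(np.linalg.norm(expanded[i].position - expanded[j].position))
            if d < 0.5:
                raise ValueError(
                    f"overlap after symmetry expansion: "
                    f"{expanded[i].label}/{expanded[j].label} at {d:.2f} A"
                )
    return text


def crystal_with_site(
    env: MetalEnvironment,
    center: tuple[float, float, float] = (0.5, 0.5, 0.5),
    cell: tuple[float, float, float, float, float, float] = (12, 12, 12, 90, 90, 90),
    **kwargs,
) -> str:
    """Embed a synthetic site into a P1 toy crystal around *center*."""
    a, b, c = cell[0], cell[1], cell[2]
    atoms = [(env.metal_element, center)]
    for nb in env.neighbors:
        rel = nb.position - env.metal_position
        atoms.append(
            (nb.element, (center[0] + rel[0] / a, center[1] + rel[1] / b,
                          center[2] + rel[2] / c))
        )
    return make_crystal(atoms, cell=cell, spacegroup="P1", **kwargs)


# ---------------------------------------------------------------------------
# toy monomer dictionaries

def _porphyrin_core(with_axial: bool) -> MonomerDictionary:
    """Fe in a porphyrin-like macrocycle, two pyrrole N formally anionic.

    One explicit Kekule structure: rings 0 and 2 are pyrrolide-type (both
    N-C bonds single), rings 1 and 3 pyrrole-type with an N=C double bond;
    methine bridges close the macrocycle with alternating single/double
    bonds so every carbon stays neutral.
    """
    atoms = [DictAtom("FE", "Fe")]
    bonds: list[DictBond] = []

    def bond(a1, a2, order="single", value=1.4, esd=0.02):
        bonds.append(DictBond(a1, a2, order, value, esd))

    for k in range(4):
        anionic = k in (0, 2)
        for nm, el in ((f"N{k}", "N"), (f"CA{k}", "C"), (f"CB{k}", "C"),
                       (f"CC{k}", "C"), (f"CD{k}", "C"), (f"CM{k}", "C"),
                       (f"HB{k}", "H"), (f"HC{k}", "H"), (f"HM{k}", "H")):
            atoms.append(DictAtom(nm, el))
        if anionic:
            bond(f"N{k}", f"CA{k}", "single")
            bond(f"N{k}", f"CD{k}", "single")
            if k == 0:
                bond(f"CA{k}", f"CB{k}", "double")
                bond(f"CB{k}", f"CC{k}", "single")
                bond(f"CC{k}", f"CD{k}", "double")
                bond(f"CD{k}", f"CM{k}", "single")
            else:  # ring 2: the double bond sits on the bridge side
                bond(f"CA{k}", f"CB{k}", "single")
                bond(f"CB{k}", f"CC{k}", "double")
                bond(f"CC{k}", f"CD{k}", "single")
                bond(f"CD{k}", f"CM{k}", "double")
        else:
            if k == 1:
                bond(f"N{k}", f"CA{k}", "single")
                bond(f"N{k}", f"CD{k}", "double")
            else:  # ring 3
                bond(f"N{k}", f"CA{k}", "double")
                bond(f"N{k}", f"CD{k}", "single")
            bond(f"CA{k}", f"CB{k}", "single")
            bond(f"CB{k}", f"CC{k}", "double")
            bond(f"CC{k}", f"CD{k}", "single")
            bond(f"CD{k}", f"CM{k}", "single" if k == 1 else "double")
        bond(f"CB{k}", f"HB{k}")
        bond(f"CC{k}", f"HC{k}")
        bond(f"CM{k}", f"HM{k}")
        bonds.append(DictBond("FE", f"N{k}", "single", 2.0, 0.05))
    # bridge closures CM{k} -> CA{k+1}
    bond("CM0", "CA1", "double")
    bond("CM1", "CA2", "double")
    bond("CM2", "CA3", "single")
    bond("CM3", "CA0", "single")
    angles = []
    if with_axial:
        atoms += [DictAtom("O5", "O"), DictAtom("H5", "H")]
        bond("O5", "H5")  # hydroxide-like anionic axial ligand
        bonds.append(DictBond("FE", "O5", "single", 1.9, 0.05))
    return MonomerDictionary(
        comp_id="HMC" if not with_axial else "HMX",
        atoms=atoms,
        bonds=bonds,
        angles=angles,
    )


def _metallocene(metal: str = "Ru") -> MonomerDictionary:
    atoms = [DictAtom(metal.upper(), metal)]
    bonds: list[DictBond] = []
    for r in (1, 2):
        names = [f"C{r}{i}" for i in range(5)]
        for i, nm in enumerate(names):
            atoms.append(DictAtom(nm, "C"))
            atoms.append(DictAtom(f"H{r}{i}", "H"))
        for i in range(5):
            bonds.append(
                DictBond(names[i], names[(i + 1) % 5], "aromatic", 1.42, 0.02)
            )
            bonds.append(DictBond(names[i], f"H{r}{i}", "single", 0.95, 0.02))
            bonds.append(DictBond(metal.upper(), names[i], "single", 2.2, 0.05))
    return MonomerDictionary(comp_id="MCN", atoms=atoms, bonds=bonds, angles=[])


def _aquo(metal: str = "Zn", n_water: int = 4) -> MonomerDictionary:
    atoms = [DictAtom(metal.upper(), metal)]
    bonds: list[DictBond] = []
    angles = []
    for i in range(1, n_water + 1):
        atoms += [DictAtom(f"O{i}", "O"), DictAtom(f"H{i}A", "H"),
                  DictAtom(f"H{i}B", "H")]
        bonds.append(DictBond(f"O{i}", f"H{i}A", "single", 0.96, 0.02))
        bonds.append(DictBond(f"O{i}", f"H{i}B", "single", 0.96, 0.02))
        bonds.append(DictBond(metal.upper(), f"O{i}", "single", 2.1, 0.08))
    for i in range(1, n_water + 1):
        for j in range(i + 1, n_water + 1):
            angles.append(DictAngle(f"O{i}", metal.upper(), f"O{j}", 109.47, 3.0))
    return MonomerDictionary(comp_id="AQ" + metal.upper()[0], atoms=atoms,
                             bonds=bonds, angles=angles)


CANNED_DICTIONARIES = {
    "haem-core": lambda: _porphyrin_core(with_axial=False),
    "haem-core-axial": lambda: _porphyrin_core(with_axial=True),
    "metallocene": _metallocene,
    "aquo": _aquo,
}


def make_toy_dictionary(spec: str | dict) -> MonomerDictionary:
    """Build a toy restraint dictionary from a canned name or a custom spec.

    A custom spec is ``{"comp_id", "atoms": [(name, element)], "bonds":
    [(a1, a2, order)]}``; bonds to metal atoms become metal links when the
    graph is derived.
    """
    if isinstance(spec, str):
        try:
            return CANNED_DICTIONARIES[spec]()
        except KeyError:
            raise ValueError(f"unknown canned dictionary {spec!r}") from None
    if not spec or not spec.get("atoms"):
        raise ValueError("empty dictionary spec")
    return MonomerDictionary(
        comp_id=spec.get("comp_id", "TOY"),
        atoms=[DictAtom(n, e) for n, e in spec["atoms"]],
        bonds=[
            DictBond(a1, a2, order, 1.5, 0.02)
            for a1, a2, order in spec.get("bonds", [])
        ],
        angles=[],
    )


# ---------------------------------------------------------------------------
# toy models

def make_model_pdb(
    instances: list[dict],
    context_atoms: list[tuple[str, str, tuple[float, float, float]]] = (),
) -> str:
    """PDB text for toy component instances plus optional context atoms.

    Each instance: ``{"comp_id", "chain", "seqid", "atoms": [(name, element,
    (x, y, z), occ, b)]}``.  Context atoms are ``(name, element, xyz)``
    placed in chain X as separate residues (protein/solvent stand-ins).
    """
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for inst in instances:
        cname = inst.get("chain", "A")
        chain = chains.setdefault(cname, gemmi.Chain(cname))
        res = gemmi.Residue()
        res.name = inst["comp_id"]
        res.seqid = gemmi.SeqId(int(inst.get("seqid", 1)), " ")
        res.het_flag = "H"
        for name, element, xyz, occ, b in inst["atoms"]:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*xyz)
            at.occ = float(occ)
            at.b_iso = float(b)
            res.add_atom(at)
        chain.add_residue(res)
    ctx_chain = gemmi.Chain("X")
    for i, (name, element, xyz) in enumerate(context_atoms, start=1):
        res = gemmi.Residue()
        res.name = "CTX"
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "H"
        at = gemmi.Atom()
        at.name = name
        at.element = gemmi.Element(element)
        at.pos = gemmi.Position(*xyz)
        at.occ = 1.0
        at.b_iso = 20.0
        res.add_atom(at)
        ctx_chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    if len(ctx_chain) > 0:
        model.add_chain(ctx_chain)
    st.add_model(model)
    st.cell = gemmi.UnitCell(50, 50, 50, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    return st.make_pdb_string()
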