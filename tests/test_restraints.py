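import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalgeom import chem
from metalgeom.classify import classify_environment
from metalgeom.fixtures import (
    SiteRecipe,
    make_model_pdb,
    make_toy_dictionary,
    site_environments,
)
from metalgeom.restraints import (
    DictAngle,
    DictAtom,
    DictBond,
    MonomerDictionary,
    emit_restraint_json,
    extract_site_from_model,
    parse_monomer_dictionary,
    read_model,
    read_restraint_json,
    reinsert_metals,
    select_instance,
    site_to_json,
    strip_and_remember_metals,
    update_dictionary,
    validate_restraint_json,
    write_monomer_dictionary,
    write_restraint_json,
)
from metalgeom.stats import accumulate


@pytest.fixture()
def aquo_dict():
    return make_toy_dictionary("aquo")  # Zn + 4 waters, bonds and angles


@pytest.fixture()
def tet_model(tmp_path, library):
    """Model with two Zn(O)4 instances differing in B, plus a context N."""
    tet = library.get("Tetrahedral").reference_coords
    insts = []
    for k, (b, center) in enumerate([(15.0, (10, 10, 10)), (40.0, (30, 30, 30))]):
        atoms = [("ZN", "Zn", center, 1.0, b)]
        for i, p in enumerate(tet):
            atoms.append(
                (f"O{i+1}", "O", tuple(np.asarray(center) + 2.0 * p), 1.0, b + 5)
            )
        insts.append({"comp_id": "AQZ", "chain": "A", "seqid": k + 1, "atoms": atoms})
    path = tmp_path / "model.pdb"
    path.write_text(make_model_pdb(insts))
    return read_model(path)


class TestDictionaryIO:
    def test_round_trip_semantics(self, aquo_dict):
        text = write_monomer_dictionary(aquo_dict)
        back = parse_monomer_dictionary(text)
        assert back.comp_id == aquo_dict.comp_id
        assert [(a.name, a.element) for a in back.atoms] == [
            (a.name, a.element) for a in aquo_dict.atoms
        ]
        assert [(b.atom1, b.atom2, b.value, b.esd) for b in back.bonds] == [
            (b.atom1, b.atom2, b.value, b.esd) for b in aquo_dict.bonds
        ]
        assert [(a.atom1, a.atom2, a.atom3, a.value) for a in back.angles] == [
            (a.atom1, a.atom2, a.atom3, a.value) for a in aquo_dict.angles
        ]

    def test_validation(self):
        with pytest.raises(ValueError):
            MonomerDictionary(comp_id="", atoms=[])
        with pytest.raises(ValueError, match="unknown atom"):
            MonomerDictionary(
                comp_id="X",
                atoms=[DictAtom("A", "C")],
                bonds=[DictBond("A", "B")],
            )
        with pytest.raises(ValueError, match="esd"):
            MonomerDictionary(
                comp_id="X",
                atoms=[DictAtom("A", "C"), DictAtom("B", "C")],
                bonds=[DictBond("A", "B", value=1.5, esd=0.0)],
            )


class TestStripReinsert:
    def test_round_trip_exact(self, aquo_dict):
        stripped, record = strip_and_remember_metals(aquo_dict)
        assert stripped.metal_names() == []
        assert not any(b.involves({"ZN"}) for b in stripped.bonds)
        assert not any(a.involves({"ZN"}) for a in stripped.angles)
        restored, _, _ = reinsert_metals(stripped, record)
        assert restored.atoms == aquo_dict.atoms
        assert restored.bonds == aquo_dict.bonds
        assert restored.angles == aquo_dict.angles

    def test_metal_free_identity(self):
        d = make_toy_dictionary(
            {"comp_id": "ORG", "atoms": [("C1", "C"), ("O1", "O")],
             "bonds": [("C1", "O1", "double")]}
        )
        stripped, record = strip_and_remember_metals(d)
        assert stripped.atoms == d.atoms
        assert record.atoms == ()

    def test_tentative_geometry(self, aquo_dict):
        stripped, record = strip_and_remember_metals(aquo_dict)
        coords = {
            "O1": (1.0, 0.0, 0.0), "O2": (-1.0, 0.0, 0.0),
            "O3": (0.0, 1.0, 0.0), "O4": (0.0, -1.0, 0.0),
        }
        coords.update({f"H{i}{s}": (9, 9, 9) for i in range(1, 5) for s in "AB"})
        restored, positions, flags = reinsert_metals(stripped, record, coords)
        assert np.allclose(positions["ZN"], [0, 0, 0])  # mean of partners
        expected = chem.covalent_radius("Zn") + chem.covalent_radius("O")
        for b in restored.bonds:
            if "ZN" in (b.atom1, b.atom2):
                assert b.value == pytest.approx(expected)
        assert not flags

    def test_single_partner_flagged(self):
        d = make_toy_dictionary(
            {"comp_id": "MONO", "atoms": [("NA", "Na"), ("O1", "O")],
             "bonds": [("NA", "O1", "single")]}
        )
        stripped, record = strip_and_remember_metals(d)
        _, positions, flags = reinsert_metals(stripped, record, {"O1": (2, 0, 0)})
        assert np.allclose(positions["NA"], [2, 0, 0])
        assert any("single bonding partner" in f for f in flags)

    def test_missing_partner_coordinates(self, aquo_dict):
        stripped, record = strip_and_remember_metals(aquo_dict)
        with pytest.raises(ValueError, match="O2"):
            reinsert_metals(stripped, record, {"O1": (1, 0, 0)})


class TestInstanceSelection:
    def test_lower_b_wins_at_equal_occupancy(self, tet_model):
        inst = select_instance(tet_model, "AQZ")
        assert (inst.chain, inst.seqid) == ("A", 1)  # B 15 beats B 40

    def test_occupancy_dominates_b(self, tmp_path, library):
        tet = library.get("Tetrahedral").reference_coords
        insts = []
        for k, (occ, b) in enumerate([(0.8, 10.0), (1.0, 40.0)]):
            atoms = [("ZN", "Zn", (10.0 * (k + 1),) * 3, occ, b)]
            for i, p in enumerate(tet):
                atoms.append(
                    (f"O{i+1}", "O",
                     tuple(np.array((10.0 * (k + 1),) * 3) + 2.0 * p), occ, b)
                )
            insts.append(
                {"comp_id": "AQZ", "chain": "B", "seqid": k + 1, "atoms": atoms}
            )
        path = tmp_path / "occ.pdb"
        path.write_text(make_model_pdb(insts))
        inst = select_instance(read_model(path), "AQZ")
        assert inst.seqid == 2  # full occupancy wins despite higher B

    def test_missing_component(self, tet_model):
        with pytest.raises(ValueError, match="HEM"):
            select_instance(tet_model, "HEM")


class TestSiteExtraction:
    def test_neighbors_from_whole_model(self, tmp_path, library):
        """A context atom within range joins the component's own ligands,
        like a coordinating histidine nitrogen."""
        sq = 2.05 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])
        atoms = [("FE", "Fe", (0, 0, 0), 1.0, 12.0)]
        for i, p in enumerate(sq):
            atoms.append((f"N{i+1}", "N", tuple(p), 1.0, 12.0))
        path = tmp_path / "hem.pdb"
        path.write_text(
            make_model_pdb(
                [{"comp_id": "HTY", "chain": "A", "seqid": 1, "atoms": atoms}],
                context_atoms=[("NE2", "N", (0, 0, 2.15)),
                               ("FAR", "N", (0, 0, 9.0))],
            )
        )
        model = read_model(path)
        inst = select_instance(model, "HTY")
        sites = extract_site_from_model(model, inst)
        env = sites["FE"][1.3]
        labels = {a.label.rsplit("/", 1)[-1] for a in env.neighbors}
        assert "NE2" in labels          # context nitrogen captured
        assert "FAR" not in labels      # distant atom is not
        assert len(env.neighbors) == 5

    def test_cap_drops_longest(self, tet_model):
        inst = select_instance(tet_model, "AQZ")
        sites = extract_site_from_model(tet_model, inst, max_coordination=3)
        assert len(sites["ZN"][1.3].neighbors) == 3

    def test_hydrogens_and_metals_excluded(self, tmp_path):
        atoms = [("ZN", "Zn", (0, 0, 0), 1.0, 10.0),
                 ("O1", "O", (2.0, 0, 0), 1.0, 10.0),
                 ("H1", "H", (2.5, 0.8, 0), 1.0, 10.0)]
        path = tmp_path / "m.pdb"
        path.write_text(
            make_model_pdb(
                [{"comp_id": "ZNO", "chain": "A", "seqid": 1, "atoms": atoms}],
                context_atoms=[("NA", "Na", (0, 2.4, 0))],
            )
        )
        model = read_model(path)
        inst = select_instance(model, "ZNO")
        env = extract_site_from_model(model, inst)["ZN"][1.3]
        assert [a.element for a in env.neighbors] == ["O"]


class TestUpdateDictionary:
    def _classified_site(self, library, recipe_kwargs=None):
        kwargs = {"sigma": 0.01, "jitter": 0.005}
        kwargs.update(recipe_kwargs or {})
        corpus = []
        for seed in range(8):
            envs = site_environments(
                SiteRecipe("Tetrahedral", seed=seed, **kwargs), library
            )
            res = classify_environment(envs, library)
            corpus.append((envs[res.best.alpha], res))
        return corpus

    def _tet_dictionary(self):
        return make_toy_dictionary("aquo")

    def _site_for_dictionary(self, library):
        # one environment whose neighbour labels equal the dictionary names
        envs = site_environments(
            SiteRecipe("Tetrahedral", seed=99, sigma=0.01), library
        )
        res = classify_environment(envs, library)
        env = envs[res.best.alpha]
        renamed = env.neighbors
        named = tuple(
            type(a)(a.element, f"O{i+1}", a.position, a.distance)
            for i, a in enumerate(renamed)
        )
        env = type(env)(env.metal_element, "ZN", env.metal_position, named,
                        env.alpha, env.source_id)
        return env, res

    def test_update_touches_only_metal_rows(self, library):
        table = accumulate(self._classified_site(library))
        d = self._tet_dictionary()
        env, res = self._site_for_dictionary(library)
        updated, report = update_dictionary(d, table, {"ZN": res}, {"ZN": env})
        before = write_monomer_dictionary(d).splitlines()
        after = write_monomer_dictionary(updated).splitlines()
        assert len(before) == len(after)
        for old, new in zip(before, after):
            if old != new:
                assert "ZN" in old and "ZN" in new
        # 4 metal bonds + 6 metal-centred angles were rewritten
        kinds = [c.kind for c in report.changes]
        assert kinds.count("bond") == 4
        assert kinds.count("angle") == 6
        assert all(b.esd > 0 for b in updated.bonds if b.esd is not None)

    def test_water_internal_bonds_untouched(self, library):
        table = accumulate(self._classified_site(library))
        d = self._tet_dictionary()
        env, res = self._site_for_dictionary(library)
        updated, _ = update_dictionary(d, table, {"ZN": res}, {"ZN": env})
        oh_before = [b for b in d.bonds if not b.involves({"ZN"})]
        oh_after = [b for b in updated.bonds if not b.involves({"ZN"})]
        assert oh_before == oh_after

    def test_no_class_updates_bonds_only(self, library):
        table = accumulate(self._classified_site(library))
        d = self._tet_dictionary()
        env, res = self._site_for_dictionary(library)
        rejected = classify_environment(
            {a: e for a, e in
             site_environments(SiteRecipe("Tetrahedral", seed=99, sigma=0.01),
                               library).items()},
            library, threshold=0.0,
        )
        updated, report = update_dictionary(d, table, {"ZN": rejected}, {})
        assert [c.kind for c in report.changes] == ["bond"] * 4  # pooled stats
        angle_values = [(a.value, a.esd) for a in updated.angles]
        assert angle_values == [(a.value, a.esd) for a in d.angles]

    def test_metal_free_dictionary_unchanged(self, library):
        d = make_toy_dictionary(
            {"comp_id": "ORG", "atoms": [("C1", "C"), ("O1", "O")],
             "bonds": [("C1", "O1", "double")]}
        )
        updated, report = update_dictionary(d, accumulate([]), {}, {})
        assert updated is d
        assert not report.changes

    def test_missing_statistics_keeps_prior(self, library):
        d = self._tet_dictionary()
        env, res = self._site_for_dictionary(library)
        updated, report = update_dictionary(d, accumulate([]), {"ZN": res}, {"ZN": env})
        assert not report.changes
        assert report.skipped
        assert [b.value for b in updated.bonds] == [b.value for b in d.bonds]


class TestRestraintJSON:
    def _doc(self, library):
        corpus = []
        for seed in range(6):
            envs = site_environments(
                SiteRecipe("Trigonal-bipyramid", seed=seed, sigma=0.02), library
            )
            res = classify_environment(envs, library)
            corpus.append((envs[res.best.alpha], res))
        table = accumulate(corpus)
        env_by_alpha = site_environments(
            SiteRecipe("Trigonal-bipyramid", seed=50, sigma=0.02), library
        )
        res = classify_environment(env_by_alpha, library)
        block = site_to_json("A/1/ZN", "Zn", res, env_by_alpha, table)
        return emit_restraint_json([block])

    def test_document_validates_and_round_trips(self, library, tmp_path):
        doc = self._doc(library)
        path = tmp_path / "restraints.json"
        write_restraint_json(doc, path)
        assert read_restraint_json(path) == doc

    def test_near_threshold_site_reports_both_classes(self, library, rng):
        """A five-coordinate site between trigonal-bipyramid and
        square-pyramid lists both passing classes, ranked."""
        from metalgeom.crystal import EnvironmentAtom, MetalEnvironment
        from metalgeom.procrustes import Shape, best_match

        tbp = library.get("Trigonal-bipyramid").reference_coords
        spy = library.get("Square-pyramid").reference_coords
        m = best_match(Shape(spy), library.get("Trigonal-bipyramid"))
        # superpose the square pyramid onto the bipyramid and interpolate
        spy_rot = m.scale * spy @ m.rotation.T
        inv = np.argsort(np.asarray(m.permutation))
        blend = 2.1 * (0.5 * tbp + 0.5 * spy_rot[inv])
        blend *= (1.0 / np.linalg.norm(blend, axis=1))[:, None] * 2.1

        neigh = tuple(
            EnvironmentAtom("O", f"O{i+1}", p, float(np.linalg.norm(p)))
            for i, p in enumerate(blend)
        )
        env = MetalEnvironment("Zn", "ZN", np.zeros(3), neigh, 1.3, "mix")
        res = classify_environment({a: env for a in (1.3, 1.2, 1.1)}, library)
        passing = {mm.class_name for mm in res.matches if mm.passed}
        assert {"Trigonal-bipyramid", "Square-pyramid"} <= passing
        block = site_to_json("A/1/ZN", "Zn", res, {a: env for a in (1.3, 1.2, 1.1)},
                             accumulate([]))
        doc = emit_restraint_json([block])
        names = [c["name"] for c in doc["sites"][0]["classes"]]
        assert "Trigonal-bipyramid" in names and "Square-pyramid" in names

    def test_invalid_documents_rejected(self):
        with pytest.raises(ValueError):
            validate_restraint_json({"schema_version": "1", "sites": []})
        with pytest.raises(ValueError):
            validate_restraint_json({"schema_version": "2", "sites": [{}]})
        with pytest.raises(ValueError):
            emit_restraint_json([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        distance=st.floats(0, 1),
        mean=st.floats(0.5, 3.5),
        sd=st.floats(0.001, 0.5),
        count=st.integers(1, 10000),
        angle=st.floats(0, 180),
        crd=st.integers(2, 16),
    )
    def test_fuzzed_site_blocks_always_validate(self, distance, mean, sd, count,
                                                angle, crd):
        """Any site block built from in-range numbers yields a valid doc."""
        block = {
            "metal": "A/1/ZN",
            "element": "Zn",
            "accepted": True,
            "classes": [
                {
                    "name": "Octahedral",
                    "coordination_number": crd,
                    "procrustes_distance": round(distance, 6),
                    "alpha": 1.3,
                    "bonds": [
                        {"ligand_element": "O",
                         "modes": [{"mean": round(mean, 4), "sd": round(sd, 4),
                                    "count": count}],
                         "most_probable": 0}
                    ],
                    "angles": [
                        {"vertex1": 0, "vertex2": 1, "mean": round(angle, 3),
                         "sd": round(sd, 3), "count": count}
                    ],
                }
            ],
        }
        doc = emit_restraint_json([block])
        validate_restraint_json(json.loads(json.dumps(doc)))
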