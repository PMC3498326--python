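"""PDB reading, fragment/target classification and contact extraction."""

import numpy as np
import pytest

from contactprefs import fragments as fr
from contactprefs import synthetic_data as sd
from tests.conftest import make_ligand


def write_fixture(tmp_path, fragment_class, planted, rng=None, name="fix.pdb"):
    text, manifest = sd.gen_fixture_pdb(fragment_class, planted, rng=rng)
    path = tmp_path / name
    path.write_text(text)
    return path, manifest


class TestReadStructure:
    def test_fixture_round_trip(self, tmp_path):
        path, _ = write_fixture(tmp_path, "f26", [("C14", (2.9, 0.3, np.pi))])
        st = fr.read_structure(path)
        assert len(st.atoms) == 7  # 4 stub atoms + 3 ligand atoms
        assert st.resolution == pytest.approx(1.8)
        assert len(st.ligand_atoms) == 3
        assert not st.flags

    def test_ligand_flagging(self, tmp_path):
        text, _ = sd.gen_fixture_pdb("f26", [])
        # drop the HETATM ligand -> flagged
        stripped = "".join(l for l in text.splitlines(keepends=True)
                           if not l.startswith("HETATM"))
        p = tmp_path / "nolig.pdb"
        p.write_text(stripped)
        st = fr.read_structure(p)
        assert any("no ligand" in f for f in st.flags)

    def test_above_resolution_cutoff_flagged(self, tmp_path):
        text, _ = sd.gen_fixture_pdb("f26", [("C14", (2.9, 0.3, np.pi))],
                                     resolution=3.0)
        p = tmp_path / "lowres.pdb"
        p.write_text(text)
        st = fr.read_structure(p)
        assert any("above cutoff" in f for f in st.flags)
        assert st.resolution == pytest.approx(3.0)

    def test_unparseable_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM  garbage line that is not fixed-width\n")
        with pytest.raises(ValueError):
            st = fr.read_structure(p)
            if not st.atoms:  # tolerant parsers may yield an empty model
                raise ValueError("no atoms parsed")


class TestFindFragments:
    def test_ethanol_hydroxyl(self):
        eth = make_ligand([("C", "C1", (0, 0, 0)), ("C", "C2", (1.53, 0, 0)),
                           ("O", "O1", (2.0, 1.35, 0))])
        classes = {h.class_id for h in fr.find_fragments(eth)}
        assert "f2" in classes and "f3" not in classes

    def test_benzene_only_aromatic_carbons(self, benzene):
        hits = fr.find_fragments(benzene)
        assert {h.class_id for h in hits} == {"f11"}
        assert len({h.main.serial for h in hits}) == 6

    def test_phenol_aromatic_hydroxyl_and_secondary_rule(self, phenol):
        hits = fr.find_fragments(phenol)
        assert any(h.class_id == "f3" for h in hits)
        # the substituted ring carbon has 3 heavy neighbours -> not secondary
        f11_mains = {h.main.serial for h in hits if h.class_id == "f11"}
        assert len(f11_mains) == 5

    def test_acetamide_carbamoyl_classes(self, acetamide):
        classes = {h.class_id for h in fr.find_fragments(acetamide)}
        assert "f7" in classes  # carbamoyl O
        assert "f29" in classes  # amino N on a planar carbon

    def test_degenerate_atom2_choices_all_emitted(self, benzene):
        hits = [h for h in fr.find_fragments(benzene) if h.class_id == "f11"]
        # each aromatic CH: 2 Atom1 choices x 1 further neighbour each
        by_main = {}
        for h in hits:
            by_main.setdefault(h.main.serial, []).append(h)
        assert all(len(v) == 2 for v in by_main.values())

    def test_deterministic_order(self, phenol):
        a = fr.find_fragments(phenol)
        b = fr.find_fragments(phenol)
        assert [(h.class_id, h.main.serial, h.atom2.serial) for h in a] == [
            (h.class_id, h.main.serial, h.atom2.serial) for h in b
        ]


class TestClassifyTarget:
    @pytest.mark.parametrize(
        "resname,name,expected",
        [
            ("GLY", "N", "C15"), ("GLY", "O", "C14"), ("GLY", "CA", "C4"),
            ("ALA", "CB", "C3"), ("PHE", "CZ", "C5"), ("MET", "SD", "C6"),
            ("CYS", "SG", "C7"), ("ASN", "ND2", "C8"), ("ARG", "NH1", "C9"),
            ("LYS", "NZ", "C10"), ("GLN", "OE1", "C11"), ("ASP", "OD2", "C12"),
            ("TYR", "OH", "C13"), ("GLY", "C", None), ("ARG", "CZ", None),
        ],
    )
    def test_classification_table(self, resname, name, expected):
        atom = fr.Atom(1, name, name[0], resname, 1, "A", np.zeros(3), het=False)
        assert fr.classify_target(atom) == expected

    def test_het_atom_never_classified(self):
        atom = fr.Atom(1, "O", "O", "HOH", 1, "A", np.zeros(3), het=True)
        assert fr.classify_target(atom) is None


class TestFindContacts:
    def test_far_atom_excluded(self, tmp_path, cutoffs):
        path, manifest = write_fixture(tmp_path, "f26", [("C14", (10.0, 0.3, np.pi))])
        assert manifest["warnings"]
        st = fr.read_structure(path)
        hits = [h for h in fr.find_fragments(st) if h.class_id == "f26"]
        assert all(not fr.find_contacts(h, st, cutoffs) for h in hits)

    def test_planted_backbone_oxygen_recovered(self, tmp_path, cutoffs):
        path, manifest = write_fixture(tmp_path, "f26", [("C14", (2.9, 0.3, np.pi))])
        st = fr.read_structure(path)
        (hit,) = [h for h in fr.find_fragments(st) if h.class_id == "f26"]
        (rec,) = fr.find_contacts(hit, st, cutoffs)
        exp = manifest["expected"][0]
        assert rec.target_class == "C14"
        assert rec.r == pytest.approx(exp["r"], abs=1e-6)
        assert rec.theta == pytest.approx(exp["theta"], abs=1e-6)
        assert rec.phi == pytest.approx(exp["phi"], abs=1e-6)

    def test_frame_invariance_under_rigid_motion(self, tmp_path, cutoffs, rng):
        planted = [("C14", (2.9, 0.3, np.pi)), ("C13", (3.0, 1.1, 2.2))]
        path0, _ = write_fixture(tmp_path, "f26", planted, name="a.pdb")
        path1, _ = write_fixture(tmp_path, "f26", planted, rng=rng, name="b.pdb")

        def extract(path):
            st = fr.read_structure(path)
            (hit,) = [h for h in fr.find_fragments(st) if h.class_id == "f26"]
            return sorted(
                [(r.target_class, r.r, r.theta, r.phi)
                 for r in fr.find_contacts(hit, st, cutoffs)]
            )

        a, b = extract(path0), extract(path1)
        assert [x[0] for x in a] == [x[0] for x in b]
        for ra, rb in zip(a, b):
            # coordinates differ only by the 0.001 A PDB write precision
            assert np.allclose(ra[1:], rb[1:], atol=2e-3)

    def test_hbond_cutoff_applies_to_o_n_pairs(self, tmp_path, cutoffs):
        # planted backbone O at 3.5 A from an amino N: within dispersion range
        # but beyond the H-bond criterion, so it must be rejected
        path, _ = write_fixture(tmp_path, "f26", [("C14", (3.5, 0.3, np.pi))])
        st = fr.read_structure(path)
        (hit,) = [h for h in fr.find_fragments(st) if h.class_id == "f26"]
        assert fr.find_contacts(hit, st, cutoffs) == []


class TestFilterAdditives:
    def _records(self, ids):
        return [
            fr.ContactRecord("f2", "C14", 2.9, 0.3, 1.0, ligand_id=i) for i in ids
        ]

    def test_empty_list_is_identity(self):
        recs = self._records(["AAA", "BBB"])
        kept, removed = fr.filter_additives(recs, [])
        assert kept == recs and removed == 0

    def test_all_listed_removes_everything(self):
        recs = self._records(["AAA", "AAA"])
        kept, removed = fr.filter_additives(recs, ["AAA"])
        assert kept == [] and removed == 2

    def test_mixed(self):
        recs = self._records(["A"] * 3 + ["B"] * 7)
        kept, removed = fr.filter_additives(recs, ["A"])
        assert len(kept) == 7 and removed == 3


class TestBuildClouds:
    def test_grouping_and_invariants(self, tmp_path, cutoffs):
        path, _ = write_fixture(
            tmp_path, "f26", [("C14", (2.9, 0.3, np.pi)), ("C12", (3.1, 1.2, 2.0))]
        )
        st = fr.read_structure(path)
        records = fr.extract_contacts(st, cutoffs, classes={"f26"})
        clouds = fr.build_clouds(records, r_max=cutoffs.r_max)
        assert set(clouds) == {("f26", "C14"), ("f26", "C12")}
        for cloud in clouds.values():
            assert cloud.to_array().shape == (1, 3)

    def test_record_beyond_cutoff_rejected(self):
        rec = fr.ContactRecord("f2", "C14", 5.0, 0.3, 1.0)
        with pytest.raises(ValueError):
            fr.TargetCloud("f2", "C14", [rec], r_max=4.0)
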