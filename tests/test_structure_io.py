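"""Coordinate I/O, altloc policies and heavy-chain mapping."""

import random

import numpy as np
import pytest

from groovestate.structure_io import (FormatError, LookupError_, MappingError,
                                      StructureModel, read_structure,
                                      resolve_chain_mapping, select_residue,
                                      write_structure, load_mapping_config)
from groovestate.synthetic import FixtureSpec, make_fixture_structure


@pytest.fixture
def fixture_model():
    return make_fixture_structure(FixtureSpec.for_states("locked", "locked"))


def _coord_map(model):
    return {(a.chain_id, a.residue_number, a.atom_name, a.altloc):
            np.asarray(a.position) for a in model.atoms}


class TestReadWrite:
    def test_atom_count_matches_generator(self, fixture_model, tmp_path):
        path = tmp_path / "fixture.pdb"
        write_structure(fixture_model, path)
        lines = [l for l in path.read_text().splitlines()
                 if l.startswith(("ATOM", "HETATM"))]
        model = read_structure(path)
        assert len(model.atoms) == len(lines) == len(fixture_model.atoms)

    def test_nonexistent_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "missing.pdb")

    def test_pdb_and_mmcif_agree(self, fixture_model, tmp_path):
        p_pdb, p_cif = tmp_path / "m.pdb", tmp_path / "m.cif"
        write_structure(fixture_model, p_pdb)
        write_structure(fixture_model, p_cif)
        m1, m2 = read_structure(p_pdb), read_structure(p_cif)
        c1, c2 = _coord_map(m1), _coord_map(m2)
        assert set(c1) == set(c2)
        for key in c1:
            assert np.allclose(c1[key], c2[key], atol=1e-3)

    def test_round_trip_identity(self, fixture_model, tmp_path):
        path = tmp_path / "rt.pdb"
        write_structure(fixture_model, path)
        reread = read_structure(path)
        c0, c1 = _coord_map(fixture_model), _coord_map(reread)
        assert set(c0) == set(c1)
        for key in c0:
            assert np.allclose(c0[key], c1[key], atol=1e-3)

    def test_hetero_ligands_retained(self, tmp_path):
        from groovestate.synthetic import LigandSpec
        spec = FixtureSpec.for_states(
            "locked", "locked", ligands=(LigandSpec("GM", "F", 33.0),))
        model = make_fixture_structure(spec)
        path = tmp_path / "lig.pdb"
        write_structure(model, path)
        het = read_structure(path).hetero_residues()
        assert [v.residue_name for v in het] == ["GM"]

    def test_zero_atom_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(FormatError):
            read_structure(path)

    def test_record_order_insensitive(self, fixture_model):
        shuffled = list(fixture_model.atoms)
        random.Random(0).shuffle(shuffled)
        model = StructureModel(entry_id="SHUF", atoms=shuffled,
                               molecule_groups={})
        for res in ({a.residue_key for a in fixture_model.atoms}):
            chain, number, icode = res
            names0 = {a.atom_name
                      for a in fixture_model.residue_atoms(chain, number, icode)}
            names1 = {a.atom_name for a in model.residue_atoms(chain, number, icode)}
            assert names0 == names1


class TestSelectResidue:
    @pytest.fixture
    def altloc_model(self):
        spec = FixtureSpec(tyr116_altlocs=(("A", 180.0, 0.7), ("B", -60.0, 0.3)))
        return make_fixture_structure(spec)

    def test_highest_occupancy_wins(self, altloc_model):
        view = select_residue(altloc_model, "A", 116)
        assert {a.altloc for a in view.atoms} == {"A"}

    def test_one_variant_per_atom_name(self, altloc_model):
        view = select_residue(altloc_model, "A", 116)
        names = [a.atom_name for a in view.atoms]
        assert len(names) == len(set(names))

    def test_occupancy_tie_broken_by_letter(self):
        spec = FixtureSpec(tyr116_altlocs=(("B", -60.0, 0.5), ("A", 180.0, 0.5)))
        model = make_fixture_structure(spec)
        view = select_residue(model, "A", 116)
        assert {a.altloc for a in view.atoms} == {"A"}

    def test_specific_altloc(self, altloc_model):
        view = select_residue(altloc_model, "A", 116,
                              altloc_policy="specific", altloc="B")
        assert {a.altloc for a in view.atoms} == {"B"}

    def test_specific_altloc_absent(self, altloc_model):
        with pytest.raises(LookupError_):
            select_residue(altloc_model, "A", 116,
                           altloc_policy="specific", altloc="C")

    def test_missing_residue(self, fixture_model):
        with pytest.raises(LookupError_):
            select_residue(fixture_model, "A", 7)

    def test_single_conformer_identity(self, fixture_model):
        view = select_residue(fixture_model, "A", 99)
        raw = fixture_model.residue_atoms("A", 99)
        assert view.atoms == raw


class TestChainMapping:
    def test_auto_long_chain_is_heavy(self):
        spec = FixtureSpec(chain_length=275, light_chain_length=99)
        model = make_fixture_structure(spec)
        mappings = resolve_chain_mapping(model)
        assert [m.heavy_chain for m in mappings.values()] == ["A"]

    def test_short_ambiguous_chains_rejected(self):
        spec = FixtureSpec(chain_length=100, light_chain_length=100)
        model = make_fixture_structure(spec)
        with pytest.raises(MappingError):
            resolve_chain_mapping(model)

    def test_explicit_config_wins(self):
        spec = FixtureSpec(chain_length=8)  # too short for the heuristic
        model = make_fixture_structure(spec)
        mappings = resolve_chain_mapping(model, {"heavy_chains": ["A"]})
        assert mappings["1"].heavy_chain == "A"

    def test_config_with_absent_chain(self, fixture_model):
        with pytest.raises(MappingError):
            resolve_chain_mapping(fixture_model, {"heavy_chains": ["Z"]})

    def test_mapped_residue_types_validated(self):
        model = make_fixture_structure(FixtureSpec())
        with pytest.raises(MappingError):
            resolve_chain_mapping(
                model, {"heavy_chains": ["A"], "residues": {"phe9": 70}})

    def test_config_file_parsing(self, tmp_path):
        cfg = tmp_path / "mapping.cfg"
        cfg.write_text("# override\nheavy_chains = A,B\ntyr116 = 200\n")
        parsed = load_mapping_config(cfg)
        assert parsed == {"heavy_chains": ["A", "B"],
                          "residues": {"tyr116": 200}}
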