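import json

import pandas as pd
import pytest

from rfsim.chem_io import (
    CacheVersionError,
    Compound,
    ReactionFormatError,
    SchemaError,
    load_compound_table,
    load_enzyme_table,
    load_fingerprint_cache,
    load_reaction_table,
    parse_reaction_smiles,
    save_fingerprint_cache,
)
from rfsim.config import CACHE_SCHEMA_VERSION
from rfsim.enzyme_db import Database


class TestParseReactionSmiles:
    def test_minimal_two_component(self):
        rec = parse_reaction_smiles("CCO>>CC=O")
        assert len(rec.substrate_instances) == 1
        assert len(rec.product_instances) == 1
        assert rec.substrate_instances[0].n_atoms == 3

    def test_atom_maps_preserved(self):
        rec = parse_reaction_smiles("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH:2]=[O:3]")
        maps = {a.GetAtomMapNum() for a in rec.substrate_instances[0].mol.GetAtoms()}
        assert maps == {1, 2, 3}

    def test_multi_component_order(self):
        rec = parse_reaction_smiles("CCO.OC=O>>CCOC=O.O")
        assert [c.n_atoms for c in rec.substrate_instances] == [3, 3]
        assert [c.n_atoms for c in rec.product_instances] == [5, 1]

    @pytest.mark.parametrize("bad", ["CCO>>", ">>CCO", "CCO", "CCO>>not_smiles"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(ReactionFormatError):
            parse_reaction_smiles(bad)


class TestCompoundTable:
    def make_table(self, tmp_path, rows):
        path = tmp_path / "compounds.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def test_valid_rows_parse(self, tmp_path):
        path = self.make_table(tmp_path, [
            {"ID": "C1", "name": "ethanol", "SMILES": "CCO"},
            {"ID": "C2", "name": "acetate", "SMILES": "CC(=O)O"},
            {"ID": "C3", "name": "water", "SMILES": "O"},
        ])
        compounds = load_compound_table(path)
        assert len(compounds) == 3
        assert all(c.parseable for c in compounds.values())

    def test_wildcard_flagged(self, tmp_path):
        path = self.make_table(tmp_path, [{"ID": "W", "name": "", "SMILES": "*C(=O)O"}])
        assert load_compound_table(path)["W"].wildcard

    def test_empty_smiles_flagged_not_fatal(self, tmp_path):
        path = self.make_table(tmp_path, [
            {"ID": "OK", "name": "", "SMILES": "CCO"},
            {"ID": "BAD", "name": "", "SMILES": ""},
            {"ID": "BAD2", "name": "", "SMILES": "xx["},
        ])
        compounds = load_compound_table(path)
        flagged = [cid for cid, c in compounds.items() if not c.parseable]
        assert sorted(flagged) == ["BAD", "BAD2"]

    def test_missing_column_schema_error(self, tmp_path):
        path = self.make_table(tmp_path, [{"ID": "C1", "structure": "CCO"}])
        with pytest.raises(SchemaError, match="SMILES"):
            load_compound_table(path)


class TestReactionTable:
    @pytest.fixture
    def compounds(self):
        return {cid: Compound.from_smiles(cid, smi)
                for cid, smi in [("A", "CCO"), ("B", "O"), ("C", "CC(=O)O")]}

    def make_table(self, tmp_path, rows):
        path = tmp_path / "reactions.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def test_equation_parsing(self, tmp_path, compounds):
        path = self.make_table(tmp_path, [{
            "ID": "R1", "equation": "1 A + 1 B = 1 C",
            "source": "x", "is_transport": "F", "EC": "1.1.1.1",
        }])
        records = load_reaction_table(path, compounds)
        assert len(records) == 1
        assert len(records[0].substrates) == 2
        assert len(records[0].products) == 1
        assert records[0].ec_numbers == ["1.1.1.1"]

    def test_stoichiometry_expands_to_instances(self, tmp_path, compounds):
        path = self.make_table(tmp_path, [{
            "ID": "R1", "equation": "2 A = 1 C", "source": "", "is_transport": "F",
        }])
        records = load_reaction_table(path, compounds)
        assert [c.id for c in records[0].substrate_instances] == ["A", "A"]

    def test_transport_dropped(self, tmp_path, compounds):
        path = self.make_table(tmp_path, [
            {"ID": "R1", "equation": "1 A = 1 C", "is_transport": "F"},
            {"ID": "RT", "equation": "1 A = 1 A", "is_transport": "T"},
        ])
        assert [r.id for r in load_reaction_table(path, compounds)] == ["R1"]

    def test_unknown_compound_skipped(self, tmp_path, compounds):
        path = self.make_table(tmp_path, [
            {"ID": "R1", "equation": "1 A = 1 X", "is_transport": "F"},
            {"ID": "R2", "equation": "1 A = 1 C", "is_transport": "F"},
        ])
        assert [r.id for r in load_reaction_table(path, compounds)] == ["R2"]

    def test_row_order_insensitive(self, tmp_path, compounds):
        rows = [
            {"ID": "R1", "equation": "1 A = 1 C", "is_transport": "F"},
            {"ID": "R2", "equation": "1 A + 1 B = 1 C", "is_transport": "F"},
        ]
        forward = load_reaction_table(self.make_table(tmp_path, rows), compounds)
        reverse = load_reaction_table(self.make_table(tmp_path, rows[::-1]), compounds)
        key = lambda recs: sorted(
            (r.id, tuple(c.id for c in r.substrate_instances)) for r in recs
        )
        assert key(forward) == key(reverse)


class TestEnzymeTable:
    def test_nonstandard_ec_flagged(self, tmp_path):
        path = tmp_path / "enzymes.csv"
        pd.DataFrame([
            {"EC": "1.1.1.1", "enzyme_id": "P001", "organism": "E. coli"},
            {"EC": "1.1.1.n3", "enzyme_id": "P002", "organism": "E. coli"},
            {"EC": "2.3.-.-", "enzyme_id": "P003", "organism": "B. subtilis"},
        ]).to_csv(path, index=False)
        anns = load_enzyme_table(path)
        assert [a.standard for a in anns] == [True, False, False]


class TestFingerprintCache:
    def test_round_trip_scores_bit_exact(self, tmp_path, planted_db, planted_queries):
        path = tmp_path / "cache.json"
        planted_db.save(path)
        reloaded = Database.load(path)
        q = planted_queries[0]
        fresh = planted_db.query(q, targets=50)
        cached = reloaded.query(q, targets=50)
        assert [(r.reaction_id, r.sim_2018, r.sim_rf, r.enzyme_id) for r in fresh] == [
            (r.reaction_id, r.sim_2018, r.sim_rf, r.enzyme_id) for r in cached
        ]

    def test_matching_radius_accepted(self, tmp_path, planted_db):
        path = tmp_path / "cache.json"
        planted_db.save(path)
        db = Database.load(path, expected_max_radius=planted_db.max_radius)
        assert len(db) == len(planted_db)

    def test_radius_mismatch_rejected(self, tmp_path, planted_db):
        path = tmp_path / "cache.json"
        planted_db.save(path)
        with pytest.raises(CacheVersionError, match="radius"):
            Database.load(path, expected_max_radius=4)

    def test_schema_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "cache.json"
        save_fingerprint_cache({"max_radius": 8, "entries": []}, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = CACHE_SCHEMA_VERSION + 1
        path.write_text(json.dumps(payload))
        with pytest.raises(CacheVersionError, match="schema"):
            load_fingerprint_cache(path)
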