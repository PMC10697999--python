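import pytest

from rfsim.aam import PassthroughMapper
from rfsim.chem_io import (
    load_compound_table,
    load_enzyme_table,
    load_reaction_table,
    parse_reaction_smiles,
)
from rfsim.enzyme_db import Database
from rfsim.fixtures import (
    FixtureSpec,
    case_study_set,
    planted_database,
    toy_mapped_reactions,
    write_planted_tables,
)

PLANTED_SEED = 1


@pytest.fixture(scope="session")
def toys():
    return toy_mapped_reactions()


@pytest.fixture(scope="session")
def planted_tables(tmp_path_factory):
    spec = FixtureSpec(seed=PLANTED_SEED)
    directory = tmp_path_factory.mktemp("planted")
    paths = write_planted_tables(spec, directory)
    _, _, _, queries, answer_key = planted_database(spec)
    return {"spec": spec, "paths": paths, "queries": queries, "answer_key": answer_key}


@pytest.fixture(scope="session")
def planted_db(planted_tables):
    paths = planted_tables["paths"]
    compounds = load_compound_table(paths["compounds"])
    records = load_reaction_table(paths["reactions"], compounds)
    enzymes = load_enzyme_table(paths["enzymes"])
    return Database.build(records, enzymes)


@pytest.fixture(scope="session")
def planted_queries(planted_tables, planted_db):
    return [
        planted_db.prepare_query(parse_reaction_smiles(smiles, rxn_id=qid))
        for qid, smiles in planted_tables["queries"]
    ]


@pytest.fixture(scope="session")
def case_study():
    records, queries, expectations = case_study_set()
    db = Database.build(records, provider=PassthroughMapper())
    return {"db": db, "records": records, "queries": queries,
            "expectations": expectations}
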