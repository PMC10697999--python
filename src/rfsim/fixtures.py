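"""Self-contained synthetic inputs: toy mapped reactions, a planted
mini-database with known EC structure, and the literature case-study set.

Everything here is generated programmatically (pure function of the seed
and the plan) or read from the small curated SMILES table shipped with the
package; nothing requires the external atom mapper or network access.

The planted database emulates the situation the reacting-fragment score is
designed for: *bifunctional* scaffold molecules carry two reactive sites
~12 bonds apart (an alcohol/amide pair or an ester/amine pair). Four
enzyme families each transform one site; family members share the reacting
centre and its surroundings out to >=6 bonds but differ in distal chain
length and branches, while the *decoy* for each query is the different
transformation applied to the *same* scaffold. Whole-compound similarity
therefore prefers the decoy (near-identical compounds, unrelated
chemistry, unrelated EC) while fragment-containment around the reacting
centre prefers the within-family neighbour (same EC to 3 digits). A "trap"
reaction per family applies the same transformation on an aromatic
scaffold (shares only the radius-0/1 centre fragments; EC shares 2
digits). What this fixture does *not* emulate: cofactor-laden reactions,
tautomers, stereochemistry, or the scale and dirtiness of a production
reaction database.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import ReactionRecord, parse_reaction_smiles


# ---------------------------------------------------------------------------
# Toy pre-mapped reactions with hand-verified reacting atoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReaction:
    """A pre-mapped reaction SMILES with expected reacting-atom index sets.

    Index sets are 0-based atom indices in each component's input atom
    order; one set per compound instance per side. ``n_rf_keys_sub`` is the
    expected number of distinct RF keys of the first substrate where that
    number is small enough to enumerate by hand (None otherwise).
    """

    name: str
    smiles: str
    reacting_sub: tuple[frozenset, ...]
    reacting_prod: tuple[frozenset, ...]
    n_rf_keys_sub: int | None = None


def toy_mapped_reactions() -> list[ToyReaction]:
    f = frozenset
    return [
        # ethanol -> acetaldehyde: C-O bond order 1->2, H changes on C and O.
        # Ethanol has 6 environment keys; all but radius-0 of the terminal
        # CH3 contain a reacting atom -> 5 RF keys.
        ToyReaction(
            "ethanol_oxidation",
            "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH:2]=[O:3]",
            (f({1, 2}),), (f({1, 2}),),
            n_rf_keys_sub=5,
        ),
        # identity reaction: nothing changes anywhere.
        ToyReaction(
            "ethanol_identity",
            "[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][OH:3]",
            (f(()),), (f(()),),
            n_rf_keys_sub=0,
        ),
        # unbalanced substitution: leaving O has no product partner; the
        # incoming Cl is unmapped; C's mapped-neighbour multiset changes.
        ToyReaction(
            "dehalogenation_unbalanced",
            "[CH3:1][OH:2]>>[CH3:1]Cl",
            (f({0, 1}),), (f({0, 1}),),
        ),
        # unbalanced hydroxylation: new O unmapped; C loses one hydrogen.
        ToyReaction(
            "hydroxylation_unbalanced",
            "[CH3:1][CH3:2]>>[CH3:1][CH2:2]O",
            (f({1}),), (f({1, 2}),),
        ),
        # balanced ester hydrolysis (acyl-oxygen cleavage): the transferred
        # methyl keeps its environment and is NOT reacting.
        ToyReaction(
            "ester_hydrolysis",
            "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
            ">>[CH3:1][C:2](=[O:3])[OH:6].[CH3:5][OH:4]",
            (f({1, 3}), f({0})), (f({1, 3}), f({1})),
        ),
        # fully-mapped spectator compound: empty reacting set for it.
        ToyReaction(
            "oxidation_with_spectator",
            "[CH3:1][CH2:2][OH:3].[CH4:10]>>[CH3:1][CH:2]=[O:3].[CH4:10]",
            (f({1, 2}), f(())), (f({1, 2}), f(())),
        ),
        # halide amination: both leaving and entering groups are unmapped;
        # the carbon keeps mapped neighbours and H count, so by the
        # environment-diff rule it is not flagged.
        ToyReaction(
            "amination_unbalanced",
            "[CH3:1][CH2:2]Br>>[CH3:1][CH2:2]N",
            (f({2}),), (f({2}),),
        ),
        # ring closure with loss of water (linear-to-ring transformation).
        ToyReaction(
            "ring_closure",
            "[CH2:1]([OH:2])[CH2:3][CH2:4][CH2:5][OH:6]"
            ">>[CH2:1]1[CH2:3][CH2:4][CH2:5][O:6]1",
            (f({0, 1, 5}),), (f({0, 4}),),
        ),
        # unbalanced decarboxylation: CO2 vanishes, methyl gains H.
        ToyReaction(
            "decarboxylation_unbalanced",
            "[CH3:1][C:2](=[O:3])[OH:4]>>[CH4:1]",
            (f({0, 1, 2, 3}),), (f({0}),),
        ),
        # double-bond migration: three carbons change bonds/H, terminal
        # methyl does not.
        ToyReaction(
            "alkene_isomerisation",
            "[CH2:1]=[CH:2][CH2:3][CH3:4]>>[CH3:1][CH:2]=[CH:3][CH3:4]",
            (f({0, 1, 2}),), (f({0, 1, 2}),),
        ),
        # protonation state change: formal charge and H count change.
        ToyReaction(
            "amine_protonation",
            "[CH3:1][NH2:2]>>[CH3:1][NH3+:2]",
            (f({1}),), (f({1}),),
        ),
    ]


# ---------------------------------------------------------------------------
# Planted mini-database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Plan for the planted database.

    ``locality_min_bonds`` is the minimum bond distance between a reacting
    centre and any cross-member decoration — family members are identical
    within this radius of their centre, so fragment weighting at the
    default inflection (5) captures exactly the conserved region.
    """

    seed: int = 0
    n_families: int = 4
    family_size: int = 5
    locality_min_bonds: int = 6
    include_traps: bool = True
    include_edge_cases: bool = True


# (chain length, ((position, branch), ...)) combos for non-query members;
# positions are chain-carbon ordinals measured from the first chain atom,
# constrained so every branch is >= 6 bonds from both reactive centres.
_MEMBER_COMBOS = [
    (13, ((7, "C"),)),
    (14, ((7, "C"), (9, "C"))),
    (12, ((7, "CC"),)),
    (14, ((8, "CC"),)),
]

_FAMILY_EC = {"A": "1.1.1", "B": "3.5.1", "C": "3.1.1", "D": "2.3.1"}
_TRAP_EC = {"A": "1.1.3.13", "B": "3.5.2.6", "C": "3.1.2.20", "D": "2.3.2.2"}


def _chain(first_map: int, length: int, branches, branch_map_start: int) -> str:
    """Mapped SMILES for a CH2 chain with optional branches.

    ``branches`` is ((ordinal, smiles), ...) where ordinal counts chain
    carbons from 1 and branch smiles is 'C' (methyl) or 'CC' (ethyl).
    """
    by_pos = dict(branches)
    parts = []
    bmap = branch_map_start
    for pos in range(1, length + 1):
        m = first_map + pos - 1
        if pos in by_pos:
            branch = by_pos[pos]
            if branch == "C":
                parts.append(f"[CH:{m}]([CH3:{bmap}])")
                bmap += 1
            else:  # ethyl
                parts.append(f"[CH:{m}]([CH2:{bmap}][CH3:{bmap + 1}])")
                bmap += 2
        else:
            parts.append(f"[CH2:{m}]")
    return "".join(parts)


def _ab_scaffold(length: int, branches) -> tuple[str, str, str]:
    """Substrate and family A/B products for an alcohol+amide scaffold."""
    chain = _chain(3, length, branches, 100)
    c, o, n = 3 + length, 4 + length, 5 + length
    tail = f"[C:{c}](=[O:{o}])[NH2:{n}]"
    sub = f"[OH:1][CH2:2]{chain}{tail}"
    prod_a = f"[O:1]=[CH:2]{chain}{tail}"
    prod_b = f"[OH:1][CH2:2]{chain}[C:{c}](=[O:{o}])[OH]"
    return sub, prod_a, prod_b


def _cd_scaffold(length: int, branches) -> tuple[str, str, str]:
    """Substrate and family C/D products for an acetate-ester+amine scaffold."""
    chain = _chain(6, length, branches, 100)
    n = 6 + length
    head = "[CH3:1][C:2](=[O:3])[O:4][CH2:5]"
    sub = f"{head}{chain}[NH2:{n}]"
    prod_c = f"[OH:4][CH2:5]{chain}[NH2:{n}]"
    prod_d = f"{head}{chain}[NH:{n}]C(C)=O"
    return sub, prod_c, prod_d


_TRAP_REACTIONS = {
    "A": ("[OH:1][CH2:2][c:3]1[cH:4][cH:5][cH:6][cH:7][cH:8]1"
          ">>[O:1]=[CH:2][c:3]1[cH:4][cH:5][cH:6][cH:7][cH:8]1"),
    "B": ("[NH2:1][C:2](=[O:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1"
          ">>[OH][C:2](=[O:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1"),
    "C": ("[CH3:1][C:2](=[O:3])[O:4][c:5]1[cH:6][cH:7][cH:8][cH:9][cH:10]1"
          ">>[OH:4][c:5]1[cH:6][cH:7][cH:8][cH:9][cH:10]1"),
    "D": ("[NH2:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1"
          ">>CC(=O)[NH:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1"),
}


def planted_database(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[tuple[str, str]], dict]:
    """Build the planted tables, query list and answer key.

    Returns (compound table, reaction table, enzyme table, queries, answer
    key). Queries are (query id, mapped reaction SMILES); the answer key
    records, per query, the identical database reaction, the EC prefix its
    within-family RF neighbour must share (3 digits), and the planted
    distal decoy that whole-compound similarity is expected to prefer.
    """
    if spec.n_families != 4 or spec.family_size < 2 or spec.family_size > 5:
        raise ValueError("plan supports 4 families of 2-5 members")
    rng = np.random.RandomState(spec.seed)

    compounds: dict[str, str] = {}
    reactions: list[dict] = []
    enzymes: list[dict] = []
    queries: list[tuple[str, str]] = []
    answer_key: dict[str, dict] = {}

    def add_compound(cid: str, smiles: str, name: str = "") -> str:
        compounds[cid] = smiles
        return cid

    def add_reaction(rid, sub_id, prod_id, ec, source="planted", transport=False):
        reactions.append({
            "ID": rid,
            "equation": f"1 {sub_id} = 1 {prod_id}",
            "source": source,
            "is_transport": "T" if transport else "F",
            "EC": ec,
        })

    # member plans: the query member (index 0) is the plain scaffold; the
    # seed permutes which distal-variation combo the other members get.
    combos = [_MEMBER_COMBOS[j] for j in rng.permutation(len(_MEMBER_COMBOS))]
    plans = [(12, ())] + combos[: spec.family_size - 1]

    for pair, (fam_x, fam_y) in (("AB", ("A", "B")), ("CD", ("C", "D"))):
        builder = _ab_scaffold if pair == "AB" else _cd_scaffold
        for j, (length, branches) in enumerate(plans, start=1):
            sub, prod_x, prod_y = builder(length, branches)
            sid = add_compound(f"S_{pair}{j}", sub, f"{pair} scaffold {j}")
            px = add_compound(f"P_{fam_x}{j}", prod_x)
            py = add_compound(f"P_{fam_y}{j}", prod_y)
            add_reaction(f"R_{fam_x}{j}", sid, px, f"{_FAMILY_EC[fam_x]}.{j}")
            add_reaction(f"R_{fam_y}{j}", sid, py, f"{_FAMILY_EC[fam_y]}.{j}")

    for fam in "ABCD":
        # enzymes for all family ECs except the last member (zero-enzyme path)
        for j in range(1, spec.family_size):
            ec = f"{_FAMILY_EC[fam]}.{j}"
            enzymes.append({"EC": ec, "enzyme_id": f"ENZ_{fam}{j}a", "organism": "Escherichia coli"})
            enzymes.append({"EC": ec, "enzyme_id": f"ENZ_{fam}{j}b", "organism": "Bacillus subtilis"})

    if spec.include_traps:
        for fam, rxn in _TRAP_REACTIONS.items():
            s, _, p = rxn.partition(">>")
            sid = add_compound(f"S_trap{fam}", s)
            pid = add_compound(f"P_trap{fam}", p)
            add_reaction(f"R_trap{fam}", sid, pid, _TRAP_EC[fam])
            enzymes.append({
                "EC": _TRAP_EC[fam], "enzyme_id": f"ENZ_trap{fam}",
                "organism": "Pseudomonas putida",
            })

    if spec.include_edge_cases:
        # wildcard compound -> reaction excluded from mapping, searchable by
        # whole-compound similarity only
        add_compound("WILD", "*C(=O)O", "acyl wildcard")
        add_compound("WILD_P", "OC(=O)O")
        add_reaction("R_wild", "WILD", "WILD_P", "6.1.1.1")
        # unparseable compound -> same degradation path
        add_compound("BAD", "", "empty smiles")
        add_reaction("R_bad", "BAD", "P_A1", "6.2.1.1")
        # transport reaction: present in the table, dropped at load
        add_reaction("R_transport", "S_AB1", "S_AB1", "", transport=True)
        # spectator compound mapped identically on both sides of one reaction
        # (built on the second scaffold so no *query* gains a second
        # identical match)
        add_compound("SPEC", "[CH4:99]", "spectator methane")
        reactions.append({
            "ID": "R_spect",
            "equation": "1 S_CD2 + 1 SPEC = 1 P_C2 + 1 SPEC",
            "source": "planted",
            "is_transport": "F",
            "EC": f"{_FAMILY_EC['C']}.9",
        })

    for fam in "ABCD":
        qid = f"Q_{fam}1"
        sub_id = f"S_AB1" if fam in "AB" else "S_CD1"
        rxn = f"{compounds[sub_id]}>>{compounds[f'P_{fam}1']}"
        queries.append((qid, rxn))
        decoy_fam = {"A": "B", "B": "A", "C": "D", "D": "C"}[fam]
        answer_key[qid] = {
            "identical": f"R_{fam}1",
            "reference_ec": f"{_FAMILY_EC[fam]}.1",
            "family_ec_prefix": _FAMILY_EC[fam],
            "family_ids": [f"R_{fam}{j}" for j in range(2, spec.family_size + 1)],
            "decoy": f"R_{decoy_fam}1",
            "min_rf_digits": 3,
        }

    compounds_df = pd.DataFrame(
        [{"ID": cid, "name": "", "SMILES": smi} for cid, smi in compounds.items()]
    )
    reactions_df = pd.DataFrame(reactions)
    enzymes_df = pd.DataFrame(enzymes)
    return compounds_df, reactions_df, enzymes_df, queries, answer_key


def write_planted_tables(spec: FixtureSpec, directory) -> dict[str, str]:
    """Write the planted tables to disk; returns the file paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    compounds, reactions, enzymes, queries, _ = planted_database(spec)
    paths = {
        "compounds": str(directory / "compounds.tsv"),
        "reactions": str(directory / "reactions.tsv"),
        "enzymes": str(directory / "enzymes.csv"),
        "queries": str(directory / "queries.tsv"),
    }
    compounds.to_csv(paths["compounds"], sep="\t", index=False)
    reactions.to_csv(paths["reactions"], sep="\t", index=False)
    enzymes.to_csv(paths["enzymes"], index=False)
    pd.DataFrame(queries, columns=["ID", "smiles"]).to_csv(
        paths["queries"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Random small molecules (property testing)
# ---------------------------------------------------------------------------

def random_molecules(seed: int, n: int, max_atoms: int = 12) -> list[Chem.Mol]:
    """Seeded random small organic molecules (connected heavy-atom trees).

    Atoms are drawn C-biased from {C, N, O, S}; a random tree topology is
    decorated with occasional C=C/C=O double bonds. Candidates failing
    valence sanitisation are discarded, so generation is deterministic in
    the seed but rejection-sampled.
    """
    rng = np.random.RandomState(seed)
    elements = ["C", "C", "C", "C", "N", "O", "S"]
    out: list[Chem.Mol] = []
    while len(out) < n:
        n_atoms = int(rng.randint(3, max_atoms + 1))
        em = Chem.RWMol()
        for _ in range(n_atoms):
            em.AddAtom(Chem.Atom(elements[rng.randint(len(elements))]))
        for i in range(1, n_atoms):
            parent = int(rng.randint(i))
            double = (
                rng.random_sample() < 0.15
                and em.GetAtomWithIdx(i).GetSymbol() == "C"
            )
            em.AddBond(parent, i, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)
        try:
            mol = em.GetMol()
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        out.append(mol)
    return out


def random_reacting_atoms(mol: Chem.Mol, rng: np.random.RandomState) -> set[int]:
    """Non-empty random atom subset to stand in for a reacting centre."""
    n = mol.GetNumAtoms()
    size = int(rng.randint(1, max(2, n // 3 + 1)))
    return set(int(i) for i in rng.choice(n, size=size, replace=False))


# ---------------------------------------------------------------------------
# Case-study set (steroid hydroxylation, tocopherol methylation,
# homogentisate ring cleavage)
# ---------------------------------------------------------------------------

def load_case_study_smiles() -> dict[str, str]:
    """Curated compound name -> SMILES table shipped with the package."""
    ref = importlib.resources.files("rfsim").joinpath("data/case_study_smiles.tsv")
    df = pd.read_csv(str(ref), sep="\t", comment="#")
    return dict(zip(df["name"], df["SMILES"]))


def mcs_map_reaction(sub_smiles: str, prod_smiles: str, timeout: int = 30) -> str:
    """Pre-map a one-substrate/one-product reaction via maximum common substructure.

    Synthetic stand-in for a learned atom mapper, adequate for reactions
    where substrate and product share one large connected scaffold (the
    case-study hydroxylations/methylations/ring cleavages). Atoms outside
    the MCS stay unmapped and are therefore detected as reacting.
    """
    sub = Chem.MolFromSmiles(sub_smiles)
    prod = Chem.MolFromSmiles(prod_smiles)
    if sub is None or prod is None:
        raise ValueError("unparseable case-study SMILES")
    mcs = rdFMCS.FindMCS(
        [sub, prod],
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        timeout=timeout,
    )
    patt = Chem.MolFromSmarts(mcs.smartsString)
    match_s = sub.GetSubstructMatch(patt)
    match_p = prod.GetSubstructMatch(patt)
    for n, (a, b) in enumerate(zip(match_s, match_p), start=1):
        sub.GetAtomWithIdx(a).SetAtomMapNum(n)
        prod.GetAtomWithIdx(b).SetAtomMapNum(n)
    return f"{Chem.MolToSmiles(sub)}>>{Chem.MolToSmiles(prod)}"


#: (reaction id, substrate name, product name, EC) for the case-study set.
CASE_STUDY_REACTIONS = [
    ("CS_steroid_query", "11-deoxycortisol", "cortisol", "1.14.15.4"),
    ("CS_steroid_2018", "cortisone", "cortisol", "1.1.1.146"),
    ("CS_steroid_rf", "17alpha-hydroxyprogesterone", "21-deoxycortisol", "1.14.15.4"),
    ("CS_toco_query", "gamma-tocopherol", "alpha-tocopherol", "2.1.1.95"),
    ("CS_toco_2018", "alpha-tocopherol", "13-hydroxy-alpha-tocopherol", "1.14.14.1"),
    ("CS_toco_rf", "gamma-tocotrienol", "alpha-tocotrienol", "2.1.1.95"),
    ("CS_homo_query", "homogentisate", "4-maleylacetoacetate", "1.13.11.5"),
    ("CS_homo_2018", "4-fumarylacetoacetate", "fumarate", "3.7.1.2"),
    ("CS_homo_rf", "hydroxyquinol", "maleylacetate", "1.13.11.37"),
]

#: Printed reference expectations for the case-study comparisons.
CASE_STUDY_EXPECTATIONS = {
    "steroid": {
        "query": "CS_steroid_query",
        "best_2018": "CS_steroid_2018",
        "best_rf": "CS_steroid_rf",
        "sim_2018_of_best_2018": 0.77,
        "sim_2018_of_best_rf": 0.68,
        "sim_rf_of_best_2018": 0.0,
    },
    "tocopherol": {
        "query": "CS_toco_query",
        "best_2018": "CS_toco_2018",
        "best_rf": "CS_toco_rf",
        "sim_rf_of_best_2018": 0.0,
    },
    "homogentisate": {
        "query": "CS_homo_query",
        "best_2018": "CS_homo_2018",
        "best_rf": "CS_homo_rf",
    },
}


def case_study_set() -> tuple[list[ReactionRecord], dict[str, ReactionRecord], dict]:
    """Pre-mapped case-study reactions as (database records, queries, expectations).

    Queries are the three named transformations; database records are the
    queries themselves plus the best whole-compound and best RF candidates
    reported for each.
    """
    smiles = load_case_study_smiles()
    records: list[ReactionRecord] = []
    queries: dict[str, ReactionRecord] = {}
    for rid, sub_name, prod_name, ec in CASE_STUDY_REACTIONS:
        mapped = mcs_map_reaction(smiles[sub_name], smiles[prod_name])
        record = parse_reaction_smiles(mapped, rxn_id=rid)
        record.ec_numbers = [ec]
        records.append(record)
        if rid.endswith("_query"):
            queries[rid] = record
    return records, queries, CASE_STUDY_EXPECTATIONS
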