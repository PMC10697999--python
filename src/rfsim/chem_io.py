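"""Parsing of compounds and reactions, table readers, and the fingerprint cache.

Input formats
-------------
* Reaction SMILES/SMARTS: ``substrates>>products`` with dot-separated
  components, optionally carrying atom-map annotations (``[CH3:1]``).
* Compound table: tab-separated with at least ID and SMILES columns
  (MetaNetX ``chem_prop`` style).
* Reaction table: tab-separated with ID, equation (``1 A + 1 B = 1 C``),
  source, transport flag and optional EC column (``reac_prop`` style).
* Enzyme table: CSV with EC, enzyme accession and organism columns
  (``seq_org.csv`` style).

Rows that fail to parse never abort a load; compounds are flagged
unparseable and reactions referencing them degrade gracefully downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from .config import CACHE_SCHEMA_VERSION, TableColumns, logger


class ReactionFormatError(ValueError):
    """Raised for malformed reaction SMILES or equations."""


class SchemaError(ValueError):
    """Raised when an input table lacks required columns."""


class CacheVersionError(ValueError):
    """Raised when a fingerprint cache is incompatible with the running code."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    """A chemical compound with its parsed heavy-atom graph.

    ``mol`` is None when the SMILES failed to parse; ``wildcard`` marks
    SMILES containing the ``*`` attachment-point token, which the atom
    mapper cannot handle (such compounds make their reactions searchable
    by whole-compound similarity only).
    """

    id: str
    smiles: str
    name: str | None = None
    mol: Chem.Mol | None = None
    parseable: bool = False
    wildcard: bool = False

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms() if self.mol is not None else 0

    @classmethod
    def from_smiles(cls, cid: str, smiles: str, name: str | None = None) -> "Compound":
        smiles = (smiles or "").strip()
        wildcard = "*" in smiles
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        return cls(
            id=cid,
            smiles=smiles,
            name=name,
            mol=mol,
            parseable=mol is not None,
            wildcard=wildcard,
        )


@dataclass
class ReactionRecord:
    """A reaction as an ordered list of (compound, stoichiometric count) pairs."""

    id: str
    substrates: list[tuple[Compound, int]]
    products: list[tuple[Compound, int]]
    source: str = ""
    ec_numbers: list[str] = field(default_factory=list)

    @property
    def substrate_instances(self) -> list[Compound]:
        """Substrates expanded to one instance per stoichiometric unit."""
        return [c for c, n in self.substrates for _ in range(n)]

    @property
    def product_instances(self) -> list[Compound]:
        return [c for c, n in self.products for _ in range(n)]

    @property
    def has_wildcard(self) -> bool:
        return any(c.wildcard for c, _ in self.substrates + self.products)

    @property
    def all_parseable(self) -> bool:
        return all(c.parseable for c, _ in self.substrates + self.products)


@dataclass(frozen=True)
class EnzymeAnnotation:
    """One EC -> enzyme accession -> organism link."""

    ec: str
    enzyme_id: str
    organism: str = ""

    @property
    def standard(self) -> bool:
        """True when every EC field is a plain integer and all 4 are present."""
        fields = self.ec.split(".")
        return len(fields) == 4 and all(f.isdigit() for f in fields)


# ---------------------------------------------------------------------------
# Reaction SMILES parsing
# ---------------------------------------------------------------------------

def parse_reaction_smiles(text: str, rxn_id: str = "query") -> ReactionRecord:
    """Parse ``substrates>>products`` into a :class:`ReactionRecord`.

    Atom-map numbers present in the input are preserved on the parsed
    molecules. Each dot-separated component becomes one compound instance
    with count 1; repeated components stay as separate instances.
    """
    if ">>" not in text:
        raise ReactionFormatError(f"reaction SMILES needs a '>>' separator: {text!r}")
    left, _, right = text.partition(">>")
    if not left.strip() or not right.strip():
        raise ReactionFormatError(f"reaction SMILES has an empty side: {text!r}")

    def parse_side(side: str, tag: str) -> list[tuple[Compound, int]]:
        out = []
        for i, comp in enumerate(side.split(".")):
            comp = comp.strip()
            if not comp:
                raise ReactionFormatError(f"empty component on {tag} side of {text!r}")
            compound = Compound.from_smiles(f"{rxn_id}_{tag}{i}", comp)
            if not compound.parseable and not compound.wildcard:
                raise ReactionFormatError(
                    f"unparseable {tag} component {comp!r} in {text!r}"
                )
            out.append((compound, 1))
        return out

    return ReactionRecord(
        id=rxn_id,
        substrates=parse_side(left, "s"),
        products=parse_side(right, "p"),
        source="smiles",
    )


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )


def load_compound_table(path, columns: TableColumns | None = None) -> dict[str, Compound]:
    """Read a tab-separated compound table into ``{id: Compound}``.

    Unparseable or empty SMILES are retained but flagged so reactions using
    them can degrade instead of failing; ``*``-containing SMILES are flagged
    wildcard (excluded from atom mapping downstream).
    """
    cols = columns or TableColumns()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(df, [cols.compound_id, cols.compound_smiles], path)
    compounds: dict[str, Compound] = {}
    n_bad = 0
    for _, row in df.iterrows():
        cid = row[cols.compound_id]
        name = row[cols.compound_name] if cols.compound_name in df.columns else None
        c = Compound.from_smiles(cid, row[cols.compound_smiles], name)
        if not c.parseable:
            n_bad += 1
        compounds[cid] = c
    if n_bad:
        logger.warning("%s: %d compound(s) with empty/unparseable SMILES", path, n_bad)
    return compounds


_TRUTHY = {"t", "true", "1", "yes", "y"}


def parse_equation(
    equation: str, compounds: Mapping[str, Compound]
) -> tuple[list[tuple[Compound, int]], list[tuple[Compound, int]]]:
    """Parse ``1 A + 2 B = 1 C`` against a compound lookup."""
    if "=" not in equation:
        raise ReactionFormatError(f"equation needs '=': {equation!r}")
    left, _, right = equation.partition("=")

    def parse_side(side: str) -> list[tuple[Compound, int]]:
        out = []
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                count, cid = 1, parts[0]
            else:
                count, cid = int(parts[0]), parts[-1]
            if cid not in compounds:
                raise KeyError(cid)
            out.append((compounds[cid], count))
        return out

    subs, prods = parse_side(left), parse_side(right)
    if not subs or not prods:
        raise ReactionFormatError(f"equation side empty: {equation!r}")
    return subs, prods


def load_reaction_table(
    path,
    compounds: Mapping[str, Compound],
    columns: TableColumns | None = None,
) -> list[ReactionRecord]:
    """Read a tab-separated reaction table; transport reactions are dropped.

    Equations referencing unknown compound IDs are skipped with a warning
    rather than aborting the load.
    """
    cols = columns or TableColumns()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(df, [cols.reaction_id, cols.reaction_equation], path)
    records: list[ReactionRecord] = []
    n_transport = n_skipped = 0
    for _, row in df.iterrows():
        rid = row[cols.reaction_id]
        if cols.reaction_transport in df.columns:
            if str(row[cols.reaction_transport]).strip().lower() in _TRUTHY:
                n_transport += 1
                continue
        try:
            subs, prods = parse_equation(row[cols.reaction_equation], compounds)
        except KeyError as e:
            logger.warning("%s: reaction %s references unknown compound %s; skipped", path, rid, e)
            n_skipped += 1
            continue
        except ReactionFormatError as e:
            logger.warning("%s: reaction %s: %s; skipped", path, rid, e)
            n_skipped += 1
            continue
        ecs: list[str] = []
        if cols.reaction_ec in df.columns:
            ecs = [e.strip() for e in str(row[cols.reaction_ec]).replace(",", ";").split(";") if e.strip()]
        source = row[cols.reaction_source] if cols.reaction_source in df.columns else ""
        records.append(ReactionRecord(rid, subs, prods, source=source, ec_numbers=ecs))
    logger.info(
        "%s: loaded %d reactions (%d transport dropped, %d skipped)",
        path, len(records), n_transport, n_skipped,
    )
    return records


def load_enzyme_table(path, columns: TableColumns | None = None) -> list[EnzymeAnnotation]:
    """Read the EC -> enzyme -> organism CSV."""
    cols = columns or TableColumns()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require(df, [cols.enzyme_ec, cols.enzyme_id], path)
    out = []
    for _, row in df.iterrows():
        organism = row[cols.enzyme_organism] if cols.enzyme_organism in df.columns else ""
        out.append(EnzymeAnnotation(
            ec=row[cols.enzyme_ec].strip(),
            enzyme_id=row[cols.enzyme_id].strip(),
            organism=organism,
        ))
    n_nonstd = sum(1 for a in out if not a.standard)
    if n_nonstd:
        logger.info("%s: %d enzyme record(s) carry non-standard EC numbers", path, n_nonstd)
    return out


# ---------------------------------------------------------------------------
# Fingerprint cache
# ---------------------------------------------------------------------------
# JSON with string-encoded integer keys: floats round-trip exactly through
# repr, and the payload stays portable/diffable. The payload dict is built
# by enzyme_db.Database; this layer owns only schema stamping/validation.

def save_fingerprint_cache(payload: dict, path) -> None:
    """Write a schema-versioned fingerprint/RF cache."""
    payload = dict(payload)
    payload["schema_version"] = CACHE_SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_fingerprint_cache(path, expected_max_radius: int | None = None) -> dict:
    """Load a cache, checking schema version and fragment radius."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("schema_version")
    if version != CACHE_SCHEMA_VERSION:
        raise CacheVersionError(
            f"{path}: cache schema version {version!r} != supported {CACHE_SCHEMA_VERSION}"
        )
    if expected_max_radius is not None and payload.get("max_radius") != expected_max_radius:
        raise CacheVersionError(
            f"{path}: cache built with max radius {payload.get('max_radius')!r}, "
            f"configured {expected_max_radius}"
        )
    return payload


def strip_atom_maps(mol: Chem.Mol) -> Chem.Mol:
    """Copy of ``mol`` with atom-map numbers cleared (for fingerprinting)."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def canonical_reaction_smiles(record: ReactionRecord) -> str:
    """Canonical (map-stripped) reaction SMILES used as a cache key."""
    def side(instances: Iterable[Compound]) -> str:
        return ".".join(sorted(
            Chem.MolToSmiles(strip_atom_maps(c.mol)) for c in instances if c.mol is not None
        ))
    return f"{side(record.substrate_instances)}>>{side(record.product_instances)}"
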