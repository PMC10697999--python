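"""Atom–atom mapping (AAM) and reacting-atom detection.

Mapping itself is delegated to a pluggable provider. Two providers ship:

* :class:`PassthroughMapper` — trusts atom-map numbers already present in
  the input reaction SMILES (pre-mapped databases, test fixtures).
* :class:`RxnMapperProvider` — adapter around the external transformer-based
  mapper, imported lazily so the rest of the pipeline carries no model
  dependency.

Reacting atoms are then detected by diffing each mapped atom's bonding
environment across the two sides. An atom is *reacting* iff any of:

a. it has no mapped partner on the opposite side (unbalanced reactions:
   appearing/leaving atoms);
b. the multiset of (neighbour map number, bond order) over its mapped
   neighbours differs between sides (bond formation/breaking/order change);
c. its total hydrogen count differs;
d. its formal charge differs.

Ring-perception changes alone do not mark an atom reacting, consistent with
fingerprinting that ignores ring membership (so linear-to-ring
transformations are driven by the actual bond changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from rdkit import Chem

from .chem_io import ReactionRecord, strip_atom_maps
from .config import logger


class MappingProvider(Protocol):
    """Maps a reaction SMILES; returns the same reaction with atom maps."""

    def map_reaction(self, reaction_smiles: str) -> str: ...


class PassthroughMapper:
    """Returns the input unchanged: atom maps must already be present."""

    name = "passthrough"

    def map_reaction(self, reaction_smiles: str) -> str:
        return reaction_smiles


class RxnMapperProvider:
    """Adapter for the external neural atom-mapper (optional dependency)."""

    name = "rxnmapper"

    def __init__(self) -> None:
        try:
            from rxnmapper import RXNMapper  # type: ignore[import-not-found]
        except ImportError as e:  # pragma: no cover - depends on optional package
            raise ImportError(
                "the 'rxnmapper' package is not installed; use the passthrough "
                "provider with pre-mapped SMILES instead"
            ) from e
        self._mapper = RXNMapper()

    def map_reaction(self, reaction_smiles: str) -> str:  # pragma: no cover
        result = self._mapper.get_attention_guided_atom_maps([reaction_smiles])[0]
        return result["mapped_rxn"]


class CachedProvider:
    """Memoizes a provider on canonical reaction SMILES (precomputed DBs)."""

    def __init__(self, provider: MappingProvider):
        self.provider = provider
        self.name = getattr(provider, "name", "cached")
        self._cache: dict[str, str] = {}

    def map_reaction(self, reaction_smiles: str) -> str:
        if reaction_smiles not in self._cache:
            self._cache[reaction_smiles] = self.provider.map_reaction(reaction_smiles)
        return self._cache[reaction_smiles]


@dataclass
class MappedReaction:
    """A reaction plus its atom-map assignment and reacting-atom sets.

    ``sub_mols``/``prod_mols`` hold one RDKit Mol per compound instance, in
    the record's instance order, with atom-map numbers on mapped atoms.
    ``reacting_sub``/``reacting_prod`` hold the per-instance sets of
    0-based atom indices that change in the reaction (empty until
    :func:`detect_reacting_atoms` runs; always empty when not mappable).
    """

    record: ReactionRecord
    mappable: bool
    swapped: bool = False
    sub_mols: list[Chem.Mol] = field(default_factory=list)
    prod_mols: list[Chem.Mol] = field(default_factory=list)
    reacting_sub: list[set[int]] = field(default_factory=list)
    reacting_prod: list[set[int]] = field(default_factory=list)


def _side_atom_count(instances) -> int:
    return sum(c.n_atoms for c in instances)


def orient_for_mapping(record: ReactionRecord) -> tuple[str, bool]:
    """Reaction SMILES oriented so the heavier side is on the left.

    The external mapper expects unbalanced reactions with the higher atom
    count on the left; ``swapped=True`` means sides were exchanged and the
    mapping must be re-oriented afterwards.
    """
    subs = record.substrate_instances
    prods = record.product_instances
    swapped = _side_atom_count(prods) > _side_atom_count(subs)
    if swapped:
        subs, prods = prods, subs
    smiles = ".".join(c.smiles for c in subs) + ">>" + ".".join(c.smiles for c in prods)
    return smiles, swapped


def _strip_duplicate_maps(mols: list[Chem.Mol]) -> None:
    """Enforce 'each map number at most once per side' (keep first)."""
    seen: set[int] = set()
    for mol in mols:
        for atom in mol.GetAtoms():
            m = atom.GetAtomMapNum()
            if m:
                if m in seen:
                    atom.SetAtomMapNum(0)
                else:
                    seen.add(m)


def map_atoms(record: ReactionRecord, provider: MappingProvider) -> MappedReaction:
    """Run the mapping provider and collect per-instance mapped molecules.

    Reactions containing wildcard or unparseable compounds, and reactions
    the provider fails on, come back with ``mappable=False`` (still usable
    for whole-compound similarity).
    """
    if record.has_wildcard or not record.all_parseable:
        return MappedReaction(record=record, mappable=False)
    oriented, swapped = orient_for_mapping(record)
    try:
        mapped_smiles = provider.map_reaction(oriented)
    except Exception as e:
        logger.warning("mapping failed for %s: %s", record.id, e)
        return MappedReaction(record=record, mappable=False)

    left, _, right = mapped_smiles.partition(">>")
    left_mols = [Chem.MolFromSmiles(s) for s in left.split(".")]
    right_mols = [Chem.MolFromSmiles(s) for s in right.split(".")]
    if any(m is None for m in left_mols + right_mols):
        logger.warning("mapper output unparseable for %s", record.id)
        return MappedReaction(record=record, mappable=False)
    if swapped:
        left_mols, right_mols = right_mols, left_mols
    if len(left_mols) != len(record.substrate_instances) or len(right_mols) != len(
        record.product_instances
    ):
        logger.warning("mapper changed component count for %s", record.id)
        return MappedReaction(record=record, mappable=False)
    _strip_duplicate_maps(left_mols)
    _strip_duplicate_maps(right_mols)
    left_maps = {a.GetAtomMapNum() for m in left_mols for a in m.GetAtoms() if a.GetAtomMapNum()}
    right_maps = {a.GetAtomMapNum() for m in right_mols for a in m.GetAtoms() if a.GetAtomMapNum()}
    if not (left_maps & right_maps):
        # no atom correspondence at all (e.g. passthrough on unmapped
        # input): treating every atom as reacting would be meaningless
        logger.warning("no shared atom maps for %s; flagged non-mappable", record.id)
        return MappedReaction(record=record, mappable=False)
    return MappedReaction(
        record=record,
        mappable=True,
        swapped=swapped,
        sub_mols=left_mols,
        prod_mols=right_mols,
    )


def _index_maps(mols: list[Chem.Mol]) -> dict[int, tuple[int, int]]:
    """map number -> (instance index, atom index)."""
    out: dict[int, tuple[int, int]] = {}
    for i, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            m = atom.GetAtomMapNum()
            if m:
                out[m] = (i, atom.GetIdx())
    return out


def _environment(atom: Chem.Atom) -> tuple:
    """(sorted (neighbour map, bond order) over mapped neighbours, H count, charge)."""
    neigh = []
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        m = other.GetAtomMapNum()
        if m:
            neigh.append((m, bond.GetBondTypeAsDouble()))
    return tuple(sorted(neigh)), atom.GetTotalNumHs(), atom.GetFormalCharge()


def detect_reacting_atoms(mapped: MappedReaction) -> MappedReaction:
    """Fill ``reacting_sub``/``reacting_prod`` by diffing mapped environments.

    Mapped atoms whose environment (rule b–d above) differs between sides
    are reacting on both sides; atoms without a mapped partner are reacting.
    Spectator compounds whose atoms all match exactly get empty sets.
    """
    if not mapped.mappable:
        mapped.reacting_sub = [set() for _ in mapped.record.substrate_instances]
        mapped.reacting_prod = [set() for _ in mapped.record.product_instances]
        return mapped

    sub_idx = _index_maps(mapped.sub_mols)
    prod_idx = _index_maps(mapped.prod_mols)
    reacting_sub: list[set[int]] = [set() for _ in mapped.sub_mols]
    reacting_prod: list[set[int]] = [set() for _ in mapped.prod_mols]

    for side_mols, side_idx, other_idx, other_mols, reacting, other_reacting in (
        (mapped.sub_mols, sub_idx, prod_idx, mapped.prod_mols, reacting_sub, reacting_prod),
    ):
        for i, mol in enumerate(side_mols):
            for atom in mol.GetAtoms():
                m = atom.GetAtomMapNum()
                if not m:
                    reacting[i].add(atom.GetIdx())
                    continue
                if m not in other_idx:
                    reacting[i].add(atom.GetIdx())
                    continue
                oi, oa = other_idx[m]
                other_atom = other_mols[oi].GetAtomWithIdx(oa)
                if _environment(atom) != _environment(other_atom):
                    reacting[i].add(atom.GetIdx())
                    other_reacting[oi].add(oa)

    # product atoms with no substrate partner
    for m, (i, a) in prod_idx.items():
        if m not in sub_idx:
            reacting_prod[i].add(a)
    for i, mol in enumerate(mapped.prod_mols):
        for atom in mol.GetAtoms():
            if not atom.GetAtomMapNum():
                reacting_prod[i].add(atom.GetIdx())

    mapped.reacting_sub = reacting_sub
    mapped.reacting_prod = reacting_prod
    return mapped


def map_and_detect(record: ReactionRecord, provider: MappingProvider) -> MappedReaction:
    """Convenience: :func:`map_atoms` followed by :func:`detect_reacting_atoms`."""
    return detect_reacting_atoms(map_atoms(record, provider))


def fingerprint_mols(mapped: MappedReaction) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    """Map-stripped molecules for fingerprinting, falling back to the record's.

    Uses the mapper's output molecules when available so that reacting-atom
    indices and fragment atom indices refer to the same atom order.
    """
    if mapped.mappable:
        subs = [strip_atom_maps(m) for m in mapped.sub_mols]
        prods = [strip_atom_maps(m) for m in mapped.prod_mols]
    else:
        subs = [strip_atom_maps(c.mol) for c in mapped.record.substrate_instances if c.mol is not None]
        prods = [strip_atom_maps(c.mol) for c in mapped.record.product_instances if c.mol is not None]
    return subs, prods
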