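"""Circular-fragment generation, reacting-fragment (RF) extraction and weighting.

Compounds are decomposed into Morgan circular environments up to radius 8
with ring membership excluded from the atom invariants (so a linear
substructure and its ring-closed counterpart can still share fragments).
Fragments that contain at least one reacting atom are classified as
reacting fragments. Each RF gets a localisation score

    f(x) = 1 / (1 + exp(k * (x - i)))        (reverse sigmoid)

where x is the maximum, over the fragment's atoms, of the bond distance to
the nearest reacting atom *within the fragment* — 0 for a fragment that is
nothing but reacting atoms, large for fragments whose periphery is far from
the reacting site. The defaults k=0.5, i=5 give near-full weight to
fragments entirely within ~5 bonds of the reacting site and suppress
larger, less specific fragments. Per-compound scores are linear-sum
normalised to total 1.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator as _rfg

from .config import DEFAULT_MAX_RADIUS


@dataclass(frozen=True)
class WeightParams:
    """Reverse-sigmoid parameters: slope ``k`` and inflection point ``i``."""

    k: float = 0.5
    i: float = 5.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"slope k must be positive, got {self.k}")


@dataclass(frozen=True)
class FragmentRecord:
    """One circular environment occurrence.

    ``key`` is the hashed environment identifier — identical substructure
    environments hash to the same key across compounds. ``count`` is the
    multiplicity of the key in the whole compound.
    """

    key: int
    center: int
    radius: int
    atoms: frozenset[int]
    count: int


@dataclass(frozen=True)
class ReactingFragment:
    """A fragment overlapping the reacting site, with its localisation x."""

    fragment: FragmentRecord
    x: int


@dataclass(frozen=True)
class RFWeightVector:
    """Normalised per-key RF weights for one compound (sums to 1)."""

    entries: dict  # key -> s_norm
    raw: dict      # key -> pre-normalisation f(x)

    def __bool__(self) -> bool:
        return bool(self.entries)

    @property
    def keys(self) -> frozenset[int]:
        return frozenset(self.entries)


EMPTY_WEIGHTS = RFWeightVector(entries={}, raw={})


@lru_cache(maxsize=8)
def _generator(max_radius: int):
    inv = _rfg.GetMorganAtomInvGen(includeRingMembership=False)
    return _rfg.GetMorganGenerator(radius=max_radius, atomInvariantsGenerator=inv)


def fingerprint(mol: Chem.Mol, max_radius: int = DEFAULT_MAX_RADIUS) -> dict[int, int]:
    """Sparse counted Morgan fingerprint ``{key: count}``."""
    if mol is None:
        return {}
    fp = _generator(max_radius).GetSparseCountFingerprint(mol)
    return dict(fp.GetNonzeroElements())


def morgan_fragments(
    mol: Chem.Mol, max_radius: int = DEFAULT_MAX_RADIUS
) -> list[FragmentRecord]:
    """All circular environments of ``mol`` as :class:`FragmentRecord`s.

    One record per (center, radius) occurrence reported by the fingerprint
    generator; duplicate environments share a key, and each record carries
    the key's total multiplicity.
    """
    if mol is None:
        return []
    ao = _rfg.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = _generator(max_radius).GetSparseCountFingerprint(mol, additionalOutput=ao)
    counts = fp.GetNonzeroElements()
    records = []
    for key, occurrences in ao.GetBitInfoMap().items():
        for center, radius in occurrences:
            if radius == 0:
                atoms = frozenset([center])
            else:
                bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
                atom_ids = {center}
                for b in bonds:
                    bond = mol.GetBondWithIdx(b)
                    atom_ids.add(bond.GetBeginAtomIdx())
                    atom_ids.add(bond.GetEndAtomIdx())
                atoms = frozenset(atom_ids)
            records.append(
                FragmentRecord(key=int(key), center=center, radius=radius,
                               atoms=atoms, count=int(counts[key]))
            )
    return records


def _fragment_x(mol: Chem.Mol, atoms: frozenset[int], reacting: set[int]) -> int:
    """Max over fragment atoms of distance to nearest in-fragment reacting atom.

    Distances are topological bond counts on the fragment-induced subgraph
    (multi-source BFS from the reacting atoms inside the fragment).
    """
    sources = atoms & reacting
    dist = {a: 0 for a in sources}
    queue = deque(sources)
    while queue:
        a = queue.popleft()
        for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
            n = nbr.GetIdx()
            if n in atoms and n not in dist:
                dist[n] = dist[a] + 1
                queue.append(n)
    # circular environments are connected, so every fragment atom is reached
    return max(dist[a] for a in atoms)


def extract_rfs(
    mol: Chem.Mol,
    fragments: list[FragmentRecord],
    reacting_atoms: set[int],
) -> list[ReactingFragment]:
    """Fragments containing >=1 reacting atom, each with its x distance."""
    if not reacting_atoms:
        return []
    out = []
    for frag in fragments:
        if frag.atoms & reacting_atoms:
            out.append(ReactingFragment(frag, _fragment_x(mol, frag.atoms, reacting_atoms)))
    return out


def reverse_sigmoid(x: float, params: WeightParams = WeightParams()) -> float:
    """f(x) = 1 / (1 + e^(k (x - i))): strictly decreasing weight in (0, 1)."""
    return 1.0 / (1.0 + math.exp(params.k * (x - params.i)))


def collapse_x(rfs: list[ReactingFragment]) -> dict[int, int]:
    """Per-key minimal x (duplicate keys keep their most localised occurrence)."""
    xmap: dict[int, int] = {}
    for rf in rfs:
        k = rf.fragment.key
        if k not in xmap or rf.x < xmap[k]:
            xmap[k] = rf.x
    return xmap


def rf_weights_from_x(
    xmap: dict[int, int], params: WeightParams = WeightParams()
) -> RFWeightVector:
    """Raw reverse-sigmoid weights per key, linear-sum normalised to 1."""
    if not xmap:
        return EMPTY_WEIGHTS
    raw = {k: reverse_sigmoid(x, params) for k, x in xmap.items()}
    total = sum(raw.values())
    return RFWeightVector(entries={k: v / total for k, v in raw.items()}, raw=raw)


def rf_weights(
    rfs: list[ReactingFragment], params: WeightParams = WeightParams()
) -> RFWeightVector:
    """Normalised RF weight vector for one compound's reacting fragments."""
    return rf_weights_from_x(collapse_x(rfs), params)


def compound_rf_x(
    mol: Chem.Mol,
    reacting_atoms: set[int],
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> dict[int, int]:
    """Fragment + RF extraction in one step: per-key minimal x for a compound."""
    return collapse_x(extract_rfs(mol, morgan_fragments(mol, max_radius), reacting_atoms))
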