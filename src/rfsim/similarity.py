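"""Reaction similarity scores: whole-compound (sim_2018) and reacting-fragment (sim_RF).

sim_2018 pairs query and database compounds greedily by counted-fingerprint
Tanimoto similarity, averages the paired scores per side (unpaired query
compounds count as 0 by default) and averages the two side means. Both
written directions of the database reaction are scored and the larger kept,
since database equations have arbitrary direction.

sim_RF reuses the winning pairing: for each paired compound the similarity
is the *containment* of the query compound's weighted RFs in the database
compound's RF key set (asymmetric by design — unbalanced queries may lack
atoms the database reaction has, so Tanimoto would punish missing
evidence). Side means S̄ and P̄ combine as sqrt(S̄ · P̄), which penalises
reactions where one side matches and the other does not. Compounds with no
RFs contribute no evidence and are excluded from the means; if a whole side
has no contributing compound, sim_RF is unavailable rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fragments import RFWeightVector

Fingerprint = dict  # key -> count


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Counted Tanimoto: sum of per-key min counts over sum of max counts."""
    if not fp_a and not fp_b:
        return 0.0
    num = den = 0
    for k in fp_a.keys() | fp_b.keys():
        a = fp_a.get(k, 0)
        b = fp_b.get(k, 0)
        num += a if a < b else b
        den += a if a > b else b
    return num / den if den else 0.0


@dataclass
class SidePairing:
    """Greedy pairing for one reaction side."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (q, d, score)
    unmatched_query: list[int] = field(default_factory=list)
    unmatched_db: list[int] = field(default_factory=list)


@dataclass
class CompoundPairing:
    """Per-side greedy pairings for one query/database reaction comparison.

    ``db_swapped`` records whether the winning orientation compared query
    substrates against the database reaction's written products.
    """

    substrates: SidePairing
    products: SidePairing
    db_swapped: bool = False


def pair_compounds(
    query_fps: list[Fingerprint], db_fps: list[Fingerprint]
) -> SidePairing:
    """Globally greedy pairing: repeatedly fix the best remaining pair.

    Ties on the maximal Tanimoto cell break deterministically by lower
    query index, then lower database index. Note the global greedy trace is
    not the optimal assignment — it follows the production tool's heuristic.
    """
    scores = [[tanimoto(q, d) for d in db_fps] for q in query_fps]
    free_q = set(range(len(query_fps)))
    free_d = set(range(len(db_fps)))
    pairing = SidePairing()
    while free_q and free_d:
        best = max(
            ((scores[q][d], q, d) for q in sorted(free_q) for d in sorted(free_d)),
            key=lambda t: (t[0], -t[1], -t[2]),
        )
        s, q, d = best
        pairing.pairs.append((q, d, s))
        free_q.remove(q)
        free_d.remove(d)
    pairing.unmatched_query = sorted(free_q)
    pairing.unmatched_db = sorted(free_d)
    return pairing


def _side_mean(pairing: SidePairing, n_query: int, unmatched_zero: bool) -> float | None:
    if n_query == 0:
        return None
    total = sum(s for _, _, s in pairing.pairs)
    if unmatched_zero:
        return total / n_query
    return total / len(pairing.pairs) if pairing.pairs else 0.0


def sim_2018_score(
    query_sub_fps: list[Fingerprint],
    query_prod_fps: list[Fingerprint],
    db_sub_fps: list[Fingerprint],
    db_prod_fps: list[Fingerprint],
    both_orientations: bool = True,
    unmatched_zero: bool = True,
) -> tuple[float, CompoundPairing]:
    """Whole-compound composite score and the pairing that produced it."""

    def score_oriented(d_sub, d_prod, swapped: bool) -> tuple[float, CompoundPairing]:
        sub = pair_compounds(query_sub_fps, d_sub)
        prod = pair_compounds(query_prod_fps, d_prod)
        s = _side_mean(sub, len(query_sub_fps), unmatched_zero)
        p = _side_mean(prod, len(query_prod_fps), unmatched_zero)
        if s is None or p is None:
            raise ValueError("query side with zero fingerprinted compounds")
        return (s + p) / 2.0, CompoundPairing(sub, prod, db_swapped=swapped)

    forward = score_oriented(db_sub_fps, db_prod_fps, swapped=False)
    if not both_orientations:
        return forward
    reverse = score_oriented(db_prod_fps, db_sub_fps, swapped=True)
    return forward if forward[0] >= reverse[0] else reverse


def rf_containment(query_weights: RFWeightVector, db_keys: frozenset | set) -> float:
    """Weighted fraction of query RFs present among the database compound's RFs."""
    if not query_weights:
        raise ValueError("containment undefined for an empty RF weight vector")
    return sum(w for k, w in query_weights.entries.items() if k in db_keys)


@dataclass
class RFScore:
    """sim_RF with its side means; ``available`` is False when either side
    had no RF-bearing paired query compound (or mapping failed)."""

    sim_rf: float | None
    s_mean: float | None
    p_mean: float | None

    @property
    def available(self) -> bool:
        return self.sim_rf is not None


UNAVAILABLE = RFScore(sim_rf=None, s_mean=None, p_mean=None)


def sim_rf_score(
    query_sub_weights: list[RFWeightVector],
    query_prod_weights: list[RFWeightVector],
    db_sub_keys: list[frozenset],
    db_prod_keys: list[frozenset],
    pairing: CompoundPairing,
) -> RFScore:
    """Compose per-pair RF containments into sqrt(S̄ · P̄).

    The pairing comes from the winning sim_2018 orientation; when that
    orientation compared the database reaction reversed, database substrate
    and product RF sets are exchanged to match.
    """
    d_sub, d_prod = db_sub_keys, db_prod_keys
    if pairing.db_swapped:
        d_sub, d_prod = d_prod, d_sub

    def side_mean(side: SidePairing, q_weights, d_keys) -> float | None:
        scores = [
            rf_containment(q_weights[q], d_keys[d])
            for q, d, _ in side.pairs
            if q_weights[q]
        ]
        return sum(scores) / len(scores) if scores else None

    s_mean = side_mean(pairing.substrates, query_sub_weights, d_sub)
    p_mean = side_mean(pairing.products, query_prod_weights, d_prod)
    if s_mean is None or p_mean is None:
        return UNAVAILABLE
    return RFScore(sim_rf=math.sqrt(s_mean * p_mean), s_mean=s_mean, p_mean=p_mean)
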