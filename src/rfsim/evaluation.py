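"""EC-digit accuracy protocol and reverse-sigmoid parameter sweep.

For each query reaction: database reactions whose sim_2018 exceeds the
identity threshold supply the reference EC numbers; they are then removed,
and the remaining reaction(s) tying for the best score (to 4 decimal
places) are the closest non-identical suggestions. Accuracy is the number
of leading EC digits shared between the reference and the suggestion —
when several ECs or tied reactions are in play, the best-scoring EC
comparison counts. Queries whose reacting fragments are unavailable fall
into a separate UA bin (included in marginal denominators by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import SCORE_DECIMALS, SearchConfig, logger
from .enzyme_db import Database, ProcessedReaction, top_nonidentical
from .fragments import WeightParams

UA = "UA"


def ec_match_digits(ec_a: str, ec_b: str) -> int:
    """Count consecutive equal leading EC fields (0-4).

    Matching stops at the first mismatch, at the shorter EC's length, or at
    a non-standard field (letters or '-'), which terminates the comparison
    at that position.
    """
    n = 0
    for fa, fb in zip(ec_a.split("."), ec_b.split(".")):
        if not (fa.isdigit() and fb.isdigit()) or fa != fb:
            break
        n += 1
    return min(n, 4)


@dataclass
class ECMatchResult:
    """Outcome of the protocol for one query under one metric."""

    query_id: str
    metric: str
    digits_matched: int | str  # 0-4 or "UA"
    best_score: float | None
    best_reaction_ids: list[str] = field(default_factory=list)


@dataclass
class AccuracySummary:
    """Distribution over {0..4, UA} and marginal probabilities P(>=d)."""

    metric: str
    counts: dict  # bin -> count, bins 0..4 and "UA"
    n_queries: int
    n_excluded: int
    include_ua_in_denominator: bool = True

    def marginal(self, d: int) -> float:
        """P(closest non-identical reaction correct to >= d EC digits)."""
        denom = self.n_queries if self.include_ua_in_denominator else (
            self.n_queries - self.counts.get(UA, 0)
        )
        if denom == 0:
            return 0.0
        num = sum(c for b, c in self.counts.items() if b != UA and b >= d)
        return num / denom

    @property
    def marginals(self) -> dict[int, float]:
        return {d: self.marginal(d) for d in (1, 2, 3, 4)}


def _reference_ecs(rows, identity_threshold: float) -> list[str]:
    """Union of EC numbers over identical matches (sim_2018 > threshold)."""
    ecs: list[str] = []
    for r in rows:
        if r.sim_2018 > identity_threshold:
            for ec in r.ec_numbers:
                if ec not in ecs:
                    ecs.append(ec)
    return ecs


def evaluate_query(
    db: Database,
    query: ProcessedReaction,
    metric: str,
    targets: int | None = None,
    config: SearchConfig | None = None,
) -> ECMatchResult | None:
    """One query through the protocol; None when no identical reference exists."""
    config = config or SearchConfig()
    rows = db.query(query, targets=targets, score_by=metric, config=config)
    refs = _reference_ecs(rows, config.identity_threshold)
    if not refs:
        return None
    best = top_nonidentical(rows, score_by=metric,
                            identity_threshold=config.identity_threshold)
    if metric == "sim_rf" and not best:
        return ECMatchResult(query.id, metric, UA, None)
    if not best:
        return ECMatchResult(query.id, metric, 0, None)
    digits = max(
        (ec_match_digits(ref, cand) for row in best for ref in refs
         for cand in row.ec_numbers),
        default=0,
    )
    score = best[0].sim_rf if metric == "sim_rf" else best[0].sim_2018
    return ECMatchResult(
        query.id, metric, digits, score,
        best_reaction_ids=sorted({r.reaction_id for r in best}),
    )


def evaluate_accuracy(
    queries: list[ProcessedReaction],
    db: Database,
    metric: str = "sim_rf",
    targets: int | None = None,
    config: SearchConfig | None = None,
) -> AccuracySummary:
    """Run the protocol over a query set and summarise the digit distribution."""
    config = config or SearchConfig()
    counts: dict = {b: 0 for b in (0, 1, 2, 3, 4, UA)}
    n_excluded = 0
    for q in queries:
        result = evaluate_query(db, q, metric, targets=targets, config=config)
        if result is None:
            logger.warning("query %s has no identical EC-annotated match; excluded", q.id)
            n_excluded += 1
            continue
        counts[result.digits_matched] += 1
    n = sum(counts.values())
    return AccuracySummary(
        metric=metric,
        counts=counts,
        n_queries=n,
        n_excluded=n_excluded,
        include_ua_in_denominator=config.include_ua_in_denominator,
    )


def percent_at_least(summary: AccuracySummary, d: int) -> float:
    """Marginal as a percentage, reported to 1 decimal place."""
    return round(100.0 * summary.marginal(d), 1)


def parameter_sweep(
    queries: list[ProcessedReaction],
    db: Database,
    slopes: list[float] = (0.5, 1.0, 2.0),
    inflections: list[float] = (0.0, 1.0, 3.0, 5.0),
    top_n: int = 50,
    min_digits: int = 3,
    config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Grid of RF accuracy percentages over (slope k, inflection i).

    For each cell the database's RF weights are re-derived from the stored
    fragment distances (fragments and mappings are never recomputed), and
    the percentage of queries whose top non-identical RF suggestion shares
    at least ``min_digits`` EC digits — within the top ``top_n`` ranked
    rows — is recorded. Rows are slopes, columns inflection points.
    """
    config = config or SearchConfig()
    original = db.params
    grid = pd.DataFrame(index=list(slopes), columns=list(inflections), dtype=float)
    try:
        for k in slopes:
            for i in inflections:
                db.params = WeightParams(k=k, i=i)
                summary = evaluate_accuracy(
                    queries, db, metric="sim_rf", targets=top_n, config=config
                )
                grid.loc[k, i] = percent_at_least(summary, min_digits)
    finally:
        db.params = original
    grid.index.name = "slope_k"
    grid.columns.name = "inflection_i"
    return grid
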