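"""Searchable reaction database: build, precompute, persist, query, rank.

A database entry stores, per compound instance, the counted Morgan
fingerprint and the per-key minimal RF distance x. RF *weights* are derived
from x and the current reverse-sigmoid parameters on demand, so a parameter
sweep only re-weights — fragments and atom mappings are computed once.

Query output is one row per (reaction, enzyme) with both similarity
columns; reactions the mapper could not handle stay searchable by
whole-compound similarity, with the RF column unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import chem_io
from .aam import CachedProvider, MappingProvider, map_and_detect, fingerprint_mols
from .chem_io import (
    Compound,
    EnzymeAnnotation,
    ReactionRecord,
    load_compound_table,
    load_enzyme_table,
    load_reaction_table,
    parse_reaction_smiles,
)
from .config import (
    DEFAULT_MAX_RADIUS,
    SCORE_DECIMALS,
    SearchConfig,
    TableColumns,
    logger,
)
from .fragments import (
    EMPTY_WEIGHTS,
    RFWeightVector,
    WeightParams,
    compound_rf_x,
    fingerprint,
    rf_weights_from_x,
)
from .similarity import CompoundPairing, RFScore, UNAVAILABLE, sim_2018_score, sim_rf_score


@dataclass
class ProcessedReaction:
    """A reaction with everything precomputed for scoring.

    Used both for database entries and for queries. ``rf_x_sub``/``rf_x_prod``
    map fragment key -> minimal distance x per compound instance (empty dict
    when the compound has no RFs or mapping failed).
    """

    record: ReactionRecord
    mappable: bool
    swapped: bool = False
    fps_sub: list[dict] = field(default_factory=list)
    fps_prod: list[dict] = field(default_factory=list)
    rf_x_sub: list[dict] = field(default_factory=list)
    rf_x_prod: list[dict] = field(default_factory=list)
    enzymes: list[EnzymeAnnotation] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def ec_numbers(self) -> list[str]:
        return self.record.ec_numbers

    def rf_keys(self) -> tuple[list[frozenset], list[frozenset]]:
        return (
            [frozenset(d) for d in self.rf_x_sub],
            [frozenset(d) for d in self.rf_x_prod],
        )

    def weights(self, params: WeightParams) -> tuple[list[RFWeightVector], list[RFWeightVector]]:
        return (
            [rf_weights_from_x(d, params) if d else EMPTY_WEIGHTS for d in self.rf_x_sub],
            [rf_weights_from_x(d, params) if d else EMPTY_WEIGHTS for d in self.rf_x_prod],
        )


def process_reaction(
    record: ReactionRecord,
    provider: MappingProvider,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> ProcessedReaction:
    """Map, detect reacting atoms, fingerprint and extract RF distances."""
    mapped = map_and_detect(record, provider)
    sub_mols, prod_mols = fingerprint_mols(mapped)
    fps_sub = [fingerprint(m, max_radius) for m in sub_mols]
    fps_prod = [fingerprint(m, max_radius) for m in prod_mols]
    if mapped.mappable:
        rf_x_sub = [
            compound_rf_x(m, r, max_radius) for m, r in zip(sub_mols, mapped.reacting_sub)
        ]
        rf_x_prod = [
            compound_rf_x(m, r, max_radius) for m, r in zip(prod_mols, mapped.reacting_prod)
        ]
    else:
        rf_x_sub = [{} for _ in sub_mols]
        rf_x_prod = [{} for _ in prod_mols]
    return ProcessedReaction(
        record=record,
        mappable=mapped.mappable,
        swapped=mapped.swapped,
        fps_sub=fps_sub,
        fps_prod=fps_prod,
        rf_x_sub=rf_x_sub,
        rf_x_prod=rf_x_prod,
    )


@dataclass
class RankedSuggestion:
    """One ranked output row (reaction x enzyme)."""

    reaction_id: str
    sim_2018: float
    sim_rf: float | None
    s_mean: float | None
    p_mean: float | None
    ec_numbers: list[str]
    enzyme_id: str
    organism: str
    is_identical: bool
    pairing: CompoundPairing | None = None


class Database:
    """Precomputed reaction database plus search."""

    def __init__(
        self,
        entries: list[ProcessedReaction],
        params: WeightParams = WeightParams(),
        max_radius: int = DEFAULT_MAX_RADIUS,
        provider_name: str = "passthrough",
    ):
        self.entries = entries
        self.params = params
        self.max_radius = max_radius
        self.provider_name = provider_name

    def __len__(self) -> int:
        return len(self.entries)

    # -- scoring ---------------------------------------------------------

    def score(
        self,
        query: ProcessedReaction,
        entry: ProcessedReaction,
        config: SearchConfig | None = None,
    ) -> tuple[float, RFScore, CompoundPairing]:
        """Both similarity scores of one query/entry comparison."""
        config = config or SearchConfig()
        s2018, pairing = sim_2018_score(
            query.fps_sub,
            query.fps_prod,
            entry.fps_sub,
            entry.fps_prod,
            both_orientations=config.both_orientations,
            unmatched_zero=config.unmatched_query_scores_zero,
        )
        if not query.mappable or not entry.mappable:
            return s2018, UNAVAILABLE, pairing
        q_sub_w, q_prod_w = query.weights(self.params)
        d_sub_k, d_prod_k = entry.rf_keys()
        rf = sim_rf_score(q_sub_w, q_prod_w, d_sub_k, d_prod_k, pairing)
        return s2018, rf, pairing

    def query(
        self,
        query: ProcessedReaction | ReactionRecord | str,
        targets: int | None = None,
        score_by: str = "sim_rf",
        config: SearchConfig | None = None,
        provider: MappingProvider | None = None,
    ) -> list[RankedSuggestion]:
        """Score every entry and return the top ranked (reaction, enzyme) rows.

        Ordering: chosen score descending (unavailable RF scores last),
        then reaction id, then enzyme id. A reaction with no enzyme
        annotations emits a single EC-only row.
        """
        if score_by not in ("sim_2018", "sim_rf"):
            raise ValueError(f"score_by must be 'sim_2018' or 'sim_rf', got {score_by!r}")
        config = config or SearchConfig()
        if targets is None:
            targets = config.targets
        query = self.prepare_query(query, provider)
        if not query.mappable and score_by == "sim_rf":
            logger.warning(
                "query %s is not mappable: RF scores unavailable, ranking by sim_2018",
                query.id,
            )
            score_by = "sim_2018"
        rows: list[RankedSuggestion] = []
        for entry in self.entries:
            s2018, rf, pairing = self.score(query, entry, config)
            identical = s2018 > config.identity_threshold
            enzymes = entry.enzymes or [EnzymeAnnotation(ec="", enzyme_id="", organism="")]
            for enz in enzymes:
                rows.append(
                    RankedSuggestion(
                        reaction_id=entry.id,
                        sim_2018=s2018,
                        sim_rf=rf.sim_rf,
                        s_mean=rf.s_mean,
                        p_mean=rf.p_mean,
                        ec_numbers=list(entry.ec_numbers),
                        enzyme_id=enz.enzyme_id,
                        organism=enz.organism,
                        is_identical=identical,
                        pairing=pairing,
                    )
                )
        rows.sort(key=lambda r: (_rank_key(r, score_by), r.reaction_id, r.enzyme_id))
        return rows[:targets]

    def prepare_query(
        self,
        query: ProcessedReaction | ReactionRecord | str,
        provider: MappingProvider | None = None,
    ) -> ProcessedReaction:
        """Accept a reaction SMILES, record or already-processed query."""
        if isinstance(query, ProcessedReaction):
            return query
        if isinstance(query, str):
            query = parse_reaction_smiles(query)
        from .aam import PassthroughMapper

        return process_reaction(query, provider or PassthroughMapper(), self.max_radius)

    # -- construction ----------------------------------------------------

    @classmethod
    def build(
        cls,
        records: list[ReactionRecord],
        enzymes: list[EnzymeAnnotation] | None = None,
        params: WeightParams = WeightParams(),
        provider: MappingProvider | None = None,
        max_radius: int = DEFAULT_MAX_RADIUS,
    ) -> "Database":
        """Precompute all entries; single-record failures never abort."""
        from .aam import PassthroughMapper

        provider = CachedProvider(provider or PassthroughMapper())
        by_ec: dict[str, list[EnzymeAnnotation]] = {}
        for ann in enzymes or []:
            by_ec.setdefault(ann.ec, []).append(ann)
        entries = []
        n_mappable = n_wildcard = 0
        for record in records:
            entry = process_reaction(record, provider, max_radius)
            entry.enzymes = [a for ec in record.ec_numbers for a in by_ec.get(ec, [])]
            n_mappable += entry.mappable
            n_wildcard += record.has_wildcard
            entries.append(entry)
        logger.info(
            "built database: %d reactions, %d mappable, %d wildcard-excluded",
            len(entries), n_mappable, n_wildcard,
        )
        return cls(entries, params=params, max_radius=max_radius,
                   provider_name=provider.name)

    @classmethod
    def build_from_tables(
        cls,
        compound_table,
        reaction_table,
        enzyme_table=None,
        params: WeightParams = WeightParams(),
        provider: MappingProvider | None = None,
        max_radius: int = DEFAULT_MAX_RADIUS,
        columns: TableColumns | None = None,
    ) -> "Database":
        compounds = load_compound_table(compound_table, columns)
        records = load_reaction_table(reaction_table, compounds, columns)
        enzymes = load_enzyme_table(enzyme_table, columns) if enzyme_table else []
        return cls.build(records, enzymes, params=params, provider=provider,
                         max_radius=max_radius)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "max_radius": self.max_radius,
            "params": {"k": self.params.k, "i": self.params.i},
            "provider": self.provider_name,
            "entries": [_entry_to_payload(e) for e in self.entries],
        }
        chem_io.save_fingerprint_cache(payload, path)

    @classmethod
    def load(cls, path, expected_max_radius: int | None = None) -> "Database":
        payload = chem_io.load_fingerprint_cache(path, expected_max_radius)
        params = WeightParams(k=payload["params"]["k"], i=payload["params"]["i"])
        entries = [_entry_from_payload(p) for p in payload["entries"]]
        return cls(entries, params=params, max_radius=payload["max_radius"],
                   provider_name=payload.get("provider", "unknown"))


def _rank_key(row: RankedSuggestion, score_by: str) -> tuple:
    if score_by == "sim_2018":
        return (0, -row.sim_2018)
    if row.sim_rf is None:
        return (1, 0.0)
    return (0, -row.sim_rf)


def top_nonidentical(
    rows: list[RankedSuggestion],
    score_by: str = "sim_rf",
    identity_threshold: float = 0.99,
    decimals: int = SCORE_DECIMALS,
) -> list[RankedSuggestion]:
    """Best non-identical rows: drop identical matches, keep all rows tying
    (at ``decimals`` places) for the maximum of the chosen score."""
    candidates = [r for r in rows if r.sim_2018 <= identity_threshold]
    if score_by == "sim_rf":
        candidates = [r for r in candidates if r.sim_rf is not None]
        scores = [round(r.sim_rf, decimals) for r in candidates]
    else:
        scores = [round(r.sim_2018, decimals) for r in candidates]
    if not candidates:
        return []
    best = max(scores)
    return [r for r, s in zip(candidates, scores) if s == best]


def _int_key_dict(d: dict) -> dict:
    return {int(k): v for k, v in d.items()}


def _entry_to_payload(e: ProcessedReaction) -> dict:
    return {
        "id": e.record.id,
        "source": e.record.source,
        "ec": list(e.record.ec_numbers),
        "sub_smiles": [c.smiles for c in e.record.substrate_instances],
        "prod_smiles": [c.smiles for c in e.record.product_instances],
        "mappable": e.mappable,
        "swapped": e.swapped,
        "fps_sub": [{str(k): v for k, v in d.items()} for d in e.fps_sub],
        "fps_prod": [{str(k): v for k, v in d.items()} for d in e.fps_prod],
        "rf_x_sub": [{str(k): v for k, v in d.items()} for d in e.rf_x_sub],
        "rf_x_prod": [{str(k): v for k, v in d.items()} for d in e.rf_x_prod],
        "enzymes": [[a.ec, a.enzyme_id, a.organism] for a in e.enzymes],
    }


def _entry_from_payload(p: dict) -> ProcessedReaction:
    record = ReactionRecord(
        id=p["id"],
        substrates=[(Compound.from_smiles(f"{p['id']}_s{i}", s), 1)
                    for i, s in enumerate(p["sub_smiles"])],
        products=[(Compound.from_smiles(f"{p['id']}_p{i}", s), 1)
                  for i, s in enumerate(p["prod_smiles"])],
        source=p.get("source", ""),
        ec_numbers=list(p["ec"]),
    )
    return ProcessedReaction(
        record=record,
        mappable=p["mappable"],
        swapped=p.get("swapped", False),
        fps_sub=[_int_key_dict(d) for d in p["fps_sub"]],
        fps_prod=[_int_key_dict(d) for d in p["fps_prod"]],
        rf_x_sub=[_int_key_dict(d) for d in p["rf_x_sub"]],
        rf_x_prod=[_int_key_dict(d) for d in p["rf_x_prod"]],
        enzymes=[EnzymeAnnotation(ec=a[0], enzyme_id=a[1], organism=a[2])
                 for a in p["enzymes"]],
    )
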