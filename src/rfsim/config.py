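"""Package-wide defaults, column-name mappings and logging setup.

The tab-separated compound/reaction tables this package reads follow the
MetaNetX ``chem_prop`` / ``reac_prop`` layout, but column names drift between
releases, so readers take a :class:`TableColumns` mapping instead of
hard-coding positions.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

#: Maximum circular-fragment radius used for Morgan fingerprints.
DEFAULT_MAX_RADIUS = 8

#: sim_2018 score above which a database reaction counts as identical to the query.
DEFAULT_IDENTITY_THRESHOLD = 0.99

#: Default number of ranked rows returned per query.
DEFAULT_TARGETS = 5000

#: Decimal places used when comparing ranked scores for ties.
SCORE_DECIMALS = 4

#: Schema version stamped into fingerprint caches.
CACHE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TableColumns:
    """Column-name mapping for the tab-separated input tables."""

    compound_id: str = "ID"
    compound_name: str = "name"
    compound_smiles: str = "SMILES"
    reaction_id: str = "ID"
    reaction_equation: str = "equation"
    reaction_source: str = "source"
    reaction_transport: str = "is_transport"
    reaction_ec: str = "EC"
    enzyme_ec: str = "EC"
    enzyme_id: str = "enzyme_id"
    enzyme_organism: str = "organism"


@dataclass
class SearchConfig:
    """Tunable behaviour of database search and evaluation.

    targets: maximum number of ranked rows returned per query.
    identity_threshold: sim_2018 above this marks a database reaction as
        identical to the query (reference for correct EC numbers).
    both_orientations: score each database reaction in both written
        directions and keep the larger sim_2018 (database equations have
        arbitrary direction; queries name one).
    unmatched_query_scores_zero: greedy pairing leaves surplus query
        compounds unpaired; count them as similarity 0 in the side mean
        (False drops them from the mean instead).
    include_ua_in_denominator: queries whose reacting fragments are
        unavailable still count in accuracy marginals.
    """

    targets: int = DEFAULT_TARGETS
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    both_orientations: bool = True
    unmatched_query_scores_zero: bool = True
    include_ua_in_denominator: bool = True
    columns: TableColumns = field(default_factory=TableColumns)


logger = logging.getLogger("rfsim")


def configure_logging(level: int = logging.INFO) -> None:
    """Send structured package logs to stderr (used by the CLI)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
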