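"""Hypergeometric over-representation analysis (ORA).

Used twice in the pipeline: on differentially expressed gene sets per
dataset and stage (feeding pathway consensus ranking), and on the pooled
target genes of shortlisted drugs. The background universe defaults to the
genes measured on the platform, not the whole genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._stats import bh_adjust, hypergeom_tail
from .consensus import StageShortlist

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeom_ora",
    "targets_to_query",
    "significant_terms",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    ``sets`` maps term_id -> (description, member genes); members are
    intersected with the universe on construction and empty sets dropped.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        filtered = {}
        for term, (desc, genes) in self.sets.items():
            members = frozenset(genes) & self.universe
            if members:
                filtered[term] = (desc, members)
            else:
                logger.info("dropping gene set %s: no members in universe", term)
        if not filtered:
            raise ValueError("no gene set has members in the universe")
        self.sets = filtered

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_ora(query: set[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each gene set against the query.

    Query genes outside the universe are dropped (counted, logged). Terms
    with zero overlap are excluded before testing; BH adjustment runs across
    the tested terms. Output is sorted by p ascending, term_id for ties.
    """
    query = set(query)
    in_universe = query & collection.universe
    n_dropped = len(query) - len(in_universe)
    if n_dropped:
        logger.info("dropped %d query genes outside the universe", n_dropped)
    if not in_universe:
        raise ValueError("empty query after universe intersection")

    rows = []
    universe_size = len(collection.universe)
    for term in sorted(collection.sets):
        desc, members = collection.sets[term]
        overlap = len(in_universe & members)
        if overlap == 0:
            continue
        p = hypergeom_tail(overlap, universe_size, len(members), len(in_universe))
        rows.append((term, desc, overlap, len(members), len(in_universe), universe_size, p))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "description", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["adj_p"] = pd.Series(dtype=float)
    return out


def targets_to_query(
    shortlist: StageShortlist, drug_targets: dict[str, set[str]]
) -> tuple[set[str], dict[str, object]]:
    """Pool the target genes of shortlisted drugs into one ORA query.

    Returns (gene set, report); the report counts shortlisted drugs with no
    mapping and lists them. Gene symbols are uppercased.
    """
    lookup = {str(d).strip().casefold(): {g.upper() for g in targets} for d, targets in drug_targets.items()}
    query: set[str] = set()
    unmapped = []
    for drug in shortlist.item_ids:
        targets = lookup.get(str(drug).strip().casefold())
        if targets:
            query |= targets
        else:
            unmapped.append(drug)
    report = {
        "n_drugs": len(shortlist),
        "n_mapped": len(shortlist) - len(unmapped),
        "unmapped": unmapped,
        "n_target_genes": len(query),
    }
    if not query:
        logger.warning("no shortlisted drug has a target mapping; empty query")
    return query, report


def significant_terms(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Strict adj_p < alpha filter, sorted by adj_p ascending."""
    if "adj_p" not in rows.columns:
        raise ValueError("enrichment table lacks adj_p")
    kept = rows[rows["adj_p"] < alpha].copy()
    return kept.sort_values(["adj_p", "term_id"], kind="mergesort").reset_index(drop=True)
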