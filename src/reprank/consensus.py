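"""Two-level weighted consensus rank aggregation.

The pipeline's core computation. Each repurposing tool emits a ranked drug
list per dataset and stage; lists are truncated to the top 50 entries,
aggregated across tools within each dataset, and the per-dataset consensus
lists are re-aggregated across datasets per stage. Both levels use the same
score,

    Score_i = w1 * R_i + w2 * A_i,      w1 = 0.7, w2 = 0.3,

where R_i is the mean normalised rank of item i over the sources that
contain it (an item at rank r of a K-item list contributes (K - r + 1)/K,
so rank 1 maps to 1) and A_i is the fraction of sources containing it.
Items scoring >= 0.75 at the cross-dataset level form the stage shortlist.
The same machinery re-ranks pathways by their per-dataset adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedDrugList",
    "StageShortlist",
    "W1",
    "W2",
    "TOP_K",
    "RETAIN_THRESHOLD",
    "truncate_top_k",
    "aggregate_within_dataset",
    "aggregate_across_datasets",
    "retain_threshold",
    "rank_pathways",
]

W1 = 0.7
W2 = 0.3
TOP_K = 50
RETAIN_THRESHOLD = 0.75


@dataclass
class RankedDrugList:
    """One tool's ranked output for one dataset and stage.

    Entries are (item_id, inhibition_score) pairs ordered reverser-first:
    the most negative inhibition score (strongest reversal of the disease
    signature) comes first.
    """

    entries: list[tuple[str, float]]
    tool_id: str = ""
    dataset_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        ids = [item for item, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate item_id within one ranked list")
        scores = [s for _, s in self.entries]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("entries must be ordered reverser-first (scores non-decreasing)")

    @classmethod
    def from_scores(
        cls, scores: dict[str, float], tool_id: str = "", dataset_id: str = "", stage: str = ""
    ) -> "RankedDrugList":
        """Build a reverser-first list from unordered drug -> score pairs."""
        entries = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
        return cls(entries=entries, tool_id=tool_id, dataset_id=dataset_id, stage=stage)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def item_ids(self) -> list[str]:
        return [item for item, _ in self.entries]


@dataclass
class StageShortlist:
    """Cross-dataset consensus items retained at score >= threshold."""

    stage: str
    retained: pd.DataFrame
    threshold: float = RETAIN_THRESHOLD

    def __len__(self) -> int:
        return len(self.retained)

    @property
    def item_ids(self) -> list[str]:
        return list(self.retained["item_id"])


def normalize_item_id(item_id: str) -> str:
    """Case-fold and strip whitespace so drug names match across tools."""
    return str(item_id).strip().casefold()


def truncate_top_k(ranked: RankedDrugList, k: int = TOP_K) -> RankedDrugList:
    """Keep the first min(k, len) entries of an ordered list."""
    return RankedDrugList(
        entries=ranked.entries[:k],
        tool_id=ranked.tool_id,
        dataset_id=ranked.dataset_id,
        stage=ranked.stage,
    )


def _aggregate_rankings(
    sources: list[dict[str, float]],
    source_sizes: list[int],
    w1: float,
    w2: float,
    absent_policy: str,
) -> pd.DataFrame:
    """Shared aggregation core.

    ``sources`` maps item -> fractional rank (1 = best) in each source;
    ``source_sizes`` gives the list length K of each source. Per item, each
    source containing it contributes a normalised rank value (K - r + 1)/K;
    R averages these over containing sources (absent_policy="ignore") or
    over all sources with absences contributing 0 ("penalize"); A is the
    fraction of sources containing the item.
    """
    if not sources:
        raise ValueError("need at least one source to aggregate")
    if absent_policy not in {"ignore", "penalize"}:
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    n_sources = len(sources)
    items: set[str] = set()
    for src in sources:
        items.update(src)
    if not items:
        raise ValueError("empty union of items")

    rows = []
    for item in sorted(items):
        values = []
        for src, size in zip(sources, source_sizes):
            if item in src:
                values.append((size - src[item] + 1.0) / size)
        appearances = len(values)
        values.sort()  # fixed summation order keeps scores invariant to source order
        if absent_policy == "ignore":
            r = float(np.mean(values))
        else:
            r = float(np.sum(values)) / n_sources
        a = appearances / n_sources
        rows.append((item, r, a, w1 * r + w2 * a, appearances))

    out = pd.DataFrame(rows, columns=["item_id", "R", "A", "score", "appearances"])
    out["n_sources"] = n_sources
    out = out.sort_values(["score", "item_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def aggregate_within_dataset(
    lists: list[RankedDrugList],
    w1: float = W1,
    w2: float = W2,
    absent_policy: str = "ignore",
) -> pd.DataFrame:
    """Aggregate one dataset's per-tool ranked lists into a consensus table.

    Ranks within each tool list come from the reverser-first order; tied
    inhibition scores receive average (fractional) ranks. Returns a
    DataFrame (item_id, R, A, score, appearances, n_sources, level,
    dataset_id, stage) sorted by score descending, ties lexicographic.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    dataset_ids = {l.dataset_id for l in lists}
    stages = {l.stage for l in lists}
    if len(dataset_ids) > 1 or len(stages) > 1:
        raise ValueError("all lists must share dataset_id and stage")

    sources, sizes = [], []
    for ranked in lists:
        scores = np.array([s for _, s in ranked.entries], dtype=float)
        ranks = stats.rankdata(scores, method="average")  # ascending: most negative first
        sources.append({normalize_item_id(item): r for (item, _), r in zip(ranked.entries, ranks)})
        sizes.append(len(ranked))
    out = _aggregate_rankings(sources, sizes, w1, w2, absent_policy)
    out["level"] = "within_dataset"
    out["dataset_id"] = next(iter(dataset_ids))
    out["stage"] = next(iter(stages))
    return out


def aggregate_across_datasets(
    per_dataset: list[pd.DataFrame],
    stage: str = "",
    w1: float = W1,
    w2: float = W2,
    absent_policy: str = "ignore",
) -> pd.DataFrame:
    """Re-rank per-dataset consensus tables into one cross-dataset table.

    Each dataset's consensus list of length M contributes normalised rank
    values (M - r + 1)/M, with fractional ranks on tied scores; A counts the
    fraction of datasets containing the item.
    """
    if not per_dataset:
        raise ValueError("need at least one per-dataset consensus table")
    sources, sizes = [], []
    for table in per_dataset:
        ranks = stats.rankdata(-table["score"].to_numpy(), method="average")
        sources.append(dict(zip(table["item_id"], ranks)))
        sizes.append(len(table))
    out = _aggregate_rankings(sources, sizes, w1, w2, absent_policy)
    out["level"] = "cross_dataset"
    out["stage"] = stage
    return out


def retain_threshold(scores: pd.DataFrame, threshold: float = RETAIN_THRESHOLD, stage: str | None = None) -> StageShortlist:
    """Keep cross-dataset items with score >= threshold (inclusive)."""
    if stage is None:
        stage = str(scores["stage"].iloc[0]) if "stage" in scores.columns and len(scores) else ""
    retained = scores[scores["score"] >= threshold].copy()
    retained = retained.sort_values(["score", "item_id"], ascending=[False, True], kind="mergesort")
    return StageShortlist(stage=stage, retained=retained.reset_index(drop=True), threshold=threshold)


def rank_pathways(
    per_dataset_enrichment: list[pd.DataFrame],
    stage: str = "",
    w1: float = W1,
    w2: float = W2,
) -> pd.DataFrame:
    """Consensus-rank pathways across datasets by per-dataset adjusted p.

    Within each dataset's enrichment table pathways are ranked by adj_p
    ascending (rank 1 = most significant; ties share the average rank), then
    the cross-dataset aggregation is applied with pathways as items.
    """
    if not per_dataset_enrichment:
        raise ValueError("need at least one enrichment table")
    sources, sizes = [], []
    for table in per_dataset_enrichment:
        if "adj_p" not in table.columns:
            raise ValueError("enrichment table lacks adj_p column")
        ranks = stats.rankdata(table["adj_p"].to_numpy(), method="average")
        key = "term_id" if "term_id" in table.columns else "item_id"
        sources.append(dict(zip(table[key], ranks)))
        sizes.append(len(table))
    out = _aggregate_rankings(sources, sizes, w1, w2, "ignore")
    out["level"] = "cross_dataset"
    out["stage"] = stage
    return out
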