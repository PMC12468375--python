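"""Consensus ranking of repurposing-tool outputs with planted true reversers.

Three tools rank drugs for four datasets; planted reversers win pairwise
rank contests 90% of the time. The two-level weighted aggregation
(0.7 * normalised rank + 0.3 * appearance fraction, within datasets then
across them) should pull the planted drugs to the top and past the 0.75
shortlist threshold.
"""

from reprank import (
    PlantedToolTruth,
    aggregate_across_datasets,
    aggregate_within_dataset,
    retain_threshold,
    gen_tool_outputs,
)

drugs = [f"drug{i:03d}" for i in range(200)]
planted = set(drugs[:20])
truth = PlantedToolTruth(planted, n_tools=3, n_datasets=4, top_k=50, rank_advantage=0.9)

per_dataset = gen_tool_outputs(drugs, truth, seed=1, stage="MM")
within = [aggregate_within_dataset(lists) for lists in per_dataset.values()]
cross = aggregate_across_datasets(within, stage="MM")
shortlist = retain_threshold(cross, threshold=0.75)

print(cross.head(5)[["item_id", "R", "A", "score"]].to_string(index=False))
print(f"\nshortlist size at score >= 0.75: {len(shortlist)}")
hits = sum(1 for d in shortlist.item_ids if d in planted)
print(f"planted reversers in the shortlist: {hits}/{len(planted)}")
# A score of 1.0 means top rank in every tool and dataset; the hit count
# shows how well consensus aggregation separates signal from decoys.
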