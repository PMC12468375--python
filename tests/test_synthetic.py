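"""Synthetic-data generators: determinism, planted structure, null behaviour."""

import json

import numpy as np
import pytest

from reprank import (
    PlantedExpressionTruth,
    PlantedSynergyTruth,
    PlantedToolTruth,
    aggregate_across_datasets,
    aggregate_within_dataset,
    bliss_score,
    gen_dose_response,
    gen_expression,
    gen_fingerprints,
    gen_tool_outputs,
    hsa_score,
    loewe_score,
    tanimoto_matrix,
    write_truth,
    zip_score,
)

DOSES = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
HILL_A = (0.0, 90.0, 1.0, 1.2)
HILL_B = (0.0, 80.0, 2.0, 0.9)


class TestGenExpression:
    def test_null_effect_means_no_expected_group_difference(self):
        truth = PlantedExpressionTruth({"GENE0000"}, {"GENE0001"}, effect_size=0.0, noise_sd=0.5)
        diffs = []
        for seed in range(30):
            ds = gen_expression(10, 10, 10, truth, seed=seed)
            case = ds.matrix.loc[:, ds.groups == "case"].mean(axis=1)
            ctrl = ds.matrix.loc[:, ds.groups == "control"].mean(axis=1)
            diffs.append((case - ctrl).to_numpy())
        assert abs(np.mean(diffs)) < 0.02

    def test_same_seed_gives_identical_matrices(self):
        truth = PlantedExpressionTruth({"GENE0000"}, set(), 1.0, 0.5)
        a = gen_expression(20, 3, 3, truth, seed=5)
        b = gen_expression(20, 3, 3, truth, seed=5)
        assert a.matrix.equals(b.matrix)
        c = gen_expression(20, 3, 3, truth, seed=6)
        assert not a.matrix.equals(c.matrix)

    def test_planted_shift_applied_to_cases_only(self):
        truth = PlantedExpressionTruth({"GENE0000"}, {"GENE0001"}, effect_size=4.0, noise_sd=0.1)
        ds = gen_expression(10, 10, 10, truth, seed=0)
        case = ds.matrix.loc[:, ds.groups == "case"].mean(axis=1)
        ctrl = ds.matrix.loc[:, ds.groups == "control"].mean(axis=1)
        assert case["GENE0000"] - ctrl["GENE0000"] == pytest.approx(4.0, abs=0.2)
        assert case["GENE0001"] - ctrl["GENE0001"] == pytest.approx(-4.0, abs=0.2)
        assert abs(case["GENE0005"] - ctrl["GENE0005"]) < 0.2

    def test_counts_too_small_rejected(self):
        truth = PlantedExpressionTruth(set(), set(), 1.0, 0.5)
        with pytest.raises(ValueError):
            gen_expression(10, 1, 5, truth, seed=0)

    def test_planted_sets_exceeding_n_genes_rejected(self):
        truth = PlantedExpressionTruth({f"GENE{i:04d}" for i in range(30)}, set(), 1.0, 0.5)
        with pytest.raises(ValueError):
            gen_expression(10, 5, 5, truth, seed=0)

    def test_disjointness_invariant_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            PlantedExpressionTruth({"GENE0000"}, {"GENE0000"}, 1.0, 0.5)


class TestGenToolOutputs:
    def test_degenerate_full_advantage_lists_exactly_the_true_set(self):
        drugs = [f"d{i}" for i in range(20)]
        truth = PlantedToolTruth(set(drugs[:5]), n_tools=3, n_datasets=2, top_k=5, rank_advantage=1.0)
        outs = gen_tool_outputs(drugs, truth, seed=0)
        for lists in outs.values():
            for ranked in lists:
                assert set(ranked.item_ids) == set(drugs[:5])

    def test_lists_have_exactly_top_k_strictly_ordered_entries(self):
        drugs = [f"d{i}" for i in range(50)]
        truth = PlantedToolTruth(set(drugs[:5]), n_tools=2, n_datasets=2, top_k=10, rank_advantage=0.8)
        outs = gen_tool_outputs(drugs, truth, seed=1)
        for lists in outs.values():
            assert len(lists) == 2
            for ranked in lists:
                scores = [s for _, s in ranked.entries]
                assert len(ranked) == 10
                assert all(b > a for a, b in zip(scores, scores[1:]))  # strictly weaker
                assert all(-100 <= s < 0 for s in scores)

    def test_null_advantage_gives_no_consensus_edge(self):
        """rank_advantage 0.5: planted vs decoy consensus means differ negligibly."""
        drugs = [f"d{i:03d}" for i in range(60)]
        truth = PlantedToolTruth(set(drugs[:10]), n_tools=3, n_datasets=2, top_k=20, rank_advantage=0.5)
        diffs = []
        for seed in range(200):
            outs = gen_tool_outputs(drugs, truth, seed=seed)
            within = [aggregate_within_dataset(lists) for lists in outs.values()]
            cross = aggregate_across_datasets(within, stage="MM").set_index("item_id")
            true_scores = [cross.loc[d, "score"] for d in drugs[:10] if d in cross.index]
            decoy_scores = [cross.loc[d, "score"] for d in cross.index if d not in set(drugs[:10])]
            diffs.append(np.mean(true_scores) - np.mean(decoy_scores))
        assert abs(np.mean(diffs)) < 0.02

    def test_planted_drugs_dominate_final_top20_at_advantage_09(self):
        drugs = [f"d{i:03d}" for i in range(200)]
        truth = PlantedToolTruth(set(drugs[:20]), n_tools=3, n_datasets=4, top_k=50, rank_advantage=0.9)
        occupancy = []
        for seed in range(20):
            outs = gen_tool_outputs(drugs, truth, seed=seed)
            within = [aggregate_within_dataset(lists) for lists in outs.values()]
            cross = aggregate_across_datasets(within, stage="MM")
            top20 = set(cross["item_id"][:20])
            occupancy.append(len(top20 & set(drugs[:20])) / 20)
        assert np.mean(occupancy) >= 0.8

    def test_empty_universe_and_oversized_top_k_rejected(self):
        truth = PlantedToolTruth({"d0"}, top_k=5)
        with pytest.raises(ValueError):
            gen_tool_outputs([], truth, seed=0)
        with pytest.raises(ValueError):
            gen_tool_outputs(["d0", "d1"], truth, seed=0)

    def test_deterministic_given_seed(self):
        drugs = [f"d{i}" for i in range(30)]
        truth = PlantedToolTruth(set(drugs[:3]), n_tools=2, n_datasets=2, top_k=10, rank_advantage=0.9)
        a = gen_tool_outputs(drugs, truth, seed=3)
        b = gen_tool_outputs(drugs, truth, seed=3)
        assert {k: [l.entries for l in v] for k, v in a.items()} == \
               {k: [l.entries for l in v] for k, v in b.items()}


class TestGenFingerprints:
    def test_single_cluster_full_similarity_is_all_identical(self):
        lib, truth = gen_fingerprints(6, 128, 1, 1.0, seed=0)
        assert tanimoto_matrix(lib, lib).min() == 1.0
        assert set(truth.values()) == {1}

    def test_within_cluster_similarity_hits_target(self):
        lib, truth = gen_fingerprints(60, 2048, 3, 0.9, seed=0)
        sims = tanimoto_matrix(lib, lib)
        same = np.array([[truth[a] == truth[b] for b in lib.ids] for a in lib.ids])
        off_diag = ~np.eye(len(lib), dtype=bool)
        within = sims[same & off_diag].mean()
        between = sims[~same].mean()
        assert within == pytest.approx(0.9, abs=0.02)
        assert between < 0.5 * within

    def test_infeasible_target_flagged_not_clipped(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_fingerprints(10, 128, 2, 0.1, seed=0, density=0.25)

    def test_seed_reproducibility(self):
        a, _ = gen_fingerprints(10, 128, 2, 0.9, seed=42)
        b, _ = gen_fingerprints(10, 128, 2, 0.9, seed=42)
        assert np.array_equal(a.bits, b.bits)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gen_fingerprints(10, 32, 2, 0.9, seed=0)  # n_bits < 64
        with pytest.raises(ValueError):
            gen_fingerprints(2, 128, 5, 0.9, seed=0)  # more clusters than drugs


class TestGenDoseResponse:
    @pytest.mark.parametrize(
        "model,score_fn",
        [("bliss", bliss_score), ("hsa", hsa_score), ("loewe", loewe_score), ("zip", zip_score)],
    )
    def test_each_model_scores_zero_on_its_own_null(self, model, score_fn):
        truth = PlantedSynergyTruth(model=model, delta=0.0, hill_params_a=HILL_A, hill_params_b=HILL_B)
        surf = gen_dose_response(truth, DOSES, DOSES, noise_sd=0.0, seed=0)
        tol = 1e-9 if model in ("bliss", "hsa") else 1e-3
        assert abs(score_fn(surf)) < tol

    def test_planted_hsa_delta_recovered_exactly(self):
        truth = PlantedSynergyTruth(model="hsa", delta=10.0, hill_params_a=HILL_A, hill_params_b=HILL_B)
        surf = gen_dose_response(truth, DOSES, DOSES, noise_sd=0.0, seed=0)
        assert hsa_score(surf) == pytest.approx(10.0, abs=1e-9)

    def test_monotherapy_margins_follow_the_hill_curves(self):
        truth = PlantedSynergyTruth(model="bliss", delta=5.0, hill_params_a=HILL_A, hill_params_b=HILL_B)
        surf = gen_dose_response(truth, DOSES, DOSES, noise_sd=0.0, seed=0)
        y_min, y_max, ec50, slope = HILL_A
        expected = y_min + (y_max - y_min) / (1.0 + (ec50 / DOSES[1:]) ** slope)
        np.testing.assert_allclose(surf.response[1:, 0], expected, atol=1e-9)

    def test_plus_ten_is_moderate_not_strong(self):
        """The strong threshold is strictly greater than +10."""
        from reprank import classify

        assert classify(10.0) == "moderate"
        assert classify(10.0001) == "strong"

    def test_negative_dose_and_empty_grid_rejected(self):
        truth = PlantedSynergyTruth(model="bliss", delta=0.0, hill_params_a=HILL_A, hill_params_b=HILL_B)
        with pytest.raises(ValueError):
            gen_dose_response(truth, np.array([-1.0, 0.0, 1.0]), DOSES, 0.0, seed=0)
        with pytest.raises(ValueError):
            gen_dose_response(truth, np.array([]), DOSES, 0.0, seed=0)


def test_truth_sidecar_round_trip(tmp_path):
    truth = PlantedExpressionTruth({"GENE0001"}, {"GENE0002"}, 2.0, 0.5)
    artifact = tmp_path / "expr.tsv"
    artifact.write_text("dummy\n")
    sidecar = write_truth(truth, artifact)
    assert sidecar.name == "expr.tsv.truth.json"
    loaded = json.loads(sidecar.read_text())
    assert loaded["de_genes_up"] == ["GENE0001"]
    assert loaded["effect_size"] == 2.0
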