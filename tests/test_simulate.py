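import numpy as np
import pandas as pd
import pytest

from oanet import simulate
from oanet.io import GeneSet
from oanet.stress import SelectionRule, select_stress_response


class TestDeTimecourse:
    def test_same_seed_bitwise_identical(self):
        a, _ = simulate.gen_de_timecourse(n_genes=200, n_planted=20, seed=5)
        b, _ = simulate.gen_de_timecourse(n_genes=200, n_planted=20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_selection_recovers_planted_exactly(self):
        de, truth = simulate.gen_de_timecourse(
            n_genes=500, n_planted=50, effect_log2fc=2.0, noise_sd=0.0, seed=1
        )
        selected = select_stress_response(de, SelectionRule())
        assert sorted(selected.genes) == sorted(truth.planted_age_genes)

    def test_p_and_fdr_within_unit_interval(self):
        de, _ = simulate.gen_de_timecourse(n_genes=300, n_planted=30, seed=2)
        assert de["p"].between(0, 1).all()
        assert de["fdr"].between(0, 1).all()

    def test_planted_signal_confined_to_aged_w1_w2(self):
        de, truth = simulate.gen_de_timecourse(
            n_genes=400, n_planted=40, effect_log2fc=3.0, noise_sd=0.2, seed=3
        )
        planted = set(truth.planted_age_genes)
        sig = de[(de["fdr"] < 0.05) & (de["gene"].isin(planted))]
        assert set(zip(sig["contrast"], sig["timepoint"])) <= {("aged", "W1"), ("aged", "W2")}

    @pytest.mark.parametrize(
        "kwargs", [dict(n_planted=500, n_genes=500), dict(noise_sd=-1.0)]
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate.gen_de_timecourse(**{"n_genes": 500, "n_planted": 50, **kwargs})

    def test_selection_recall_with_noise(self):
        """Mean recall of planted genes stays high at moderate noise."""
        recalls = []
        for seed in range(10):
            de, truth = simulate.gen_de_timecourse(
                n_genes=1000, n_planted=50, effect_log2fc=2.0, noise_sd=0.5, seed=seed
            )
            selected = set(select_stress_response(de).genes)
            recalls.append(len(selected & set(truth.planted_age_genes)) / 50)
        assert np.mean(recalls) >= 0.9


class TestNetwork:
    def test_no_cross_module_edges_when_p_out_zero(self):
        g, truth = simulate.gen_network(
            n_nodes=60, module_sizes=(20, 20, 20), p_in=0.5, p_out=0.0, seed=4
        )
        for u, v in g.edges():
            assert truth.planted_module_map[u] == truth.planted_module_map[v]

    def test_receptor_wired_into_its_module(self):
        g, truth = simulate.gen_network(seed=0, receptor_module=2)
        neigh = list(g.neighbors(simulate.RECEPTOR))
        assert len(neigh) >= 3
        assert all(truth.planted_module_map[v] == 2 for v in neigh)

    def test_edge_weights_in_half_open_unit_interval(self):
        g, _ = simulate.gen_network(n_nodes=80, module_sizes=(30, 30), seed=6)
        ws = [d["weight"] for _, _, d in g.edges(data=True)]
        assert all(0 < w <= 1 for w in ws)

    def test_empty_module_list_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_network(module_sizes=())

    def test_perfect_blocks_recovered_by_module_detection(self):
        from oanet.netprop import detect_modules

        g, truth = simulate.gen_network(
            n_nodes=20, module_sizes=(10, 10), p_in=1.0, p_out=0.0, seed=1
        )
        part = detect_modules(g)
        blocks = {}
        for node, mod in part.assignments.items():
            blocks.setdefault(mod, set()).add(node)
        truth_blocks = {}
        for node, mod in truth.planted_module_map.items():
            truth_blocks.setdefault(mod, set()).add(node)
        assert set(map(frozenset, blocks.values())) == set(map(frozenset, truth_blocks.values()))


class TestSignatureResponse:
    def test_unknown_active_cytokine_rejected(self):
        with pytest.raises(ValueError, match="not in panel"):
            simulate.gen_signature_response(active={"NOPE": 1.0})

    def test_noiseless_response_equals_linear_model(self):
        S, y, truth = simulate.gen_signature_response(
            n_genes=300, active={"CYT03": 2.5}, noise_sd=0.0, seed=8
        )
        z = np.array([truth.true_activities[c] for c in S.columns])
        np.testing.assert_allclose(y.to_numpy(), S.to_numpy() @ z, atol=1e-12)

    def test_same_seed_identical(self):
        a = simulate.gen_signature_response(n_genes=100, seed=3)[1]
        b = simulate.gen_signature_response(n_genes=100, seed=3)[1]
        pd.testing.assert_series_equal(a, b)


class TestMetaStudies:
    def test_same_seed_identical_table(self):
        a = simulate.gen_meta_studies(seed=11)
        b = simulate.gen_meta_studies(seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_homogeneous_large_n_pools_to_truth(self):
        from oanet.meta import pool_study_table

        studies = simulate.gen_meta_studies(k=10, true_smd=0.8, tau2=0.0, n_per_arm=2000, seed=2)
        pooled = pool_study_table(studies)
        assert abs(pooled.smd - 0.8) < 0.1
        assert pooled.I2 < 30.0

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_meta_studies(k=1)


class TestExprModules:
    def test_same_seed_identical(self):
        a, _ = simulate.gen_expr_modules(seed=9)
        b, _ = simulate.gen_expr_modules(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_module_warns(self):
        with pytest.warns(UserWarning, match="min size"):
            simulate.gen_expr_modules(module_sizes=(10, 60), seed=0)

    def test_counts_non_negative_integers(self):
        counts, _ = simulate.gen_expr_modules(module_sizes=(30, 30), n_samples=8, seed=1)
        assert (counts.to_numpy() >= 0).all()
        assert np.allclose(counts.to_numpy() % 1, 0)


class TestPerturbationLibrary:
    def test_planted_reverser_scores_most_negative(self):
        from oanet.cmap import score_and_rank

        query = GeneSet(name="Q", genes=tuple(f"G{i:06d}" for i in range(1, 21)))
        lib, truth = simulate.gen_perturbation_library(
            n_perts=40, n_genes=400, query_up=query, plant_reverser=True, seed=0
        )
        scored = score_and_rank(lib, query)
        assert scored.iloc[0]["perturbation"] == truth.reverser_id
        assert scored.iloc[0]["es"] == scored["es"].min()

    def test_profile_with_query_on_top_scores_positive(self):
        from oanet.cmap import connectivity_es

        query = GeneSet(name="Q", genes=("G000001", "G000002", "G000003"))
        lib, _ = simulate.gen_perturbation_library(
            n_perts=5, n_genes=50, query_up=query, plant_reverser=False, seed=0
        )
        profile = lib.iloc[0].copy()
        top = profile.max()
        for i, g in enumerate(query.genes):
            profile[g] = top + 3 - i
        assert connectivity_es(query, profile) > 0

    def test_empty_query_rejected_when_planting(self):
        with pytest.raises(ValueError):
            simulate.gen_perturbation_library(query_up=None, plant_reverser=True)

    def test_median_tau_of_random_profiles_near_zero(self):
        from oanet.cmap import score_and_rank

        query = GeneSet(name="Q", genes=tuple(f"G{i:06d}" for i in range(1, 26)))
        lib, _ = simulate.gen_perturbation_library(
            n_perts=100, n_genes=500, query_up=query, plant_reverser=False, seed=5
        )
        scored = score_and_rank(lib, query)
        assert -35 <= scored["tau"].median() <= 35
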