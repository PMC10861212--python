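import itertools

import numpy as np
import pandas as pd
import pytest

from oanet.io import GeneSet
from oanet.stress import (
    SelectionRule,
    fc_trajectory_pca,
    filter_top_regulated,
    select_shared_response,
    select_stress_response,
    significant_genes,
)


def brute_force_selection(de, rule, target="aged"):
    """Independent set-comprehension oracle for the selection algebra."""
    def sig(contrast, tp):
        out = set()
        for _, r in de.iterrows():
            if r["contrast"] != contrast or r["timepoint"] != tp:
                continue
            if r["fdr"] >= rule.fdr_threshold:
                continue
            if rule.direction == "up" and r["log2fc"] > 0:
                out.add(r["gene"])
            if rule.direction == "down" and r["log2fc"] < 0:
                out.add(r["gene"])
        return out

    hit = {
        g
        for g in de["gene"].unique()
        if all(g in sig(target, t) for t in rule.required_timepoints)
    }
    if rule.exclusion == "any":
        drop = {
            g
            for g in de["gene"].unique()
            if any(g in sig(rule.exclusion_contrast, t) for t in rule.required_timepoints)
        }
    else:
        drop = {
            g
            for g in de["gene"].unique()
            if all(g in sig(rule.exclusion_contrast, t) for t in rule.required_timepoints)
        }
    return hit - drop


class TestSelection:
    def test_hand_table_membership(self, toy_de_table):
        selected = select_stress_response(toy_de_table, SelectionRule())
        assert set(selected.genes) == {"G1"}  # aged-only up at W1+W2

    def test_matches_enumeration_oracle_on_hand_table(self, toy_de_table):
        for direction, exclusion in itertools.product(["up", "down"], ["any", "all"]):
            rule = SelectionRule(direction=direction, exclusion=exclusion)
            got = set(select_stress_response(toy_de_table, rule).genes)
            assert got == brute_force_selection(toy_de_table, rule)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(12)]
        rows = []
        for g in genes:
            for c in ("young", "aged"):
                for t in ("W1", "W2"):
                    rows.append(
                        dict(
                            gene=g,
                            contrast=c,
                            timepoint=t,
                            log2fc=rng.normal(),
                            p=rng.random(),
                            fdr=rng.random(),
                            mean_expr=rng.uniform(1, 100),
                        )
                    )
        de = pd.DataFrame(rows)
        rule = SelectionRule(fdr_threshold=0.3)
        assert set(select_stress_response(de, rule).genes) == brute_force_selection(de, rule)

    def test_up_down_disjoint(self, toy_de_table):
        up = set(select_stress_response(toy_de_table, SelectionRule(direction="up")).genes)
        down = set(select_stress_response(toy_de_table, SelectionRule(direction="down")).genes)
        assert not (up & down)

    def test_raising_fdr_threshold_is_monotone(self, toy_de_table):
        loose = set(select_stress_response(toy_de_table, SelectionRule(fdr_threshold=0.5)).genes)
        strict = set(select_stress_response(toy_de_table, SelectionRule(fdr_threshold=0.001)).genes)
        # strict target sets shrink but exclusion shrinks too; check on the
        # target intersection alone, where monotonicity is exact
        rule_l = SelectionRule(fdr_threshold=0.5)
        rule_s = SelectionRule(fdr_threshold=0.001)
        tgt_l = significant_genes(toy_de_table, "aged", "W1", rule_l)
        tgt_s = significant_genes(toy_de_table, "aged", "W1", rule_s)
        assert tgt_s <= tgt_l

    def test_missing_timepoint_named(self, toy_de_table):
        with pytest.raises(ValueError, match="W9"):
            select_stress_response(
                toy_de_table, SelectionRule(required_timepoints=("W1", "W9"))
            )

    def test_shared_response(self, toy_de_table):
        shared = select_shared_response(toy_de_table, SelectionRule())
        assert set(shared.genes) == {"G2"}


class TestTrajectoryPca:
    def _de(self, matrix, conditions, genes):
        rows = []
        for (contrast, tp), vals in zip(conditions, matrix):
            for g, v in zip(genes, vals):
                rows.append(
                    dict(gene=g, contrast=contrast, timepoint=tp, log2fc=v, p=0.5, fdr=0.5, mean_expr=1.0)
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_have_identical_scores(self):
        de = self._de(
            [[1.0, 2.0], [1.0, 2.0], [3.0, -1.0]],
            [("young", "W1"), ("young", "W2"), ("aged", "W1")],
            ["GA", "GB"],
        )
        scores, _, _ = fc_trajectory_pca(de, GeneSet(name="s", genes=("GA", "GB")))
        np.testing.assert_allclose(scores.loc["young:W1"], scores.loc["young:W2"])

    def test_two_by_two_matches_hand_svd(self):
        # centred matrix [[1, -1], [-1, 1]]: PC1 direction (1,-1)/sqrt(2),
        # scores +/- sqrt(2), all variance on PC1
        de = self._de(
            [[2.0, 0.0], [0.0, 2.0]], [("young", "W1"), ("aged", "W1")], ["GA", "GB"]
        )
        scores, var_frac, loadings = fc_trajectory_pca(de, GeneSet(name="s", genes=("GA", "GB")))
        np.testing.assert_allclose(np.abs(scores["PC1"]), np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(var_frac[0], 1.0, atol=1e-12)
        # sign convention: the largest-|loading| entry is positive
        assert loadings["PC1"].abs().max() == pytest.approx(loadings["PC1"].max())

    def test_variance_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(6)]
        conditions = [(c, t) for c in ("young", "aged") for t in ("D1", "W1", "W2", "W6")]
        de = self._de(rng.normal(size=(8, 6)), conditions, genes)
        _, var_frac, _ = fc_trajectory_pca(de, GeneSet(name="s", genes=tuple(genes)), n_components=4)
        assert var_frac.sum() <= 1.0 + 1e-12
        assert all(np.diff(var_frac) <= 1e-12)

    def test_constant_matrix_rejected(self):
        de = self._de([[1.0, 1.0], [1.0, 1.0]], [("young", "W1"), ("aged", "W1")], ["GA", "GB"])
        with pytest.raises(ValueError, match="zero variance"):
            fc_trajectory_pca(de, GeneSet(name="s", genes=("GA", "GB")))


class TestTopRegulated:
    def _toy(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D", "E"],
                "contrast": ["osm"] * 5,
                "timepoint": ["4h"] * 5,
                "log2fc": [3.0, 2.6, 2.4, 3.5, 0.1],
                "p": [0.01] * 5,
                "fdr": [0.01] * 5,
                "mean_expr": [20.0, 15.0, 50.0, 5.0, 80.0],
            }
        )

    def test_default_thresholds_on_toy_table(self):
        got = filter_top_regulated(self._toy(), "osm", mean_expr_min=10.0, log2fc_min=2.5)
        assert set(got.genes) == {"A", "B"}

    def test_infinite_threshold_gives_empty_set(self):
        got = filter_top_regulated(self._toy(), "osm", log2fc_min=np.inf)
        assert len(got) == 0

    def test_matches_row_scan_oracle_on_random_table(self):
        rng = np.random.default_rng(3)
        de = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(50)],
                "contrast": ["c"] * 50,
                "timepoint": ["t"] * 50,
                "log2fc": rng.normal(2, 1, 50),
                "p": rng.random(50),
                "fdr": rng.random(50),
                "mean_expr": rng.uniform(0, 30, 50),
            }
        )
        got = set(filter_top_regulated(de, "c", mean_expr_min=10, log2fc_min=2.5).genes)
        oracle = {
            r["gene"]
            for _, r in de.iterrows()
            if r["mean_expr"] > 10 and r["log2fc"] > 2.5
        }
        assert got == oracle
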