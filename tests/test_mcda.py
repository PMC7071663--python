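"""Distributive normalization, weighted-sum scoring and ranking."""

import numpy as np
import pandas as pd
import pytest

import prioritycompass as pc
from prioritycompass.mcda import (
    CRITERIA,
    McdaError,
    rank_interventions,
    weight_sensitivity,
)


def random_matrix(n_rows: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(n_rows, len(CRITERIA))),
        index=pd.Index([f"3.{i + 4}" for i in range(n_rows)], name="code"),
        columns=list(CRITERIA),
    )


class TestNormalize:
    def test_column_becomes_shares(self):
        m = pd.DataFrame({"a": [2.0, 3.0, 5.0]}, index=["x", "y", "z"])
        norm = pc.normalize_distributive(m)
        assert norm["a"].tolist() == pytest.approx([0.2, 0.3, 0.5])

    def test_single_row_becomes_ones(self):
        m = pd.DataFrame({"a": [4.0], "b": [0.7]}, index=["x"])
        norm = pc.normalize_distributive(m)
        assert norm.loc["x"].tolist() == [1.0, 1.0]

    def test_negative_entry_rejected_naming_cell(self):
        m = pd.DataFrame({"a": [1.0], "b": [-2.0]}, index=["x"])
        with pytest.raises(McdaError, match=r"'x'.*'b'"):
            pc.normalize_distributive(m)

    def test_all_zero_column_warns_and_stays_zero(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            norm = pc.normalize_distributive(m)
        assert norm["b"].tolist() == [0.0, 0.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_column_scaling_invariance(self, seed):
        m = random_matrix(12, seed)
        scaled = m.copy()
        scaled[CRITERIA[2]] *= 37.5
        a = pc.normalize_distributive(m)
        b = pc.normalize_distributive(scaled)
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)


class TestAggregateScores:
    def test_uniform_weights_symmetric_rows(self):
        norm = pd.DataFrame({"a": [0.6, 0.4], "b": [0.4, 0.6]},
                            index=["i", "j"])
        scores = pc.aggregate_scores(norm, {"a": 0.5, "b": 0.5})
        assert scores.tolist() == pytest.approx([0.5, 0.5])

    def test_degenerate_weight_selects_column(self):
        norm = pc.normalize_distributive(random_matrix(6, 0))
        w = pd.Series([1.0, 0, 0, 0, 0], index=list(CRITERIA))
        scores = pc.aggregate_scores(norm, w)
        assert np.allclose(scores.to_numpy(), norm[CRITERIA[0]].to_numpy())

    def test_matches_double_loop_oracle(self, printed_weights):
        norm = pc.normalize_distributive(random_matrix(10, 3))
        scores = pc.aggregate_scores(
            norm, pd.Series(printed_weights, index=list(CRITERIA))
        )
        for i, code in enumerate(norm.index):
            expected = 0.0
            for j, crit in enumerate(norm.columns):
                expected += printed_weights[j] * norm.iloc[i, j]
            assert abs(scores[code] - expected) < 1e-12

    def test_label_mismatch_rejected(self):
        norm = pd.DataFrame({"a": [1.0]})
        with pytest.raises(McdaError, match="labels"):
            pc.aggregate_scores(norm, {"b": 1.0})

    def test_scores_sum_to_one(self, printed_weights):
        norm = pc.normalize_distributive(random_matrix(25, 7))
        w = pd.Series(printed_weights, index=list(CRITERIA))
        scores = pc.aggregate_scores(norm, w / w.sum())
        assert scores.sum() == pytest.approx(1.0, abs=1e-9)


class TestRank:
    def test_descending_dense_ranks(self):
        ranking = rank_interventions({"a": 0.5, "b": 0.3, "c": 0.2})
        assert ranking["code"].tolist() == ["a", "b", "c"]
        assert ranking["rank"].tolist() == [1, 2, 3]

    def test_tie_broken_by_burden_criterion(self):
        tb = pd.DataFrame({"attributable_burden": [5.0, 7.0]},
                          index=["a", "b"])
        ranking = rank_interventions({"a": 0.5, "b": 0.5}, tiebreak_values=tb)
        assert ranking["code"].tolist() == ["b", "a"]

    def test_remaining_tie_broken_by_code(self):
        ranking = rank_interventions({"b": 0.5, "a": 0.5})
        assert ranking["code"].tolist() == ["a", "b"]

    def test_nan_rejected(self):
        with pytest.raises(McdaError, match="NaN"):
            rank_interventions({"a": float("nan"), "b": 0.1})

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.random(15),
                           index=[f"c{i}" for i in range(15)])
        shuffled = scores.sample(frac=1.0, random_state=seed)
        a = rank_interventions(scores)
        b = rank_interventions(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_dominant_row_ranks_first_for_any_weights(self):
        m = random_matrix(8, 11)
        m.loc["3.4"] = m.to_numpy().max() * 2  # dominates every column
        for seed in range(5):
            rng = np.random.default_rng(seed)
            w = rng.random(len(CRITERIA)) + 0.01
            ranking = pc.build_ranking(m, w / w.sum())
            assert ranking.loc[0, "code"] == "3.4"


class TestBuildRanking:
    def test_contributions_sum_to_score(self, printed_weights):
        m = random_matrix(10, 5)
        ranking = pc.build_ranking(
            m, pd.Series(printed_weights, index=list(CRITERIA))
        )
        contrib = ranking[[f"contrib_{c}" for c in CRITERIA]].sum(axis=1)
        assert np.allclose(contrib.to_numpy(), ranking["score"].to_numpy(),
                           atol=1e-12)

    def test_subset_preserves_within_column_order(self):
        """Dropping rows and renormalizing rescales a column by a constant,
        so pairwise order inside a criterion column is preserved."""
        m = random_matrix(12, 9)
        sub = m.iloc[:8]
        full_norm = pc.normalize_distributive(m)
        sub_norm = pc.normalize_distributive(sub)
        for crit in CRITERIA:
            full_order = full_norm.loc[sub.index, crit].rank()
            sub_order = sub_norm[crit].rank()
            assert full_order.tolist() == sub_order.tolist()


class TestSensitivity:
    def test_tiny_perturbation_freezes_ranks(self, printed_weights):
        m = random_matrix(10, 1)
        res = weight_sensitivity(m, printed_weights, perturbation=1e-9,
                                 reps=20, seed=0)
        assert (res.rank_range["min_rank"] == res.rank_range["max_rank"]).all()

    def test_dominant_intervention_fully_stable(self, printed_weights):
        m = random_matrix(8, 2)
        m.loc["3.4"] = m.to_numpy().max() * 2
        res = weight_sensitivity(m, printed_weights, perturbation=0.2,
                                 reps=50, seed=1)
        assert res.top1_code == "3.4" and res.top1_stability == 1.0

    def test_deterministic_under_fixed_seed(self, printed_weights):
        m = random_matrix(40, 6)
        a = weight_sensitivity(m, printed_weights, perturbation=0.2,
                               reps=100, seed=123)
        b = weight_sensitivity(m, printed_weights, perturbation=0.2,
                               reps=100, seed=123)
        assert a.top1_stability == b.top1_stability
        pd.testing.assert_frame_equal(a.rank_range, b.rank_range)

    def test_invalid_params_rejected(self, printed_weights):
        m = random_matrix(5, 0)
        with pytest.raises(McdaError):
            weight_sensitivity(m, printed_weights, perturbation=1.5, reps=10)
        with pytest.raises(McdaError):
            weight_sensitivity(m, printed_weights, perturbation=0.2, reps=0)
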