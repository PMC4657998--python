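"""Shadow-feature, stepwise-LDA and RFE selectors, and the consensus union."""

import numpy as np
import pandas as pd
import pytest

from vocclass import (
    boruta_select,
    consensus_union,
    rfe_select,
    step_lda_select,
)
from vocclass.feature_table import ContractError
from vocclass.selection import SelectionResult
from vocclass.validation import make_folds
from vocclass.classifiers import FisherLDA


def _planted_data(rng, n=100, n_noise=20, p_a=0.9, p_b=0.1):
    """One discriminative binary feature + iid coin-flip noise; balanced labels."""
    y = np.repeat([0, 1], n // 2)
    planted = np.where(y == 1, rng.random(n) < p_a, rng.random(n) < p_b).astype(float)
    noise = (rng.random((n, n_noise)) < 0.5).astype(float)
    X = np.column_stack([planted, noise])
    names = ["planted"] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=names), y


class TestBoruta:
    def test_perfect_separator_confirmed(self, rng):
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame(
            {"sep": y.astype(float), "n1": rng.random(60), "n2": rng.random(60)}
        )
        res = boruta_select(X, y, max_iter=25, n_trees=30, seed=0)
        assert "sep" in res.selected

    def test_planted_feature_recovered_across_seeds(self, rng):
        hits = 0
        for seed in range(3):
            X, y = _planted_data(np.random.default_rng(100 + seed))
            res = boruta_select(X, y, max_iter=30, n_trees=40, seed=seed)
            hits += "planted" in res.selected
        assert hits == 3

    def test_null_false_positives_controlled(self):
        """Label-independent coin flips: confirmations stay at the alpha level."""
        confirmed = 0
        for seed in range(3):
            rng = np.random.default_rng(500 + seed)
            X = (rng.random((100, 40)) < 0.5).astype(float)
            y = np.repeat([0, 1], 50)
            res = boruta_select(X, y, max_iter=30, alpha=0.01, n_trees=40, seed=seed)
            confirmed += len(res.selected)
        assert confirmed <= 3  # 120 feature-tests at alpha 0.01

    def test_constant_feature_auto_rejected(self, rng):
        X = pd.DataFrame(
            {"const": np.zeros(40), "a": rng.random(40), "b": rng.random(40)}
        )
        res = boruta_select(X, np.repeat([0, 1], 20), max_iter=10, n_trees=20, seed=0)
        assert "const" in res.diagnostics["rejected"]

    def test_min_iterations_contract(self, rng):
        with pytest.raises(ValueError, match="max_iter"):
            boruta_select(pd.DataFrame(np.ones((10, 2))), np.repeat([0, 1], 5), max_iter=5)


class TestStepLDA:
    def test_first_pick_is_best_single_feature(self, rng):
        """The greedy first step equals an exhaustive scan of single-feature CV accuracy."""
        X, y = _planted_data(rng, n=80, n_noise=6)
        res = step_lda_select(X, y, k_inner=5, seed=3)
        assert res.selected[0] == "planted"
        # independent exhaustive oracle over the canonical sample order
        Xc, yc = X.to_numpy(), y
        order = np.lexsort([Xc[:, j] for j in range(Xc.shape[1] - 1, -1, -1)] + [yc])
        Xo, yo = Xc[order], yc[order]
        folds = make_folds(len(yo), 5, labels=yo, stratified=True, seed=3)
        best_acc, best_j = -1.0, None
        for j in range(Xo.shape[1]):
            accs = []
            for f in range(5):
                te = folds == f
                m = FisherLDA().fit(Xo[~te][:, [j]], yo[~te])
                accs.append((m.predict(Xo[te][:, [j]]) == yo[te]).mean())
            if np.mean(accs) > best_acc:
                best_acc, best_j = np.mean(accs), j
        assert X.columns[best_j] == res.selected[0]

    def test_max_features_one(self, rng):
        X, y = _planted_data(rng, n=60, n_noise=4)
        res = step_lda_select(X, y, k_inner=5, max_features=1, seed=0)
        assert len(res.selected) == 1

    def test_noise_terminates_small(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame((rng.random((60, 8)) < 0.5).astype(float))
        y = np.repeat([0, 1], 30)
        res = step_lda_select(X, y, k_inner=5, seed=1)
        assert len(res.selected) <= 3
        assert res.diagnostics["direction"] == "forward"


class TestRFE:
    def test_full_set_only_no_elimination(self, rng):
        X, y = _planted_data(rng, n=40, n_noise=5)
        res = rfe_select(X, y, subset_sizes=[6], k_inner=4, n_trees=20, seed=0)
        assert sorted(res.selected) == sorted(X.columns)

    def test_planted_features_survive_elimination(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(300 + seed)
            y = np.repeat([0, 1], 50)
            p1 = np.where(y == 1, rng.random(100) < 0.85, rng.random(100) < 0.15)
            p2 = np.where(y == 1, rng.random(100) < 0.2, rng.random(100) < 0.8)
            noise = (rng.random((100, 30)) < 0.5).astype(float)
            X = pd.DataFrame(np.column_stack([p1, p2, noise]))
            X.columns = ["p1", "p2"] + [f"n{i}" for i in range(30)]
            res = rfe_select(X, y, subset_sizes=[32, 16, 8, 4, 2], k_inner=5,
                             n_trees=40, seed=seed)
            hits += ("p1" in res.selected) and ("p2" in res.selected)
        assert hits >= 2

    def test_pure_noise_collapses_to_smallest(self):
        smallest = 0
        for seed in range(2):
            rng = np.random.default_rng(700 + seed)
            X = pd.DataFrame((rng.random((60, 16)) < 0.5).astype(float))
            y = np.repeat([0, 1], 30)
            res = rfe_select(X, y, subset_sizes=[16, 8, 4, 2], k_inner=5,
                             n_trees=25, seed=seed)
            smallest += res.diagnostics["chosen_size"] == 2
        assert smallest >= 1  # the one-SE rule prefers parsimony on noise

    def test_bagged_trees_ranker(self, rng):
        X, y = _planted_data(rng, n=60, n_noise=6)
        res = rfe_select(X, y, ranker="bagged_trees", subset_sizes=[7, 3], k_inner=4,
                         n_trees=20, seed=0)
        assert res.method == "rfe_bagtree"
        assert set(res.selected) <= set(X.columns)

    def test_empty_sizes_rejected(self, rng):
        X, y = _planted_data(rng, n=20, n_noise=2)
        with pytest.raises(ValueError, match="subset_sizes"):
            rfe_select(X, y, subset_sizes=[])


class TestConsensus:
    @pytest.mark.parametrize(
        "sets, expected",
        [
            ([{"a", "b"}, {"b", "c"}, set(), {"c"}], ["a", "b", "c"]),
            ([set(), set(), set(), set()], []),
            ([{"a"}] * 4, ["a"]),
        ],
    )
    def test_union_rule(self, sets, expected):
        universe = ("a", "b", "c", "d")
        results = [
            SelectionResult(method=f"m{i}", selected=[f for f in universe if f in s],
                            universe=universe)
            for i, s in enumerate(sets)
        ]
        res = consensus_union(results)
        assert res.selected == expected
        assert res.method == "consensus"

    def test_order_follows_universe(self):
        universe = ("z", "y", "x")
        r1 = SelectionResult(method="a", selected=["x"], universe=universe)
        r2 = SelectionResult(method="b", selected=["z"], universe=universe)
        assert consensus_union([r1, r2]).selected == ["z", "x"]

    def test_mismatched_universe_rejected(self):
        r1 = SelectionResult(method="a", selected=[], universe=("a", "b"))
        r2 = SelectionResult(method="b", selected=[], universe=("a", "c"))
        with pytest.raises(ContractError):
            consensus_union([r1, r2])


class TestRowOrderInvariance:
    def test_selectors_ignore_sample_order(self, rng):
        """Shuffling the rows at a fixed seed leaves every selected set unchanged."""
        X, y = _planted_data(rng, n=60, n_noise=8)
        perm = rng.permutation(len(y))
        Xs, ys = X.iloc[perm].reset_index(drop=True), y[perm]
        b1 = boruta_select(X, y, max_iter=15, n_trees=25, seed=4)
        b2 = boruta_select(Xs, ys, max_iter=15, n_trees=25, seed=4)
        assert b1.selected == b2.selected
        s1 = step_lda_select(X, y, k_inner=5, seed=4)
        s2 = step_lda_select(Xs, ys, k_inner=5, seed=4)
        assert s1.selected == s2.selected
        r1 = rfe_select(X, y, subset_sizes=[9, 4, 2], k_inner=4, n_trees=25, seed=4)
        r2 = rfe_select(Xs, ys, subset_sizes=[9, 4, 2], k_inner=4, n_trees=25, seed=4)
        assert r1.selected == r2.selected
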