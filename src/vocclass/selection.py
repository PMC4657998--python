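"""Four feature-selection wrappers and their union consensus.

The biomarker panel is the union of the features chosen by four independent
selectors, mirroring the "selected by at least one approach" rule:

* :func:`boruta_select` — all-relevant shadow-feature scheme: each iteration
  augments the data with a column-permuted copy of every undecided feature,
  fits a random forest, and scores a *hit* when a real feature's importance
  beats the best shadow; a two-sided binomial test on the hit count confirms
  or rejects features at level ``alpha``.
* :func:`step_lda_select` — greedy forward stepwise LDA guided by inner
  k-fold CV accuracy.
* :func:`rfe_select` — backwards elimination from an importance ranking
  (ranker = random forest, or bagged trees with all features per split),
  picking the smallest subset within one standard error of the best CV
  accuracy.

All selectors canonicalize the sample order (sort by label, then feature
values) before touching any RNG, so their output is invariant to permuting
the input rows at a fixed seed.  Ties everywhere break by input column
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .classifiers import FisherLDA
from .feature_table import ContractError
from .validation import make_folds

__all__ = [
    "SelectionResult",
    "boruta_select",
    "step_lda_select",
    "rfe_select",
    "consensus_union",
    "make_selector_suite",
    "selection_to_csv",
]


@dataclass
class SelectionResult:
    """Selected feature set of one method (or the consensus union)."""

    method: str  # {boruta, step_lda, rfe_forest, rfe_bagtree, consensus}
    selected: list[str]
    scores: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    universe: tuple = ()


def _coerce(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("exactly two classes required")
    return X, y, names


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic total order over samples: by label, then feature values."""
    _, y_codes = np.unique(y, return_inverse=True)
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [y_codes]
    return np.lexsort(keys)


def boruta_select(
    X,
    y,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_trees: int = 500,
    seed: int = 0,
) -> SelectionResult:
    """Shadow-feature all-relevant selection around a random forest.

    Constant features are rejected outright.  Features still undecided after
    ``max_iter`` iterations are reported *tentative* and excluded from the
    selection; an all-rejected outcome yields an empty (valid) selection.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    X, y, names = _coerce(X, y)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    rng = np.random.default_rng(seed)
    status = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    status[X.std(axis=0) == 0] = -1
    hits = np.zeros(p, dtype=int)
    trials = np.zeros(p, dtype=int)
    n_iter = 0
    for it in range(max_iter):
        und = np.nonzero(status == 0)[0]
        if und.size == 0:
            break
        n_iter = it + 1
        shadows = rng.permuted(X[:, und], axis=0)
        X_aug = np.hstack([X[:, und], shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        ).fit(X_aug, y)
        imp = forest.feature_importances_
        shadow_max = imp[und.size:].max()
        hits[und] += imp[: und.size] > shadow_max
        trials[und] += 1
        for f in und:
            test = binomtest(int(hits[f]), int(trials[f]), 0.5)
            if test.pvalue < alpha:
                status[f] = 1 if hits[f] * 2 > trials[f] else -1
    selected = [names[i] for i in range(p) if status[i] == 1]
    tentative = [names[i] for i in range(p) if status[i] == 0]
    hit_rate = np.divide(hits, trials, out=np.zeros(p), where=trials > 0)
    return SelectionResult(
        method="boruta",
        selected=selected,
        scores={names[i]: float(hit_rate[i]) for i in range(p)},
        diagnostics={
            "iterations": n_iter,
            "tentative": tentative,
            "rejected": [names[i] for i in range(p) if status[i] == -1],
            "alpha": alpha,
        },
        universe=tuple(names),
    )


def _lda_cv_accuracy(X, y, cols, folds, k) -> float | None:
    """Mean fold accuracy of an LDA on the given columns; None if every fold fails."""
    accs = []
    for j in range(k):
        te = folds == j
        tr = ~te
        try:
            m = FisherLDA().fit(X[np.ix_(tr, cols)], y[tr])
        except (ValueError, np.linalg.LinAlgError):
            return None
        accs.append(float((m.predict(X[np.ix_(te, cols)]) == y[te]).mean()))
    return float(np.mean(accs))


def step_lda_select(
    X,
    y,
    k_inner: int = 10,
    max_features: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward stepwise LDA selection scored by inner-CV accuracy.

    The first step always takes the best single feature; subsequent features
    are added only while CV accuracy strictly improves (or until
    ``max_features``).  Candidates whose LDA fit fails in any fold are
    skipped and logged.  Ties break by input column order.
    """
    X, y, names = _coerce(X, y)
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least 1 feature")
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    n = len(X)
    k = min(k_inner, n)
    folds = make_folds(n, k, labels=y, stratified=True, seed=seed)
    cap = p if max_features is None else min(max_features, p)
    selected_idx: list[int] = []
    skipped: list[str] = []
    trail: list[tuple[str, float]] = []
    # baseline: majority-class accuracy under the same folds
    _, yc = np.unique(y, return_inverse=True)
    base_accs = []
    for j in range(k):
        te = folds == j
        maj = np.bincount(yc[~te]).argmax()
        base_accs.append(float((yc[te] == maj).mean()))
    current = float(np.mean(base_accs))
    while len(selected_idx) < cap:
        best_acc, best_f = -1.0, None
        for f in range(p):
            if f in selected_idx:
                continue
            acc = _lda_cv_accuracy(X, y, selected_idx + [f], folds, k)
            if acc is None:
                skipped.append(names[f])
                continue
            if acc > best_acc:
                best_acc, best_f = acc, f
        if best_f is None:
            break
        if selected_idx and best_acc <= current:
            break
        selected_idx.append(best_f)
        current = max(current, best_acc)
        trail.append((names[best_f], best_acc))
    return SelectionResult(
        method="step_lda",
        selected=[names[i] for i in selected_idx],
        scores={name: acc for name, acc in trail},
        diagnostics={"direction": "forward", "cv_trail": trail,
                     "baseline_accuracy": float(np.mean(base_accs)),
                     "skipped": sorted(set(skipped))},
        universe=tuple(names),
    )


def rfe_select(
    X,
    y,
    ranker: str = "forest",
    subset_sizes: Sequence[int] | None = None,
    k_inner: int = 10,
    n_trees: int = 500,
    seed: int = 0,
) -> SelectionResult:
    """Backwards elimination from a one-shot importance ranking.

    ``ranker='forest'`` uses random feature subsets per split;
    ``'bagged_trees'`` is the same ensemble with every feature available at
    each split.  For each candidate subset size the top-ranked features are
    scored by k-fold CV; the result is the smallest subset whose mean
    accuracy is within one standard error of the best.
    """
    if ranker not in ("forest", "bagged_trees"):
        raise ValueError(f"unknown ranker {ranker!r}")
    X, y, names = _coerce(X, y)
    p = X.shape[1]
    if subset_sizes is None:
        sizes, s = [], p
        while s >= 2:
            sizes.append(s)
            s //= 2
        subset_sizes = sizes
    subset_sizes = list(subset_sizes)
    if not subset_sizes:
        raise ValueError("subset_sizes must be non-empty")
    if sorted(subset_sizes, reverse=True) != subset_sizes or subset_sizes[0] > p:
        raise ValueError("subset_sizes must be sorted descending with max <= feature count")
    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    rng = np.random.default_rng(seed)
    max_features = "sqrt" if ranker == "forest" else None

    full = RandomForestClassifier(
        n_estimators=n_trees, max_features=max_features,
        random_state=int(rng.integers(2**31)), n_jobs=1,
    ).fit(X, y)
    imp = full.feature_importances_
    rank = np.argsort(-imp, kind="stable")  # ties by input order

    n = len(X)
    k = min(k_inner, n)
    folds = make_folds(n, k, labels=y, stratified=True, seed=int(rng.integers(2**31)))
    size_stats = []
    for s in subset_sizes:
        cols = rank[:s]
        accs = []
        for j in range(k):
            te = folds == j
            tr = ~te
            m = RandomForestClassifier(
                n_estimators=n_trees, max_features=max_features,
                random_state=int(rng.integers(2**31)), n_jobs=1,
            ).fit(X[np.ix_(tr, cols)], y[tr])
            accs.append(float((m.predict(X[np.ix_(te, cols)]) == y[te]).mean()))
        size_stats.append((s, float(np.mean(accs)), float(np.std(accs, ddof=1) / np.sqrt(k))))
    best_size, best_mean, best_se = max(size_stats, key=lambda t: t[1])
    eligible = [s for s, m, _ in size_stats if m >= best_mean - best_se]
    chosen = min(eligible)
    cols = rank[:chosen]
    method = "rfe_forest" if ranker == "forest" else "rfe_bagtree"
    return SelectionResult(
        method=method,
        selected=[names[i] for i in cols],
        scores={names[i]: float(imp[i]) for i in range(p)},
        diagnostics={"size_stats": size_stats, "chosen_size": chosen,
                     "best": (best_size, best_mean, best_se), "ranker": ranker},
        universe=tuple(names),
    )


def consensus_union(results: Sequence[SelectionResult]) -> SelectionResult:
    """Union of the per-method selections, ordered by the input table's columns."""
    results = list(results)
    if not results:
        raise ValueError("need at least one SelectionResult")
    universe = results[0].universe
    for r in results[1:]:
        if tuple(r.universe) != tuple(universe):
            raise ContractError("selection results cover different feature universes")
    member = set()
    for r in results:
        member.update(r.selected)
    selected = [f for f in universe if f in member]
    flags = {
        f: {r.method: (f in r.selected) for r in results} for f in universe
    }
    return SelectionResult(
        method="consensus",
        selected=selected,
        scores={f: sum(v.values()) for f, v in flags.items()},
        diagnostics={"methods": [r.method for r in results], "flags": flags},
        universe=tuple(universe),
    )


def make_selector_suite(
    methods: Sequence[str] = ("boruta", "step_lda", "rfe_forest", "rfe_bagtree"),
    n_trees: int = 100,
    boruta_iter: int = 100,
    alpha: float = 0.01,
    max_features: int | None = 12,
    k_inner: int = 10,
) -> Callable:
    """Build ``suite(X_df, y, seed) -> SelectionResult`` running the chosen
    selectors and returning their consensus (used for nested rdCV and the
    pipeline's full-data selection)."""

    def suite(Xdf, y, seed: int) -> SelectionResult:
        ss = np.random.SeedSequence(entropy=int(seed) % (2**31))
        seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(4)]
        results = []
        if "boruta" in methods:
            results.append(boruta_select(Xdf, y, max_iter=boruta_iter, alpha=alpha,
                                         n_trees=n_trees, seed=seeds[0]))
        if "step_lda" in methods:
            results.append(step_lda_select(Xdf, y, k_inner=k_inner,
                                           max_features=max_features, seed=seeds[1]))
        if "rfe_forest" in methods:
            results.append(rfe_select(Xdf, y, ranker="forest", k_inner=k_inner,
                                      n_trees=n_trees, seed=seeds[2]))
        if "rfe_bagtree" in methods:
            results.append(rfe_select(Xdf, y, ranker="bagged_trees", k_inner=k_inner,
                                      n_trees=n_trees, seed=seeds[3]))
        return consensus_union(results)

    return suite


def selection_to_csv(results: Sequence[SelectionResult], path) -> None:
    """Two-column serialization: feature, bitmask of selecting methods (bit i = method i)."""
    results = list(results)
    universe = results[0].universe
    masks = {}
    for f in universe:
        mask = 0
        for i, r in enumerate(results):
            if f in r.selected:
                mask |= 1 << i
        masks[f] = mask
    pd.DataFrame(
        {"feature": list(universe), "method_mask": [masks[f] for f in universe]}
    ).to_csv(path, index=False)
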