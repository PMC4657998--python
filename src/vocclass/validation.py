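"""Cross-validation engines, permutation nulls, metrics and summaries.

Two resampling schemes estimate out-of-sample accuracy:

* **Repeated k-fold CV** — k folds, each held out once, the whole partition
  re-randomized R times; one metric record *per fold* (30 repeats × 10 folds
  → 300 fold-level accuracies, so individual values are coarse multiples of
  1/10 or 1/11 on a 102-sample cohort).
* **Repeated double CV (rdCV)** — a nested scheme: each outer repeat splits
  the cohort into ``k_outer`` folds; the calibration portion drives an inner
  repeated k-fold loop that tunes the model (and, in ``nested`` selection
  mode, re-selects features), the tuned model is refit on the calibration set
  and scored on the outer test fold; predictions from all outer folds are
  pooled into one confusion matrix → one record *per outer repeat*.

Each scheme has a **Monte-Carlo permutation null**: at the start of every
repeat the class labels are randomly permuted (class sizes preserved) and the
full scheme runs on the permuted labels, estimating the accuracy achievable
by chance.  The analytic companion is :func:`chance_agreement`, p² + q², the
accuracy of a random classifier whose predicted marginals match the class
marginals.

All randomness cascades from ``CVScheme.master_seed`` through
``numpy.random.SeedSequence`` spawn keys, so any repeat is reproducible in
isolation and identical seeds give bit-identical metric streams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import FisherLDA, RandomForest
from .feature_table import ContractError, FeatureTable

__all__ = [
    "CVScheme",
    "ModelSpec",
    "MetricRecord",
    "SummaryRow",
    "ROCData",
    "ValidationResult",
    "make_folds",
    "repeated_kfold_cv",
    "repeated_double_cv",
    "monte_carlo_null",
    "confusion_metrics",
    "six_number_summary",
    "chance_agreement",
    "pooled_roc",
]


# -- plans and specs -------------------------------------------------------

@dataclass(frozen=True)
class CVScheme:
    """Full specification of a resampling plan."""

    kind: str  # {"repeated_kfold", "repeated_double"}
    repeats: int = 30
    k_outer: int = 10
    inner_repeats: int = 30
    inner_k: int = 10
    permute_labels: bool = False
    selection_mode: str = "full_data"  # {"full_data", "nested"}
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("repeated_kfold", "repeated_double"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.repeats < 1 or self.k_outer < 2:
            raise ValueError("repeats >= 1 and k_outer >= 2 required")
        if self.kind == "repeated_double" and self.inner_k < 2:
            raise ValueError("inner_k >= 2 required for repeated_double")
        if self.selection_mode not in ("full_data", "nested"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")

    @classmethod
    def repeated_kfold(cls, repeats: int = 30, k: int = 10, **kw) -> "CVScheme":
        return cls(kind="repeated_kfold", repeats=repeats, k_outer=k, **kw)

    @classmethod
    def repeated_double(
        cls, repeats: int = 30, k_outer: int = 3, inner_k: int = 10, inner_repeats: int = 30, **kw
    ) -> "CVScheme":
        return cls(
            kind="repeated_double",
            repeats=repeats,
            k_outer=k_outer,
            inner_k=inner_k,
            inner_repeats=inner_repeats,
            **kw,
        )


@dataclass(frozen=True)
class ModelSpec:
    """What to fit in each fold: model family, fixed parameters, tuning grid.

    ``continuous`` names design columns (typically the PSA covariate) that
    are log-transformed and z-scored on the training portion before an LDA
    fit; the forest receives all columns unscaled.  ``grid`` overrides the
    default tuning grid (forest: mtry over {1, floor(sqrt(p)), floor(p/2)};
    LDA: relative ridge over {1e-6, 1e-3}).
    """

    kind: str  # {"lda", "forest"}
    n_trees: int = 500
    mtry: Optional[int] = None
    priors: str = "empirical"
    ridge: float = 1e-6
    continuous: tuple = ()
    grid: tuple = ()

    def __post_init__(self):
        if self.kind not in ("lda", "forest"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def tuning_grid(self, p: int) -> tuple:
        if self.grid:
            return tuple(self.grid)
        if self.kind == "forest":
            cands = sorted({1, max(1, int(math.isqrt(p))), max(1, p // 2)})
            return tuple({"mtry": m} for m in cands)
        return ({"ridge": 1e-6}, {"ridge": 1e-3})


class _FoldModel:
    """One fold's model: optional train-only log/z-score of continuous columns + estimator."""

    def __init__(self, spec: ModelSpec, cont_idx: Sequence[int], seed: int, params: dict):
        self.spec = spec
        self.cont_idx = list(cont_idx)
        if spec.kind == "lda":
            self.est = FisherLDA(priors=spec.priors, ridge=params.get("ridge", spec.ridge))
            self._transform = bool(self.cont_idx)
        else:
            self.est = RandomForest(
                n_trees=spec.n_trees, mtry=params.get("mtry", spec.mtry), seed=seed
            )
            self._transform = False

    def _prep(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if not self._transform:
            return X
        X = X.astype(float, copy=True)
        if fit:
            self._stats = []
        for pos, j in enumerate(self.cont_idx):
            col = np.log(np.maximum(X[:, j], 1e-12))
            if fit:
                mu, sd = col.mean(), col.std()
                self._stats.append((mu, sd if sd > 0 else 1.0))
            mu, sd = self._stats[pos]
            X[:, j] = (col - mu) / sd
        return X

    def fit(self, X, y):
        self.est.fit(self._prep(np.asarray(X, float), fit=True), y)
        return self

    def predict(self, X):
        return self.est.predict(self._prep(np.asarray(X, float), fit=False))

    def proba1(self, X):
        return self.est.predict_proba(self._prep(np.asarray(X, float), fit=False))[:, 1]


# -- records and summaries -------------------------------------------------

@dataclass
class MetricRecord:
    """Accuracy/sensitivity/specificity for one evaluation unit (fold or outer repeat)."""

    unit: str  # {"fold", "outer_repeat"}
    repeat_index: int
    fold_index: Optional[int]
    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    n_test: int
    confusion: tuple  # (TP, FP, TN, FN)


@dataclass(frozen=True)
class SummaryRow:
    """Min / 1st Qu. / Median / Mean / 3rd Qu. / Max on the metric's scale."""

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float

    def as_dict(self) -> dict:
        return {
            "Min.": self.min,
            "1st.Qu.": self.q1,
            "Median": self.median,
            "Mean": self.mean,
            "3rd.Qu.": self.q3,
            "Max.": self.max,
        }


@dataclass
class ROCData:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_metrics(y_true, y_pred, positive_class) -> MetricRecord:
    """Exact confusion-matrix metrics for one evaluation unit.

    Sensitivity (specificity) is ``None`` when the truth contains no positive
    (negative) cases.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("y_true and y_pred must have equal length >= 1")
    known = set(np.unique(y_true)) | set(np.unique(y_pred))
    labels_seen = set(np.unique(y_true))
    if positive_class not in known:
        raise ContractError(f"positive class {positive_class!r} not among labels {sorted(map(str, known))}")
    if len(labels_seen | {positive_class}) > 2 or len(known) > 2:
        raise ContractError(f"more than two label values: {sorted(map(str, known))}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int((pos_t & pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    n = len(y_true)
    return MetricRecord(
        unit="fold",
        repeat_index=-1,
        fold_index=None,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn > 0 else None,
        specificity=tn / (tn + fp) if tn + fp > 0 else None,
        n_test=n,
        confusion=(tp, fp, tn, fn),
    )


def six_number_summary(values) -> SummaryRow:
    """Quartiles by linear interpolation of order statistics (position (n-1)p + 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("six_number_summary requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return SummaryRow(
        min=float(arr.min()), q1=float(q1), median=float(med),
        mean=float(arr.mean()), q3=float(q3), max=float(arr.max()),
    )


def chance_agreement(n_pos: int, n_neg: int) -> float:
    """Accuracy of a random classifier with fixed marginal frequencies: p² + q²."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be non-empty")
    p = n_pos / (n_pos + n_neg)
    return p * p + (1 - p) * (1 - p)


def pooled_roc(scores, y_true, positive_class) -> ROCData:
    """ROC over pooled per-sample scores with trapezoidal AUC.

    Thresholds sweep the distinct score values; constant scores give the
    single-segment diagonal (AUC 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(y_true) == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative case")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    return ROCData(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


# -- fold construction -----------------------------------------------------

def make_folds(
    sample_count: int,
    k: int,
    labels=None,
    stratified: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Assign each sample a fold id in 0..k-1; sizes differ by at most 1.

    Stratified mode balances class counts per fold to within 1; if some class
    has fewer members than folds it degrades to a plain partition with a
    warning.  Deterministic given ``seed``.
    """
    if not 2 <= k <= sample_count:
        raise ValueError(f"require 2 <= k <= n, got k={k}, n={sample_count}")
    seed = int(seed) % (2**32)
    if stratified and labels is not None:
        labels = np.asarray(labels)
        if np.bincount(pd.factorize(labels)[0]).min() < k:
            warnings.warn("a class has fewer samples than folds; using unstratified folds")
            stratified = False
    if stratified and labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(sample_count), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(sample_count))
    assign = np.full(sample_count, -1, dtype=int)
    for j, (_, test_idx) in enumerate(splits):
        assign[test_idx] = j
    return assign


def _child_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _resolve_positive(table: FeatureTable, positive_class):
    if positive_class is not None:
        return positive_class
    classes = table.classes
    return "cancer" if "cancer" in classes else classes[0]


def _design(table: FeatureTable, feature_set, spec: ModelSpec):
    feature_set = list(feature_set)
    df = table.design_matrix(feature_set)
    cont_names = set(spec.continuous) | set(table.covariates.columns)
    cont_idx = [i for i, c in enumerate(df.columns) if c in cont_names]
    return df, df.to_numpy(float), cont_idx


# -- results container -----------------------------------------------------

@dataclass
class ValidationResult:
    """Metric records from one scheme run, plus pooled test-fold scores.

    ``score_matrix`` holds, per sample × repeat, the class-positive score the
    sample received when it sat in a test fold (NaN if skipped); Fig-2-style
    pooled ROC averages each sample's scores over repeats.
    """

    records: list
    scheme: CVScheme
    model_kind: str
    feature_set: tuple
    positive_class: object
    labels: np.ndarray
    score_matrix: np.ndarray
    log: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.records])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies().mean())

    def summary(self, metric: str = "accuracy") -> SummaryRow:
        vals = [getattr(r, metric) for r in self.records]
        vals = [v for v in vals if v is not None]
        return six_number_summary(vals)

    def summary_frame(self, percent: bool = False) -> pd.DataFrame:
        rows = {}
        for metric in ("accuracy", "sensitivity", "specificity"):
            row = self.summary(metric).as_dict()
            if percent:
                row = {k: 100 * v for k, v in row.items()}
            rows[metric] = row
        return pd.DataFrame(rows).T

    def pooled_scores(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.score_matrix, axis=1)

    def roc(self) -> ROCData:
        return pooled_roc(self.pooled_scores(), self.labels, self.positive_class)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            tp, fp, tn, fn = r.confusion
            rows.append(
                dict(unit=r.unit, repeat=r.repeat_index, fold=r.fold_index,
                     accuracy=r.accuracy, sensitivity=r.sensitivity,
                     specificity=r.specificity, n_test=r.n_test,
                     tp=tp, fp=fp, tn=tn, fn=fn)
            )
        return pd.DataFrame(rows)


# -- engines ---------------------------------------------------------------

def _metric(y_true, y_pred, unit, repeat, fold=None) -> MetricRecord:
    rec = confusion_metrics(y_true, y_pred, positive_class=1)
    rec.unit = unit
    rec.repeat_index = repeat
    rec.fold_index = fold
    return rec


def repeated_kfold_cv(
    table: FeatureTable,
    model_spec: ModelSpec,
    feature_set: Sequence[str],
    scheme: CVScheme,
    positive_class=None,
) -> ValidationResult:
    """Repeated k-fold CV: one fold-level record per fold per repeat."""
    if scheme.kind != "repeated_kfold":
        raise ValueError("scheme.kind must be 'repeated_kfold'")
    feature_set = list(feature_set)
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    pos = _resolve_positive(table, positive_class)
    _, X, cont_idx = _design(table, feature_set, model_spec)
    y_true01 = (table.labels.to_numpy() == pos).astype(int)
    n, k = len(X), scheme.k_outer
    records: list[MetricRecord] = []
    log: list[str] = []
    scores = np.full((n, scheme.repeats), np.nan)
    for r in range(scheme.repeats):
        ss = np.random.SeedSequence(entropy=scheme.master_seed, spawn_key=(r,))
        perm_ss, fold_ss, model_ss = ss.spawn(3)
        y = y_true01
        if scheme.permute_labels:
            y = np.random.default_rng(perm_ss).permutation(y_true01)
        folds = make_folds(n, k, labels=y, stratified=scheme.stratified, seed=_child_int(fold_ss))
        fold_seeds = model_ss.spawn(k)
        for j in range(k):
            te = folds == j
            tr = ~te
            if len(np.unique(y[tr])) < 2:
                log.append(f"repeat {r} fold {j}: training portion single-class, skipped")
                continue
            model = _FoldModel(model_spec, cont_idx, seed=_child_int(fold_seeds[j]), params={})
            model.fit(X[tr], y[tr])
            y_hat = model.predict(X[te])
            scores[te, r] = model.proba1(X[te])
            records.append(_metric(y[te], y_hat, "fold", r, j))
    return ValidationResult(
        records=records, scheme=scheme, model_kind=model_spec.kind,
        feature_set=tuple(feature_set), positive_class=pos,
        labels=table.labels.to_numpy(), score_matrix=scores, log=log,
    )


def _inner_cv_accuracy(
    X, y, spec: ModelSpec, cont_idx, params: dict, k: int, repeats: int,
    ss: np.random.SeedSequence, stratified: bool,
) -> float:
    """Mean fold accuracy of the inner tuning loop for one parameter candidate."""
    n = len(X)
    k = min(k, n)
    accs = []
    for r in range(repeats):
        rep_ss = np.random.SeedSequence(entropy=_child_int(ss), spawn_key=(r,))
        fold_ss, model_ss = rep_ss.spawn(2)
        folds = make_folds(n, k, labels=y, stratified=stratified, seed=_child_int(fold_ss))
        fold_seeds = model_ss.spawn(k)
        for j in range(k):
            te = folds == j
            tr = ~te
            if len(np.unique(y[tr])) < 2:
                continue
            m = _FoldModel(spec, cont_idx, seed=_child_int(fold_seeds[j]), params=params)
            m.fit(X[tr], y[tr])
            accs.append(float((m.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs)) if accs else 0.0


def repeated_double_cv(
    table: FeatureTable,
    model_spec: ModelSpec,
    scheme: CVScheme,
    feature_set: Sequence[str],
    selector_suite: Optional[Callable] = None,
    positive_class=None,
) -> ValidationResult:
    """Repeated double CV: one pooled outer-repeat record per repeat.

    In ``full_data`` selection mode ``feature_set`` is the pre-selected panel.
    In ``nested`` mode ``feature_set`` is the candidate universe and
    ``selector_suite(values_df, labels, seed) -> [names]`` is called on each
    calibration set; covariate columns in ``feature_set`` always stay in the
    model.  An empty nested selection falls back to the full universe
    (logged).
    """
    if scheme.kind != "repeated_double":
        raise ValueError("scheme.kind must be 'repeated_double'")
    feature_set = list(feature_set)
    if not feature_set:
        raise ValueError("feature_set must be non-empty")
    pos = _resolve_positive(table, positive_class)
    df, X, _ = _design(table, feature_set, model_spec)
    voc_cols = [c for c in feature_set if c in table.values.columns]
    y_true01 = (table.labels.to_numpy() == pos).astype(int)
    labels_raw = table.labels.to_numpy()
    n, k_out = len(X), scheme.k_outer
    records: list[MetricRecord] = []
    log: list[str] = []
    chosen_params: list = []
    panel_sizes: list[int] = []
    scores = np.full((n, scheme.repeats), np.nan)
    for r in range(scheme.repeats):
        ss = np.random.SeedSequence(entropy=scheme.master_seed, spawn_key=(r,))
        perm_ss, fold_ss, inner_ss, model_ss, select_ss = ss.spawn(5)
        y = y_true01
        if scheme.permute_labels:
            y = np.random.default_rng(perm_ss).permutation(y_true01)
        folds = make_folds(n, k_out, labels=y, stratified=scheme.stratified, seed=_child_int(fold_ss))
        neg = next(c for c in table.classes if c != pos)
        labels_used = np.where(y == 1, pos, neg)
        fold_inner = inner_ss.spawn(k_out)
        fold_model = model_ss.spawn(k_out)
        fold_select = select_ss.spawn(k_out)
        y_pool = np.empty(0, dtype=int)
        yhat_pool = np.empty(0, dtype=int)
        for j in range(k_out):
            te = folds == j
            tr = ~te
            if len(np.unique(y[tr])) < 2:
                log.append(f"repeat {r} outer fold {j}: calibration single-class, skipped")
                continue
            cols = feature_set
            if scheme.selection_mode == "nested" and selector_suite is not None and voc_cols:
                sub = table.values.loc[table.values.index[tr], voc_cols]
                res = selector_suite(sub, labels_used[tr], _child_int(fold_select[j]))
                sel = list(res.selected) if hasattr(res, "selected") else list(res)
                if not sel:
                    log.append(f"repeat {r} outer fold {j}: empty nested panel, using all features")
                    sel = voc_cols
                cols = sel + [c for c in feature_set if c not in table.values.columns]
            col_idx = [feature_set.index(c) for c in cols]
            Xs = X[:, col_idx]
            cont_idx_s = [i for i, c in enumerate(cols) if c in table.covariates.columns]
            panel_sizes.append(len(cols))
            grid = model_spec.tuning_grid(len(cols))
            if len(grid) > 1 and scheme.inner_repeats > 0:
                inner_accs = [
                    _inner_cv_accuracy(
                        Xs[tr], y[tr], model_spec, cont_idx_s, params,
                        scheme.inner_k, scheme.inner_repeats,
                        np.random.SeedSequence(entropy=_child_int(fold_inner[j]), spawn_key=(gi,)),
                        scheme.stratified,
                    )
                    for gi, params in enumerate(grid)
                ]
                best = grid[int(np.argmax(inner_accs))]
            else:
                best = grid[0]
            chosen_params.append(best)
            model = _FoldModel(model_spec, cont_idx_s, seed=_child_int(fold_model[j]), params=best)
            model.fit(Xs[tr], y[tr])
            y_hat = model.predict(Xs[te])
            scores[te, r] = model.proba1(Xs[te])
            y_pool = np.concatenate([y_pool, y[te]])
            yhat_pool = np.concatenate([yhat_pool, y_hat])
        if len(y_pool):
            records.append(_metric(y_pool, yhat_pool, "outer_repeat", r))
    return ValidationResult(
        records=records, scheme=scheme, model_kind=model_spec.kind,
        feature_set=tuple(feature_set), positive_class=pos,
        labels=labels_raw, score_matrix=scores, log=log,
        diagnostics={"chosen_params": chosen_params, "panel_sizes": panel_sizes},
    )


def monte_carlo_null(
    table: FeatureTable,
    model_spec: ModelSpec,
    feature_set: Sequence[str],
    scheme: CVScheme,
    positive_class=None,
) -> ValidationResult:
    """Run the scheme with labels permuted at the start of each repeat.

    The feature panel stays fixed (it is not re-selected from permuted
    labels); class sizes are preserved by the permutation.
    """
    scheme = replace(scheme, permute_labels=True)
    if scheme.kind == "repeated_kfold":
        return repeated_kfold_cv(table, model_spec, feature_set, scheme, positive_class)
    return repeated_double_cv(table, model_spec, scheme, feature_set, None, positive_class)
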