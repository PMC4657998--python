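"""Study-level model object: filter → consensus selection → validation.

:class:`VOCStudy` is the front door of the package.  It is built from a
:class:`~vocclass.feature_table.FeatureTable` (or a cohort CSV), holds the
analysis configuration — which model families, which feature sources (VOC
panel, PSA covariate, or both), which resampling scheme — and ``fit()``
executes the whole pipeline, returning a :class:`StudyResults` carrying the
filter report, the per-method and consensus selections, the metric records
of every model × feature-source combination, and paper-style six-number
summary tables via ``summary()``.

Typical use::

    table, truth = generate_cohort(SyntheticConfig(seed=1))
    study = VOCStudy(table, models=("forest", "lda"), sources=("voc", "voc+psa"),
                     scheme=CVScheme.repeated_double(master_seed=1))
    results = study.fit()
    print(results.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .feature_table import (
    FeatureTable,
    FilterReport,
    binarize,
    prevalence_filter,
    read_feature_table,
)
from .selection import SelectionResult, make_selector_suite, selection_to_csv
from .validation import (
    CVScheme,
    ModelSpec,
    ValidationResult,
    repeated_double_cv,
    repeated_kfold_cv,
)

__all__ = ["VOCStudy", "StudyResults"]


class VOCStudy:
    """Configured analysis of one cohort table.

    Parameters
    ----------
    table : FeatureTable
        Cohort data; abundances are binarized at ``threshold`` if needed.
    models : sequence of {"forest", "lda"}
    sources : sequence of {"voc", "psa", "voc+psa"}
        ``psa`` stands for all covariate columns of the table.
    scheme : CVScheme
        Resampling plan (default: repeated 10-fold, 30 repeats).
    panel : optional list of feature names
        Pre-selected VOC panel; when absent and a source needs VOCs, the
        four-selector consensus is run on the filtered table (full-data
        mode) or inside each calibration set (nested mode).
    n_trees : int
        Forest size for the classifiers.
    selector_trees, boruta_iter, max_panel : selector knobs.
    """

    def __init__(
        self,
        table: FeatureTable,
        models: Sequence[str] = ("forest", "lda"),
        sources: Sequence[str] = ("voc",),
        scheme: Optional[CVScheme] = None,
        panel: Optional[Sequence[str]] = None,
        selectors: Sequence[str] = ("boruta", "step_lda", "rfe_forest", "rfe_bagtree"),
        filter_low: float = 0.20,
        filter_high: float = 0.90,
        threshold: float = 0.0,
        n_trees: int = 500,
        selector_trees: int = 100,
        boruta_iter: int = 100,
        max_panel: int = 12,
        positive_class=None,
    ):
        models = tuple(models)
        sources = tuple(sources)
        if not models or not sources:
            raise ValueError("at least one model and one feature source required")
        for m in models:
            if m not in ("forest", "lda"):
                raise ValueError(f"unknown model {m!r}")
        for s in sources:
            if s not in ("voc", "psa", "voc+psa"):
                raise ValueError(f"unknown feature source {s!r}")
        self.table = table
        self.models = models
        self.sources = sources
        self.scheme = scheme or CVScheme.repeated_kfold()
        self.panel = list(panel) if panel is not None else None
        self.selectors = tuple(selectors)
        self.filter_low = filter_low
        self.filter_high = filter_high
        self.threshold = threshold
        self.n_trees = n_trees
        self.selector_trees = selector_trees
        self.boruta_iter = boruta_iter
        self.max_panel = max_panel
        self.positive_class = positive_class

    @classmethod
    def from_csv(cls, path, label_column: str = "class",
                 covariate_columns: Sequence[str] = ("psa",), **kwargs) -> "VOCStudy":
        table = read_feature_table(path, label_column=label_column,
                                   covariate_columns=covariate_columns)
        return cls(table, **kwargs)

    # -----------------------------------------------------------------

    def _needs_voc(self) -> bool:
        return any(s in ("voc", "voc+psa") for s in self.sources)

    def fit(self) -> "StudyResults":
        table = self.table if self.table.binary else binarize(self.table, self.threshold)
        filtered, report = prevalence_filter(table, self.filter_low, self.filter_high)

        suite = make_selector_suite(
            methods=self.selectors, n_trees=self.selector_trees,
            boruta_iter=self.boruta_iter, max_features=self.max_panel,
        )
        panel = self.panel
        consensus: Optional[SelectionResult] = None
        if (
            panel is None
            and self._needs_voc()
            and self.scheme.selection_mode == "full_data"
        ):
            consensus = suite(filtered.values, filtered.labels.to_numpy(),
                              self.scheme.master_seed)
            panel = consensus.selected or list(filtered.feature_names)

        covs = list(filtered.covariates.columns)
        validations: dict[tuple[str, str], ValidationResult] = {}
        for source in self.sources:
            if source == "voc":
                feats = list(panel) if panel is not None else list(filtered.feature_names)
            elif source == "psa":
                if not covs:
                    raise ValueError("source 'psa' requires covariate columns")
                feats = covs
            else:
                feats = (list(panel) if panel is not None else list(filtered.feature_names)) + covs
            for model in self.models:
                spec = ModelSpec(kind=model, n_trees=self.n_trees, continuous=tuple(covs))
                if self.scheme.kind == "repeated_kfold":
                    res = repeated_kfold_cv(filtered, spec, feats, self.scheme,
                                            self.positive_class)
                else:
                    nested_suite = suite if self.scheme.selection_mode == "nested" else None
                    res = repeated_double_cv(filtered, spec, self.scheme, feats,
                                             nested_suite, self.positive_class)
                validations[(model, source)] = res
        return StudyResults(
            study=self, filter_report=report, consensus=consensus,
            panel=list(panel) if panel is not None else None, validations=validations,
        )


@dataclass
class StudyResults:
    """Everything one ``VOCStudy.fit()`` produced."""

    study: VOCStudy
    filter_report: FilterReport
    consensus: Optional[SelectionResult]
    panel: Optional[list]
    validations: dict

    def summary(self, percent: bool = False) -> pd.DataFrame:
        """Six-number accuracy summaries, one row per model × feature source."""
        rows = []
        for (model, source), res in self.validations.items():
            row = {"model": model, "source": source, "scheme": res.scheme.kind,
                   "permuted": res.scheme.permute_labels, "n_units": len(res.records)}
            stats = res.summary("accuracy").as_dict()
            if percent:
                stats = {k: 100 * v for k, v in stats.items()}
            row.update(stats)
            if res.scheme.kind == "repeated_double":
                scale = 100 if percent else 1
                row["Sens.Mean"] = scale * res.summary("sensitivity").mean
                row["Spec.Mean"] = scale * res.summary("specificity").mean
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir) -> list:
        """Write metric CSVs, summaries, ROC, panel, filter report and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _w(name, writer):
            path = outdir / name
            writer(path)
            written.append(path)

        _w("filter_report.csv", lambda p: self.filter_report.to_frame().to_csv(p))
        if self.panel is not None:
            _w("panel.csv", lambda p: pd.Series(self.panel, name="feature").to_csv(p, index=False))
        for (model, source), res in self.validations.items():
            tag = f"{model}_{source.replace('+', '_')}"
            _w(f"metrics_{tag}.csv", lambda p, r=res: r.to_frame().to_csv(p, index=False))
            _w(f"summary_{tag}.csv", lambda p, r=res: r.summary_frame().to_csv(p))
            if res.scheme.kind == "repeated_double" and not res.scheme.permute_labels:
                roc = res.roc()
                _w(f"roc_{tag}.csv", lambda p, roc=roc: pd.DataFrame(
                    {"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(p, index=False))
        manifest = {
            "version": __version__,
            "models": list(self.study.models),
            "sources": list(self.study.sources),
            "scheme": asdict(self.study.scheme),
            "panel": self.panel,
            "filter": {"low": self.study.filter_low, "high": self.study.filter_high},
            "n_trees": self.study.n_trees,
            "n_samples": self.study.table.n_samples,
            "class_counts": {str(k): int(v) for k, v in self.study.table.class_counts().items()},
            "outputs": [p.name for p in written],
        }
        aucs = {}
        for (model, source), res in self.validations.items():
            if res.scheme.kind == "repeated_double" and not res.scheme.permute_labels:
                aucs[f"{model}_{source}"] = res.roc().auc
        if aucs:
            manifest["auc"] = aucs
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        written.append(outdir / "manifest.json")
        return written
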