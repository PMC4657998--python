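"""Synthetic urine-VOC cohorts with planted discriminative compounds.

The generator emulates the statistical structure of a processed GC-MS
presence/absence table from a prostate-biopsy cohort: 59 cancer / 43 control
samples, ~150 binary VOC features, and a right-skewed serum PSA covariate
with class medians near 6.2 (control) and 10.2 ng/mL (cancer).

Feature blocks (positions shuffled within the table):

* ``n_planted`` discriminative compounds with class-specific prevalences —
  by default three "down-regulated" features at (control 0.60, cancer 0.30)
  and one "up-regulated" at (0.30, 0.60), a detectable-but-imperfect signal
  at this cohort size;
* background features sharing one prevalence across classes, uniform on
  ``background_prevalence_range``;
* rare and common blocks whose prevalences sit below 0.20 / above 0.90 in
  both groups, so the dual prevalence filter removes them (in expectation).

Every feature is an independent per-sample coin flip given its class
prevalence; PSA is log-normal per class with log-median = ln(target median),
independent of the VOC flags.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "generate_psa", "write_truth"]

_DEFAULT_PLANTED = ((0.60, 0.30), (0.60, 0.30), (0.60, 0.30), (0.30, 0.60))


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a generated cohort.

    ``planted_prevalence`` holds (control, cancer) detection fractions per
    planted feature.  ``psa_median`` / ``psa_log_sd`` are (control, cancer)
    pairs; log-sd defaults 0.75 / 1.1 give sample ranges at n≈50 resembling
    0.8–30 and 3.4–647 ng/mL.
    """

    n_cancer: int = 59
    n_control: int = 43
    n_features: int = 150
    n_planted: int = 4
    planted_prevalence: tuple = _DEFAULT_PLANTED
    background_prevalence_range: tuple = (0.25, 0.85)
    n_rare: int = 20
    rare_prevalence_range: tuple = (0.02, 0.12)
    n_common: int = 20
    common_prevalence_range: tuple = (0.95, 0.99)
    psa_median: tuple = (6.2, 10.2)
    psa_log_sd: tuple = (0.75, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_cancer < 2 or self.n_control < 2:
            raise ValueError("class sizes must be >= 2")
        if self.n_planted != len(self.planted_prevalence):
            raise ValueError("planted_prevalence must have n_planted entries")
        if self.n_planted + self.n_rare + self.n_common > self.n_features:
            raise ValueError("n_planted + n_rare + n_common exceeds n_features")
        for pair in self.planted_prevalence:
            if not all(0 <= q <= 1 for q in pair):
                raise ValueError("prevalences must lie in [0, 1]")
        if any(m <= 0 for m in self.psa_median):
            raise ValueError("PSA target medians must be positive")
        if any(s < 0 for s in self.psa_log_sd):
            raise ValueError("PSA log-sd must be non-negative")


@dataclass
class SyntheticTruth:
    """What was planted: per-feature roles and prevalences, PSA parameters, seed."""

    planted_features: list[str]
    roles: dict  # feature -> {planted, background, rare, common}
    prevalence: pd.DataFrame  # features x (control, cancer) true prevalences
    psa_median: tuple
    psa_log_sd: tuple
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted_features": self.planted_features,
            "roles": self.roles,
            "prevalence": {f: list(map(float, row)) for f, row in self.prevalence.iterrows()},
            "psa_median": list(self.psa_median),
            "psa_log_sd": list(self.psa_log_sd),
            "seed": self.seed,
        }


def generate_psa(config: SyntheticConfig, seed: int | None = None,
                 n_per_class: tuple | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-class log-normal PSA draws (control array, cancer array).

    log-median equals ln(target median), so sample medians converge to the
    Table-1-style targets as n grows; log-sd 0 collapses to the median
    exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_ctrl, n_canc = n_per_class or (config.n_control, config.n_cancer)
    out = []
    for median, sd, n in zip(config.psa_median, config.psa_log_sd, (n_ctrl, n_canc)):
        out.append(np.exp(rng.normal(math.log(median), sd, size=n)))
    return out[0], out[1]


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw one cohort: binary VOC matrix + PSA covariate + class labels."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n_bg = config.n_features - config.n_planted - config.n_rare - config.n_common

    roles: list[str] = (
        ["planted"] * config.n_planted
        + ["background"] * n_bg
        + ["rare"] * config.n_rare
        + ["common"] * config.n_common
    )
    # per-feature (control, cancer) prevalence
    prev = []
    for pair in config.planted_prevalence:
        prev.append(tuple(pair))
    for _ in range(n_bg):
        q = rng.uniform(*config.background_prevalence_range)
        prev.append((q, q))
    for _ in range(config.n_rare):
        q = rng.uniform(*config.rare_prevalence_range)
        prev.append((q, q))
    for _ in range(config.n_common):
        q = rng.uniform(*config.common_prevalence_range)
        prev.append((q, q))

    perm = rng.permutation(config.n_features)
    width = len(str(config.n_features))
    names = [f"voc{str(i + 1).zfill(width)}" for i in range(config.n_features)]
    roles = [roles[j] for j in perm]
    prev = [prev[j] for j in perm]

    n = config.n_control + config.n_cancer
    labels = np.array(["control"] * config.n_control + ["cancer"] * config.n_cancer)
    is_cancer = labels == "cancer"
    matrix = np.empty((n, config.n_features), dtype=np.int8)
    for j, (q_ctrl, q_canc) in enumerate(prev):
        q = np.where(is_cancer, q_canc, q_ctrl)
        matrix[:, j] = rng.random(n) < q

    psa_ctrl, psa_canc = generate_psa(config, seed=int(rng.integers(2**31)))
    psa = np.concatenate([psa_ctrl, psa_canc])

    sample_ids = [f"S{str(i + 1).zfill(3)}" for i in range(n)]
    values = pd.DataFrame(matrix, index=sample_ids, columns=names)
    table = FeatureTable(
        values=values,
        labels=pd.Series(labels, index=sample_ids, name="class"),
        covariates=pd.DataFrame({"psa": psa}, index=sample_ids),
        binary=True,
    )
    truth = SyntheticTruth(
        planted_features=[names[j] for j in range(config.n_features) if roles[j] == "planted"],
        roles=dict(zip(names, roles)),
        prevalence=pd.DataFrame(prev, index=names, columns=["control", "cancer"]),
        psa_median=config.psa_median,
        psa_log_sd=config.psa_log_sd,
        seed=config.seed,
    )
    return table, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
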