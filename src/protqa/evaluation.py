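"""Performance measures and leave-one-target-out cross-validation.

Per target, three measures compare predicted with observed GDT_TS:

* RMSE — root-mean-square prediction error over the target's models;
* LOSS — observed quality of the best model minus observed quality of the
  model the method ranked first (0 when the top-ranked model *is* best);
* 5-LOSS — the same gap minimized over the five top-ranked models.

Method performance over a benchmark is the median (and mean) of these
across targets, estimated by leave-one-target-out (LOTO): for each
target, train on all other targets and predict the held-out one.
Targets carrying ``filtered_flag`` are excluded from every training fold
but still evaluated as test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .structures import LABEL_COLUMN, TargetSet
from .featurize import DEFAULT_BLOCKS, FeatureExtractor
from .regressor import BoostedQARegressor

MEASURES = ("rmse", "loss", "loss5")


@dataclass
class TargetEvaluation:
    target_id: str
    rmse: float
    loss: float
    loss5: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if not 0 <= self.loss5 <= self.loss <= 1:
            raise ValueError("expected 0 <= loss5 <= loss <= 1")


@dataclass
class EvaluationReport:
    per_target: list  # list[TargetEvaluation]
    fold_training_targets: dict = field(default_factory=dict)  # test target -> trained-on ids

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.target_id, e.rmse, e.loss, e.loss5) for e in self.per_target],
            columns=["target_id"] + list(MEASURES),
        ).set_index("target_id")

    def median(self, measure: str) -> float:
        return float(self.frame()[measure].median())

    def mean(self, measure: str) -> float:
        return float(self.frame()[measure].mean())

    def summary(self) -> dict:
        return {
            **{f"median_{m}": self.median(m) for m in MEASURES},
            **{f"mean_{m}": self.mean(m) for m in MEASURES},
        }


def _ranked_ids(predicted: np.ndarray, model_ids) -> list:
    """Model ids sorted by descending prediction; ties by lexicographic id."""
    order = sorted(range(len(predicted)), key=lambda i: (-predicted[i], model_ids[i]))
    return [model_ids[i] for i in order]


def evaluate_target(
    predicted, observed, model_ids=None, target_id: str = ""
) -> TargetEvaluation:
    """RMSE / LOSS / 5-LOSS of one target's predictions."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1 or len(predicted) < 1:
        raise ValueError("predicted and observed must be equal-length 1-D arrays")
    if (observed < 0).any() or (observed > 1).any():
        raise ValueError("observed labels must lie in [0, 1]")
    if model_ids is None:
        model_ids = [f"m{i:04d}" for i in range(len(predicted))]
    model_ids = list(model_ids)
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    obs_by_id = dict(zip(model_ids, observed))
    best = float(observed.max())
    ranked = _ranked_ids(predicted, model_ids)
    loss = best - obs_by_id[ranked[0]]
    loss5 = min(best - obs_by_id[m] for m in ranked[: min(5, len(ranked))])
    return TargetEvaluation(target_id, rmse, float(loss), float(loss5))


def leave_one_target_out(
    dataset: list,
    blocks=DEFAULT_BLOCKS,
    estimator: BoostedQARegressor | None = None,
    table: pd.DataFrame | None = None,
    filtered: set | None = None,
) -> EvaluationReport:
    """LOTO cross-validation over a list of :class:`TargetSet`.

    ``table`` may supply a precomputed labeled feature table (as produced
    by :class:`FeatureExtractor` with the same ``blocks``) to avoid
    recomputing pairwise similarities per fold; otherwise it is built
    here.  ``filtered`` adds to the targets flagged in the dataset.
    """
    if len(dataset) < 3:
        raise ValueError("LOTO needs at least 3 targets")
    target_sets = [t for t in dataset if isinstance(t, TargetSet)]
    if table is None:
        if len(target_sets) != len(dataset):
            raise ValueError("a feature table is required when dataset holds bare ids")
        table = FeatureExtractor(blocks=blocks, include_label=True).transform(dataset)
    if LABEL_COLUMN not in table.columns:
        raise ValueError("LOTO requires observed labels in the feature table")
    filtered = set(filtered or ()) | {t.target_id for t in target_sets if t.filtered_flag}
    all_targets = [t.target_id if isinstance(t, TargetSet) else str(t) for t in dataset]
    proto = estimator if estimator is not None else BoostedQARegressor()

    evaluations = []
    fold_logs = {}
    for held_out in all_targets:
        train_ids = [t for t in all_targets if t != held_out and t not in filtered]
        if not train_ids:
            raise ValueError(f"empty training fold for target {held_out!r}")
        train_tab = table[table.index.get_level_values(0).isin(train_ids)]
        test_tab = table[table.index.get_level_values(0) == held_out]
        model = clone_estimator(proto)
        model.fit(train_tab)
        pred = model.predict(test_tab)
        obs = test_tab[LABEL_COLUMN].to_numpy()
        ids = list(test_tab.index.get_level_values(1))
        evaluations.append(evaluate_target(pred, obs, ids, target_id=held_out))
        fold_logs[held_out] = train_ids
    return EvaluationReport(evaluations, fold_logs)


def clone_estimator(est: BoostedQARegressor) -> BoostedQARegressor:
    from sklearn.base import clone

    return clone(est)


def compare_methods(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    measure: str = "rmse",
    alternative: str = "less",
) -> float:
    """One-sided Wilcoxon signed-rank p-value on paired per-target measures.

    ``alternative="less"`` tests whether method a's per-target values are
    systematically smaller (better) than method b's.  Zero differences are
    discarded; if every pair ties the test is uninformative and 0.5 is
    returned by convention.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    fa, fb = report_a.frame(), report_b.frame()
    if set(fa.index) != set(fb.index):
        raise ValueError("reports cover different target sets")
    a = fa[measure].to_numpy()
    b = fb.loc[fa.index, measure].to_numpy()
    diff = a - b
    if np.all(diff == 0):
        return 0.5
    res = wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue)


def write_report(report: EvaluationReport, path) -> None:
    report.frame().reset_index().to_csv(path, sep="\t", index=False)


def write_casp_qa(
    target_id: str,
    predictions: pd.DataFrame,
    path,
    author: str = "protqa",
    qmode: int = 1,
) -> None:
    """Emit global scores in the CASP QA exchange format (QMODE 1)."""
    lines = [
        "PFRMAT QA",
        f"TARGET {target_id}",
        f"AUTHOR {author}",
        "METHOD consensus features + gradient boosted trees",
        f"MODEL {qmode}",
    ]
    for (_, model_id), row in predictions.iterrows():
        lines.append(f"{model_id} {row['predicted_gdt_ts']:.4f}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
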