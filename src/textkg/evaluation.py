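"""Benchmark harness: deterministic k-fold CV, weighted F1, result tables.

Every model in a benchmark is trained and scored on identical fold
assignments per task, so score differences reflect the models, not the
splits.  Models whose triple representation directly encodes the relation
type (translational input) are excluded from relation-type tasks, where
that encoding would hand them the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .data import TextTriplePair, make_cv_splits
from .exceptions import ConfigError, DataError

TASK_KINDS = ("relation_type", "context_annotation", "correctness")


@dataclass
class TaskSpec:
    """One fine-tuning classification task."""

    name: str
    classes: list[str]
    kind: str

    def __post_init__(self):
        if self.kind not in TASK_KINDS:
            raise ConfigError(f"kind must be one of {TASK_KINDS}")
        if not 2 <= len(self.classes) <= 10:
            raise ConfigError("class count must be in [2, 10]")

    @property
    def excluded_for_transe(self) -> bool:
        """Relation-type tasks are unfair to relation-encoding inputs."""
        return self.kind == "relation_type"


class ModelRunner(Protocol):
    """What the harness needs from a benchmarked model."""

    name: str
    uses_transe_input: bool

    def fit(self, pairs: list[TextTriplePair], labels: list[str],
            classes: list[str], seed: int): ...


@dataclass
class BenchmarkResult:
    model: str
    task: str
    fold_scores: list[float] = field(default_factory=list)
    excluded: bool = False

    @property
    def mean_f1(self) -> float | None:
        if self.excluded or not self.fold_scores:
            return None
        return float(np.mean(self.fold_scores))


def weighted_f1(true_labels, predicted_labels) -> float:
    """Average of per-class F1 scores weighted by true-instance counts.

    Classes absent from the true labels carry zero weight; a class with a
    zero precision+recall denominator contributes an F1 of 0.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if not true_labels or len(true_labels) != len(predicted_labels):
        raise DataError("need equal-length, non-empty label sequences")
    return float(f1_score(true_labels, predicted_labels, average="weighted",
                          zero_division=0))


def relative_gain(best_variant: float, best_baseline: float) -> float | None:
    """Percentage gain of the best variant over the best baseline.

    ``100 * (a - b) / b``; undefined (None) when the baseline score is 0.
    """
    if best_baseline == 0:
        return None
    return 100.0 * (best_variant - best_baseline) / best_baseline


def run_benchmark(
    models: list[ModelRunner],
    tasks: list[TaskSpec],
    datasets: dict[str, tuple[list[TextTriplePair], list[str]]],
    k: int = 5,
    seed: int = 0,
) -> list[BenchmarkResult]:
    """Train/score every (model, task) cell under shared deterministic CV.

    ``datasets[task.name]`` is (pairs, labels).  For each task a single
    stratified k-fold split is computed once and reused across all models;
    each fold's classifier trains on the other k-1 folds and is scored by
    weighted F1 on the held-out fold.
    """
    results: list[BenchmarkResult] = []
    for task in tasks:
        if task.name not in datasets:
            raise ConfigError(f"no dataset provided for task {task.name!r}")
        pairs, labels = datasets[task.name]
        if len(pairs) != len(labels):
            raise DataError(f"task {task.name}: pairs and labels must align")
        split = make_cv_splits(pairs, k=k, seed=seed, labels=labels)
        label_of = dict(zip((p.pair_id for p in pairs), labels))
        folds = []
        for f in range(k):
            test_ids = set(split.test_ids(f))
            train = [p for p in pairs if p.pair_id not in test_ids]
            test = [p for p in pairs if p.pair_id in test_ids]
            folds.append((train, test))
        for model in models:
            if task.excluded_for_transe and model.uses_transe_input:
                results.append(BenchmarkResult(model.name, task.name,
                                               excluded=True))
                continue
            scores = []
            for f, (train, test) in enumerate(folds):
                clf = model.fit(train, [label_of[p.pair_id] for p in train],
                                task.classes, seed=seed + f)
                pred = clf.predict(test)
                scores.append(weighted_f1(
                    [label_of[p.pair_id] for p in test], pred))
            results.append(BenchmarkResult(model.name, task.name,
                                           fold_scores=scores))
    return results


def results_table(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Long-format table: one row per (model, task, fold)."""
    rows = []
    for r in results:
        if r.excluded:
            rows.append({"model": r.model, "task": r.task, "fold": None,
                         "weighted_f1": None, "excluded": True})
        else:
            for f, s in enumerate(r.fold_scores):
                rows.append({"model": r.model, "task": r.task, "fold": f,
                             "weighted_f1": s, "excluded": False})
    return pd.DataFrame(rows)


def summary_table(results: list[BenchmarkResult],
                  baseline_models: list[str] | None = None) -> pd.DataFrame:
    """Mean weighted F1 per model x task, plus absolute and relative gains.

    The gain rows compare the best non-baseline variant against the best
    baseline on each task (relative gain as a percentage of the baseline).
    """
    means: dict[str, dict[str, float]] = {}
    tasks: list[str] = []
    for r in results:
        if r.task not in tasks:
            tasks.append(r.task)
        means.setdefault(r.model, {})[r.task] = (
            float("nan") if r.mean_f1 is None else r.mean_f1)
    df = pd.DataFrame(means).T.reindex(columns=tasks)
    if baseline_models:
        variants = [m for m in df.index if m not in baseline_models]
        if variants:
            abs_gain, rel_gain = {}, {}
            for t in tasks:
                best_b = df.loc[[m for m in baseline_models if m in df.index], t].max()
                best_v = df.loc[variants, t].max()
                abs_gain[t] = best_v - best_b
                g = relative_gain(best_v, best_b) if best_b == best_b else None
                rel_gain[t] = float("nan") if g is None else g
            df.loc["absolute_gain"] = pd.Series(abs_gain)
            df.loc["relative_gain_pct"] = pd.Series(rel_gain)
    return df


def write_results(results: list[BenchmarkResult], directory: str | Path,
                  baseline_models: list[str] | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results_table(results).to_csv(directory / "results.tsv", sep="\t", index=False)
    summary_table(results, baseline_models).to_csv(
        directory / "summary.tsv", sep="\t")


def benchmark_task_specs() -> list[TaskSpec]:
    """The eight-task benchmark layout: class counts 2,2,10,10,5,3,2,8.

    Two relation-type tasks, four context-annotation tasks, and two
    correctness tasks; synthetic datasets with matching class counts plug
    in through the same interface as curated ones.
    """
    def cs(n):
        return [f"c{i}" for i in range(n)]
    return [
        TaskSpec("polarity", cs(2), "relation_type"),
        TaskSpec("interaction_type", cs(2), "relation_type"),
        TaskSpec("cell_line", cs(10), "context_annotation"),
        TaskSpec("disease", cs(10), "context_annotation"),
        TaskSpec("location", cs(5), "context_annotation"),
        TaskSpec("species", cs(3), "context_annotation"),
        TaskSpec("correct_binary", cs(2), "correctness"),
        TaskSpec("correct_multiclass", cs(8), "correctness"),
    ]
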