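"""Per-repetition evaluation of the model family on the fixed test strata.

For each recognition task (arousal, valence) and each training group (High,
Low, Total, plus optional transfer-initialized models), R independent
training repetitions are run with repetition-specific seeds, and every
trained model is scored on the identical baseline / unambiguous / ambiguous
test sets. The result is a long *repetition-level evaluation table* — one
row per (task, condition, group, repetition, test item) with the continuous
score, the thresholded class, and the correctness bit — which is the unit of
all downstream statistics, plus mean (SD) metric summaries across
repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_score, recall_score

from .classifier import TrainedModel, macro_f1, predict, pretrain_transfer
from .config import TrainingConfig
from .stats import InferenceError, roc_auc

CONDITIONS = ("baseline", "unambiguous", "ambiguous")


@dataclass
class TaskData:
    """Prepared arrays for one recognition task.

    ``train`` maps group tag -> (X_train, y_train, reg_train, X_val, y_val);
    ``tests`` maps condition -> (item ids, X, y).
    """

    dimension: str
    train: dict[str, tuple] = field(default_factory=dict)
    tests: dict[str, tuple] = field(default_factory=dict)


def compute_metrics(labels, scores, preds) -> dict[str, float]:
    """Standard binary metrics for one (model, condition, repetition) cell.

    Macro precision/recall/F1 and accuracy from the thresholded predictions;
    ROC-AUC (Mann–Whitney, half credit for ties) and PR-AUC (step-wise
    average precision, positive class = high) from the continuous scores.
    AUCs are undefined (NaN) when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    scores = np.asarray(scores, dtype=float)
    out = {
        "macro_precision": float(precision_score(labels, preds, average="macro", zero_division=0)),
        "macro_recall": float(recall_score(labels, preds, average="macro", zero_division=0)),
        "macro_f1": macro_f1(labels, preds),
        "accuracy": float((labels == preds).mean()),
    }
    if len(np.unique(labels)) < 2:
        out["roc_auc"] = float("nan")
        out["pr_auc"] = float("nan")
    else:
        out["roc_auc"] = roc_auc(scores, labels)
        out["pr_auc"] = float(average_precision_score(labels, scores))
    return out


def evaluate_model(model: TrainedModel, task_data: TaskData, tag: str, repetition: int,
                   task: str) -> pd.DataFrame:
    """Score one trained model on every test condition of a task."""
    frames = []
    for condition, (items, X, y) in task_data.tests.items():
        res = predict(model, X, labels=y)
        res.insert(0, "item", list(items))
        res.insert(0, "repetition", repetition)
        res.insert(0, "group", tag)
        res.insert(0, "condition", condition)
        res.insert(0, "task", task)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def run_repetitions(
    tasks: dict[str, TaskData],
    config: TrainingConfig,
    repetitions: int = 5,
    seed: int = 0,
    transfer: bool = False,
) -> pd.DataFrame:
    """Train every group's model R times and assemble the evaluation table.

    Repetition r uses seed ``seed + r`` (r = 1..R), so repetitions are
    independent given the master seed while the whole table is reproducible.
    Every model within a repetition shares its architecture and config; all
    models are evaluated on the identical per-condition item sets.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    chunks = []
    for task, data in tasks.items():
        for rep in range(1, repetitions + 1):
            models = pretrain_transfer(data.train, config, seed=seed + rep, transfer=transfer)
            for tag, model in models.items():
                chunks.append(evaluate_model(model, data, tag, rep, task))
    table = pd.concat(chunks, ignore_index=True)
    _check_item_coverage(table)
    return table


def _check_item_coverage(table: pd.DataFrame) -> None:
    """Every (group, repetition) must cover exactly the same items per cell."""
    for (task, condition), cell in table.groupby(["task", "condition"]):
        ref = None
        for _, sub in cell.groupby(["group", "repetition"]):
            items = frozenset(sub["item"])
            if ref is None:
                ref = items
            elif items != ref:
                raise InferenceError(
                    f"item sets differ across (group, repetition) in ({task}, {condition})"
                )


def summarize_evaluation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of every metric across repetitions, per task/condition/group."""
    rows = []
    for (task, condition, group, rep), cell in table.groupby(
        ["task", "condition", "group", "repetition"]
    ):
        m = compute_metrics(cell["label"], cell["score"], cell["pred"])
        m.update(task=task, condition=condition, group=group, repetition=rep)
        rows.append(m)
    per_rep = pd.DataFrame(rows)
    metrics = ["macro_precision", "macro_recall", "macro_f1", "accuracy", "roc_auc", "pr_auc"]
    agg = per_rep.groupby(["task", "condition", "group"])[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
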