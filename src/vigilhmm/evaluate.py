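"""Evaluation protocol: confusion matrix, accuracy, configuration sweep.

Accuracy is (TP + TN) / (TP + FP + FN + TN) with **hypovigilance as the
positive class** (the event the detector exists to catch), even though the
class label itself is "-". Model configurations DM1-DM4 vary the number of
HMM states (2 or 3) and the training ratio (50% or 67%); the "All" baseline
trains a single detector on sequences pooled across operators and is
evaluated per operator. Per-configuration improvement over "All" is reported
as relative percent, and a one-sided one-sample t-test checks whether mean
accuracy exceeds a floor (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vigilhmm import detector as det
from vigilhmm.detector import EEGSequence, HYPO, NORMAL
from vigilhmm.hmm_core import InputError
from vigilhmm.preprocess import split_train_test


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive = hypovigilance ("-")."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(preds: Sequence[str], truths: Sequence[str]) -> ConfusionMatrix:
    """Count prediction outcomes against truth for aligned label lists."""
    if len(preds) != len(truths) or len(preds) == 0:
        raise InputError("preds and truths must be non-empty and aligned")
    cm = ConfusionMatrix()
    for p, t in zip(preds, truths):
        if p not in (NORMAL, HYPO) or t not in (NORMAL, HYPO):
            raise InputError(f"unknown label in ({p!r}, {t!r})")
        if t == HYPO:
            if p == HYPO:
                cm.tp += 1
            else:
                cm.fn += 1
        else:
            if p == HYPO:
                cm.fp += 1
            else:
                cm.tn += 1
    return cm


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise InputError("accuracy undefined for an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


@dataclass
class ExperimentConfig:
    """One detector configuration of the evaluation sweep."""

    name: str = "custom"
    n_states: int = 2
    training_ratio: float = 0.67
    pooled: bool = False
    seed: int = 0
    refine: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.training_ratio < 1:
            raise InputError("training_ratio must be in (0, 1)")
        if self.n_states < 2:
            raise InputError("n_states must be >= 2")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **kw) -> "ExperimentConfig":
        presets = {
            "DM1": dict(n_states=2, training_ratio=0.50),
            "DM2": dict(n_states=2, training_ratio=0.67),
            "DM3": dict(n_states=3, training_ratio=0.50),
            "DM4": dict(n_states=3, training_ratio=0.67),
            "All": dict(n_states=2, training_ratio=0.67, pooled=True),
        }
        if name not in presets:
            raise InputError(f"unknown preset {name!r}")
        return cls(name=name, seed=seed, **{**presets[name], **kw})


def _split_by_operator(
    dataset: Iterable[EEGSequence], ratio: float, seed: int
) -> tuple[dict[str, list[EEGSequence]], dict[str, list[EEGSequence]]]:
    by_op: dict[str, list[EEGSequence]] = {}
    for s in dataset:
        by_op.setdefault(s.operator_id, []).append(s)
    train: dict[str, list[EEGSequence]] = {}
    test: dict[str, list[EEGSequence]] = {}
    seeds = np.random.SeedSequence(seed).generate_state(len(by_op))
    for (op, group), s in zip(sorted(by_op.items()), seeds):
        try:
            train[op], test[op] = split_train_test(group, ratio, int(s) % (2**31))
        except InputError as exc:
            raise InputError(f"operator {op}: {exc}") from exc
    return train, test


def run_configuration(
    dataset: list[EEGSequence], cfg: ExperimentConfig
) -> tuple[dict[str, float], pd.DataFrame]:
    """Train/evaluate one configuration; returns per-operator accuracies.

    Per-operator configs fit one detector per operator on that operator's
    stratified training split and score the matching test split. The pooled
    "All" configuration fits a single detector on the union of all training
    splits (the same splits, so test sets are identical) and is still scored
    per operator. Fully reproducible from ``cfg.seed``.
    """
    train, test = _split_by_operator(dataset, cfg.training_ratio, cfg.seed)
    frames = []
    accs: dict[str, float] = {}
    if cfg.pooled:
        pooled = [
            replace(s, operator_id="__all__") for group in train.values() for s in group
        ]
        model = det.train_detector(
            pooled, cfg.n_states, seed=cfg.seed, refine=cfg.refine,
            training_ratio=cfg.training_ratio,
        )
        models = {op: model for op in train}
    else:
        models = {
            op: det.train_detector(
                group, cfg.n_states, seed=cfg.seed, refine=cfg.refine,
                training_ratio=cfg.training_ratio,
            )
            for op, group in train.items()
        }
    for op in sorted(test):
        rep = det.classification_report(models[op], test[op])
        rep.insert(0, "configuration", cfg.name)
        rep["operator_id"] = op
        frames.append(rep)
        cm = confusion(rep["predicted_label"].tolist(), rep["true_label"].tolist())
        accs[op] = accuracy(cm)
    return accs, pd.concat(frames, ignore_index=True)


def run_sweep(
    dataset: list[EEGSequence],
    configs: Sequence[ExperimentConfig],
    seed: int | None = None,
) -> pd.DataFrame:
    """Accuracy table (operator x configuration) for a list of configurations."""
    rows = {}
    for cfg in configs:
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        accs, _ = run_configuration(dataset, cfg)
        rows[cfg.name] = accs
    return pd.DataFrame(rows).sort_index()


def improvement_over_all(
    per_op: Mapping[str, float],
    all_model: Mapping[str, float],
    mode: str = "relative",
) -> float:
    """Average percent improvement of a per-operator config over "All".

    ``relative`` (default): mean over operators of (acc - acc_all)/acc_all
    x 100. ``absolute``: mean of (acc - acc_all) x 100 percentage points.
    """
    if set(per_op) != set(all_model):
        raise InputError("operator sets differ between the two accuracy tables")
    if not per_op:
        raise InputError("empty accuracy tables")
    deltas = []
    for op in per_op:
        a, b = per_op[op], all_model[op]
        if mode == "relative":
            if b == 0:
                raise InputError(f"operator {op}: baseline accuracy 0, relative % undefined")
            deltas.append((a - b) / b * 100.0)
        elif mode == "absolute":
            deltas.append((a - b) * 100.0)
        else:
            raise InputError(f"unknown improvement mode {mode!r}")
    return float(np.mean(deltas))


def accuracy_floor_test(
    accuracies: Sequence[float], floor: float = 0.7, alpha: float = 0.05
) -> dict:
    """One-sided one-sample t-test of mean accuracy > ``floor``.

    With zero variance the t statistic is undefined; the mean is compared
    with the floor directly and reported without a statistic.
    """
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size < 2:
        raise InputError("need at least two accuracies for the t-test")
    mean = float(acc.mean())
    if acc.std(ddof=1) < 1e-15:
        return {
            "t": None,
            "p_value": None,
            "mean": mean,
            "floor": floor,
            "reject": mean > floor,
            "note": "zero variance; direct comparison of mean with floor",
        }
    res = stats.ttest_1samp(acc, popmean=floor, alternative="greater")
    return {
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean": mean,
        "floor": floor,
        "reject": bool(res.pvalue < alpha),
    }
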