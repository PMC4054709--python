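"""Dual-HMM hypovigilance detection and state-based vigilance trends.

Two complementary views of the same data:

* **Model-based**: for each operator a pair of Gaussian HMMs is trained, one
  on sequences labelled normal vigilance ("+", recorded during difficult
  tasks) and one on hypovigilance sequences ("-", easy tasks). A new
  sequence is assigned the label whose HMM gives it the larger
  log-likelihood.
* **State-based**: a single HMM pooled over all sequences of an operator,
  whose posterior state-occupancy profile is compared across task-difficulty
  levels; a positive correlation between difficulty and occupancy of the
  vigilance state supports the difficulty-as-label hypothesis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from vigilhmm import hmm_core
from vigilhmm.hmm_core import GaussianHMM, InputError

logger = logging.getLogger(__name__)

NORMAL = "+"
HYPO = "-"

#: simulated-cockpit task difficulty grouping
DIFFICULT_TASKS = ("landing", "emergency landing", "air-to-air combat")
EASY_TASKS = ("taking off", "missile launch", "navigation")
TASK_DIFFICULTY: dict[str, str] = {
    **{t: "difficult" for t in DIFFICULT_TASKS},
    **{t: "easy" for t in EASY_TASKS},
}

_MODEL_FORMAT = "vigilhmm-detector-1"


@dataclass
class EEGSequence:
    """One observation sequence E_mn with its provenance and label."""

    features: np.ndarray
    operator_id: str
    task_id: str = ""
    difficulty: str | int = "unknown"
    vigilance: str = "unknown"
    state_path: np.ndarray | None = None  # generating path, synthetic data only

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.features.shape[0] < 1:
            raise InputError("sequence must have at least one frame")
        if self.vigilance not in (NORMAL, HYPO, "unknown"):
            raise InputError(f"invalid vigilance label {self.vigilance!r}")

    @property
    def length(self) -> int:
        return self.features.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.features.shape[1]


@dataclass
class DetectionModel:
    """Per-operator pair (n-HMM for "+", h-HMM for "-")."""

    operator_id: str
    n_hmm: GaussianHMM
    h_hmm: GaussianHMM
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_hmm.obs_dim != self.h_hmm.obs_dim:
            raise InputError("the two HMMs must share obs_dim")

    def to_dict(self) -> dict:
        return {
            "format_version": _MODEL_FORMAT,
            "operator_id": self.operator_id,
            "n_hmm": self.n_hmm.to_dict(),
            "h_hmm": self.h_hmm.to_dict(),
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionModel":
        if d.get("format_version") != _MODEL_FORMAT:
            raise InputError(f"unrecognised model format {d.get('format_version')!r}")
        return cls(
            operator_id=d["operator_id"],
            n_hmm=GaussianHMM.from_dict(d["n_hmm"]),
            h_hmm=GaussianHMM.from_dict(d["h_hmm"]),
            training_meta=d.get("training_meta", {}),
        )

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: Path) -> "DetectionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def auto_label(
    seqs: Iterable[EEGSequence],
    difficult_group: Iterable[str | int] = ("difficult",),
    easy_group: Iterable[str | int] = ("easy",),
) -> list[EEGSequence]:
    """Label sequences by task difficulty: difficult -> "+", easy -> "-".

    Encodes the difficulty-as-label hypothesis: demanding tasks force normal
    vigilance, undemanding ones admit hypovigilance. Returns new sequence
    objects; counts per label are logged.
    """
    difficult = set(difficult_group)
    easy = set(easy_group)
    out = []
    counts = {NORMAL: 0, HYPO: 0}
    for s in seqs:
        if s.difficulty in difficult:
            label = NORMAL
        elif s.difficulty in easy:
            label = HYPO
        else:
            raise InputError(
                f"sequence {s.operator_id}/{s.task_id}: unknown difficulty "
                f"{s.difficulty!r}"
            )
        counts[label] += 1
        out.append(
            EEGSequence(
                features=s.features,
                operator_id=s.operator_id,
                task_id=s.task_id,
                difficulty=s.difficulty,
                vigilance=label,
                state_path=s.state_path,
            )
        )
    logger.info("auto_label: %d '+' (normal), %d '-' (hypovigilance)", counts[NORMAL], counts[HYPO])
    return out


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def train_detector(
    seqs: list[EEGSequence],
    G: int = 2,
    *,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    cov_floor: float = 1e-6,
    refine: bool = True,
    training_ratio: float | None = None,
) -> DetectionModel:
    """Train a per-operator detection model from labelled sequences.

    The "+" sequences train the n-HMM, the "-" sequences the h-HMM, each by
    k-means initialisation followed (by default) by Baum-Welch refinement,
    with independent seeds derived from ``seed``. All sequences must belong
    to one operator: the method is per-operator by construction.
    """
    if not seqs:
        raise InputError("no training sequences")
    operators = {s.operator_id for s in seqs}
    if len(operators) != 1:
        raise InputError(
            f"train_detector requires sequences from a single operator, got {sorted(operators)}"
        )
    dims = {s.obs_dim for s in seqs}
    if len(dims) != 1:
        raise InputError("sequences have inconsistent obs_dim")
    plus = [s.features for s in seqs if s.vigilance == NORMAL]
    minus = [s.features for s in seqs if s.vigilance == HYPO]
    if not plus or not minus:
        raise InputError("both vigilance labels must be present for training")
    seed_plus, seed_minus = _derived_seeds(seed, 2)
    models = {}
    traces = {}
    for key, data, s in (("n", plus, seed_plus), ("h", minus, seed_minus)):
        if refine:
            m, tr = hmm_core.fit_em(
                data, G, max_iter=max_iter, tol=tol, seed=s, cov_floor=cov_floor
            )
        else:
            m = hmm_core.kmeans_init(data, G, s, cov_floor=cov_floor)
            tr = hmm_core.EMTrace(log_likelihoods=[], n_iter=0, converged=True)
        models[key] = m
        traces[key] = tr
    meta = {
        "G": G,
        "seed": seed,
        "refine": refine,
        "n_train_plus": len(plus),
        "n_train_minus": len(minus),
        "em_iters": {k: traces[k].n_iter for k in traces},
        "config": {"max_iter": max_iter, "tol": tol, "cov_floor": cov_floor},
    }
    if training_ratio is not None:
        meta["training_ratio"] = training_ratio
    return DetectionModel(
        operator_id=next(iter(operators)),
        n_hmm=models["n"],
        h_hmm=models["h"],
        training_meta=meta,
    )


def classify(model: DetectionModel, seq: EEGSequence) -> tuple[str, float, float]:
    """Maximum-likelihood vigilance label for one sequence.

    Returns ``(label, loglik_plus, loglik_minus)``; the label is "+" when the
    n-HMM wins and on exact ties (falsely declaring hypovigilance would
    trigger an unnecessary intervention; ties are logged).
    """
    if seq.obs_dim != model.n_hmm.obs_dim:
        raise InputError(
            f"sequence obs_dim {seq.obs_dim} != model obs_dim {model.n_hmm.obs_dim}"
        )
    ll_plus = hmm_core.log_likelihood(model.n_hmm, seq.features)
    ll_minus = hmm_core.log_likelihood(model.h_hmm, seq.features)
    if ll_plus == ll_minus:
        warnings.warn("likelihood tie; resolving to normal vigilance ('+')")
        return NORMAL, ll_plus, ll_minus
    label = NORMAL if ll_plus > ll_minus else HYPO
    return label, ll_plus, ll_minus


def classification_report(
    model: DetectionModel, seqs: Iterable[EEGSequence]
) -> pd.DataFrame:
    """One row per sequence: ids, truth, prediction, both log-likelihoods."""
    rows = []
    for s in seqs:
        label, lp, lm = classify(model, s)
        rows.append(
            {
                "operator_id": s.operator_id,
                "task_id": s.task_id,
                "true_label": s.vigilance,
                "predicted_label": label,
                "loglik_plus": lp,
                "loglik_minus": lm,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# state-based analysis


def state_occupancy(
    hmm: GaussianHMM,
    seqs_by_level: Mapping[str | int, list[EEGSequence]],
    *,
    mode: str = "posterior",
) -> dict[str | int, np.ndarray]:
    """Average state-occupancy vector per difficulty level.

    ``hmm`` is a single model pooled over all sequences regardless of class.
    ``mode="posterior"`` averages the forward-backward posteriors (gamma)
    over every frame of the level's sequences; ``mode="viterbi"`` uses
    decoded-path state frequencies instead. Each returned vector sums to 1.
    Levels without sequences are omitted with a warning.
    """
    out: dict[str | int, np.ndarray] = {}
    for level, group in seqs_by_level.items():
        if not group:
            warnings.warn(f"difficulty level {level!r} has no sequences; omitted")
            continue
        acc = np.zeros(hmm.n_states)
        n = 0
        for s in group:
            if mode == "posterior":
                gamma, _ = hmm_core.posteriors(hmm, s.features)
                acc += gamma.sum(axis=0)
            elif mode == "viterbi":
                path, _ = hmm_core.viterbi(hmm, s.features)
                acc += np.bincount(path.states, minlength=hmm.n_states)
            else:
                raise InputError(f"unknown occupancy mode {mode!r}")
            n += s.length
        out[level] = acc / n
    return out


def identify_vigilance_state(
    occupancy_by_level: Mapping[str | int, np.ndarray]
) -> int:
    """State index playing the role of "state 1" (normal vigilance).

    Chosen as the state with the highest occupancy at the most difficult
    level (levels compared by their sort order).
    """
    if not occupancy_by_level:
        raise InputError("empty occupancy mapping")
    hardest = sorted(occupancy_by_level)[-1]
    return int(np.argmax(occupancy_by_level[hardest]))


def difficulty_correlation(
    occupancy_by_level: Mapping[str | int, np.ndarray],
    vigilance_state: int,
    *,
    method: str = "pearson",
    alpha: float = 0.05,
) -> dict:
    """Correlation between task-difficulty rank and vigilance-state occupancy.

    Returns ``{"r", "p_value", "n", "is_significant"}``; a constant occupancy
    series yields ``r=None`` with ``is_significant=False`` rather than NaN.
    """
    levels = sorted(occupancy_by_level)
    if len(levels) < 3:
        raise InputError("need at least 3 difficulty levels for a correlation")
    ranks = np.arange(1, len(levels) + 1, dtype=float)
    occ = np.array([occupancy_by_level[lv][vigilance_state] for lv in levels])
    if np.ptp(occ) < 1e-15:
        return {"r": None, "p_value": None, "n": len(levels), "is_significant": False}
    if method == "pearson":
        r, p = stats.pearsonr(ranks, occ)
    elif method == "spearman":
        r, p = stats.spearmanr(ranks, occ)
    else:
        raise InputError(f"unknown correlation method {method!r}")
    return {
        "r": float(r),
        "p_value": float(p),
        "n": len(levels),
        "is_significant": bool(p < alpha),
    }


def group_by_difficulty(seqs: Iterable[EEGSequence]) -> dict[str | int, list[EEGSequence]]:
    out: dict[str | int, list[EEGSequence]] = {}
    for s in seqs:
        out.setdefault(s.difficulty, []).append(s)
    return out
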