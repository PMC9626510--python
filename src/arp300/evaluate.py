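"""Nine-way target decoding and every reported metric.

Per-epoch scores from any fitted scorer are grouped per trial (one score per
stimulus), decoded by argmax, and summarised as per-run accuracy, binary
AUC, and Wolpaw information transfer rate; paired t-tests and one-way ANOVA
cover the significance analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet, average_repetitions

__all__ = [
    "ITRParams", "EvalReport", "decode_trial", "accuracy_table",
    "summarize_accuracy_matrix", "wolpaw_bits", "itr_bits_per_min",
    "auc_binary", "crossval", "paired_ttest", "oneway_anova",
    "averaging_comparison",
]


@dataclass(frozen=True)
class ITRParams:
    """Wolpaw ITR setting: N targets, selection time T seconds.

    Default T = 2.0 s: nine flashes at 175 ms SOA plus the 425 ms needed to
    complete the final 600 ms epoch; preparation/lock time excluded.
    """

    n_targets: int = 9
    selection_time_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if self.selection_time_s <= 0:
            raise ValueError("selection_time_s must be positive")


def decode_trial(scores: np.ndarray, n_stimuli: int | None = None) -> int:
    """Predicted stimulus = argmax of the per-stimulus scores (ties -> lowest
    index).  ``scores[i]`` must be the score of stimulus i."""
    scores = np.asarray(scores, dtype=float).ravel()
    if n_stimuli is not None and len(scores) != n_stimuli:
        raise ValueError(f"expected {n_stimuli} scores, got {len(scores)}")
    if len(scores) == 0:
        raise ValueError("empty score vector")
    return int(np.argmax(scores))


def wolpaw_bits(P: float, N: int) -> float:
    """Wolpaw bits per selection: log2 N + P log2 P + (1-P) log2((1-P)/(N-1)).

    Continuous limits at P = 0 and P = 1.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"accuracy P must be in [0, 1], got {P}")
    if N < 2:
        raise ValueError("N must be >= 2")
    bits = math.log2(N)
    if P > 0.0:
        bits += P * math.log2(P)
    if P < 1.0:
        bits += (1.0 - P) * math.log2((1.0 - P) / (N - 1))
    return bits


def itr_bits_per_min(P: float, N: int, T_s: float) -> float:
    """Wolpaw ITR in bits/min for one selection every ``T_s`` seconds."""
    if T_s <= 0:
        raise ValueError("selection time must be positive")
    return wolpaw_bits(P, N) * 60.0 / T_s


def auc_binary(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random target outscores a random non-target
    (ties count 1/2), via the rank-sum identity."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test; df = n - 1."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA: returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F undefined")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def summarize_accuracy_matrix(matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Row (participant) means and their grand mean, in percent.

    ``matrix`` is participants x runs, values already in percent.
    """
    participant_means = matrix.mean(axis=1)
    return participant_means, float(participant_means.mean())


def accuracy_table(
    decoded: np.ndarray,
    truth: np.ndarray,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Participant x run accuracy matrix (percent) from per-trial decisions.

    ``meta`` must carry one row per decision with columns ``participant``
    and ``run`` aligned with ``decoded``/``truth``.
    """
    decoded = np.asarray(decoded).ravel()
    truth = np.asarray(truth).ravel()
    if not (len(decoded) == len(truth) == len(meta)):
        raise ValueError("decoded, truth and meta must be aligned")
    df = pd.DataFrame({
        "participant": np.asarray(meta["participant"]),
        "run": np.asarray(meta["run"]),
        "correct": (decoded == truth).astype(float),
    })
    matrix = df.pivot_table(index="participant", columns="run",
                            values="correct", aggfunc="mean") * 100.0
    return matrix


@dataclass
class EvalReport:
    """Aggregated decoding results of one evaluation."""

    per_run_accuracy: dict[int, float]  # run -> percent
    mean_accuracy: float  # percent
    per_target_accuracy: dict[int, float]  # stimulus -> percent
    auc: float
    itr_bits_per_min: float
    itr_params: ITRParams
    n_trials: int
    n_correct: int
    folds: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_run_accuracy": {str(k): v for k, v in self.per_run_accuracy.items()},
            "mean_accuracy": self.mean_accuracy,
            "per_target_accuracy": {str(k): v for k, v in self.per_target_accuracy.items()},
            "auc": self.auc,
            "itr_bits_per_min": self.itr_bits_per_min,
            "itr": {"n_targets": self.itr_params.n_targets,
                    "selection_time_s": self.itr_params.selection_time_s},
            "n_trials": self.n_trials,
            "n_correct": self.n_correct,
            "folds": self.folds,
            "seed": self.seed,
            "extra": self.extra,
        }


def _trial_groups(epochs: EpochSet) -> dict[tuple[int, int, int], np.ndarray]:
    """Epoch indices per (run, block, trial), each a full stimulus sweep."""
    groups: dict[tuple[int, int, int], list[int]] = {}
    m = epochs.meta
    for i in range(epochs.n_epochs):
        key = (int(m["run"][i]), int(m["block"][i]), int(m["trial"][i]))
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in sorted(groups.items())}


def _decode_groups(
    epochs: EpochSet,
    scores: np.ndarray,
    target_of_block: dict[int, int],
    keys: list[tuple[int, int, int]] | None = None,
    groups: dict[tuple[int, int, int], np.ndarray] | None = None,
):
    """Argmax-decode each trial group; returns records of decisions."""
    groups = groups if groups is not None else _trial_groups(epochs)
    keys = keys if keys is not None else list(groups)
    records = []
    for key in keys:
        idx = groups[key]
        stim = epochs.meta["stimulus"][idx]
        order = np.argsort(stim)
        per_stim = scores[idx[order]]
        pred = decode_trial(per_stim)
        tgt = target_of_block[key[1]]
        records.append({
            "run": key[0], "block": key[1], "trial": key[2],
            "predicted": pred, "target": tgt, "correct": pred == tgt,
        })
    return records


def _report_from_records(records, all_scores, all_labels, itr_params, folds, seed) -> EvalReport:
    df = pd.DataFrame(records)
    per_run = (df.groupby("run")["correct"].mean() * 100.0).to_dict()
    per_target = (df.groupby("target")["correct"].mean() * 100.0).to_dict()
    n_correct = int(df["correct"].sum())
    mean_acc = 100.0 * n_correct / len(df)
    auc = auc_binary(all_scores, all_labels)
    itr = itr_bits_per_min(mean_acc / 100.0, itr_params.n_targets,
                           itr_params.selection_time_s)
    return EvalReport(
        per_run_accuracy={int(k): float(v) for k, v in per_run.items()},
        mean_accuracy=float(mean_acc),
        per_target_accuracy={int(k): float(v) for k, v in per_target.items()},
        auc=float(auc),
        itr_bits_per_min=float(itr),
        itr_params=itr_params,
        n_trials=len(df),
        n_correct=n_correct,
        folds=folds,
        seed=seed,
        extra={"trials": records},
    )


def crossval(
    epochs: EpochSet,
    model_factory: Callable[[], object],
    target_of_block: dict[int, int],
    folds: int = 5,
    seed: int | None = 0,
    itr_params: ITRParams = ITRParams(),
) -> EvalReport:
    """K-fold cross-validated decoding.

    Trials — never individual epochs — are assigned to folds, stratified over
    runs so every fold spans all runs.  Each fold trains a fresh scorer from
    ``model_factory`` on the remaining trials, scores the held-out epochs,
    and argmax-decodes each held-out trial.  Reproducible given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    groups = _trial_groups(epochs)
    keys = list(groups)
    if folds > len(keys):
        raise ValueError(f"{folds} folds but only {len(keys)} trials")
    rng = np.random.default_rng(seed)
    fold_of: dict[tuple[int, int, int], int] = {}
    by_run: dict[int, list] = {}
    for key in keys:
        by_run.setdefault(key[0], []).append(key)
    counter = 0
    for run in sorted(by_run):
        run_keys = by_run[run]
        order = rng.permutation(len(run_keys))
        for j in order:
            fold_of[run_keys[j]] = counter % folds
            counter += 1

    all_records = []
    held_scores = np.empty(epochs.n_epochs)
    held_mask = np.zeros(epochs.n_epochs, bool)
    for fold in range(folds):
        test_keys = [k for k in keys if fold_of[k] == fold]
        train_idx = np.concatenate([groups[k] for k in keys if fold_of[k] != fold])
        test_idx = np.concatenate([groups[k] for k in test_keys])
        scorer = model_factory()
        scorer.fit(epochs.subset(np.sort(train_idx)))
        scores = np.asarray(scorer.score(epochs.subset(test_idx))).ravel()
        full_scores = np.empty(epochs.n_epochs)
        full_scores[test_idx] = scores
        held_scores[test_idx] = scores
        held_mask[test_idx] = True
        all_records.extend(
            _decode_groups(epochs, full_scores, target_of_block,
                           keys=test_keys, groups=groups)
        )
    assert held_mask.all()
    return _report_from_records(
        all_records, held_scores, epochs.labels, itr_params, folds, seed
    )


def holdout_eval(
    train_epochs: EpochSet,
    test_epochs: EpochSet,
    model_factory: Callable[[], object],
    target_of_block: dict[int, int],
    itr_params: ITRParams = ITRParams(),
) -> EvalReport:
    """Single train/test evaluation with the same decoding and report."""
    scorer = model_factory()
    scorer.fit(train_epochs)
    scores = np.asarray(scorer.score(test_epochs)).ravel()
    records = _decode_groups(test_epochs, scores, target_of_block)
    return _report_from_records(records, scores, test_epochs.labels,
                                itr_params, 0, None)


def averaging_comparison(
    epochs: EpochSet,
    model_factory: Callable[[], object],
    target_of_block: dict[int, int],
    ks: tuple[int, ...] = (1, 2, 3, 5),
    folds: int = 5,
    seed: int | None = 0,
    soa_s: float = 0.175,
    epoch_tail_s: float = 0.425,
    n_stimuli: int = 9,
) -> pd.DataFrame:
    """Accuracy and per-selection ITR of a scorer at several averaging depths.

    Averaging k repetitions multiplies the selection time by k (the k flash
    sweeps must all be presented), so accuracy gains are traded against ITR.
    """
    rows = []
    for k in ks:
        avg = average_repetitions(epochs, k)
        t_sel = k * (n_stimuli * soa_s) + epoch_tail_s
        itr_params = ITRParams(n_targets=n_stimuli, selection_time_s=t_sel)
        report = crossval(avg, model_factory, target_of_block,
                          folds=folds, seed=seed, itr_params=itr_params)
        rows.append({
            "k": k,
            "accuracy_pct": report.mean_accuracy,
            "itr_bits_per_min": report.itr_bits_per_min,
            "auc": report.auc,
            "selection_time_s": t_sel,
        })
    return pd.DataFrame(rows)
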