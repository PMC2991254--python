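"""Scores and null models for interaction predictions.

The figure of merit throughout is the F-score, the harmonic mean of
precision and recall: F = 2PR/(P+R) with P = TP/(TP+FP) and
R = TP/(TP+FN).  It is preferred over accuracy because interaction screens
are unbalanced (far more non-interacting than interacting combinations).

Null models:

* wild-type-pattern null -- use a wild-type protein's interaction pattern
  as the prediction for its mutant's pattern;
* graded noise injection -- move a fraction of interactions onto randomly
  chosen non-interacting pairs before training;
* full randomization -- keep the network fixed but randomly reassign
  sequences to proteins.

Empirical p-values use the add-one rule p = (1 + #{null >= obs})/(1 + N),
whose floor at 1/(N+1) matches "p < 0.001" from 1000 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interactions import InteractionDataset, Label
from .records import ProteinRecord


@dataclass(frozen=True)
class ScoreReport:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    fscore: float
    degenerate: bool = False  # a precision/recall denominator was zero

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def score_counts(tp: int, fp: int, fn: int, tn: int) -> ScoreReport:
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fscore = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return ScoreReport(tp, fp, fn, tn, precision, recall, fscore, degenerate)


def score(predicted, truth) -> ScoreReport:
    """Score a binary prediction vector against a truth vector."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {truth.shape} truths"
        )
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())
    return score_counts(tp, fp, fn, tn)


def fscore(predicted, truth) -> float:
    return score(predicted, truth).fscore


def wildtype_null(wild_labels, mutant_labels) -> ScoreReport:
    """Wild-type interaction pattern as the predictor of the mutant pattern."""
    return score(wild_labels, mutant_labels)


def inject_noise(
    data: InteractionDataset, fraction: float, seed: int
) -> InteractionDataset:
    """Move round(fraction * n_interacting) interactions onto random
    previously non-interacting pairs.  Conserves the interacting count."""
    if not 0 <= fraction <= 1:
        raise ValueError("noise fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    pos = data.pairs_with(Label.INTERACTING)
    neg = data.pairs_with(Label.NON_INTERACTING)
    n_move = int(round(fraction * len(pos)))
    if n_move == 0:
        return data.copy()
    if n_move > len(neg):
        raise ValueError(
            f"cannot move {n_move} interactions: only {len(neg)} non-interacting pairs"
        )
    out = data.copy()
    removed = rng.choice(len(pos), size=n_move, replace=False)
    added = rng.choice(len(neg), size=n_move, replace=False)
    for i in removed:
        out.pairs[pos[i]] = Label.NON_INTERACTING
    for i in added:
        out.pairs[neg[i]] = Label.INTERACTING
    return out


def randomize_sequence_assignment(
    data: InteractionDataset, seqs: dict[str, ProteinRecord], seed: int
) -> dict[str, ProteinRecord]:
    """Keep the network, permute which sequence belongs to which protein."""
    ids = sorted(data.proteins)
    missing = [pid for pid in ids if pid not in seqs]
    if missing:
        raise ValueError(f"no sequence for proteins {missing}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    out = dict(seqs)
    for pid, j in zip(ids, perm):
        src = seqs[ids[j]]
        out[pid] = ProteinRecord(id=pid, sequence=src.sequence, species=src.species)
    return out


def empirical_pvalue(
    observed: float, null_samples, direction: str = "greater"
) -> float:
    """Add-one empirical p-value against a null sample."""
    null = np.asarray(list(null_samples), dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    if direction == "greater":
        extreme = int((null >= observed).sum())
    elif direction == "less":
        extreme = int((null <= observed).sum())
    else:
        raise ValueError("direction must be 'greater' or 'less'")
    return (1 + extreme) / (1 + null.size)
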