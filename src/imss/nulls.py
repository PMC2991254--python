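"""Retrain-under-perturbation null analyses.

Each analysis retrains the full pipeline on a perturbed input and scores
the resulting model by its out-of-bag F against the *unperturbed* labels
(OOB predictions stand in for cross-validated ones: every training row is
scored only by trees that never saw it).  Two perturbations:

* graded label noise -- a fraction of interactions moved onto random
  non-interacting pairs before training (10-40% grid);
* full randomization -- the network kept, sequences randomly reassigned
  to proteins.

A skilled model degrades smoothly with noise and collapses under full
reassignment; the gap to the unperturbed F, calibrated by an empirical
p-value, is the evidence that the learned motifs are real.
"""

from __future__ import annotations

import logging

import numpy as np

from .classify import PipelineConfig, fit_pipeline
from .interactions import InteractionDataset, Label
from .records import ProteinRecord
from .scoring import inject_noise, randomize_sequence_assignment, score

logger = logging.getLogger(__name__)


def oob_fscore_against(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    config: PipelineConfig,
    reference: dict | None = None,
) -> float:
    """Fit the pipeline and return its OOB F-score.

    ``reference`` maps canonical pairs to booleans; when given, the OOB
    predictions are scored against it instead of the (possibly perturbed)
    training labels.  A run in which discovery finds nothing scores 0.
    """
    try:
        model = fit_pipeline(data, seqs, config)
    except ValueError as exc:
        logger.info("pipeline failed under perturbation (%s); F = 0", exc)
        return 0.0
    pred = model.oob_proba >= model.threshold
    if reference is None:
        truth = [data.pairs[p] is Label.INTERACTING for p in model.training_pairs]
    else:
        truth = [bool(reference[p]) for p in model.training_pairs]
    return score(pred, truth).fscore


def reassignment_null(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    config: PipelineConfig,
    n_reps: int,
    seed: int,
) -> list[float]:
    """F-scores of models trained after random sequence reassignment."""
    out = []
    for rep in range(n_reps):
        permuted = randomize_sequence_assignment(data, seqs, seed=seed + rep)
        out.append(oob_fscore_against(data, permuted, config))
    return out


def noise_curve(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    config: PipelineConfig,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4),
    n_seeds: int = 10,
    seed: int = 0,
) -> dict[float, list[float]]:
    """F against the clean labels after training on noise-injected labels."""
    clean = {
        pair: lab is Label.INTERACTING for pair, lab in data.labeled_pairs()
    }
    out: dict[float, list[float]] = {}
    for frac in fractions:
        vals = []
        for s in range(n_seeds):
            noisy = inject_noise(data, frac, seed=seed + 1000 * s + int(frac * 100))
            vals.append(oob_fscore_against(noisy, seqs, config, reference=clean))
        out[frac] = vals
    return out
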