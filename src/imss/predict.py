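"""Applying a trained model: new sequences, in-silico mutants, deltas.

A mutant's predicted interaction pattern is compared against a reference
pattern (by default the model's own wild-type predictions; optionally the
experimentally observed wild-type pattern) yielding an
:class:`InteractionDelta` -- which partners were lost, gained, or kept --
and a coarse effect category (loss-only / gain-only / both / none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import TrainedModel, predict_proba_pairs
from .interactions import Pair, canonical_pair
from .mutations import MutationSpec, apply_mutations
from .records import ProteinRecord


@dataclass
class PredictionSet:
    """Predicted labels and probabilities for a set of unordered pairs."""

    pairs: list[Pair]
    probabilities: np.ndarray
    labels: np.ndarray
    threshold: float
    model_id: str = ""

    def label_of(self, a: str, b: str) -> bool:
        key = canonical_pair(a, b)
        return bool(self.labels[self.pairs.index(key)])


@dataclass
class InteractionDelta:
    """Partner changes of a variant relative to a reference protein."""

    reference_id: str
    variant_id: str
    partner_universe: list[str]
    losses: list[str]
    gains: list[str]
    kept: list[str]

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    @property
    def n_gains(self) -> int:
        return len(self.gains)


def predict_pairs(
    model: TrainedModel,
    seqs: dict[str, ProteinRecord],
    query_pairs: list[tuple[str, str]],
    model_id: str = "",
) -> PredictionSet:
    """Forest probabilities and thresholded labels for query pairs."""
    pairs = [canonical_pair(a, b) for a, b in query_pairs]
    probs = predict_proba_pairs(model, seqs, pairs)
    return PredictionSet(
        pairs=pairs,
        probabilities=probs,
        labels=probs >= model.threshold,
        threshold=model.threshold,
        model_id=model_id,
    )


def interaction_delta(
    reference_labels,
    variant_labels,
    universe: list[str],
    reference_id: str = "reference",
    variant_id: str = "variant",
) -> InteractionDelta:
    """Set differences between two partner-label vectors over one universe."""
    ref = np.asarray(reference_labels, dtype=bool)
    var = np.asarray(variant_labels, dtype=bool)
    if not (len(ref) == len(var) == len(universe)):
        raise ValueError("label vectors and universe must have equal length")
    losses = [u for u, r, v in zip(universe, ref, var) if r and not v]
    gains = [u for u, r, v in zip(universe, ref, var) if v and not r]
    kept = [u for u, r, v in zip(universe, ref, var) if r and v]
    return InteractionDelta(reference_id, variant_id, list(universe), losses, gains, kept)


def classify_mutant_effect(delta: InteractionDelta) -> str:
    """loss_only / gain_only / both / none."""
    if delta.n_losses and delta.n_gains:
        return "both"
    if delta.n_losses:
        return "loss_only"
    if delta.n_gains:
        return "gain_only"
    return "none"


def predict_mutant(
    model: TrainedModel,
    wildtype: ProteinRecord,
    specs: MutationSpec | list[MutationSpec],
    partners: dict[str, ProteinRecord],
    reference_labels=None,
) -> tuple[PredictionSet, InteractionDelta]:
    """Apply a mutation, rescan features, predict against all partners.

    The delta is computed versus the model's own wild-type predictions
    unless explicit ``reference_labels`` (e.g. experimental wild-type
    data) are supplied.
    """
    if isinstance(specs, MutationSpec):
        specs = [specs]
    mutant = apply_mutations(wildtype, specs)
    mutant = ProteinRecord("MUTANT__", mutant.sequence, mutant.species)

    universe = sorted(partners)
    seqs = dict(partners)
    seqs[wildtype.id] = wildtype
    seqs[mutant.id] = mutant

    mutant_pred = predict_pairs(model, seqs, [(mutant.id, u) for u in universe])
    if reference_labels is None:
        wild_pred = predict_pairs(model, seqs, [(wildtype.id, u) for u in universe])
        reference_labels = [wild_pred.label_of(wildtype.id, u) for u in universe]
    variant_labels = [mutant_pred.label_of(mutant.id, u) for u in universe]
    delta = interaction_delta(
        reference_labels,
        variant_labels,
        universe,
        reference_id=wildtype.id,
        variant_id=f"{wildtype.id} {'/'.join(s.text for s in specs)}",
    )
    return mutant_pred, delta
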