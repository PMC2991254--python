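"""Correlated motif-pair discovery.

A motif is a fixed-length pattern over the 20 amino acids plus the wildcard
``*``; it matches a sequence window when the Hamming distance, counted over
non-wildcard positions only, is at most ``max_mismatch`` (an (l,d) motif).
An ``X`` residue in a sequence never matches a non-wildcard motif position.

A motif *pair* (lock, key) is the unit feature of the interaction
classifier: a protein pair supports the motif pair when one protein carries
the lock and the other the key (either orientation).  Discovery seeds
candidate pairs from exact substrings of interacting sequence pairs, scores
each candidate by enrichment of support among interacting versus
non-interacting pairs (a hypergeometric upper tail), removes redundant
candidates whose supporting-pair set is subsumed by a better one, and keeps
the top k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import hypergeom

from .interactions import InteractionDataset, Label
from .records import ProteinRecord

logger = logging.getLogger(__name__)

WILDCARD = "*"
_TINY = 1e-300


@dataclass(frozen=True)
class Motif:
    """An (l,d) pattern: fixed length, wildcards, mismatch tolerance."""

    motif_id: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        from .records import AMINO_ACIDS

        bad = set(self.pattern) - set(AMINO_ACIDS + WILDCARD)
        if bad:
            raise ValueError(f"pattern may use the 20 residues and '*' only, got {sorted(bad)}")
        n_fixed = sum(1 for c in self.pattern if c != WILDCARD)
        if n_fixed == 0:
            raise ValueError("motif needs at least one non-wildcard position")
        if not 0 <= self.max_mismatch < n_fixed:
            raise ValueError(
                f"max_mismatch {self.max_mismatch} must be < non-wildcard "
                f"count {n_fixed}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def n_fixed(self) -> int:
        return sum(1 for c in self.pattern if c != WILDCARD)


@dataclass(frozen=True)
class MotifOccurrence:
    """A motif hit: 1-based inclusive residue span within one protein."""

    protein_id: str
    motif_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("occurrence coordinates must satisfy 1 <= start <= end")


@dataclass
class MotifPair:
    """An unordered (lock, key) motif pair with its discovery statistics."""

    pair_id: str
    motif_x: Motif
    motif_y: Motif
    support_pos: int = 0
    support_neg: int = 0
    score: float = 0.0

    def motifs(self) -> tuple[Motif, Motif]:
        return (self.motif_x, self.motif_y)


@dataclass
class DiscoveryParams:
    """Knobs of the correlated-motif search.

    l, d -- motif length and mismatch tolerance; the defaults (8, 2) cover
    the 3-6 residue cores seen in validated interaction motifs with room
    for degenerate flanks.  top_k bounds the returned list; min_support
    drops rare candidates; wildcard_threshold is the majority fraction a
    consensus column needs to stay a literal residue.
    """

    l: int = 8
    d: int = 2
    top_k: int = 200
    min_support: int = 3
    wildcard_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.wildcard_threshold <= 1:
            raise ValueError("wildcard_threshold must be in (0,1]")


# ---------------------------------------------------------------------------
# matching


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


_STAR = ord(WILDCARD)


def _window_mismatches(pattern: str, seq: str) -> np.ndarray:
    """Mismatch count of every length-l window against the pattern."""
    l = len(pattern)
    enc_seq = _encode(seq)
    if len(enc_seq) < l:
        return np.zeros(0, dtype=np.int64)
    windows = sliding_window_view(enc_seq, l)
    pat = _encode(pattern)
    fixed = pat != _STAR
    return ((windows[:, fixed] != pat[fixed])).sum(axis=1)


def match_positions(motif: Motif, record: ProteinRecord) -> list[MotifOccurrence]:
    """All windows within Hamming distance d of the motif, ascending start."""
    mism = _window_mismatches(motif.pattern, record.sequence)
    starts = np.nonzero(mism <= motif.max_mismatch)[0]
    l = len(motif)
    return [
        MotifOccurrence(record.id, motif.motif_id, int(s) + 1, int(s) + l)
        for s in starts
    ]


def motif_matches(motif: Motif, record: ProteinRecord) -> bool:
    mism = _window_mismatches(motif.pattern, record.sequence)
    return bool(mism.size) and bool((mism <= motif.max_mismatch).any())


def pair_supports(pair: MotifPair, a: ProteinRecord, b: ProteinRecord) -> bool:
    """True iff the lock hits one protein and the key the other (either way)."""
    xa = motif_matches(pair.motif_x, a)
    yb = motif_matches(pair.motif_y, b)
    if xa and yb:
        return True
    xb = motif_matches(pair.motif_x, b) if b.id != a.id else xa
    ya = motif_matches(pair.motif_y, a) if b.id != a.id else yb
    return xb and ya


# ---------------------------------------------------------------------------
# scoring


def enrichment_score(
    support_pos: np.ndarray | int,
    support_neg: np.ndarray | int,
    n_pos: int,
    n_neg: int,
) -> np.ndarray | float:
    """-log hypergeometric upper-tail P(X >= support_pos).

    Population: all labeled pairs; successes: pairs supporting the motif
    pair; draws: the interacting pairs.  Monotone in support_pos at fixed
    support_neg.
    """
    k = np.asarray(support_pos)
    s = k + np.asarray(support_neg)
    p = hypergeom.sf(k - 1, n_pos + n_neg, s, n_pos)
    out = -np.log(np.maximum(p, _TINY))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# discovery


def _exact_lmer_indices(
    seq: str, l: int, pattern_index: dict[str, int], patterns: list[str]
) -> list[int]:
    out = []
    seen: set[int] = set()
    for i in range(len(seq) - l + 1):
        sub = seq[i : i + l]
        if "X" in sub:
            continue
        idx = pattern_index.get(sub)
        if idx is None:
            idx = len(patterns)
            pattern_index[sub] = idx
            patterns.append(sub)
        if idx not in seen:
            seen.add(idx)
            out.append(idx)
    return out


def _match_matrix(
    patterns: list[str], protein_seqs: list[str], d: int, l: int
) -> np.ndarray:
    """Bool matrix [pattern, protein]: does the pattern hit the protein?"""
    n_pat = len(patterns)
    pat_arr = np.vstack([_encode(p) for p in patterns]) if n_pat else np.zeros((0, l), np.uint8)
    out = np.zeros((n_pat, len(protein_seqs)), dtype=bool)
    for j, seq in enumerate(protein_seqs):
        enc = _encode(seq)
        if len(enc) < l:
            continue
        windows = sliding_window_view(enc, l)
        # chunk patterns to bound the mismatch tensor
        chunk = max(1, 4_000_000 // max(1, windows.shape[0] * l))
        for lo in range(0, n_pat, chunk):
            sub = pat_arr[lo : lo + chunk]
            mism = (sub[:, None, :] != windows[None, :, :]).sum(axis=2)
            out[lo : lo + chunk, j] = (mism <= d).any(axis=1)
    return out


def discover_motif_pairs(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    params: DiscoveryParams,
) -> list[MotifPair]:
    """D-STAR-style search for motif pairs enriched in interacting pairs.

    Candidate seeds are all (substring-of-A, substring-of-B) length-l pairs
    drawn from interacting pairs (A,B); each is scored with the
    d-mismatch support over all labeled pairs; candidates below
    ``min_support`` are dropped; a greedy redundancy filter discards any
    candidate whose supporting interacting-pair set is a subset of an
    already kept one; the top_k survivors are returned ranked by score,
    with lexicographic pattern tie-breaks for determinism.
    """
    pos_pairs = data.pairs_with(Label.INTERACTING)
    neg_pairs = data.pairs_with(Label.NON_INTERACTING)
    if not pos_pairs:
        raise ValueError("no interacting pairs")
    l = params.l

    protein_ids = sorted({p for pair in data.pairs for p in pair})
    prot_index = {pid: i for i, pid in enumerate(protein_ids)}
    protein_seqs = [seqs[pid].sequence for pid in protein_ids]

    pattern_index: dict[str, int] = {}
    patterns: list[str] = []
    lmers = {
        pid: _exact_lmer_indices(seqs[pid].sequence, l, pattern_index, patterns)
        for pid in protein_ids
    }

    candidates: set[tuple[int, int]] = set()
    for a, b in pos_pairs:
        for x in lmers[a]:
            for y in lmers[b]:
                candidates.add((x, y) if x <= y else (y, x))
    if not candidates:
        return []
    cand = np.array(sorted(candidates), dtype=np.int64)
    cx, cy = cand[:, 0], cand[:, 1]

    M = _match_matrix(patterns, protein_seqs, params.d, l)

    n_cand = len(cand)
    support_pos = np.zeros(n_cand, dtype=np.int64)
    support_neg = np.zeros(n_cand, dtype=np.int64)
    pos_support_rows = np.zeros((n_cand, len(pos_pairs)), dtype=bool)
    for k, (a, b) in enumerate(pos_pairs):
        ia, ib = prot_index[a], prot_index[b]
        sup = (M[cx, ia] & M[cy, ib]) | (M[cx, ib] & M[cy, ia])
        support_pos += sup
        pos_support_rows[:, k] = sup
    for a, b in neg_pairs:
        ia, ib = prot_index[a], prot_index[b]
        support_neg += (M[cx, ia] & M[cy, ib]) | (M[cx, ib] & M[cy, ia])

    keep = support_pos >= params.min_support
    if not keep.any():
        return []
    cx, cy = cx[keep], cy[keep]
    support_pos, support_neg = support_pos[keep], support_neg[keep]
    pos_support_rows = pos_support_rows[keep]
    scores = enrichment_score(support_pos, support_neg, len(pos_pairs), len(neg_pairs))

    order = sorted(
        range(len(cx)),
        key=lambda i: (-scores[i], patterns[cx[i]], patterns[cy[i]]),
    )

    kept: list[MotifPair] = []
    kept_masks: list[int] = []
    for i in order:
        mask = int.from_bytes(np.packbits(pos_support_rows[i]).tobytes(), "big")
        if any(mask | km == km for km in kept_masks):
            continue
        px, py = patterns[cx[i]], patterns[cy[i]]
        pair = MotifPair(
            pair_id=f"{px}|{py}",
            motif_x=Motif(px, px, params.d),
            motif_y=Motif(py, py, params.d),
            support_pos=int(support_pos[i]),
            support_neg=int(support_neg[i]),
            score=float(scores[i]),
        )
        kept.append(pair)
        kept_masks.append(mask)
        if len(kept) >= params.top_k:
            break
    return kept


# ---------------------------------------------------------------------------
# wildcard consensus


def _consensus_pattern(windows: list[str], threshold: float) -> str | None:
    """Majority consensus; columns below the majority fraction become '*'."""
    if not windows:
        return None
    arr = np.array([list(w) for w in windows])
    cols = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        residues, counts = np.unique(col, return_counts=True)
        best = counts.argmax()
        frac = counts[best] / len(col)
        ch = residues[best]
        cols.append(ch if frac >= threshold and ch != "X" else WILDCARD)
    pattern = "".join(cols)
    return pattern if any(c != WILDCARD for c in pattern) else None


def generalize_to_consensus(
    pair: MotifPair,
    seqs: dict[str, ProteinRecord],
    params: DiscoveryParams,
) -> MotifPair:
    """Broaden both motifs to wildcard consensus over their matched windows.

    All matched windows across the family are stacked column-wise; columns
    whose majority residue falls below ``wildcard_threshold`` become ``*``.
    If every column would degenerate (or too few literal positions remain
    to honour the mismatch budget) the input motif is kept unchanged.
    """
    new_motifs = []
    for motif in pair.motifs():
        windows = []
        for rec in seqs.values():
            for occ in match_positions(motif, rec):
                windows.append(rec.sequence[occ.start - 1 : occ.end])
        pattern = _consensus_pattern(windows, params.wildcard_threshold)
        if pattern is None:
            logger.warning(
                "motif %s: consensus fully degenerate, keeping seed pattern",
                motif.motif_id,
            )
            new_motifs.append(motif)
            continue
        n_fixed = sum(1 for c in pattern if c != WILDCARD)
        if n_fixed <= motif.max_mismatch:
            new_motifs.append(motif)
            continue
        new_motifs.append(Motif(pattern, pattern, motif.max_mismatch))
    mx, my = new_motifs
    return replace(pair, pair_id=f"{mx.pattern}|{my.pattern}", motif_x=mx, motif_y=my)


def rescore_pair(
    pair: MotifPair, data: InteractionDataset, seqs: dict[str, ProteinRecord]
) -> MotifPair:
    """Recompute supports and score (used after consensus generalization)."""
    sp = sn = 0
    for (a, b), label in data.labeled_pairs():
        if pair_supports(pair, seqs[a], seqs[b]):
            if label is Label.INTERACTING:
                sp += 1
            else:
                sn += 1
    n_pos = data.n_interacting
    n_neg = data.n_non_interacting
    return replace(
        pair,
        support_pos=sp,
        support_neg=sn,
        score=float(enrichment_score(sp, sn, n_pos, n_neg)),
    )
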