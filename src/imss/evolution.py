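"""Evolutionary analyses of motif occurrences.

Covers ortholog mapping by bidirectional best hit on pairwise identity,
motif versus non-motif conservation across orthologs, scanning pairwise
alignments for clean single-column indels and classifying them into the
four post-duplication scenarios (indel overlapping a motif in neither,
both, only the inserted or only the deleted copy), SNP/motif overlap with
a random-placement null, correlated-mutation (coevolving column) detection
on a multiple alignment, and motif distance to exon borders.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import ks_2samp, pearsonr

from .motifs import WILDCARD, MotifOccurrence
from .records import ProteinRecord

logger = logging.getLogger(__name__)

GAP = "-"


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def identity(self) -> float:
        """Fraction of identical columns among columns with no gap."""
        both = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != GAP and y != GAP
        ]
        if not both:
            return 0.0
        return sum(x == y for x, y in both) / len(both)

    def ungapped(self, which: str) -> str:
        s = self.aligned_a if which == "a" else self.aligned_b
        return s.replace(GAP, "")

    def column_of(self, which: str) -> dict[int, int]:
        """Map 1-based residue index -> 1-based alignment column."""
        s = self.aligned_a if which == "a" else self.aligned_b
        out, res = {}, 0
        for col, ch in enumerate(s, start=1):
            if ch != GAP:
                res += 1
                out[res] = col
        return out

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(self.id_b, self.id_a, self.aligned_b, self.aligned_a)


def _aligner(open_gap: float = -10.0, extend_gap: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = "global"
    return aligner


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    open_gap: float = -10.0,
    extend_gap: float = -1.0,
) -> PairwiseAlignment:
    """Global affine-gap alignment (BLOSUM62-scored), deterministic."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aln = _aligner(open_gap, extend_gap).align(a.sequence, b.sequence)[0]
    return PairwiseAlignment(a.id, b.id, str(aln[0]), str(aln[1]))


def from_aligned(id_a: str, id_b: str, aligned_a: str, aligned_b: str) -> PairwiseAlignment:
    """Wrap an externally produced (e.g. MUSCLE) pairwise alignment."""
    return PairwiseAlignment(id_a, id_b, aligned_a.upper(), aligned_b.upper())


# ---------------------------------------------------------------------------
# orthologs


def bbh_orthologs(
    queries: list[ProteinRecord], targets: list[ProteinRecord]
) -> dict[str, dict[str, str]]:
    """Bidirectional best hits by pairwise identity, per target species.

    Returns query id -> {species -> ortholog id}.  Ties are broken
    lexicographically (and logged).
    """
    if not queries or not targets:
        raise ValueError("both protein sets must be nonempty")
    identity: dict[tuple[str, str], float] = {}
    for q in queries:
        for t in targets:
            identity[(q.id, t.id)] = align_pair(q, t).identity

    species = sorted({t.species for t in targets})
    out: dict[str, dict[str, str]] = {q.id: {} for q in queries}
    for sp in species:
        sp_targets = [t for t in targets if t.species == sp]
        for q in queries:
            ranked = sorted(sp_targets, key=lambda t: (-identity[(q.id, t.id)], t.id))
            if len(ranked) > 1 and identity[(q.id, ranked[0].id)] == identity[(q.id, ranked[1].id)]:
                logger.warning("tie for best hit of %s in %s; lexicographic break", q.id, sp)
            best_t = ranked[0]
            back = sorted(queries, key=lambda p: (-identity[(p.id, best_t.id)], p.id))
            if back[0].id == q.id:
                out[q.id][sp] = best_t.id
    return out


# ---------------------------------------------------------------------------
# conservation


def window_conservation(
    alignment: PairwiseAlignment,
    start: int,
    end: int,
    pattern: str | None = None,
) -> float | None:
    """Fraction of residues in [start, end] of sequence A identical in B.

    ``pattern`` (same length as the window) restricts the count to its
    non-wildcard positions.  Residues aligned to a gap count as not
    conserved; a window entirely within a gap region returns None.
    """
    colmap = alignment.column_of("a")
    cols = [colmap[r] for r in range(start, end + 1) if r in colmap]
    if not cols:
        return None
    total = matched = 0
    for k, r in enumerate(range(start, end + 1)):
        if pattern is not None and pattern[k] == WILDCARD:
            continue
        if r not in colmap:
            continue
        c = colmap[r]
        total += 1
        if alignment.aligned_b[c - 1] == alignment.aligned_a[c - 1]:
            matched += 1
    if total == 0:
        return None
    return matched / total


def motif_conservation(
    occ: MotifOccurrence,
    alignments: list[PairwiseAlignment],
    pattern: str | None = None,
    mode: str = "per_ortholog",
) -> float | None:
    """Conservation of one motif occurrence across ortholog alignments.

    ``per_ortholog`` (default) averages the per-ortholog conserved
    fractions; ``pooled`` pools characters across orthologs.
    """
    fractions, weights = [], []
    for aln in alignments:
        if aln.id_a != occ.protein_id:
            raise ValueError(f"alignment {aln.id_a} does not involve {occ.protein_id}")
        frac = window_conservation(aln, occ.start, occ.end, pattern)
        if frac is None:
            logger.warning(
                "occurrence %s:%d-%d falls in gap region of alignment to %s",
                occ.protein_id, occ.start, occ.end, aln.id_b,
            )
            continue
        fractions.append(frac)
        weights.append(occ.end - occ.start + 1)
    if not fractions:
        return None
    if mode == "pooled":
        return float(np.average(fractions, weights=weights))
    return float(np.mean(fractions))


def nonmotif_baseline(
    start: int,
    end: int,
    alignments_by_protein: dict[str, list[PairwiseAlignment]],
) -> list[float]:
    """Conservation of the same residue window in motif-free proteins.

    Callers pass the ortholog alignments of proteins that have no motif
    occurrence at [start, end]; the calculation matches
    :func:`motif_conservation`.
    """
    out = []
    for pid, alns in alignments_by_protein.items():
        occ = MotifOccurrence(pid, "baseline", start, end)
        frac = motif_conservation(occ, alns)
        if frac is not None:
            out.append(frac)
    return out


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need size >= 2")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# indels


@dataclass
class IndelEvent:
    """A clean single-column indel inside a near-identical stretch."""

    alignment: PairwiseAlignment
    window_start: int  # 1-based alignment column of one qualifying window
    window_length: int
    indel_column: int  # 1-based alignment column of the gap
    gap_in: str  # 'a' or 'b': which copy lacks the residue
    scenario: str | None = None


def scan_indels(
    alignment: PairwiseAlignment, d: int = 6, identity_cutoff: int = 5
) -> list[IndelEvent]:
    """Find isolated one-column indels flanked by near-identity.

    A window of ``d`` columns qualifies when it contains exactly one gap
    column, the gap is a run of length 1, and at least ``identity_cutoff``
    of the remaining columns are identical.  Overlapping windows for the
    same gap column merge into one event.
    """
    sa, sb = alignment.aligned_a, alignment.aligned_b
    n = len(sa)
    gap_cols = [i for i in range(n) if sa[i] == GAP or sb[i] == GAP]
    gap_set = set(gap_cols)
    events = []
    for c in gap_cols:
        if c - 1 in gap_set or c + 1 in gap_set:
            continue  # gap run longer than one column
        found = None
        for w0 in range(max(0, c - d + 1), min(c, n - d) + 1):
            window = range(w0, w0 + d)
            if sum(1 for i in window if i in gap_set) != 1:
                continue
            ident = sum(1 for i in window if i != c and sa[i] == sb[i])
            if ident >= identity_cutoff:
                found = w0
                break
        if found is not None:
            events.append(
                IndelEvent(
                    alignment=alignment,
                    window_start=found + 1,
                    window_length=d,
                    indel_column=c + 1,
                    gap_in="a" if sa[c] == GAP else "b",
                )
            )
    return events


def _occurrence_columns(
    occ: MotifOccurrence, alignment: PairwiseAlignment, which: str
) -> tuple[int, int] | None:
    colmap = alignment.column_of(which)
    cols = [colmap[r] for r in range(occ.start, occ.end + 1) if r in colmap]
    if not cols:
        return None
    return min(cols), max(cols)


def classify_indel_scenario(
    event: IndelEvent,
    occurrences_a: list[MotifOccurrence],
    occurrences_b: list[MotifOccurrence],
) -> str:
    """Post-duplication scenarios for an indel in a duplicate pair.

    I: no motif overlaps the indel in either copy; II: a motif overlaps
    in both copies; III: only in the insertion-bearing (ungapped) copy;
    IV: only in the deletion-bearing (gapped) copy.
    """
    aln, c = event.alignment, event.indel_column

    def overlaps(occs: list[MotifOccurrence], which: str) -> bool:
        for occ in occs:
            span = _occurrence_columns(occ, aln, which)
            if span and span[0] <= c <= span[1]:
                return True
        return False

    motif_a = overlaps(occurrences_a, "a")
    motif_b = overlaps(occurrences_b, "b")
    gapped_has = motif_a if event.gap_in == "a" else motif_b
    ungapped_has = motif_b if event.gap_in == "a" else motif_a
    if gapped_has and ungapped_has:
        scenario = "II"
    elif ungapped_has:
        scenario = "III"
    elif gapped_has:
        scenario = "IV"
    else:
        scenario = "I"
    event.scenario = scenario
    return scenario


# ---------------------------------------------------------------------------
# duplicate pairs


def find_duplicate_pairs(
    proteins: list[ProteinRecord],
    references: list[ProteinRecord],
    reference_clades: dict[str, str],
) -> list[tuple[str, str, str]]:
    """Same-species protein pairs whose best reference hits share a clade.

    Returns (id_1, id_2, clade) triples; a cheap proxy for post-duplication
    paralog pairs when no tree is available.
    """
    best_clade: dict[str, str] = {}
    for p in proteins:
        ranked = sorted(
            references, key=lambda r: (-align_pair(p, r).identity, r.id)
        )
        best_clade[p.id] = reference_clades[ranked[0].id]
    out = []
    by_species: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        by_species.setdefault(p.species, []).append(p)
    for sp in sorted(by_species):
        members = sorted(by_species[sp], key=lambda p: p.id)
        for p1, p2 in itertools.combinations(members, 2):
            if best_clade[p1.id] == best_clade[p2.id]:
                out.append((p1.id, p2.id, best_clade[p1.id]))
    return out


# ---------------------------------------------------------------------------
# SNP overlap


@dataclass(frozen=True)
class SNPRecord:
    protein_id: str
    position: int  # 1-based residue
    ref_aa: str
    alt_aa: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("SNP must change the residue")


def snp_motif_overlap(
    snps: list[SNPRecord], occurrences: list[MotifOccurrence]
) -> int:
    """Total SNP weight falling inside any motif occurrence."""
    by_protein: dict[str, list[MotifOccurrence]] = {}
    for occ in occurrences:
        by_protein.setdefault(occ.protein_id, []).append(occ)
    total = 0
    for snp in snps:
        for occ in by_protein.get(snp.protein_id, []):
            if occ.start <= snp.position <= occ.end:
                total += snp.count
                break
    return total


def randomized_motif_null(
    snps: list[SNPRecord],
    occurrences: list[MotifOccurrence],
    sequence_lengths: dict[str, int],
    seed: int,
    trials: int = 1000,
) -> list[int]:
    """Null overlap distribution from random motif re-placement.

    Each trial re-places, per protein, the same number of occurrences with
    the same lengths at uniform random positions, then recounts the SNP
    overlap.
    """
    rng = np.random.default_rng(seed)
    by_protein: dict[str, list[int]] = {}
    for occ in occurrences:
        by_protein.setdefault(occ.protein_id, []).append(occ.end - occ.start + 1)
    out = []
    for _ in range(trials):
        placed: list[MotifOccurrence] = []
        for pid in sorted(by_protein):
            L = sequence_lengths[pid]
            for length in by_protein[pid]:
                start = int(rng.integers(1, max(1, L - length + 1) + 1))
                placed.append(MotifOccurrence(pid, "random", start, start + length - 1))
        out.append(snp_motif_overlap(snps, placed))
    return out


# ---------------------------------------------------------------------------
# correlated mutations


def caps_correlated_columns(
    msa: list[ProteinRecord] | list[tuple[str, str]],
    r_cutoff: float = 0.4,
    min_coverage: float = 0.5,
) -> list[tuple[int, int, float]]:
    """Coevolving alignment column pairs by correlated substitution scores.

    For every pair of columns (i, j) with at least ``min_coverage`` non-gap
    residues, the BLOSUM62 transition scores at i and at j are collected
    over all sequence pairs (pairs with a gap at either column excluded)
    and their Pearson correlation computed; column pairs with r >= cutoff
    are returned (1-based columns).  Zero-variance columns are skipped.
    """
    rows = [
        (rec.id, rec.sequence) if isinstance(rec, ProteinRecord) else rec
        for rec in msa
    ]
    if len(rows) < 4:
        raise ValueError("need at least 4 aligned sequences")
    seqs = [s for _, s in rows]
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    blosum = substitution_matrices.load("BLOSUM62")

    usable = []
    for j in range(ncol):
        cov = sum(1 for s in seqs if s[j] != GAP) / len(seqs)
        if cov >= min_coverage:
            usable.append(j)
        else:
            logger.warning("column %d coverage %.2f below %.2f; skipped", j + 1, cov, min_coverage)

    pair_idx = list(itertools.combinations(range(len(seqs)), 2))
    score_vec: dict[int, np.ndarray] = {}
    for j in usable:
        vals = []
        for s, t in pair_idx:
            a, b = seqs[s][j], seqs[t][j]
            vals.append(np.nan if GAP in (a, b) else float(blosum[a, b]))
        score_vec[j] = np.array(vals)

    out = []
    for i, j in itertools.combinations(usable, 2):
        vi, vj = score_vec[i], score_vec[j]
        ok = ~(np.isnan(vi) | np.isnan(vj))
        if ok.sum() < 3:
            continue
        if np.std(vi[ok]) == 0 or np.std(vj[ok]) == 0:
            continue
        r = float(pearsonr(vi[ok], vj[ok]).statistic)
        if r >= r_cutoff:
            out.append((i + 1, j + 1, r))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


# ---------------------------------------------------------------------------
# exon borders


@dataclass(frozen=True)
class ExonBorder:
    protein_id: str
    boundary_after: int  # junction falls after this residue (0 = before first)

    def __post_init__(self) -> None:
        if self.boundary_after < 0:
            raise ValueError("boundary_after must be >= 0")


@dataclass
class ExonBorderReport:
    near_motifs: list[str]
    far_motifs: list[str]
    proteins_per_motif: dict[str, int]
    mean_proteins_near: float
    mean_proteins_far: float
    min_distance: dict[str, float]  # per motif id


def _occurrence_border_distance(occ: MotifOccurrence, borders: list[ExonBorder]) -> float:
    best = float("inf")
    for b in borders:
        j = b.boundary_after
        if occ.start - 1 <= j <= occ.end:
            return 0.0
        dist = (occ.start - 1) - j if j < occ.start - 1 else j - occ.end
        best = min(best, dist)
    return best


def exon_border_analysis(
    occurrences: list[MotifOccurrence],
    borders: list[ExonBorder],
    near_cutoff: int = 3,
) -> ExonBorderReport:
    """Group motifs by proximity to exon borders; compare their spread.

    A motif is "near" when any of its occurrences lies under
    ``near_cutoff`` residues from a border of its protein (proteins with
    no borders give infinite distance).  Reports, per group, the mean
    number of distinct proteins the motifs occur in.
    """
    borders_by_protein: dict[str, list[ExonBorder]] = {}
    for b in borders:
        borders_by_protein.setdefault(b.protein_id, []).append(b)

    motif_ids = sorted({occ.motif_id for occ in occurrences})
    min_dist = {m: float("inf") for m in motif_ids}
    proteins: dict[str, set[str]] = {m: set() for m in motif_ids}
    for occ in occurrences:
        proteins[occ.motif_id].add(occ.protein_id)
        d = _occurrence_border_distance(
            occ, borders_by_protein.get(occ.protein_id, [])
        )
        min_dist[occ.motif_id] = min(min_dist[occ.motif_id], d)

    near = [m for m in motif_ids if min_dist[m] < near_cutoff]
    far = [m for m in motif_ids if min_dist[m] >= near_cutoff]
    counts = {m: len(proteins[m]) for m in motif_ids}
    return ExonBorderReport(
        near_motifs=near,
        far_motifs=far,
        proteins_per_motif=counts,
        mean_proteins_near=float(np.mean([counts[m] for m in near])) if near else 0.0,
        mean_proteins_far=float(np.mean([counts[m] for m in far])) if far else 0.0,
        min_distance=min_dist,
    )
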