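# Methods

## Model

The package treats interaction specificity in a paralogous family as a
function of *correlated motif pairs*.  A motif is an (l,d) pattern: a
length-l string over the 20 amino acids plus the wildcard `*`, matching a
window when the Hamming distance counted over non-wildcard positions is at
most d.  An `X` in a sequence matches only wildcard positions.  A motif
pair (lock, key) is supported by an unordered protein pair when one
protein matches the lock and the other the key, in either orientation;
homodimers collapse both orientations.  The classifier assumes that the
presence/absence vector of a modest number of such motif pairs carries the
specificity signal, and that a protein's partners can be predicted from
sequence alone once those pairs are known.

## Discovery

Candidate seeds are all exact (substring-of-A, substring-of-B) pairs of
length l drawn from interacting pairs (A,B) — positive-set seeding keeps
the candidate space tractable and focuses the search where signal must be.
Each candidate is scored by the enrichment of its d-mismatch support among
interacting versus non-interacting pairs, as −log of the hypergeometric
upper tail P(X ≥ support_pos) with the labeled pairs as population and the
interacting pairs as draws.  This score is monotone in positive support at
fixed negative support (property-tested).  Candidates below a minimum
positive support are dropped; scanning candidates in rank order (score
descending, then lexicographic on the two patterns for full determinism),
a candidate whose supporting interacting-pair set is a subset of an
already kept candidate's set is discarded; the first `top_k` survivors are
returned.  Each surviving motif is then generalized to a wildcard
consensus: all matched windows in the family are stacked column-wise and
columns whose majority residue falls below `wildcard_threshold` become
`*`; a consensus that would wipe out every literal position (or leave
fewer literals than the mismatch budget d) falls back to the seed pattern.
Generalized pairs are re-scored.

The exact scoring and wildcard rules of the original correlated-search
tooling in this area are not published in reusable form; both are kept
behind configuration so alternates can be swapped in.

## Clustering and selection

Columns of the binary pair × motif-pair feature matrix are merged by
greedy neighbor-count (GROMOS-style) clustering on the Jaccard similarity
of their occurrence sets — the number of sequence pairs where both motif
pairs fire divided by the number where at least one fires — at a default
cutoff of 0.8.  The unassigned column with the most unassigned neighbors
at or above the cutoff becomes a representative and absorbs them; ties
break on column id.  Representatives form the reduced feature set.

A Random Forest (default 500 trees; 100 in the desk-scale test
configuration) is pruned by backward elimination: fit, record the
out-of-bag F-score at the decision threshold (default 0.5), drop the 20%
of columns with the lowest impurity importance (at least one), repeat down
to a single column.  The final set is the smallest one whose OOB F is
within one standard error of the best, with the SE approximated
binomially as sqrt(F(1−F)/n).  OOB rows that were never out of bag (rare
at these forest sizes) receive the training base rate as probability.
Class imbalance is handled by the F-score criterion alone, not by
resampling.  Homodimer rows can be up/down-weighted
(`homodimer_weight`, default 1.0 — the screens give no reason to weight
them differently).

`TrainedModel.training_summary` holds resubstitution scores (so
re-predicting the training pairs reproduces it exactly); `oob_summary`
holds the out-of-bag scores that approximate held-out performance.

## Cross-validation and null models

Leave-one-protein-out CV removes every pair involving the held-out
protein and re-runs the configured pipeline on the remainder; by default
(`cv_scope="full"`) discovery itself is re-run inside each fold, which is
the leak-free choice; `classify_only` reuses globally discovered motifs
and re-fits only clustering/selection.  A grouping argument turns the same
machinery into leave-subfamily-out CV.  A fold in which discovery finds
nothing scores F = 0.

Three null models calibrate the classifier:

* **wild-type-pattern null** — score the wild-type interaction pattern as
  the prediction for a mutant's pattern;
* **noise injection** — move `round(fraction × n_interacting)`
  interactions onto uniformly chosen previously non-interacting pairs
  (interacting count conserved), default grid 10–40% × 10 seeds;
* **sequence reassignment** — permute which sequence belongs to which
  protein while keeping the network fixed.

For the retraining nulls the reported statistic is the retrained model's
out-of-bag F against the *clean* labels.  OOB is used as the
cross-validation stand-in because a fully grown forest reproduces its
training rows almost perfectly even on junk features, so resubstitution F
cannot separate a skilled model from a memorizing one; OOB predictions
come only from trees that never saw the row.  Empirical p-values use the
add-one rule p = (1 + #{null ≥ obs}) / (1 + N), whose floor of 1/(N+1)
matches the convention of reporting p < 0.001 from 1000 trials.

## Mutants

Mutations use 1-based inclusive residue coordinates in the standard
notation: `S61R`, a range replacement `SIPK62-65MQD` (length may change),
multi-site `V66I/N150Y` applied C-terminal-first so earlier coordinates
stay valid.  The residues named in the string must match the sequence —
mismatches are reported with expected-versus-found, which catches
off-by-one conventions immediately.  `predict_mutant` applies the
mutation, rescans the selected motif pairs, predicts against the partner
universe (default: the whole loaded family, matching a matrix screen) and
returns losses/gains/kept versus the model's own wild-type predictions;
a reference pattern (e.g. experimental wild-type data) can be supplied
instead, which is the convention of the packaged mutant matrix.

The packaged matrix (`imss.table1`) encodes the published screen of 7
wild types and 15 mutants against 32 family members, with unlisted
wild-type combinations non-interacting by the table's own convention.
Two internal inconsistencies of the source table are documented rather
than patched: the CAL N150Y row's cells recompute to 18 gains where its
printed column says 16, and the AGL14 wild-type-null F recomputes to
12/19 ≈ 0.632 where 0.56 is printed.  Tests pin the recomputed values.

## Evolutionary analyses

* **Alignment** — global affine-gap alignment, BLOSUM62, gap open −10 /
  extend −1, deterministic first-optimum; externally aligned FASTA is
  accepted anywhere an alignment is consumed.  Identity is the fraction of
  identical columns among gap-free columns.
* **Orthologs** — bidirectional best hit per target species on pairwise
  identity, lexicographic tie-break (logged).
* **Conservation** — for a motif occurrence, the fraction of its residues
  identical in the ortholog through the alignment columns; residues
  aligned to gaps count as unconserved, windows entirely in gaps are
  excluded with a warning.  Multiple orthologs are averaged per-ortholog
  by default (`pooled` pools characters instead; the right choice is not
  derivable from first principles, so both exist).  The non-motif baseline
  applies the identical calculation to the same residue window in proteins
  without a motif there.
* **Indels** — a window of d = 6 alignment columns reports an event when
  it contains exactly one gap column, the gap run has length 1 (longer
  runs are excluded outright, per the one-indel rule), and ≥ 5 of the
  remaining columns are identical; windows reporting the same gap column
  merge into one event.  Scenarios: I — no motif overlaps the indel column
  in either copy; II — both copies; III — only the ungapped
  (insertion-bearing) copy; IV — only the gapped (deletion-bearing) copy.
* **SNP overlap** — observed count-weighted SNPs inside motif occurrences,
  against a null that re-places each protein's occurrences (same number,
  same lengths) uniformly at random, 1000 trials.
* **Correlated mutations** — for each column pair with ≥ 50% non-gap
  coverage, Pearson correlation of BLOSUM62 transition scores over all
  sequence pairs (gapped pairs excluded, zero-variance columns skipped),
  cutoff r ≥ 0.4.  The divergence-time correction of the original CAPS
  method is deliberately omitted — plain correlation is transparent and
  sufficient for flagging candidate contacts — and noted as an extension
  point.
* **Exon borders** — `boundary_after = b` places the junction between
  residues b and b+1; an occurrence spanning the junction has distance 0,
  otherwise distance is residue counts to the nearest junction, infinite
  for proteins without borders.  Motifs with any occurrence closer than 3
  residues form the "near" group; the report compares the mean number of
  proteins the motifs of each group occur in.

## Synthetic data

The generator emulates a family-scale matrix screen.  Defaults: 20
proteins of length 60 drawn uniformly over the 20 residues
(family-derived frequencies optional), 3 planted (lock, key) pairs of
length 8, each protein carrying each lock/key independently with
probability 0.2, interaction under the `any_pair` rule (some planted pair
split across the two proteins in either orientation), no label noise,
heterodimers only.  Under this rule the positive fraction has the closed
form 1 − (1 − p²)^(2k) ≈ 22% — deliberately close to the roughly
one-in-four positive rate of family-scale yeast two-hybrid matrices, so
that the always-interacting baseline F (~0.36) stays far below a skilled
model and null separations are meaningful.  Label noise reuses the
noise-injection semantics; ground truth records patterns, occurrence
coordinates and noiseless labels, and everything is a pure function of
(config, seed).

Ortholog sets substitute residues at `background_rate` outside planted
motifs and `motif_rate` inside (no indels, so true alignments are
gapless).  What the generator does *not* emulate: domain architecture,
phylogenetic correlation between family members, indel evolution, motif
degeneracy gradients.  Passing tests therefore demonstrate that the
machinery recovers a planted complementarity rule under realistic sparsity
and noise — not that real families obey that rule.

## Problem sizes and numerical choices

The test and acceptance configuration uses top_k = 50 candidate pairs,
100 trees, 50 reassignment retrainings and 10 noise seeds per fraction —
sizes chosen so the full analysis re-runs from scratch in minutes on one
CPU while leaving wide margins on every property it checks.  All
tie-breaks (candidate ranking, clustering, importance-based drops,
best-hit selection) are lexicographic and therefore platform-independent;
every stochastic component takes an explicit seed.  Scores with degenerate
denominators (no predicted or no true positives) are reported as 0 with a
`degenerate` flag rather than NaN, because mutants with empty predicted
patterns do occur.

## Known limitations

Discovery is O(positive pairs × substring pairs); it is comfortable at
family scale (≤ a few hundred proteins) and makes no attempt at index
structures.  The enrichment score and wildcard rule are reasonable
defaults, not reconstructions of the original tooling's unpublished
choices.  The forest's probability threshold is fixed (default 0.5), with
no ROC machinery.  Leave-family-out CV is implemented but has no
reference numbers.  Real cross-species performance depends on motif
strictness effects that the synthetic generator does not model.
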