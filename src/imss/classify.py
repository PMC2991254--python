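"""Training: motif-pair features, clustering, forest, feature selection.

The classifier works on a binary feature matrix whose rows are labeled
unordered protein pairs and whose columns are motif pairs (1 when the
protein pair supports the motif pair).  Before selection, near-duplicate
columns are merged by GROMOS-style greedy clustering on the Jaccard
similarity of their occurrence sets; a Random Forest is then pruned by
backward feature elimination scored by the out-of-bag F-score, keeping the
smallest feature set within one standard error of the best.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .interactions import InteractionDataset, Label, Pair, canonical_pair
from .motifs import (
    DiscoveryParams,
    Motif,
    MotifPair,
    discover_motif_pairs,
    generalize_to_consensus,
    motif_matches,
    rescore_pair,
)
from .records import ProteinRecord
from .scoring import ScoreReport, score

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Binary presence of motif pairs across labeled protein pairs."""

    pairs: list[Pair]
    X: pd.DataFrame  # rows align with ``pairs``; columns are motif-pair ids
    y: np.ndarray  # 1 = interacting, 0 = non-interacting


def _motif_hit_table(
    motif_pairs: list[MotifPair], seqs: dict[str, ProteinRecord], ids: list[str]
) -> dict[str, dict[str, bool]]:
    motifs: dict[str, Motif] = {}
    for mp in motif_pairs:
        for m in mp.motifs():
            motifs.setdefault(f"{m.pattern}/{m.max_mismatch}", m)
    return {
        key: {pid: motif_matches(m, seqs[pid]) for pid in ids}
        for key, m in motifs.items()
    }


def _pair_feature(mp: MotifPair, hits, a: str, b: str) -> bool:
    hx = hits[f"{mp.motif_x.pattern}/{mp.motif_x.max_mismatch}"]
    hy = hits[f"{mp.motif_y.pattern}/{mp.motif_y.max_mismatch}"]
    return (hx[a] and hy[b]) or (hx[b] and hy[a])


def build_feature_matrix(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    motif_pairs: list[MotifPair],
) -> FeatureMatrix:
    """Binary features over the dataset's labeled pairs (unknowns excluded)."""
    rows = list(data.labeled_pairs())
    ids = sorted({p for (pair, _) in rows for p in pair})
    hits = _motif_hit_table(motif_pairs, seqs, ids)
    pairs = [pair for pair, _ in rows]
    y = np.array([1 if lab is Label.INTERACTING else 0 for _, lab in rows])
    X = pd.DataFrame(
        {
            mp.pair_id: [_pair_feature(mp, hits, a, b) for (a, b) in pairs]
            for mp in motif_pairs
        },
        index=pd.Index(range(len(pairs))),
        dtype=np.int8,
    )
    return FeatureMatrix(pairs=pairs, X=X, y=y)


# ---------------------------------------------------------------------------
# GROMOS clustering


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]


def cluster_motif_pairs(features: FeatureMatrix, cutoff: float) -> list[Cluster]:
    """Greedy neighbor-count clustering of feature columns.

    Similarity between two columns is the Jaccard index of their occurrence
    sets: pairs where both fire divided by pairs where at least one fires.
    Repeatedly the unassigned column with the most unassigned neighbors at
    similarity >= cutoff becomes a representative and absorbs them.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0,1]")
    cols = list(features.X.columns)
    if not cols:
        return []
    V = features.X.to_numpy(dtype=bool)
    inter = (V[:, :, None] & V[:, None, :]).sum(axis=0).astype(float)
    union = (V[:, :, None] | V[:, None, :]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)

    unassigned = set(range(len(cols)))
    clusters: list[Cluster] = []
    while unassigned:
        best = None
        for i in sorted(unassigned):
            nbrs = [j for j in unassigned if j != i and sim[i, j] >= cutoff]
            if best is None or len(nbrs) > len(best[1]):
                best = (i, nbrs)
        rep, nbrs = best
        members = sorted([rep] + nbrs)
        clusters.append(
            Cluster(representative=cols[rep], members=tuple(cols[j] for j in members))
        )
        unassigned -= set(members)
    return clusters


# ---------------------------------------------------------------------------
# forest + backward elimination


@dataclass
class SelectionParams:
    n_estimators: int = 500
    drop_fraction: float = 0.2
    threshold: float = 0.5
    homodimer_weight: float = 1.0


@dataclass
class TrainedModel:
    """Selected motif-pair features plus the fitted ensemble."""

    selected_pairs: list[MotifPair]
    forest: RandomForestClassifier
    threshold: float
    training_summary: ScoreReport  # resubstitution scores on the training pairs
    oob_summary: ScoreReport | None = None  # out-of-bag scores (held-out proxy)
    elimination_path: list[tuple[int, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    # runtime-only (not serialized): training rows and their OOB probabilities
    training_pairs: list[Pair] = field(default_factory=list)
    oob_proba: np.ndarray | None = None

    @property
    def feature_ids(self) -> list[str]:
        return [mp.pair_id for mp in self.selected_pairs]


def _oob_labels(rf: RandomForestClassifier, y: np.ndarray, threshold: float) -> np.ndarray:
    proba = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    base_rate = float(np.mean(y))
    proba = np.where(np.isnan(proba), base_rate, proba)
    return (proba >= threshold).astype(int)


def _fit_forest(
    X: pd.DataFrame,
    y: np.ndarray,
    params: SelectionParams,
    seed: int,
    sample_weight: np.ndarray | None,
) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=params.n_estimators,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small data: some rows may never be OOB
        rf.fit(X.to_numpy(), y, sample_weight=sample_weight)
    return rf


def select_features(
    features: FeatureMatrix,
    params: SelectionParams,
    seed: int,
    sample_weight: np.ndarray | None = None,
) -> TrainedModel:
    """Backward elimination of motif-pair features by OOB F-score.

    Repeatedly fit the forest, drop the lowest-importance fraction of
    columns, and track the OOB F-score; return the smallest feature set
    whose OOB F is within one standard error of the best, refit on it.
    ``selected_pairs`` are filled in by the pipeline wrapper; here the
    model's feature columns are returned via ``params['selected_columns']``.
    """
    y = features.y
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present for training")
    cols = list(features.X.columns)
    path: list[tuple[list[str], float]] = []
    while cols:
        rf = _fit_forest(features.X[cols], y, params, seed, sample_weight)
        f = score(_oob_labels(rf, y, params.threshold), y).fscore
        path.append((cols.copy(), f))
        if len(cols) == 1:
            break
        imp = rf.feature_importances_
        n_drop = max(1, int(round(params.drop_fraction * len(cols))))
        if n_drop >= len(cols):
            n_drop = len(cols) - 1
        order = sorted(range(len(cols)), key=lambda i: (imp[i], cols[i]))
        dropped = set(order[:n_drop])
        cols = [c for i, c in enumerate(cols) if i not in dropped]

    best_f = max(f for _, f in path)
    n = len(y)
    se = float(np.sqrt(max(best_f * (1 - best_f), 0.0) / n))
    eligible = [(c, f) for c, f in path if f >= best_f - se]
    chosen_cols, _ = min(eligible, key=lambda cf: (len(cf[0]), cf[0]))

    rf = _fit_forest(features.X[chosen_cols], y, params, seed, sample_weight)
    proba = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    proba = np.where(np.isnan(proba), float(np.mean(y)), proba)
    oob = (proba >= params.threshold).astype(int)
    resub = rf.predict_proba(features.X[chosen_cols].to_numpy())
    resub_labels = (resub[:, list(rf.classes_).index(1)] >= params.threshold).astype(int)
    return TrainedModel(
        selected_pairs=[],
        forest=rf,
        threshold=params.threshold,
        training_summary=score(resub_labels, y),
        oob_summary=score(oob, y),
        elimination_path=[(len(c), f) for c, f in path],
        params={"selected_columns": chosen_cols, "seed": seed, **asdict(params)},
        training_pairs=list(features.pairs),
        oob_proba=proba,
    )


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """End-to-end configuration: discovery, clustering, selection."""

    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    generalize: bool = True
    cluster_cutoff: float = 0.8
    selection: SelectionParams = field(default_factory=SelectionParams)
    cv_scope: str = "full"  # rerun discovery inside each CV fold
    seed: int = 0


def fit_pipeline(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    config: PipelineConfig,
) -> TrainedModel:
    """Discovery -> consensus -> clustering -> selection, in one call."""
    discovered = discover_motif_pairs(data, seqs, config.discovery)
    if not discovered:
        raise ValueError("discovery produced no motif pairs")
    if config.generalize:
        seen: dict[str, MotifPair] = {}
        for mp in discovered:
            gen = generalize_to_consensus(mp, seqs, config.discovery)
            if gen.pair_id != mp.pair_id:
                gen = rescore_pair(gen, data, seqs)
            seen.setdefault(gen.pair_id, gen)
        discovered = list(seen.values())
    features = build_feature_matrix(data, seqs, discovered)

    clusters = cluster_motif_pairs(features, config.cluster_cutoff)
    reps = [c.representative for c in clusters]
    by_id = {mp.pair_id: mp for mp in discovered}
    features = FeatureMatrix(features.pairs, features.X[reps], features.y)

    weight = None
    if config.selection.homodimer_weight != 1.0:
        weight = np.array(
            [
                config.selection.homodimer_weight if a == b else 1.0
                for (a, b) in features.pairs
            ]
        )
    model = select_features(features, config.selection, config.seed, weight)
    model.selected_pairs = [by_id[c] for c in model.params["selected_columns"]]
    return model


def model_feature_vector(
    model: TrainedModel, seqs: dict[str, ProteinRecord], pairs: list[Pair]
) -> np.ndarray:
    """Features for query pairs, built exactly as in training."""
    ids = sorted({p for pair in pairs for p in pair})
    short = [pid for pid in ids if len(seqs[pid]) < max(len(mp.motif_x.pattern) for mp in model.selected_pairs)]
    if short:
        logger.info("sequences shorter than motif length (all-zero features): %s", short)
    hits = _motif_hit_table(model.selected_pairs, seqs, ids)
    return np.array(
        [
            [_pair_feature(mp, hits, a, b) for mp in model.selected_pairs]
            for (a, b) in pairs
        ],
        dtype=np.int8,
    )


def predict_proba_pairs(
    model: TrainedModel, seqs: dict[str, ProteinRecord], pairs: list[Pair]
) -> np.ndarray:
    X = model_feature_vector(model, seqs, pairs)
    proba = model.forest.predict_proba(X)
    return proba[:, list(model.forest.classes_).index(1)]


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    per_protein: dict[str, float]
    mean: float
    sd: float


def loo_cv(
    data: InteractionDataset,
    seqs: dict[str, ProteinRecord],
    config: PipelineConfig,
    groups: dict[str, str] | None = None,
) -> CVReport:
    """Leave-one-protein-out cross-validation.

    For each held-out protein (or group, when ``groups`` maps proteins to
    e.g. subfamilies) every pair involving it is removed, the pipeline is
    re-run on the remainder (including discovery when ``cv_scope='full'``),
    and the held-out pairs are scored by F.
    """
    proteins = sorted(data.proteins)
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins for leave-one-out CV")
    if groups is None:
        groups = {p: p for p in proteins}
    group_names = sorted(set(groups.values()))

    base_pairs: list[MotifPair] | None = None
    if config.cv_scope == "classify_only":
        base_pairs = discover_motif_pairs(data, seqs, config.discovery)

    per: dict[str, float] = {}
    for g in group_names:
        held = {p for p in proteins if groups[p] == g}
        test_rows = [
            (pair, lab)
            for pair, lab in data.labeled_pairs()
            if held & set(pair)
        ]
        if not test_rows:
            logger.warning("group %s has no labeled pairs; skipped", g)
            continue
        train = InteractionDataset(
            proteins,
            {
                pair: lab
                for pair, lab in data.pairs.items()
                if not (held & set(pair))
            },
        )
        if config.cv_scope == "classify_only":
            pairs = [rescore_pair(mp, train, seqs) for mp in base_pairs]
            features = build_feature_matrix(train, seqs, pairs)
            clusters = cluster_motif_pairs(features, config.cluster_cutoff)
            features = FeatureMatrix(
                features.pairs, features.X[[c.representative for c in clusters]], features.y
            )
            model = select_features(features, config.selection, config.seed)
            by_id = {mp.pair_id: mp for mp in pairs}
            model.selected_pairs = [by_id[c] for c in model.params["selected_columns"]]
        else:
            try:
                model = fit_pipeline(train, seqs, config)
            except ValueError as exc:
                logger.warning("fold %s: pipeline failed (%s); F = 0", g, exc)
                per[g] = 0.0
                continue
        probs = predict_proba_pairs(model, seqs, [pair for pair, _ in test_rows])
        pred = probs >= model.threshold
        truth = [lab is Label.INTERACTING for _, lab in test_rows]
        per[g] = score(pred, truth).fscore

    values = np.array(list(per.values()))
    return CVReport(per_protein=per, mean=float(values.mean()), sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: str) -> None:
    """Versioned JSON metadata plus a joblib sidecar for the ensemble."""
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "threshold": model.threshold,
        "params": {k: v for k, v in model.params.items()},
        "training_summary": asdict(model.training_summary),
        "oob_summary": asdict(model.oob_summary) if model.oob_summary else None,
        "elimination_path": model.elimination_path,
        "motif_pairs": [
            {
                "pair_id": mp.pair_id,
                "pattern_x": mp.motif_x.pattern,
                "pattern_y": mp.motif_y.pattern,
                "d": mp.motif_x.max_mismatch,
                "support_pos": mp.support_pos,
                "support_neg": mp.support_neg,
                "score": mp.score,
            }
            for mp in model.selected_pairs
        ],
        "forest_file": str(path) + ".joblib",
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)
    joblib.dump(model.forest, str(path) + ".joblib")


def load_model(path: str) -> TrainedModel:
    with open(path) as fh:
        meta = json.load(fh)
    if meta["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {meta['schema_version']}")
    pairs = [
        MotifPair(
            pair_id=d["pair_id"],
            motif_x=Motif(d["pattern_x"], d["pattern_x"], d["d"]),
            motif_y=Motif(d["pattern_y"], d["pattern_y"], d["d"]),
            support_pos=d["support_pos"],
            support_neg=d["support_neg"],
            score=d["score"],
        )
        for d in meta["motif_pairs"]
    ]
    forest = joblib.load(meta["forest_file"])
    return TrainedModel(
        selected_pairs=pairs,
        forest=forest,
        threshold=meta["threshold"],
        training_summary=ScoreReport(**meta["training_summary"]),
        oob_summary=ScoreReport(**meta["oob_summary"]) if meta.get("oob_summary") else None,
        elimination_path=[tuple(x) for x in meta["elimination_path"]],
        params=meta["params"],
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


class ImssClassifier(BaseEstimator, ClassifierMixin):
    """Interaction classifier over pairs of protein sequences.

    X is an (n_samples, 2) array-like of amino-acid sequence strings (the
    two members of each candidate pair); y is binary (1 = interacting).
    The estimator runs the full pipeline -- correlated motif-pair
    discovery, wildcard consensus, occurrence clustering, Random-Forest
    backward elimination -- and predicts interaction probabilities for new
    sequence pairs.  Composable with sklearn model selection at the pair
    level; use :func:`loo_cv` for protein-level hold-out.
    """

    def __init__(
        self,
        l: int = 8,
        d: int = 2,
        top_k: int = 200,
        min_support: int = 3,
        wildcard_threshold: float = 0.6,
        generalize: bool = True,
        cluster_cutoff: float = 0.8,
        n_estimators: int = 500,
        drop_fraction: float = 0.2,
        threshold: float = 0.5,
        homodimer_weight: float = 1.0,
        random_state: int = 0,
    ):
        self.l = l
        self.d = d
        self.top_k = top_k
        self.min_support = min_support
        self.wildcard_threshold = wildcard_threshold
        self.generalize = generalize
        self.cluster_cutoff = cluster_cutoff
        self.n_estimators = n_estimators
        self.drop_fraction = drop_fraction
        self.threshold = threshold
        self.homodimer_weight = homodimer_weight
        self.random_state = random_state

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            discovery=DiscoveryParams(
                l=self.l,
                d=self.d,
                top_k=self.top_k,
                min_support=self.min_support,
                wildcard_threshold=self.wildcard_threshold,
                seed=self.random_state,
            ),
            generalize=self.generalize,
            cluster_cutoff=self.cluster_cutoff,
            selection=SelectionParams(
                n_estimators=self.n_estimators,
                drop_fraction=self.drop_fraction,
                threshold=self.threshold,
                homodimer_weight=self.homodimer_weight,
            ),
            seed=self.random_state,
        )

    @staticmethod
    def _as_pairs(X) -> list[tuple[str, str]]:
        pairs = [(str(row[0]), str(row[1])) for row in np.asarray(X, dtype=object)]
        if any(len(row) != 2 for row in np.asarray(X, dtype=object)):
            raise ValueError("X must have exactly two sequence columns")
        return pairs

    def _registry(self, pairs: list[tuple[str, str]]):
        """Map distinct sequences to stable synthetic protein ids."""
        ids: dict[str, str] = {}
        for sa, sb in pairs:
            for s in (sa, sb):
                if s not in ids:
                    ids[s] = f"SEQ{len(ids):04d}"
        return ids

    def fit(self, X, y):
        pairs = self._as_pairs(X)
        y = np.asarray(y).astype(int)
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        ids = self._registry(pairs)
        seqs = {pid: ProteinRecord(pid, s) for s, pid in ids.items()}
        data = InteractionDataset(sorted(seqs))
        for (sa, sb), label in zip(pairs, y):
            data.add_pair(
                ids[sa], ids[sb], Label.INTERACTING if label else Label.NON_INTERACTING
            )
        self.model_ = fit_pipeline(data, seqs, self._config())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        self.selected_pair_ids_ = self.model_.feature_ids
        self.oob_fscore_ = self.model_.oob_summary.fscore
        return self

    def predict_proba(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("estimator is not fitted")
        pairs = self._as_pairs(X)
        seqs = {}
        query = []
        for k, (sa, sb) in enumerate(pairs):
            ia, ib = f"QA{k}", f"QB{k}"
            seqs[ia] = ProteinRecord(ia, sa)
            seqs[ib] = ProteinRecord(ib, sb)
            query.append(canonical_pair(ia, ib))
        p1 = predict_proba_pairs(self.model_, seqs, query)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)
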