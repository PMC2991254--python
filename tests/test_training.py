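import numpy as np
import pandas as pd
import pytest

import imss.classify as classify
from imss.classify import (
    FeatureMatrix,
    ImssClassifier,
    SelectionParams,
    cluster_motif_pairs,
    fit_pipeline,
    load_model,
    loo_cv,
    predict_proba_pairs,
    save_model,
    select_features,
)
from imss.interactions import Label
from imss.scoring import fscore


def matrix_from(columns: dict[str, list[int]], y=None) -> FeatureMatrix:
    n = len(next(iter(columns.values())))
    X = pd.DataFrame(columns, dtype=np.int8)
    pairs = [(f"P{i}", f"Q{i}") for i in range(n)]
    if y is None:
        y = np.zeros(n, dtype=int)
    return FeatureMatrix(pairs=pairs, X=X, y=np.asarray(y))


# ---------------------------------------------------------------------------
# GROMOS clustering


def test_identical_columns_merge():
    fm = matrix_from({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]})
    clusters = cluster_motif_pairs(fm, cutoff=0.9)
    assert len(clusters) == 1 and set(clusters[0].members) == {"a", "b"}


def test_disjoint_columns_stay_singletons():
    fm = matrix_from({"a": [1, 0, 0], "b": [0, 1, 0], "c": [0, 0, 1]})
    clusters = cluster_motif_pairs(fm, cutoff=0.1)
    assert sorted(len(c.members) for c in clusters) == [1, 1, 1]


def test_invalid_cutoff_rejected():
    fm = matrix_from({"a": [1, 0]})
    for bad in (0.0, 1.5, -0.1):
        with pytest.raises(ValueError):
            cluster_motif_pairs(fm, cutoff=bad)


def gromos_oracle(columns: dict[str, set[int]], cutoff: float) -> list[set[str]]:
    """Independent set-based reimplementation of the greedy clustering rule."""

    def jaccard(a, b):
        union = columns[a] | columns[b]
        return len(columns[a] & columns[b]) / len(union) if union else 0.0

    unassigned = sorted(columns)
    clusters = []
    while unassigned:
        best_rep, best_nbrs = None, None
        for rep in unassigned:
            nbrs = [c for c in unassigned if c != rep and jaccard(rep, c) >= cutoff]
            if best_nbrs is None or len(nbrs) > len(best_nbrs):
                best_rep, best_nbrs = rep, nbrs
        cluster = {best_rep, *best_nbrs}
        clusters.append(cluster)
        unassigned = [c for c in unassigned if c not in cluster]
    return clusters


@pytest.mark.parametrize("seed", range(10))
def test_clustering_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    cols = {f"c{i}": rng.integers(0, 2, size=15).tolist() for i in range(10)}
    fm = matrix_from(cols)
    got = [set(c.members) for c in cluster_motif_pairs(fm, cutoff=0.5)]
    sets = {k: {i for i, v in enumerate(vals) if v} for k, vals in cols.items()}
    expected = gromos_oracle(sets, 0.5)
    assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


def test_clustering_is_partition(family, pipeline_config, trained):
    from imss.classify import build_feature_matrix

    records, data, _ = family
    fm = build_feature_matrix(data, records, trained.selected_pairs)
    clusters = cluster_motif_pairs(fm, cutoff=0.8)
    members = [m for c in clusters for m in c.members]
    assert sorted(members) == sorted(fm.X.columns)
    assert len(members) == len(set(members))


# ---------------------------------------------------------------------------
# feature selection


def test_perfect_feature_survives_to_final_set():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=100)
    cols = {"signal": y.tolist()}
    for i in range(9):
        cols[f"noise{i}"] = rng.integers(0, 2, size=100).tolist()
    fm = matrix_from(cols, y)
    model = select_features(fm, SelectionParams(n_estimators=100), seed=0)
    assert "signal" in model.params["selected_columns"]
    assert model.oob_summary.fscore == 1.0


def test_single_class_labels_rejected():
    fm = matrix_from({"a": [1, 0, 1]}, [1, 1, 1])
    with pytest.raises(ValueError, match="both labels"):
        select_features(fm, SelectionParams(n_estimators=10), seed=0)


def test_planted_features_recovered_across_seeds():
    """3 informative out of 50 columns: all 3 selected in >= 90% of runs."""
    hits = 0
    n_runs = 20
    for seed in range(n_runs):
        rng = np.random.default_rng(1000 + seed)
        n = 120
        planted = {f"planted{i}": rng.random(n) < 0.25 for i in range(3)}
        y = (planted["planted0"] | planted["planted1"] | planted["planted2"]).astype(int)
        cols = {k: v.astype(int).tolist() for k, v in planted.items()}
        for i in range(47):
            cols[f"noise{i:02d}"] = (rng.random(n) < 0.25).astype(int).tolist()
        fm = matrix_from(cols, y)
        model = select_features(fm, SelectionParams(n_estimators=100), seed=seed)
        if all(f"planted{i}" in model.params["selected_columns"] for i in range(3)):
            hits += 1
    assert hits >= int(0.9 * n_runs)


def test_all_noise_features_score_at_chance_level():
    rng = np.random.default_rng(7)
    n = 150
    y = (rng.random(n) < 0.3).astype(int)
    cols = {f"n{i}": (rng.random(n) < 0.3).astype(int).tolist() for i in range(20)}
    fm = matrix_from(cols, y)
    model = select_features(fm, SelectionParams(n_estimators=100), seed=0)
    pi = y.mean()
    baseline = 2 * pi / (1 + pi)  # always-predict-interacting F
    assert model.oob_summary.fscore <= baseline + 0.1


def test_selection_deterministic_given_seed():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=80)
    cols = {f"c{i}": rng.integers(0, 2, size=80).tolist() for i in range(12)}
    m1 = select_features(matrix_from(cols, y), SelectionParams(n_estimators=50), seed=5)
    m2 = select_features(matrix_from(cols, y), SelectionParams(n_estimators=50), seed=5)
    assert m1.params["selected_columns"] == m2.params["selected_columns"]
    assert m1.elimination_path == m2.elimination_path


# ---------------------------------------------------------------------------
# leave-one-protein-out CV


def sub_dataset(data, records, n):
    ids = sorted(records)[:n]
    return classify.InteractionDataset(
        ids, {p: l for p, l in data.pairs.items() if set(p) <= set(ids)}
    )


def small_config():
    from imss.classify import PipelineConfig
    from imss.motifs import DiscoveryParams

    return PipelineConfig(
        discovery=DiscoveryParams(top_k=20, min_support=1, seed=1),
        selection=SelectionParams(n_estimators=60),
        seed=1,
    )


def test_loo_holds_out_all_pairs_of_each_protein(family, monkeypatch):
    records, data, _ = family
    seen_train = []
    real_fit = classify.fit_pipeline

    def spy(train_data, seqs, config):
        seen_train.append(train_data)
        return real_fit(train_data, seqs, config)

    monkeypatch.setattr(classify, "fit_pipeline", spy)
    sub_ids = sorted(records)[:10]
    sub_data = sub_dataset(data, records, 10)
    report = loo_cv(sub_data, records, small_config())
    assert len(seen_train) == len(report.per_protein)
    held_out = set()
    for train_data in seen_train:
        absent = {
            pid
            for pid in sub_ids
            if not any(pid in pair for pair in train_data.pairs)
        }
        assert absent, "each fold must fully exclude at least one protein"
        held_out |= absent
    assert held_out == set(report.per_protein)


def test_cv_mean_matches_per_protein_values(family):
    records, data, _ = family
    sub_data = sub_dataset(data, records, 10)
    report = loo_cv(sub_data, records, small_config())
    assert report.mean == pytest.approx(
        np.mean(list(report.per_protein.values())), abs=1e-12
    )
    assert all(0 <= f <= 1 for f in report.per_protein.values())


def test_loo_requires_three_proteins(family, pipeline_config):
    records, data, _ = family
    with pytest.raises(ValueError, match="at least 3"):
        loo_cv(classify.InteractionDataset(["A", "B"]), records, pipeline_config)


# ---------------------------------------------------------------------------
# serialization & estimator facade


def test_model_round_trip_reproduces_predictions(tmp_path, family, trained):
    records, data, _ = family
    path = tmp_path / "model.json"
    save_model(trained, str(path))
    back = load_model(str(path))
    query = [pair for pair, _ in data.labeled_pairs()][:40]
    np.testing.assert_array_equal(
        predict_proba_pairs(trained, records, query),
        predict_proba_pairs(back, records, query),
    )
    assert back.feature_ids == trained.feature_ids


def test_estimator_sklearn_contract(family):
    from sklearn.base import clone

    records, data, _ = family
    rows = [
        (records[a].sequence, records[b].sequence)
        for (a, b), _ in data.labeled_pairs()
    ]
    y = [1 if lab is Label.INTERACTING else 0 for _, lab in data.labeled_pairs()]
    clf = ImssClassifier(top_k=30, n_estimators=80, random_state=0)
    clone(clf)  # get_params/set_params round trip
    clf.fit(rows, y)
    assert list(clf.classes_) == [0, 1]
    proba = clf.predict_proba(rows[:10])
    assert proba.shape == (10, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    # a skilled fit on noiseless planted data classifies its training pairs well
    assert fscore(clf.predict(rows), y) >= 0.9


def test_training_summary_reproduced_by_self_prediction(family, trained):
    records, data, _ = family
    probs = predict_proba_pairs(trained, records, trained.training_pairs)
    pred = probs >= trained.threshold
    truth = [data.pairs[p] is Label.INTERACTING for p in trained.training_pairs]
    assert fscore(pred, truth) == pytest.approx(trained.training_summary.fscore)
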