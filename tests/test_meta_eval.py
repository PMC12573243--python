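import numpy as np
import pytest

from metanet.errors import ConfigurationError, InputError, ParameterError
from metanet.meta_autoencoder import MetaRepresentation
from metanet.meta_eval import (SCOPE_CATEGORY, SCOPE_MODALITY, EvalReport,
                               baseline_raw_weights, evaluate,
                               fit_meta_classifier, predict_dataset,
                               predict_dataset_batch, predict_modality,
                               read_embeddings_csv, tsne_coords,
                               write_confusion_csv, write_embeddings_csv)


# ---------------------------------------------------------------------------
# brute-force kNN oracle: full distance sort + majority vote, same tie rule

def knn_oracle(X, labels, k, query):
    d = np.sqrt(((X - query) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:k]
    neigh = [labels[i] for i in idx]
    counts = {}
    for lab in neigh:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    means = {lab: np.mean([d[i] for i in idx if labels[i] == lab]) for lab in tied}
    lo = min(means.values())
    return sorted(lab for lab, m in means.items() if m == lo)[0]


def make_refs(rng, n=200, dim=16, n_labels=8):
    X = rng.standard_normal((n, dim))
    labels = [f"sv:{i % n_labels}" for i in range(n)]
    return X, labels


def test_knn_matches_bruteforce_oracle(rng):
    X, labels = make_refs(rng)
    clf = fit_meta_classifier(list(zip(X, labels)), k=10)
    queries = rng.standard_normal((50, 16))
    predicted = predict_dataset_batch(clf, queries)
    expected = [knn_oracle(X, labels, 10, q) for q in queries]
    assert predicted == expected


def test_unanimous_neighborhood(rng):
    X = np.vstack([np.zeros((10, 4)), np.ones((10, 4)) * 5])
    labels = ["a"] * 10 + ["b"] * 10
    clf = fit_meta_classifier(list(zip(X, labels)), k=10)
    assert predict_dataset(clf, np.zeros(4)) == "a"


def test_k1_nearest(rng):
    X = np.array([[0.0], [1.0], [4.0]])
    clf = fit_meta_classifier(list(zip(X, ["x", "y", "z"])), k=1)
    assert predict_dataset(clf, np.array([0.9])) == "y"


def test_vote_tie_broken_by_mean_distance():
    X = np.array([[0.0], [0.2], [1.0], [1.1]])
    labels = ["a", "b", "b", "a"]
    clf = fit_meta_classifier(list(zip(X, labels)), k=4)
    # query 0: a-distances {0, 1.1} mean 0.55; b {0.2, 1.0} mean 0.6 -> a
    assert predict_dataset(clf, np.array([0.0])) == "a"


def test_vote_tie_lexicographic_label():
    X = np.array([[-1.0], [1.0]])
    clf = fit_meta_classifier(list(zip(X, ["b", "a"])), k=2)
    # equal votes and equal mean distances -> lexicographically first
    assert predict_dataset(clf, np.array([0.0])) == "a"


def test_fit_requires_k_points(rng):
    X, labels = make_refs(rng, n=5)
    with pytest.raises(ParameterError):
        fit_meta_classifier(list(zip(X, labels)), k=10)
    with pytest.raises(ParameterError):
        fit_meta_classifier([], k=1)


def test_query_dimension_checked(rng):
    X, labels = make_refs(rng, n=20)
    clf = fit_meta_classifier(list(zip(X, labels)), k=3)
    with pytest.raises(InputError):
        predict_dataset(clf, np.zeros(5))


def test_predict_modality_maps_and_errors(rng):
    X = np.zeros((10, 3))
    clf = fit_meta_classifier(list(zip(X, ["v:aer"] * 10)), k=5)
    assert predict_modality(clf, np.zeros(3), {"v:aer": "vision"}) == "vision"
    with pytest.raises(ConfigurationError):
        predict_modality(clf, np.zeros(3), {"sa:3": "B"})


# ---------------------------------------------------------------------------
# evaluation protocol

def mk_emb(vec, did, modality, split="validation", seed=0):
    return MetaRepresentation(np.asarray(vec, dtype=float), did, modality, seed, split)


def two_cluster_embeddings(rng, n_per=20):
    """Two well-separated dataset clusters, one per modality."""
    train, val = [], []
    for i, (did, mod, center) in enumerate([("sv:0", "A", 0.0), ("sa:0", "B", 10.0)]):
        pts = rng.standard_normal((n_per, 16)) * 0.1 + center
        for j, p in enumerate(pts):
            split = "train" if j < n_per // 2 else "validation"
            (train if split == "train" else val).append(mk_emb(p, did, mod, split))
    return train, val


def test_perfect_toy_evaluation(rng):
    train, val = two_cluster_embeddings(rng)
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    modality_map = {"sv:0": "A", "sa:0": "B"}
    rep_m = evaluate(clf, val, SCOPE_MODALITY, modality_map)
    rep_c = evaluate(clf, val, SCOPE_CATEGORY)
    assert rep_m.modality_accuracy == 1.0
    assert rep_c.category_accuracy == 1.0
    conf = rep_c.confusion
    assert (conf == np.diag(np.diag(conf))).all()


def test_confusion_row_sums_match_counts(rng):
    train, val = two_cluster_embeddings(rng, n_per=14)
    # add noise so predictions are imperfect, counts must still balance
    for e in val:
        e.m = e.m + rng.standard_normal(16) * 8
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    rep = evaluate(clf, val, SCOPE_CATEGORY)
    labels = rep.confusion_labels
    per_dataset = {d: sum(1 for e in val if e.dataset_id == d) for d in labels}
    for lab, row in zip(labels, rep.confusion):
        assert row.sum() == per_dataset[lab]
    assert rep.confusion.sum() == len(val)


def test_modality_at_least_category_accuracy(rng):
    """Label coarsening: a correct dataset prediction is a correct modality
    prediction, so modality accuracy dominates."""
    train, val = two_cluster_embeddings(rng, n_per=16)
    for e in val:
        e.m = e.m + rng.standard_normal(16) * 6
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    modality_map = {"sv:0": "A", "sa:0": "B"}
    rep_m = evaluate(clf, val, SCOPE_MODALITY, modality_map)
    rep_c = evaluate(clf, val, SCOPE_CATEGORY)
    assert rep_m.modality_accuracy >= rep_c.category_accuracy


def test_category_scope_restricts_to_reference_datasets(rng):
    train, val = two_cluster_embeddings(rng)
    heldout = [mk_emb(rng.standard_normal(16), "sv:9", "A") for _ in range(5)]
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    rep = evaluate(clf, val + heldout, SCOPE_CATEGORY)
    assert rep.n_eval == len(val)


def test_evaluate_empty_set(rng):
    train, _ = two_cluster_embeddings(rng)
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    with pytest.raises(InputError):
        evaluate(clf, [], SCOPE_MODALITY, {})


def test_chance_levels(rng):
    train, val = two_cluster_embeddings(rng)
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    rep_m = evaluate(clf, val, SCOPE_MODALITY, {"sv:0": "A", "sa:0": "B"})
    rep_c = evaluate(clf, val, SCOPE_CATEGORY)
    assert rep_m.modality_chance == 0.5
    assert rep_c.category_chance == 0.5  # two reference datasets


# ---------------------------------------------------------------------------
# raw-weight baseline

def test_baseline_uses_4096_dims(tiny_zoo):
    rep = baseline_raw_weights(tiny_zoo, k=3)
    assert rep.input_dim == 4096
    assert rep.n_eval == len(tiny_zoo.split("validation"))


def test_baseline_matches_oracle_on_toy_zoo(tiny_zoo):
    k = 3
    train = tiny_zoo.split("train")
    val = tiny_zoo.split("validation")
    X = np.stack([n.W.reshape(-1) for n in train])
    labels = [n.dataset_id for n in train]
    clf = fit_meta_classifier(list(zip(X, labels)), k=k)
    predicted = predict_dataset_batch(clf, np.stack([n.W.reshape(-1) for n in val]))
    expected = [knn_oracle(X, labels, k, n.W.reshape(-1)) for n in val]
    assert predicted == expected


def test_baseline_and_meta_score_same_nets(tiny_zoo, tiny_meta):
    from metanet.meta_autoencoder import embed_zoo

    unitwise, interunit = tiny_meta
    embs = [e for e in embed_zoo(tiny_zoo, unitwise, interunit) if e.split == "validation"]
    base = baseline_raw_weights(tiny_zoo, k=3)
    assert base.n_eval == len(embs)


# ---------------------------------------------------------------------------
# t-SNE

def test_tsne_shape_and_determinism(rng):
    X = rng.standard_normal((60, 16))
    a = tsne_coords(X, perplexity=5, seed=3)
    b = tsne_coords(X, perplexity=5, seed=3)
    assert a.shape == (60, 2)
    np.testing.assert_allclose(a, b)


def test_tsne_rejects_small_n(rng):
    with pytest.raises(ParameterError):
        tsne_coords(rng.standard_normal((20, 16)), perplexity=30, seed=0)


def test_tsne_separates_separated_clusters(rng):
    X = np.vstack([rng.standard_normal((30, 16)), rng.standard_normal((30, 16)) + 25])
    coords = tsne_coords(X, perplexity=5, seed=1)
    a, b = coords[:30], coords[30:]
    intra = np.linalg.norm(a - a.mean(0), axis=1).mean()
    inter = np.linalg.norm(a.mean(0) - b.mean(0))
    assert inter > intra


# ---------------------------------------------------------------------------
# writers

def test_embeddings_csv_roundtrip(tmp_path, rng):
    embs = [mk_emb(rng.standard_normal(16), f"sv:{i}", "A", seed=i) for i in range(5)]
    path = tmp_path / "emb.csv"
    write_embeddings_csv(embs, path)
    loaded = read_embeddings_csv(path)
    for a, b in zip(embs, loaded):
        np.testing.assert_array_equal(a.m, b.m)
        assert a.dataset_id == b.dataset_id and a.replicate_seed == b.replicate_seed


def test_confusion_csv_written(tmp_path, rng):
    train, val = two_cluster_embeddings(rng)
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k=3)
    rep = evaluate(clf, val, SCOPE_CATEGORY)
    path = tmp_path / "confusion.csv"
    write_confusion_csv(rep, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == len(rep.confusion_labels) + 1
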