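"""kNN classification of embedded networks and the evaluation protocol.

The meta-classifier is a k-nearest-neighbour vote over the reference
embeddings of the training split, labelled by dataset id.  Modality
predictions coarsen the predicted dataset id through a dataset ->
modality map, so held-out datasets (which have no labelled references)
can still be scored at the modality level.  A raw-weight baseline runs
the identical protocol on the flattened 4096-d weight matrices.

Tie handling is explicit and deterministic: the majority label wins;
vote ties are broken by the smallest mean neighbour distance, then by
lexicographic label order.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, InputError, ParameterError
from .first_order_zoo import ModelZoo
from .meta_autoencoder import MetaRepresentation

SCOPE_MODALITY = "modality_all_datasets"
SCOPE_CATEGORY = "category_train_datasets"


@dataclass
class MetaClassifier:
    """Frozen kNN reference set over embeddings labelled by dataset id."""

    X: np.ndarray
    labels: list[str]
    k: int
    metric: str = "euclidean"
    _nn: NearestNeighbors = field(init=False, repr=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise ParameterError("reference set must be a non-empty 2-D array")
        if self.X.shape[0] < self.k:
            raise ParameterError(f"need at least k={self.k} reference points, "
                                 f"got {self.X.shape[0]}")
        if len(self.labels) != self.X.shape[0]:
            raise ParameterError("one label per reference point required")
        self._nn = NearestNeighbors(n_neighbors=self.k, algorithm="brute", metric=self.metric)
        self._nn.fit(self.X)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def reference_label_set(self) -> set[str]:
        return set(self.labels)


def fit_meta_classifier(train_embeddings: list[tuple[np.ndarray, str]], k: int,
                        metric: str = "euclidean") -> MetaClassifier:
    """Store the labelled reference embeddings; kNN needs no iterative training."""
    if not train_embeddings:
        raise ParameterError("empty reference set")
    X = np.stack([np.asarray(v, dtype=np.float64) for v, _ in train_embeddings])
    labels = [label for _, label in train_embeddings]
    return MetaClassifier(X, labels, k, metric)


def _vote(labels: list[str], dists: np.ndarray) -> str:
    """Majority vote; ties -> smallest mean neighbour distance -> lexicographic."""
    counts = Counter(labels)
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    means = {lab: np.mean([d for l, d in zip(labels, dists) if l == lab]) for lab in tied}
    lo = min(means.values())
    closest = sorted(lab for lab, m in means.items() if m == lo)
    return closest[0]


def predict_dataset(clf: MetaClassifier, query: np.ndarray) -> str:
    """Predicted dataset id for one query embedding."""
    return predict_dataset_batch(clf, np.asarray(query)[None])[0]


def predict_dataset_batch(clf: MetaClassifier, queries: np.ndarray) -> list[str]:
    queries = np.asarray(queries, dtype=np.float64)
    if queries.ndim != 2 or queries.shape[1] != clf.dim:
        raise InputError(f"queries must be (N, {clf.dim}), got {queries.shape}")
    dists, idx = clf._nn.kneighbors(queries)
    out = []
    for row_d, row_i in zip(dists, idx):
        out.append(_vote([clf.labels[j] for j in row_i], row_d))
    return out


def predict_modality(clf: MetaClassifier, query: np.ndarray,
                     modality_map: dict[str, str]) -> str:
    """Predict the dataset id, then coarsen it to a modality tag."""
    did = predict_dataset(clf, query)
    if did not in modality_map:
        raise ConfigurationError(f"dataset id {did!r} has no modality mapping")
    return modality_map[did]


@dataclass
class EvalReport:
    """Accuracies and bookkeeping of one evaluation pass."""

    scope: str
    n_eval: int
    modality_accuracy: float | None = None
    category_accuracy: float | None = None
    modality_chance: float | None = None
    category_chance: float | None = None
    confusion: np.ndarray | None = None
    confusion_labels: list[str] | None = None
    input_dim: int | None = None

    def to_dict(self) -> dict:
        out = {"scope": self.scope, "n_eval": self.n_eval,
               "modality_accuracy": self.modality_accuracy,
               "category_accuracy": self.category_accuracy,
               "modality_chance": self.modality_chance,
               "category_chance": self.category_chance,
               "input_dim": self.input_dim}
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
            out["confusion_labels"] = self.confusion_labels
        return out


def evaluate(clf: MetaClassifier, embeddings: list[MetaRepresentation], scope: str,
             modality_map: dict[str, str] | None = None) -> EvalReport:
    """Score validation embeddings at the requested granularity.

    ``modality_all_datasets`` scores every embedding's modality
    (held-out datasets included); ``category_train_datasets`` scores the
    dataset id over embeddings whose dataset appears in the reference
    set, and also builds the per-dataset confusion matrix.
    """
    if scope not in (SCOPE_MODALITY, SCOPE_CATEGORY):
        raise ParameterError(f"unknown scope {scope!r}")
    if not embeddings:
        raise InputError("empty evaluation set")

    if scope == SCOPE_CATEGORY:
        ref = clf.reference_label_set()
        embeddings = [e for e in embeddings if e.dataset_id in ref]
        if not embeddings:
            raise InputError("no evaluation embeddings belong to reference datasets")

    queries = np.stack([e.m for e in embeddings])
    predicted = predict_dataset_batch(clf, queries)
    report = EvalReport(scope=scope, n_eval=len(embeddings), input_dim=clf.dim)

    if scope == SCOPE_MODALITY:
        if modality_map is None:
            raise ConfigurationError("modality scope requires a dataset -> modality map")
        missing = {p for p in predicted if p not in modality_map}
        if missing:
            raise ConfigurationError(f"dataset ids with no modality mapping: {sorted(missing)}")
        hits = sum(modality_map[p] == e.modality_tag for p, e in zip(predicted, embeddings))
        report.modality_accuracy = hits / len(embeddings)
        report.modality_chance = 1.0 / len({e.modality_tag for e in embeddings})
    else:
        labels = sorted({e.dataset_id for e in embeddings} | clf.reference_label_set())
        index = {lab: i for i, lab in enumerate(labels)}
        confusion = np.zeros((len(labels), len(labels)), dtype=int)
        hits = 0
        for p, e in zip(predicted, embeddings):
            confusion[index[e.dataset_id], index[p]] += 1
            hits += p == e.dataset_id
        report.category_accuracy = hits / len(embeddings)
        report.category_chance = 1.0 / len(clf.reference_label_set())
        report.confusion = confusion
        report.confusion_labels = labels
    return report


def embeddings_from_zoo_weights(zoo: ModelZoo, split: str) -> list[MetaRepresentation]:
    """Flattened 4096-d weight 'embeddings' — reuses the provenance carrier.

    The MetaRepresentation shape check does not apply here, so build the
    records directly.
    """
    out = []
    for net in zoo.split(split):
        rec = MetaRepresentation.__new__(MetaRepresentation)
        rec.m = net.W.reshape(-1)
        rec.dataset_id = net.dataset_id
        rec.modality_tag = net.modality_tag
        rec.replicate_seed = net.replicate_seed
        rec.split = net.split
        out.append(rec)
    return out


def baseline_raw_weights(zoo: ModelZoo, k: int, metric: str = "euclidean",
                         scope: str = SCOPE_CATEGORY,
                         modality_map: dict[str, str] | None = None) -> EvalReport:
    """Identical kNN protocol with the flattened 4096-d weight matrix as input."""
    train = embeddings_from_zoo_weights(zoo, "train")
    val = embeddings_from_zoo_weights(zoo, "validation")
    clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train], k, metric)
    if modality_map is None:
        modality_map = zoo.modality_of()
    return evaluate(clf, val, scope, modality_map)


def tsne_coords(embeddings: np.ndarray, perplexity: float, seed: int) -> np.ndarray:
    """Seeded 2-D t-SNE of the embedding matrix."""
    from sklearn.manifold import TSNE

    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise InputError("embeddings must be a 2-D array")
    if X.shape[0] <= 3 * perplexity:
        raise ParameterError(f"need more than {3 * perplexity} points for "
                             f"perplexity {perplexity}, got {X.shape[0]}")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# Writers

def write_report_json(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)


def write_confusion_csv(report: EvalReport, path) -> None:
    if report.confusion is None:
        raise InputError("report has no confusion matrix")
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["true\\predicted"] + report.confusion_labels)
        for lab, row in zip(report.confusion_labels, report.confusion):
            writer.writerow([lab] + [int(v) for v in row])


def write_embeddings_csv(embeddings: list[MetaRepresentation], path) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        dim = embeddings[0].m.size if embeddings else 0
        writer.writerow(["dataset_id", "modality_tag", "replicate_seed", "split"]
                        + [f"m{i}" for i in range(dim)])
        for e in embeddings:
            writer.writerow([e.dataset_id, e.modality_tag, e.replicate_seed, e.split]
                            + [repr(float(v)) for v in e.m])


def read_embeddings_csv(path) -> list[MetaRepresentation]:
    out = []
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader)
        n_meta = len(header) - 4
        for row in reader:
            vec = np.array([float(v) for v in row[4 : 4 + n_meta]])
            rec = MetaRepresentation.__new__(MetaRepresentation)
            rec.m, rec.dataset_id, rec.modality_tag = vec, row[0], row[1]
            rec.replicate_seed, rec.split = int(row[2]), row[3]
            out.append(rec)
    return out
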