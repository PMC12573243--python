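"""End-to-end experiment runner with stage caching and a run manifest.

Stages: synthetic suite -> first-order zoo -> meta-autoencoder ->
embeddings -> evaluation.  Each stage's output file name carries a hash
of the config subtree it depends on (including upstream hashes), so
rerunning an unchanged config reuses cached artifacts, while any
relevant config change invalidates exactly the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import ExperimentConfig, subtree_hash, validate_config
from .errors import MetanetError
from .first_order_zoo import ModelZoo, load_zoo, save_zoo, train_zoo
from .meta_autoencoder import (embed_zoo, load_meta, save_meta, train_interunit,
                               train_unitwise)
from .meta_eval import (SCOPE_CATEGORY, SCOPE_MODALITY, baseline_raw_weights,
                        evaluate, fit_meta_classifier, read_embeddings_csv,
                        tsne_coords, write_confusion_csv, write_embeddings_csv,
                        write_report_json)
from .synthetic_data import load_suite, make_synthetic_suite, save_suite

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: dict
    paths: dict[str, Path]
    manifest: dict
    embeddings: list = field(repr=False, default_factory=list)


def run_experiment(config, progress: bool = False) -> ExperimentResult:
    """Execute (or resume) the full pipeline described by ``config``."""
    config = validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    paths: dict[str, Path] = {}

    def stage(name, cache_key, filename, build, load):
        path = out_dir / filename
        t0 = time.perf_counter()
        if config.cache and path.exists():
            logger.info("stage %s: reusing cached %s", name, path.name)
            result = load(path)
            cached = True
        else:
            try:
                result = build(path)
            except MetanetError as exc:
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc
            cached = False
        stages[name] = {"hash": cache_key, "path": path.name, "cached": cached,
                        "checksum": _sha256(path), "wall_seconds": time.perf_counter() - t0}
        paths[name] = path
        if progress:
            print(f"stage {name}: {'cached' if cached else 'built'} "
                  f"({stages[name]['wall_seconds']:.1f}s)", flush=True)
        return result

    # -- suite --------------------------------------------------------------
    suite_hash = subtree_hash(config.suite, config.seed)

    def build_suite(path):
        cfg_a, cfg_b = config.modality_configs()
        entries = make_synthetic_suite(cfg_a, cfg_b, config.suite.n_patches_per_dataset)
        save_suite(entries, path)
        return entries

    suite = stage("suite", suite_hash, f"suite_{suite_hash}.h5", build_suite, load_suite)

    # -- first-order zoo ----------------------------------------------------
    zoo_hash = subtree_hash(config.first_order, suite_hash, config.seed)

    def build_zoo(path):
        fo = config.first_order
        zoo = train_zoo(suite, fo.n_models, fo.n_train, base_seed=config.seed,
                        epochs=fo.epochs, batch_size=fo.batch_size,
                        learning_rate=fo.learning_rate, progress=progress)
        save_zoo(zoo, path)
        return zoo

    zoo: ModelZoo = stage("zoo", zoo_hash, f"zoo_{zoo_hash}.h5", build_zoo, load_zoo)

    # -- meta-autoencoder (both stages, trained in sequence) ----------------
    meta_hash = subtree_hash(config.unitwise, config.interunit, zoo_hash, config.seed)
    losses_path = out_dir / f"meta_{meta_hash}.losses.json"

    def build_meta(path):
        uw = train_unitwise(zoo, epochs=config.unitwise.epochs, seed=config.seed,
                            batch_size=config.unitwise.batch_size,
                            learning_rate=config.unitwise.learning_rate)
        iu = train_interunit(zoo, uw, epochs=config.interunit.epochs, seed=config.seed + 1,
                             batch_size=config.interunit.batch_size,
                             learning_rate=config.interunit.learning_rate)
        save_meta(uw, iu, path)
        with open(losses_path, "w") as f:
            json.dump({"unitwise": {"initial": uw.initial_loss, "final": uw.final_loss},
                       "interunit": {"initial": iu.initial_loss, "final": iu.final_loss}},
                      f, indent=2)
        return uw, iu

    unitwise, interunit = stage("meta", meta_hash, f"meta_{meta_hash}.h5",
                                build_meta, load_meta)
    losses = json.loads(losses_path.read_text()) if losses_path.exists() else None

    # -- embeddings ---------------------------------------------------------
    embed_hash = subtree_hash(meta_hash)

    def build_embeddings(path):
        embs = embed_zoo(zoo, unitwise, interunit)
        write_embeddings_csv(embs, path)
        return embs

    embeddings = stage("embed", embed_hash, f"embeddings_{embed_hash}.csv",
                       build_embeddings, read_embeddings_csv)

    # -- evaluation (meta pipeline and raw-weight baseline) -----------------
    eval_hash = subtree_hash(config.knn, embed_hash)
    modality_map = zoo.modality_of()
    train_embs = [e for e in embeddings if e.split == "train"]
    val_embs = [e for e in embeddings if e.split == "validation"]

    def build_eval(path):
        clf = fit_meta_classifier([(e.m, e.dataset_id) for e in train_embs],
                                  config.knn.k, config.knn.metric)
        rep_mod = evaluate(clf, val_embs, SCOPE_MODALITY, modality_map)
        rep_cat = evaluate(clf, val_embs, SCOPE_CATEGORY, modality_map)
        base_mod = baseline_raw_weights(zoo, config.knn.k, config.knn.metric,
                                        SCOPE_MODALITY, modality_map)
        base_cat = baseline_raw_weights(zoo, config.knn.k, config.knn.metric,
                                        SCOPE_CATEGORY, modality_map)
        report = {
            "modality_accuracy": rep_mod.modality_accuracy,
            "category_accuracy": rep_cat.category_accuracy,
            "baseline_modality_accuracy": base_mod.modality_accuracy,
            "baseline_category_accuracy": base_cat.category_accuracy,
            "modality_chance": rep_mod.modality_chance,
            "category_chance": rep_cat.category_chance,
            "n_eval_modality": rep_mod.n_eval,
            "n_eval_category": rep_cat.n_eval,
            "confusion": rep_cat.confusion.tolist(),
            "confusion_labels": rep_cat.confusion_labels,
            "losses": losses,
        }
        write_report_json(report, path)
        write_confusion_csv(rep_cat, out_dir / f"confusion_{eval_hash}.csv")
        return report

    report = stage("eval", eval_hash, f"report_{eval_hash}.json", build_eval,
                   lambda p: json.loads(Path(p).read_text()))

    # -- optional t-SNE -----------------------------------------------------
    if config.tsne.enabled:
        tsne_hash = subtree_hash(config.tsne, embed_hash)

        def build_tsne(path):
            import numpy as np

            coords = tsne_coords(np.stack([e.m for e in val_embs]),
                                 config.tsne.perplexity, config.seed)
            with open(path, "w") as f:
                f.write("dataset_id,modality_tag,x,y\n")
                for e, (x, y) in zip(val_embs, coords):
                    f.write(f"{e.dataset_id},{e.modality_tag},{x!r},{y!r}\n")
            return coords

        stage("tsne", tsne_hash, f"tsne_{tsne_hash}.csv", build_tsne,
              lambda p: None)

    manifest = {
        "config": config.resolved_dict(),
        "seed": config.seed,
        "stages": stages,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    paths["manifest"] = out_dir / "manifest.json"

    return ExperimentResult(config=config, report=report, paths=paths,
                            manifest=manifest, embeddings=embeddings)


# ---------------------------------------------------------------------------
# Protocol planner (structural arithmetic, no data or compute)

@dataclass(frozen=True)
class ProtocolStub:
    """Counts-only description of an experiment protocol."""

    n_meta_train_datasets: int
    n_heldout_datasets: int
    n_models_per_dataset: int
    n_train_per_dataset: int
    k: int = 10
    meta_dim: int = 16


#: the full-scale replication protocol: 20 meta-training datasets
#: (10 vision + 5 + 5 audio), 21 additional held-out datasets
#: (10 vision + 11 audio), 600 nets per dataset split 500/100.
PAPER_SCALE_STUB = ProtocolStub(n_meta_train_datasets=20, n_heldout_datasets=21,
                                n_models_per_dataset=600, n_train_per_dataset=500)


def plan_protocol(stub: ProtocolStub) -> dict:
    """Derive the structural counts of a protocol from a counts-only stub."""
    n_val = stub.n_models_per_dataset - stub.n_train_per_dataset
    n_eval_datasets = stub.n_meta_train_datasets + stub.n_heldout_datasets
    return {
        "n_meta_train_datasets": stub.n_meta_train_datasets,
        "n_eval_datasets": n_eval_datasets,
        "nets_per_dataset": stub.n_models_per_dataset,
        "n_train_per_dataset": stub.n_train_per_dataset,
        "n_validation_per_dataset": n_val,
        "knn_reference_points": stub.n_meta_train_datasets * stub.n_train_per_dataset,
        "modality_eval_nets": n_eval_datasets * n_val,
        "category_eval_nets": stub.n_meta_train_datasets * n_val,
        "embedding_dim": stub.meta_dim,
        "k": stub.k,
    }
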