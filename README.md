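# metanet

Embed populations of small trained neural networks — via their weight
matrices alone — into a low-dimensional "meta-representation" space, and
show that a kNN classifier on those embeddings recovers the modality
(vision-like vs. audio-like) and the category of the data each network
was trained on.

The pipeline:

1. **Patch data** — 16×16 patches flattened to 256-vectors, either
   extracted from real images / WAV audio (`metanet.patch_extraction`)
   or generated synthetically with a controlled vision/audio
   second-order-statistics contrast (`metanet.synthetic_data`).
2. **First-order zoo** — many 256→16→256 autoencoders (linear bias-free
   encoder) trained per dataset; only the 256×16 encoder weight matrix
   is kept, labelled with its dataset and a train/validation split
   (`metanet.first_order_zoo`).
3. **Meta-autoencoder** — two stages trained in sequence
   (`metanet.meta_autoencoder`): a convolutional autoencoder compresses
   each of the 16 weight columns ("filters", viewed as 16×16 images) to
   a 3-d latent; the 16 latents are canonically sorted (making the
   embedding exactly invariant to hidden-unit permutations) and a linear
   48→16→48 autoencoder produces the final 16-d embedding.
4. **Evaluation** — a kNN (k=10) meta-classifier over the training
   embeddings predicts dataset ids; modality predictions coarsen the
   dataset id; a 4096-d raw-weight kNN baseline runs the same protocol;
   confusion matrix and optional t-SNE coordinates are written out
   (`metanet.meta_eval`).

All neural-network training runs on a small internal NumPy layer
(`metanet._nn`: conv/dense/batch-norm/max-pool, Glorot init, Adam, MSE)
— no deep-learning framework required, fully deterministic given seeds,
single CPU.

## CLI

End-to-end from a YAML config (all fields optional; defaults give the
desk-scale synthetic experiment):

```bash
metanet run --config experiment.yaml
```

Stage by stage:

```bash
metanet patches --modality vision --in images/ --out suite.h5 --n-patches 20000 --seed 0
metanet train-zoo --suite suite.h5 --n-models 60 --n-train 50 --seed 0 --out zoo.h5
metanet train-meta --zoo zoo.h5 --epochs 50 --seed 0 --out meta.h5
metanet embed --zoo zoo.h5 --meta meta.h5 --out embeddings.csv
metanet eval --zoo zoo.h5 --embeddings embeddings.csv --k 10 --out results/
metanet tsne --embeddings embeddings.csv --perplexity 30 --seed 0 --out tsne.csv
metanet plan            # structural counts of the full-scale protocol
metanet validate --config experiment.yaml
```

`metanet run` caches each stage keyed by a hash of the config subtree it
depends on, and writes a `manifest.json` with seeds, stage checksums and
wall times into the output directory.

## Configuration

See `metanet.config.ExperimentConfig` for the full schema. A minimal
example:

```yaml
seed: 1
out_dir: runs/demo
suite:
  n_patches_per_dataset: 20000
first_order: {n_models: 60, n_train: 50, epochs: 1}
unitwise: {epochs: 50}
interunit: {epochs: 50}
knn: {k: 10}
```
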