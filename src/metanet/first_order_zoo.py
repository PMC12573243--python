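"""Train and serialize the population of first-order autoencoders.

Each first-order network is a 256 -> 16 -> 256 autoencoder with a
linear, bias-free encoder; only the 256 x 16 encoder weight matrix is
kept.  A ModelZoo holds one labelled population per dataset with a
train/validation split fixed at construction time.  Replicate seeds are
derived solely from (base_seed, dataset_id, replicate index), so zoo
training is independent of execution order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from ._nn import DTYPE, Adam, Parameter, glorot_uniform, mse_loss
from .errors import FormatError, InputError, ParameterError, TrainingError
from .patch_extraction import PATCH_DIM, PatchMatrix

N_UNITS = 16
WEIGHT_SHAPE = (PATCH_DIM, N_UNITS)


@dataclass
class FirstOrderNet:
    """Encoder weights of one trained first-order autoencoder plus provenance."""

    W: np.ndarray
    dataset_id: str
    modality_tag: str
    replicate_seed: int
    split: str = "train"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.shape != WEIGHT_SHAPE:
            raise InputError(f"weight matrix must be {WEIGHT_SHAPE}, got {self.W.shape}")
        if not np.isfinite(self.W).all():
            raise InputError("weight matrix contains non-finite entries")
        if self.split not in ("train", "validation"):
            raise InputError(f"unknown split {self.split!r}")


@dataclass
class ModelZoo:
    nets: list[FirstOrderNet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nets)

    def dataset_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for net in self.nets:
            seen.setdefault(net.dataset_id, None)
        return list(seen)

    def modality_of(self) -> dict[str, str]:
        return {net.dataset_id: net.modality_tag for net in self.nets}

    def split(self, which: str) -> list[FirstOrderNet]:
        return [net for net in self.nets if net.split == which]

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for net in self.nets:
            d = out.setdefault(net.dataset_id, {"train": 0, "validation": 0})
            d[net.split] += 1
        return out


def train_first_order(patches: PatchMatrix, seed: int, epochs: int = 1,
                      batch_size: int = 256, learning_rate: float = 1e-3,
                      return_decoder: bool = False):
    """Train one 256->16->256 autoencoder and return its encoder weights.

    Glorot-uniform init, MSE loss, Adam.  The encoder is linear with no
    bias; the decoder (untied, with bias) is discarded after training
    unless ``return_decoder`` is set, in which case ``(net, V, b)`` is
    returned for diagnostics.
    """
    X = patches.values.astype(DTYPE)
    if X.shape[0] < 1:
        raise InputError("empty patch matrix")
    rng = np.random.default_rng(seed)
    W = Parameter(glorot_uniform(rng, WEIGHT_SHAPE, PATCH_DIM, N_UNITS))
    V = Parameter(glorot_uniform(rng, (N_UNITS, PATCH_DIM), N_UNITS, PATCH_DIM))
    b = Parameter(np.zeros(PATCH_DIM))
    opt = Adam([W, V, b], lr=learning_rate)
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = X[order[start : start + batch_size]]
            h = xb @ W.value
            out = h @ V.value + b.value
            loss, dout = mse_loss(out, xb)
            opt.zero_grad()
            V.grad += h.T @ dout
            b.grad += dout.sum(axis=0)
            dh = dout @ V.value.T
            W.grad += xb.T @ dh
            opt.step()
    if not np.isfinite(W.value).all():
        raise TrainingError("first-order training produced non-finite weights")
    net = FirstOrderNet(W.value, patches.source_dataset_id, patches.modality_tag, seed)
    if return_decoder:
        return net, V.value.astype(np.float64), b.value.astype(np.float64)
    return net


def reconstruction_mse(W: np.ndarray, V: np.ndarray, b: np.ndarray, X: np.ndarray) -> float:
    """Held-out reconstruction error of an encoder/decoder pair (test helper)."""
    out = (X @ W) @ V + b
    return float(np.mean((out - X) ** 2))


def _train_first_order_batch(patches: PatchMatrix, seeds: list[int], epochs: int,
                             batch_size: int, learning_rate: float) -> np.ndarray:
    """Train many first-order nets on one dataset simultaneously.

    Replicates ``train_first_order``'s arithmetic exactly per net — same
    per-seed init draws, shuffles, batch slices and Adam updates — but
    stacks the nets along a leading axis so every operation is one
    batched BLAS call (bit-identical to the per-net path, since all ops
    are elementwise or independent per batch slice).  Returns the
    stacked encoder weights, shape (n_nets, 256, 16).
    """
    X = patches.values.astype(DTYPE)
    n = X.shape[0]
    rngs = [np.random.default_rng(s) for s in seeds]
    m = len(rngs)
    W = Parameter(np.stack([glorot_uniform(r, WEIGHT_SHAPE, PATCH_DIM, N_UNITS) for r in rngs]))
    V = Parameter(np.stack([glorot_uniform(r, (N_UNITS, PATCH_DIM), N_UNITS, PATCH_DIM)
                            for r in rngs]))
    b = Parameter(np.zeros((m, 1, PATCH_DIM)))
    opt = Adam([W, V, b], lr=learning_rate)
    for _ in range(epochs):
        orders = np.stack([r.permutation(n) for r in rngs])
        for start in range(0, n, batch_size):
            xb = X[orders[:, start : start + batch_size]]  # (m, bs, 256)
            h = xb @ W.value
            out = h @ V.value + b.value
            dout = (2.0 / (xb.shape[1] * PATCH_DIM)) * (out - xb)
            opt.zero_grad()
            V.grad += np.swapaxes(h, 1, 2) @ dout
            b.grad += dout.sum(axis=1, keepdims=True)
            dh = dout @ np.swapaxes(V.value, 1, 2)
            W.grad += np.swapaxes(xb, 1, 2) @ dh
            opt.step()
    if not np.isfinite(W.value).all():
        raise TrainingError("first-order training produced non-finite weights")
    return W.value


def replicate_seed(base_seed: int, dataset_id: str, replicate: int) -> int:
    """Deterministic per-net seed from (base_seed, dataset_id, replicate index)."""
    ss = np.random.SeedSequence([base_seed, zlib.crc32(dataset_id.encode()), replicate])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def train_zoo(suite, n_models: int, n_train: int, base_seed: int, epochs: int = 1,
              batch_size: int = 256, learning_rate: float = 1e-3,
              progress: bool = False) -> ModelZoo:
    """Train ``n_models`` nets per dataset; the first ``n_train`` are the train split.

    ``suite`` is a list of objects with ``dataset_id`` and ``patches``
    attributes (see synthetic_data.SuiteEntry) or a dict
    dataset_id -> PatchMatrix.
    """
    if isinstance(suite, dict):
        items = [(did, pm) for did, pm in suite.items()]
    else:
        items = [(entry.dataset_id, entry.patches) for entry in suite]
    if not items:
        raise InputError("empty suite")
    if not (0 < n_train < n_models):
        raise ParameterError(f"need 0 < n_train ({n_train}) < n_models ({n_models})")
    nets = []
    for did, pm in items:
        seeds = [replicate_seed(base_seed, did, rep) for rep in range(n_models)]
        stacked = _train_first_order_batch(pm, seeds, epochs=epochs,
                                           batch_size=batch_size,
                                           learning_rate=learning_rate)
        for rep, seed in enumerate(seeds):
            nets.append(FirstOrderNet(stacked[rep], did, pm.modality_tag, seed,
                                      split="train" if rep < n_train else "validation"))
        if progress:
            print(f"  {did}: {n_models} nets trained", flush=True)
    return ModelZoo(nets)


def save_zoo(zoo: ModelZoo, path) -> None:
    """HDF5 container: one group per net with W plus label attributes."""
    import h5py

    manifest = []
    with h5py.File(path, "w") as f:
        for i, net in enumerate(zoo.nets):
            grp = f.create_group(f"net_{i:05d}")
            grp.create_dataset("W", data=net.W)
            grp.attrs["dataset_id"] = net.dataset_id
            grp.attrs["modality_tag"] = net.modality_tag
            grp.attrs["replicate_seed"] = net.replicate_seed
            grp.attrs["split"] = net.split
            manifest.append({"dataset_id": net.dataset_id, "modality_tag": net.modality_tag,
                             "split": net.split})
        f.attrs["manifest"] = json.dumps(manifest)


def load_zoo(path) -> ModelZoo:
    import h5py

    nets = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            grp = f[name]
            for attr in ("dataset_id", "modality_tag", "replicate_seed", "split"):
                if attr not in grp.attrs:
                    raise FormatError(f"group {name!r} missing attribute {attr!r}")
            if "W" not in grp:
                raise FormatError(f"group {name!r} missing weight matrix")
            try:
                net = FirstOrderNet(grp["W"][...], str(grp.attrs["dataset_id"]),
                                    str(grp.attrs["modality_tag"]),
                                    int(grp.attrs["replicate_seed"]),
                                    str(grp.attrs["split"]))
            except InputError as exc:
                raise FormatError(f"group {name!r}: {exc}") from exc
            nets.append(net)
    return ModelZoo(nets)
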