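"""Two-stage autoencoder over first-order weight matrices.

Stage 1 (unitwise): each of the 16 encoder columns ("filters"),
reshaped to 16 x 16, is compressed to a 3-vector by a convolutional
autoencoder (three conv + batch-norm + max-pool blocks, then two fully
connected layers; the decoder mirrors the encoder with nearest-
neighbour upsampling).  Stage 2 (interunit): the 16 filter latents are
canonically sorted, flattened to 48 values and compressed to the final
16-dimensional embedding by a linear autoencoder with biases.

The stages are trained in sequence because the sorting between them
depends on the trained stage-1 encoder.  Sorting makes the embedding
invariant to any permutation of the 16 hidden units (columns of W), as
long as the 16 latents are pairwise distinct.

Inference passes run sample by sample with batch-norm in running-
statistics mode, so an embedding never depends on what else is in the
batch — this is what makes the permutation invariance bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import (DTYPE, Adam, BatchNorm2d, Conv2d, Dense, Flatten, MaxPool2d,
                  ReLU, Reshape, Sequential, Upsample2d, mse_loss)
from .errors import FormatError, InputError, StateError, TrainingError
from .first_order_zoo import FirstOrderNet, ModelZoo

FILTER_SIDE = 16
N_FILTERS = 16
UNIT_LATENT_DIM = 3
META_DIM = 16
FLAT_DIM = N_FILTERS * UNIT_LATENT_DIM  # 48


@dataclass
class MetaRepresentation:
    """16-d embedding of one first-order network, with its provenance labels."""

    m: np.ndarray
    dataset_id: str
    modality_tag: str
    replicate_seed: int
    split: str

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=np.float64)
        if self.m.shape != (META_DIM,):
            raise InputError(f"meta-representation must have shape ({META_DIM},)")
        if not np.isfinite(self.m).all():
            raise InputError("meta-representation contains non-finite entries")


def filters_of(net: FirstOrderNet) -> list[np.ndarray]:
    """Column j of W reshaped row-major to 16 x 16, for j = 0..15."""
    W = np.asarray(net.W, dtype=np.float64)
    if W.shape != (FILTER_SIDE * FILTER_SIDE, N_FILTERS):
        raise InputError(f"expected a {FILTER_SIDE * FILTER_SIDE} x {N_FILTERS} weight matrix")
    return [W[:, j].reshape(FILTER_SIDE, FILTER_SIDE) for j in range(N_FILTERS)]


class UnitwiseAutoencoder:
    """Convolutional autoencoder mapping a 16 x 16 filter to a 3-d latent.

    Encoder: [Conv(1->8) BN ReLU Pool] x (8->16) x (16->32) -> flatten
    128 -> Dense 32 (ReLU) -> Dense 3 (linear).  Decoder mirrors with
    2x nearest-neighbour upsampling; the output conv is linear.
    """

    channels = (8, 16, 32)
    fc_hidden = 32

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels
        self.encoder = Sequential([
            Conv2d(1, c1, rng), BatchNorm2d(c1), ReLU(), MaxPool2d(),
            Conv2d(c1, c2, rng), BatchNorm2d(c2), ReLU(), MaxPool2d(),
            Conv2d(c2, c3, rng), BatchNorm2d(c3), ReLU(), MaxPool2d(),
            Flatten(),
            Dense(c3 * 4, self.fc_hidden, rng), ReLU(),
            Dense(self.fc_hidden, UNIT_LATENT_DIM, rng),
        ])
        # the gradient w.r.t. the raw input filter is never consumed
        self.encoder.layers[0].skip_input_grad = True
        self.decoder = Sequential([
            Dense(UNIT_LATENT_DIM, self.fc_hidden, rng), ReLU(),
            Dense(self.fc_hidden, c3 * 4, rng), ReLU(),
            Reshape(c3, 2, 2),
            Upsample2d(), Conv2d(c3, c2, rng), BatchNorm2d(c2), ReLU(),
            Upsample2d(), Conv2d(c2, c1, rng), BatchNorm2d(c1), ReLU(),
            Upsample2d(), Conv2d(c1, 1, rng),
        ])
        self.trained = False
        self.initial_loss: float | None = None
        self.final_loss: float | None = None
        # multiplicative input standardization, fitted from the training
        # filters; without it the tiny weight scale (std ~0.05) is far
        # below the unit scale that batch-norm imposes internally and the
        # reconstruction cannot beat the predict-zero baseline
        self.input_scale = np.ones(1, dtype=DTYPE)

    @property
    def latent_dim(self) -> int:
        return UNIT_LATENT_DIM

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x, training), training)

    def eval_loss(self, x: np.ndarray, chunk: int = 256) -> float:
        # chunked so a large evaluation set does not blow up im2col buffers
        total = 0.0
        for start in range(0, x.shape[0], chunk):
            xc = x[start : start + chunk]
            out = self._forward(xc, training=False)
            total += float(((out - xc) ** 2).sum())
        return total / x.size

    def fit(self, filters: np.ndarray, epochs: int = 50, batch_size: int = 128,
            learning_rate: float = 1e-3, seed: int = 0) -> float:
        """Train on (M, 16, 16) filters; returns the final training loss."""
        x = np.asarray(filters, dtype=DTYPE).reshape(-1, 1, FILTER_SIDE, FILTER_SIDE)
        if x.shape[0] < 1:
            raise InputError("no filters to train on")
        std = float(x.std())
        self.input_scale[0] = 1.0 / std if std > 0 else 1.0
        x = x * self.input_scale[0]
        rng = np.random.default_rng(seed)
        params = self.encoder.parameters() + self.decoder.parameters()
        opt = Adam(params, lr=learning_rate)
        self.initial_loss = self.eval_loss(x)
        n = x.shape[0]
        last = np.nan
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                xb = x[order[start : start + batch_size]]
                out = self._forward(xb, training=True)
                loss, dout = mse_loss(out, xb)
                opt.zero_grad()
                dlatent = self.decoder.backward(dout)
                self.encoder.backward(dlatent)
                opt.step()
                last = loss
        self.trained = True
        self.final_loss = self.eval_loss(x)
        if not np.isfinite(self.final_loss):
            raise TrainingError("unitwise training diverged")
        return self.final_loss

    def encode(self, filters: np.ndarray) -> np.ndarray:
        """Embed (M, 16, 16) filters to (M, 3), one sample at a time.

        Per-sample processing guarantees each latent is independent of
        the rest of the batch (bit-exact), which the permutation
        invariance of the full pipeline relies on.
        """
        if not self.trained:
            raise StateError("unitwise autoencoder is not trained")
        x = np.asarray(filters, dtype=DTYPE).reshape(-1, 1, FILTER_SIDE, FILTER_SIDE)
        x = x * self.input_scale[0]
        out = np.empty((x.shape[0], UNIT_LATENT_DIM))
        for i in range(x.shape[0]):
            out[i] = self.encoder.forward(x[i : i + 1], training=False)[0]
        return out

    def state(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.state().items()}
        out.update({f"decoder.{k}": v for k, v in self.decoder.state().items()})
        out["input_scale"] = self.input_scale
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in self.state().items():
            arr[...] = state[key]
        self.trained = True


class InterunitAutoencoder:
    """Linear 48 -> 16 -> 48 autoencoder with biases in both layers."""

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        self.enc = Dense(FLAT_DIM, META_DIM, rng)
        self.dec = Dense(META_DIM, FLAT_DIM, rng)
        self.trained = False
        self.initial_loss: float | None = None
        self.final_loss: float | None = None

    @property
    def latent_dim(self) -> int:
        return META_DIM

    def eval_loss(self, x: np.ndarray) -> float:
        out = self.dec.forward(self.enc.forward(x, training=False), training=False)
        return float(np.mean((out - x) ** 2))

    def fit(self, x: np.ndarray, epochs: int = 50, batch_size: int = 128,
            learning_rate: float = 1e-3, seed: int = 0) -> float:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim != 2 or x.shape[1] != FLAT_DIM:
            raise InputError(f"expected (M, {FLAT_DIM}) inputs, got {x.shape}")
        rng = np.random.default_rng(seed)
        opt = Adam(self.enc.parameters() + self.dec.parameters(), lr=learning_rate)
        self.initial_loss = self.eval_loss(x)
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                xb = x[order[start : start + batch_size]]
                out = self.dec.forward(self.enc.forward(xb, training=True), training=True)
                loss, dout = mse_loss(out, xb)
                opt.zero_grad()
                self.enc.backward(self.dec.backward(dout))
                opt.step()
        self.trained = True
        self.final_loss = self.eval_loss(x)
        if not np.isfinite(self.final_loss):
            raise TrainingError("interunit training diverged")
        return self.final_loss

    def encode(self, x: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("interunit autoencoder is not trained")
        x = np.asarray(x, dtype=DTYPE)
        single = x.ndim == 1
        x2 = x[None] if single else x
        out = np.empty((x2.shape[0], META_DIM))
        for i in range(x2.shape[0]):
            out[i] = self.enc.forward(x2[i : i + 1], training=False)[0]
        return out[0] if single else out

    def state(self) -> dict[str, np.ndarray]:
        out = {f"enc.{k}": v for k, v in self.enc.state().items()}
        out.update({f"dec.{k}": v for k, v in self.dec.state().items()})
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in self.state().items():
            arr[...] = state[key]
        self.trained = True


def _pooled_filters(nets: list[FirstOrderNet]) -> np.ndarray:
    """Stack all filters of all nets into an (16 * n_nets, 16, 16) array."""
    stacks = []
    for net in nets:
        stacks.extend(filters_of(net))
    return np.stack(stacks)


def train_unitwise(zoo: ModelZoo, epochs: int = 50, seed: int = 0,
                   batch_size: int = 128, learning_rate: float = 1e-3) -> UnitwiseAutoencoder:
    """Train stage 1 on the pooled filters of the zoo's train split."""
    train_nets = zoo.split("train")
    if not train_nets:
        raise InputError("zoo has no training nets")
    model = UnitwiseAutoencoder(seed=seed)
    model.fit(_pooled_filters(train_nets), epochs=epochs, batch_size=batch_size,
              learning_rate=learning_rate, seed=seed + 1)
    return model


def embed_filter(params: UnitwiseAutoencoder, f: np.ndarray) -> np.ndarray:
    """Encode one 16 x 16 filter to its 3-d latent (inference mode)."""
    f = np.asarray(f, dtype=np.float64)
    if f.shape != (FILTER_SIDE, FILTER_SIDE):
        raise InputError(f"filter must be {FILTER_SIDE} x {FILTER_SIDE}")
    return params.encode(f[None])[0]


def sort_filters(latents, expected_count: int = N_FILTERS) -> np.ndarray:
    """Sort latent rows ascending by first coordinate, ties by second then third.

    The lexicographic total order makes the result depend only on the
    *set* of latents, not their input order.
    """
    z = np.asarray(latents, dtype=np.float64)
    if z.ndim != 2 or z.shape != (expected_count, UNIT_LATENT_DIM):
        raise InputError(f"expected {expected_count} latents of dimension {UNIT_LATENT_DIM}, "
                         f"got array of shape {z.shape}")
    order = np.lexsort((z[:, 2], z[:, 1], z[:, 0]))
    return z[order]


def _sorted_flat(net: FirstOrderNet, unitwise: UnitwiseAutoencoder) -> np.ndarray:
    latents = unitwise.encode(np.stack(filters_of(net)))
    return sort_filters(latents).reshape(-1)  # filter-major, row-major -> 48

def train_interunit(zoo: ModelZoo, unitwise: UnitwiseAutoencoder, epochs: int = 50,
                    seed: int = 0, batch_size: int = 128,
                    learning_rate: float = 1e-3) -> InterunitAutoencoder:
    """Train stage 2 on the sorted, flattened filter latents of the train split."""
    if not unitwise.trained:
        raise StateError("unitwise stage must be trained first")
    train_nets = zoo.split("train")
    if not train_nets:
        raise InputError("zoo has no training nets")
    x = np.stack([_sorted_flat(net, unitwise) for net in train_nets])
    model = InterunitAutoencoder(seed=seed)
    model.fit(x, epochs=epochs, batch_size=batch_size, learning_rate=learning_rate,
              seed=seed + 1)
    return model


def embed_network(net: FirstOrderNet, unitwise: UnitwiseAutoencoder,
                  interunit: InterunitAutoencoder) -> MetaRepresentation:
    """Full pipeline: filters -> 3-d latents -> sort -> flatten -> 16-d embedding."""
    if not unitwise.trained or not interunit.trained:
        raise StateError("both meta-autoencoder stages must be trained")
    m = interunit.encode(_sorted_flat(net, unitwise))
    return MetaRepresentation(m, net.dataset_id, net.modality_tag,
                              net.replicate_seed, net.split)


def embed_zoo(zoo: ModelZoo, unitwise: UnitwiseAutoencoder,
              interunit: InterunitAutoencoder) -> list[MetaRepresentation]:
    return [embed_network(net, unitwise, interunit) for net in zoo.nets]


# ---------------------------------------------------------------------------
# Serialization

def save_meta(unitwise: UnitwiseAutoencoder, interunit: InterunitAutoencoder, path) -> None:
    """Store both stages in one HDF5 file with a JSON architecture header."""
    import h5py

    arch = {
        "unitwise": {"channels": list(UnitwiseAutoencoder.channels),
                     "fc_hidden": UnitwiseAutoencoder.fc_hidden,
                     "latent_dim": UNIT_LATENT_DIM},
        "interunit": {"in_dim": FLAT_DIM, "latent_dim": META_DIM},
    }
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = json.dumps(arch)
        g1 = f.create_group("unitwise")
        for key, arr in unitwise.state().items():
            g1.create_dataset(key, data=arr)
        g2 = f.create_group("interunit")
        for key, arr in interunit.state().items():
            g2.create_dataset(key, data=arr)


def load_meta(path) -> tuple[UnitwiseAutoencoder, InterunitAutoencoder]:
    import h5py

    with h5py.File(path, "r") as f:
        if "architecture" not in f.attrs:
            raise FormatError("meta container missing architecture header")
        for group in ("unitwise", "interunit"):
            if group not in f:
                raise FormatError(f"meta container missing group {group!r}")
        unitwise = UnitwiseAutoencoder(seed=0)
        unitwise.load_state({k: f["unitwise"][k][...] for k in f["unitwise"]})
        interunit = InterunitAutoencoder(seed=0)
        interunit.load_state({k: f["interunit"][k][...] for k in f["interunit"]})
    return unitwise, interunit
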