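import itertools
from dataclasses import replace

import numpy as np
import pytest

from metanet.errors import InputError, StateError
from metanet.first_order_zoo import FirstOrderNet
from metanet.meta_autoencoder import (FLAT_DIM, META_DIM, UNIT_LATENT_DIM,
                                      InterunitAutoencoder, UnitwiseAutoencoder,
                                      embed_filter, embed_network, filters_of,
                                      load_meta, save_meta, sort_filters,
                                      train_interunit, train_unitwise)


# ---------------------------------------------------------------------------
# filters_of

def test_filters_of_shape_and_roundtrip(rng):
    W = rng.standard_normal((256, 16))
    net = FirstOrderNet(W, "d", "A", 0)
    filters = filters_of(net)
    assert len(filters) == 16
    for j, f in enumerate(filters):
        assert f.shape == (16, 16)
        np.testing.assert_array_equal(f.reshape(-1), W[:, j])


def test_filters_of_permutes_with_columns(rng):
    W = rng.standard_normal((256, 16))
    perm = rng.permutation(16)
    f1 = filters_of(FirstOrderNet(W, "d", "A", 0))
    f2 = filters_of(FirstOrderNet(W[:, perm], "d", "A", 0))
    for k, p in enumerate(perm):
        np.testing.assert_array_equal(f2[k], f1[p])


def test_filters_of_rejects_bad_shape():
    net = FirstOrderNet(np.zeros((256, 16)), "d", "A", 0)
    net.W = np.zeros((100, 16))  # bypass constructor validation
    with pytest.raises(InputError):
        filters_of(net)


# ---------------------------------------------------------------------------
# unitwise stage

def test_unitwise_latent_dim_is_3(tiny_meta):
    unitwise, _ = tiny_meta
    assert unitwise.latent_dim == UNIT_LATENT_DIM == 3


def test_unitwise_training_reduces_loss_on_structured_filters():
    """DERIVED: loss at init vs after training, on compressible inputs."""
    rng = np.random.default_rng(1)
    # low-rank structured "filters": outer products of a few smooth profiles
    basis = np.stack([np.sin(np.linspace(0, (k + 1) * np.pi, 16)) for k in range(3)])
    coeff = rng.standard_normal((512, 3, 2))
    filters = np.einsum("nki,kr->nir", coeff[:, :, :1], basis) * 0.05
    filters = filters.reshape(512, 16, 1) * basis[0][None, None, :]
    model = UnitwiseAutoencoder(seed=0)
    model.fit(filters, epochs=30, batch_size=128, seed=2)
    assert model.final_loss < model.initial_loss


def test_unitwise_determinism():
    rng = np.random.default_rng(3)
    filters = rng.standard_normal((64, 16, 16)) * 0.05
    m1 = UnitwiseAutoencoder(seed=9)
    m2 = UnitwiseAutoencoder(seed=9)
    l1 = m1.fit(filters, epochs=2, seed=4)
    l2 = m2.fit(filters, epochs=2, seed=4)
    assert l1 == l2
    np.testing.assert_array_equal(m1.encode(filters[:5]), m2.encode(filters[:5]))


def test_embed_filter_output_and_determinism(tiny_meta, rng):
    unitwise, _ = tiny_meta
    f = rng.standard_normal((16, 16)) * 0.1
    z1 = embed_filter(unitwise, f)
    z2 = embed_filter(unitwise, f)
    assert z1.shape == (3,)
    np.testing.assert_array_equal(z1, z2)


def test_embed_filter_batch_independent(tiny_meta, rng):
    """Two copies of one filter, batched with others or alone, embed
    identically (inference-mode batch-norm independence)."""
    unitwise, _ = tiny_meta
    f = rng.standard_normal((16, 16)) * 0.1
    others = rng.standard_normal((6, 16, 16)) * 0.1
    batch = np.concatenate([f[None], others, f[None]])
    z_batch = unitwise.encode(batch)
    z_single = embed_filter(unitwise, f)
    np.testing.assert_array_equal(z_batch[0], z_single)
    np.testing.assert_array_equal(z_batch[-1], z_single)


def test_embed_requires_training(rng):
    model = UnitwiseAutoencoder(seed=0)
    with pytest.raises(StateError):
        model.encode(rng.standard_normal((1, 16, 16)))


def test_unitwise_encoder_matches_naive_reimplementation(tiny_meta, rng):
    """Stage-1 oracle: re-run the encoder arithmetic with naive loops on the
    stored parameter arrays and compare to embed_filter (tolerance 1e-5)."""
    unitwise, _ = tiny_meta
    state = unitwise.state()

    def naive_conv(x, W, b):  # x: (C, H, W); W: (O, C*9)
        C, H, Wd = x.shape
        O = W.shape[0]
        Wk = W.reshape(O, C, 3, 3).astype(np.float64)
        xp = np.zeros((C, H + 2, Wd + 2))
        xp[:, 1:-1, 1:-1] = x
        out = np.zeros((O, H, Wd))
        for o in range(O):
            for i in range(H):
                for j in range(Wd):
                    out[o, i, j] = (Wk[o] * xp[:, i : i + 3, j : j + 3]).sum() + b[o]
        return out

    def naive_bn(x, prefix):
        g = state[f"encoder.{prefix}.gamma"].astype(np.float64)
        be = state[f"encoder.{prefix}.beta"].astype(np.float64)
        rm = state[f"encoder.{prefix}.running_mean"].astype(np.float64)
        rv = state[f"encoder.{prefix}.running_var"].astype(np.float64)
        return g[:, None, None] * (x - rm[:, None, None]) / np.sqrt(rv[:, None, None] + 1e-5) \
            + be[:, None, None]

    def naive_pool(x):
        C, H, W = x.shape
        out = np.zeros((C, H // 2, W // 2))
        for c in range(C):
            for i in range(H // 2):
                for j in range(W // 2):
                    out[c, i, j] = x[c, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max()
        return out

    f = (rng.standard_normal((16, 16)) * 0.1)
    x = (f[None].astype(np.float32) * state["input_scale"][0]).astype(np.float64)
    for li, prefix in ((0, 1), (4, 5), (8, 9)):
        x = naive_conv(x, state[f"encoder.{li}.W"].astype(np.float64),
                       state[f"encoder.{li}.b"].astype(np.float64))
        x = naive_bn(x, prefix)
        x = np.maximum(x, 0.0)
        x = naive_pool(x)
    v = x.reshape(-1)
    v = np.maximum(v @ state["encoder.13.W"].astype(np.float64)
                   + state["encoder.13.b"].astype(np.float64), 0.0)
    expected = v @ state["encoder.15.W"].astype(np.float64) \
        + state["encoder.15.b"].astype(np.float64)

    np.testing.assert_allclose(embed_filter(unitwise, f), expected, atol=1e-5)


# ---------------------------------------------------------------------------
# sorting

def test_sort_filters_idempotent(rng):
    z = np.sort(rng.standard_normal((16, 3)), axis=0)
    np.testing.assert_array_equal(sort_filters(z), z[np.lexsort((z[:, 2], z[:, 1], z[:, 0]))])
    s = sort_filters(z)
    np.testing.assert_array_equal(sort_filters(s), s)


def test_sort_filters_all_permutations_of_toy_instance(rng):
    """DERIVED: exhaustive check over all 3! row orders of a 3-row instance."""
    z = rng.standard_normal((3, 3))
    outputs = {sort_filters(z[list(p)], expected_count=3).tobytes()
               for p in itertools.permutations(range(3))}
    assert len(outputs) == 1


def test_sort_filters_reversal_invariant(rng):
    z = rng.standard_normal((16, 3))
    np.testing.assert_array_equal(sort_filters(z), sort_filters(z[::-1]))


def test_sort_filters_tie_break_total_order():
    z = np.array([[1.0, 2.0, 3.0], [1.0, 1.0, 5.0], [1.0, 1.0, 4.0]])
    out = sort_filters(z, expected_count=3)
    np.testing.assert_array_equal(out, [[1.0, 1.0, 4.0], [1.0, 1.0, 5.0], [1.0, 2.0, 3.0]])


def test_sort_filters_wrong_count(rng):
    with pytest.raises(InputError):
        sort_filters(rng.standard_normal((15, 3)))


# ---------------------------------------------------------------------------
# interunit stage

def test_interunit_dims(tiny_meta):
    _, interunit = tiny_meta
    assert interunit.enc.W.value.shape == (FLAT_DIM, META_DIM) == (48, 16)
    assert interunit.dec.W.value.shape == (META_DIM, FLAT_DIM)


def test_interunit_training_reduces_loss(tiny_zoo, tiny_meta):
    unitwise, _ = tiny_meta
    model = train_interunit(tiny_zoo, unitwise, epochs=20, seed=8)
    assert model.final_loss < model.initial_loss


def test_interunit_single_point_capacity():
    """A linear AE with a 16-d bottleneck can represent one 48-d point."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal((1, FLAT_DIM))
    model = InterunitAutoencoder(seed=1)
    model.fit(x, epochs=4000, batch_size=1, learning_rate=0.02, seed=3)
    assert model.final_loss < 1e-4
    assert model.final_loss < model.initial_loss * 1e-2


def test_interunit_requires_trained_unitwise(tiny_zoo):
    with pytest.raises(StateError):
        train_interunit(tiny_zoo, UnitwiseAutoencoder(seed=0), epochs=1, seed=0)


# ---------------------------------------------------------------------------
# full embedding

def test_embed_network_dimension(tiny_zoo, tiny_meta):
    unitwise, interunit = tiny_meta
    rep = embed_network(tiny_zoo.nets[0], unitwise, interunit)
    assert rep.m.shape == (META_DIM,)
    assert rep.dataset_id == tiny_zoo.nets[0].dataset_id


def test_embed_network_permutation_invariance(tiny_zoo, tiny_meta, rng):
    unitwise, interunit = tiny_meta
    net = tiny_zoo.nets[5]
    latents = unitwise.encode(np.stack(filters_of(net)))
    assert len(np.unique(latents[:, 0])) == 16  # tie-free first coordinates
    base = embed_network(net, unitwise, interunit).m
    for _ in range(4):
        perm = rng.permutation(16)
        permuted = replace(net, W=net.W[:, perm])
        np.testing.assert_array_equal(embed_network(permuted, unitwise, interunit).m, base)


def test_embed_network_requires_trained_stages(tiny_zoo):
    with pytest.raises(StateError):
        embed_network(tiny_zoo.nets[0], UnitwiseAutoencoder(seed=0),
                      InterunitAutoencoder(seed=0))


def test_meta_roundtrip_serialization(tiny_zoo, tiny_meta, tmp_path):
    unitwise, interunit = tiny_meta
    path = tmp_path / "meta.h5"
    save_meta(unitwise, interunit, path)
    uw2, iu2 = load_meta(path)
    net = tiny_zoo.nets[3]
    np.testing.assert_array_equal(embed_network(net, unitwise, interunit).m,
                                  embed_network(net, uw2, iu2).m)
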