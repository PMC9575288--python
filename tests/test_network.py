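"""Forward rules of the four extractors and the fusion head."""

import numpy as np
import pytest
from conftest import numeric_grad

from nerd import nn
from nerd._autograd import Tensor, conv1d, maxpool1d
from nerd.featurize import MolecularGraph, smiles_to_graph
from nerd.network import (AutoencoderSpec, CNNExtractor, Conv1DSpec, FusionHead,
                          FusionSpec, GCNExtractor, GCNSpec, GraphBatch,
                          NetworkSpec, NeRDNetwork, FeatureTensors,
                          cne_pretrain, conv_output_length, gcn_layer_forward,
                          mse_loss, normalized_adjacency, pool_output_length)


# -------------------------------------------------------------- GCN layer

def dense_gcn_oracle(H, A, W):
    """Explicit dense evaluation: relu(D^-1/2 (A+I) D^-1/2 H W)."""
    a_tilde = A + np.eye(A.shape[0])
    d = np.diag(1.0 / np.sqrt(a_tilde.sum(axis=1)))
    return np.maximum(d @ a_tilde @ d @ H @ W, 0.0)


def test_gcn_single_node_identity_propagation():
    out = gcn_layer_forward(np.array([[2.5]]), np.zeros((1, 1)), np.array([[1.0]]))
    np.testing.assert_allclose(out.numpy(), [[2.5]])


def test_gcn_two_connected_nodes_average():
    H = np.array([[2.0], [4.0]])
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = gcn_layer_forward(H, A, np.array([[1.0]]))
    np.testing.assert_allclose(out.numpy(), [[3.0], [3.0]])


def test_gcn_matches_dense_oracle_on_random_graphs(rng):
    for _ in range(100):
        n = int(rng.integers(1, 9))
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        H = rng.normal(size=(n, 4))
        W = rng.normal(size=(4, 3))
        out = gcn_layer_forward(H, A, W).numpy()
        np.testing.assert_allclose(out, dense_gcn_oracle(H, A, W), atol=1e-6)


def test_gcn_rejects_dimension_mismatch():
    with pytest.raises(ValueError, match="does not match"):
        gcn_layer_forward(np.ones((2, 3)), np.zeros((2, 2)), np.ones((4, 2)))


def test_normalized_adjacency_rejects_self_loops():
    with pytest.raises(ValueError, match="self-loops"):
        normalized_adjacency(np.eye(2))


# -------------------------------------------------------- conv/pool lengths

@pytest.mark.parametrize("L,f,expected", [(20, 8, 13), (881, 8, 874), (10, 2, 9)])
def test_conv_length_formula(L, f, expected):
    assert conv_output_length(L, f) == expected


def test_conv_pool_lengths_on_grid():
    for L in range(10, 1001, 37):
        for f in (2, 4, 8):
            assert conv_output_length(L, f) == (L - f) + 1
            assert pool_output_length(L, 3, 3) == L // 3


def test_conv1d_hand_example_and_delta_kernel(rng):
    x = Tensor(np.array([[[1.0, 2.0, 3.0]]]))
    w = Tensor(np.array([[[1.0, 0.0]]]))
    np.testing.assert_allclose(conv1d(x, w).numpy(), [[[1.0, 2.0]]])

    sig = rng.normal(size=(1, 1, 30))
    delta = np.zeros((1, 1, 8))
    delta[0, 0, 0] = 1.0
    out = conv1d(Tensor(sig), Tensor(delta)).numpy()
    np.testing.assert_allclose(out[0, 0], sig[0, 0, :23])


def test_conv1d_errors_on_short_input():
    with pytest.raises(ValueError, match="shorter than kernel"):
        conv1d(Tensor(np.ones((1, 1, 4))), Tensor(np.ones((1, 1, 8))))


def test_maxpool_examples_and_bounds(rng):
    x = Tensor(np.array([[[1.0, 3.0, 2.0, 5.0, 4.0, 6.0]]]))
    np.testing.assert_allclose(maxpool1d(x, 3, 3).numpy(), [[[3.0, 6.0]]])

    const = Tensor(np.full((1, 1, 10), 7.0))
    out = maxpool1d(const, 3, 3).numpy()
    assert out.shape[-1] == 10 // 3 and np.all(out == 7.0)

    for _ in range(100):
        L = int(rng.integers(3, 60))
        x = rng.normal(size=(1, 2, L))
        out = maxpool1d(Tensor(x), 3, 3).numpy()
        assert out.max() <= x.max() and out.min() >= x.min()


# ----------------------------------------------------------- CNN extractor

def test_mfe_stage_lengths_for_881_bit_input():
    """881 -> conv 874 -> pool 291 -> conv 284 -> pool 94 -> conv 87 -> pool 29."""
    spec = Conv1DSpec()
    lengths = [881]
    for _ in range(3):
        lengths.append(conv_output_length(lengths[-1], spec.kernel_size))
        lengths.append(pool_output_length(lengths[-1], spec.pool_window))
    assert lengths == [881, 874, 291, 284, 94, 87, 29]
    rng_ = np.random.default_rng(0)
    extractor = CNNExtractor(881, spec, rng_)
    assert extractor.flat_dim == 16 * 29
    out = extractor(Tensor(rng_.random((5, 881), dtype=np.float32)))
    assert out.shape == (5, 128)


def test_cnn_extractor_error_names_stage():
    with pytest.raises(ValueError, match="conv layer 1"):
        CNNExtractor(4, Conv1DSpec(), np.random.default_rng(0))
    with pytest.raises(ValueError, match="layer 3"):
        CNNExtractor(80, Conv1DSpec(), np.random.default_rng(0))


def test_zero_input_zero_bias_gives_zero_feature_maps():
    spec = Conv1DSpec()
    extractor = CNNExtractor(200, spec, np.random.default_rng(0), dtype=np.float64)
    x = Tensor(np.zeros((2, 1, 200)))
    assert np.all(extractor.body(x).numpy() == 0.0)


# ----------------------------------------------------------------- DSE

def test_dse_output_and_pooled_widths():
    spec = GCNSpec()
    assert spec.pooled_dim == 4 * 78 == 312
    extractor = GCNExtractor(spec, np.random.default_rng(0))
    batch = GraphBatch.from_graphs([smiles_to_graph("CCO"),
                                    smiles_to_graph("c1ccccc1")])
    out = extractor(batch)
    assert out.shape == (2, 128)


def test_dse_invariant_to_duplicating_the_molecule(rng):
    """Two disjoint copies of a molecule share the max-pooled embedding."""
    extractor = GCNExtractor(GCNSpec(), np.random.default_rng(3))
    for smiles in ["CCO", "c1ccncc1", "CC(C)CC", "CC(=O)OC", "CCSCC",
                   "c1ccccc1O", "CCNCC", "C1CCCCC1", "CCCC", "OCCO"]:
        g = smiles_to_graph(smiles)
        n = g.n_atoms
        X2 = np.vstack([g.node_features, g.node_features])
        A2 = np.zeros((2 * n, 2 * n), dtype=np.float32)
        A2[:n, :n] = g.adjacency
        A2[n:, n:] = g.adjacency
        doubled = MolecularGraph(X2, A2)
        single = extractor(GraphBatch.from_graphs([g])).numpy()
        double = extractor(GraphBatch.from_graphs([doubled])).numpy()
        np.testing.assert_allclose(single, double, atol=1e-5)


def test_graph_batch_rejects_empty_graph():
    g = smiles_to_graph("CCO")
    empty = MolecularGraph(np.zeros((0, 78)), np.zeros((0, 0)))
    with pytest.raises(ValueError, match="at least one atom"):
        GraphBatch.from_graphs([g, empty])


# ----------------------------------------------------------------- CNE

def test_mse_loss_hand_values():
    assert mse_loss(Tensor(np.array([1.0, 2.0])), np.array([1.0, 2.0])).item() == 0.0
    assert mse_loss(Tensor(np.array([1.0, 1.0])), np.array([0.0, 0.0])).item() == 1.0


def test_cne_bottleneck_width_and_determinism(rng):
    from nerd.network import StackedAutoencoder

    model = StackedAutoencoder(2000, AutoencoderSpec(), np.random.default_rng(0))
    model.eval()
    x = rng.random((3, 2000)).astype(np.float32)
    x[2] = x[0]  # identical cells
    z1 = model.encode(Tensor(x)).numpy()
    z2 = model.encode(Tensor(x)).numpy()
    assert z1.shape == (3, 256)
    np.testing.assert_array_equal(z1, z2)
    np.testing.assert_array_equal(z1[0], z1[2])


def test_cne_pretrain_beats_mean_baseline_on_low_rank_data(rng):
    from nerd.network import StackedAutoencoder

    m, dim, r = 80, 400, 5
    L = rng.normal(size=(m, r))
    B = rng.normal(size=(r, dim)) / np.sqrt(r)
    X = (L @ B + 0.05 * rng.normal(size=(m, dim))).astype(np.float32)
    X = (X - X.mean(0)) / X.std(0)
    model = StackedAutoencoder(dim, AutoencoderSpec(encoder_hidden=(128, 64),
                                                    bottleneck=16),
                               np.random.default_rng(1))
    history = cne_pretrain(model, X, epochs=60, lr=3e-3, seed=0)
    mean_mse = float((X ** 2).mean())  # column-mean predictor on standardized data
    assert history[-1] < mean_mse
    running_best = np.minimum.accumulate(history)
    assert np.all(np.diff(running_best) <= 0)


def test_cne_pretrain_rejects_bad_epochs():
    from nerd.network import StackedAutoencoder

    model = StackedAutoencoder(50, AutoencoderSpec(encoder_hidden=(16,),
                                                   bottleneck=4),
                               np.random.default_rng(0))
    with pytest.raises(ValueError, match="epochs"):
        cne_pretrain(model, np.zeros((4, 50)), epochs=0)


# --------------------------------------------------------------- fusion

def test_fusion_all_zero_weights_predicts_half():
    head = FusionHead(8, FusionSpec(hidden=(4,), dropout=0.0),
                      np.random.default_rng(0), dtype=np.float64)
    for p in head.parameters():
        p.data[...] = 0.0
    head.eval()
    out = head(Tensor(np.random.default_rng(1).normal(size=(3, 8))))
    np.testing.assert_allclose(out.numpy(), 0.5)


def test_fusion_output_strictly_inside_unit_interval(rng):
    head = FusionHead(16, FusionSpec(hidden=(8, 4), dropout=0.0),
                      np.random.default_rng(2), dtype=np.float64)
    head.eval()
    x = rng.normal(scale=5, size=(50, 16))
    out = head(Tensor(x)).numpy()
    assert np.all(out > 0) and np.all(out < 1)


def test_fusion_train_mode_needs_batch():
    head = FusionHead(8, FusionSpec(hidden=(4,), dropout=0.0),
                      np.random.default_rng(0))
    head.train()
    with pytest.raises(ValueError, match="batch"):
        head(Tensor(np.zeros((1, 8), dtype=np.float32)))


def test_eval_mode_prediction_is_batch_size_invariant(rng):
    head = FusionHead(8, FusionSpec(hidden=(6, 4), dropout=0.1),
                      np.random.default_rng(4), dtype=np.float64)
    nn.set_dropout_rng(head, np.random.default_rng(0))
    head.train()
    for _ in range(5):  # populate running statistics
        head(Tensor(rng.normal(size=(32, 8))))
    head.eval()
    batch = rng.normal(size=(64, 8))
    together = head(Tensor(batch)).numpy()
    alone = head(Tensor(batch[:1])).numpy()
    assert abs(together[0] - alone[0]) < 1e-6


# ------------------------------------------------- end-to-end determinism

def test_network_forward_deterministic_given_seed(rng):
    spec = NetworkSpec(
        autoencoder=AutoencoderSpec(encoder_hidden=(32,), bottleneck=8),
        fusion=FusionSpec(hidden=(16,), dropout=0.0))
    graphs = GraphBatch.from_graphs([smiles_to_graph("CCO"), smiles_to_graph("CCN")])
    feats = FeatureTensors(
        fingerprints=rng.integers(0, 2, (2, 881)).astype(np.float32),
        graphs=graphs,
        mirna=rng.normal(size=(3, 200)).astype(np.float32),
        cnv=rng.normal(size=(3, 300)).astype(np.float32))
    d = np.array([0, 1, 1])
    c = np.array([0, 1, 2])
    n1 = NeRDNetwork(spec, 200, 300, seed=11).eval()
    n2 = NeRDNetwork(spec, 200, 300, seed=11).eval()
    np.testing.assert_array_equal(n1(feats, d, c).numpy(), n2(feats, d, c).numpy())
    n3 = NeRDNetwork(spec, 200, 300, seed=12).eval()
    assert not np.array_equal(n1(feats, d, c).numpy(), n3(feats, d, c).numpy())


# ------------------------------------------------------ gradient checks

def _check_param_grads(loss_fn, module, params, rtol=1e-4):
    loss = loss_fn()
    module.zero_grad()
    loss.backward()
    for p in params:
        analytic = p.grad.copy()
        saved = p.data.copy()

        def f(x, p=p):
            p.data = x
            out = float(loss_fn().item())
            return out
        num = numeric_grad(f, saved.copy())
        p.data = saved
        np.testing.assert_allclose(analytic, num, rtol=rtol, atol=1e-6)


def test_numeric_gradient_through_each_extractor(rng):
    """Numerical vs analytic gradients of the MSE loss, tiny instances."""
    target = rng.normal(size=3)

    # CNN extractor (kernel/pool shrunk so a length-40 input survives 3 stages)
    spec = Conv1DSpec(kernels_per_layer=(2, 3, 4), kernel_size=3,
                      pool_window=2, pool_stride=2, output_dim=4)
    cnn = CNNExtractor(40, spec, np.random.default_rng(0), dtype=np.float64)
    x = Tensor(rng.normal(size=(3, 40)))
    _check_param_grads(lambda: mse_loss(cnn(x).sum(axis=1), target), cnn,
                       [cnn.body.layers[0].weight, cnn.fc.bias], rtol=1e-4)

    # GCN extractor
    gspec = GCNSpec(input_dim=4, width_multipliers=(1, 2), output_dim=3)
    gcn = GCNExtractor(gspec, np.random.default_rng(1), dtype=np.float64)
    graphs = GraphBatch.from_graphs(_tiny_graphs(rng), dtype=np.float64)
    _check_param_grads(lambda: mse_loss(gcn(graphs).sum(axis=1), target), gcn,
                       [gcn.weights[0], gcn.fc.weight], rtol=1e-4)

    # autoencoder
    from nerd.network import StackedAutoencoder
    ae = StackedAutoencoder(12, AutoencoderSpec(encoder_hidden=(8,), bottleneck=4),
                            np.random.default_rng(2), dtype=np.float64)
    xa = rng.normal(size=(3, 12))
    _check_param_grads(lambda: mse_loss(ae(Tensor(xa)), xa), ae,
                       [ae.encoder.layers[0].weight, ae.decoder.layers[-1].bias],
                       rtol=1e-4)

    # fusion head (train mode, batch statistics in the graph)
    head = FusionHead(6, FusionSpec(hidden=(5,), dropout=0.0),
                      np.random.default_rng(3), dtype=np.float64)
    head.train()
    xf = Tensor(rng.normal(size=(3, 6)))
    _check_param_grads(lambda: mse_loss(head(xf), target), head,
                       [head.blocks[0].layers[0].weight,
                        head.blocks[0].layers[1].gamma, head.out.weight],
                       rtol=1e-4)


def _tiny_graphs(rng):
    graphs = []
    for n in (2, 3, 4):
        A = np.triu((rng.random((n, n)) < 0.6).astype(float), 1)
        A = A + A.T
        X = rng.normal(size=(n, 4))
        g = MolecularGraph.__new__(MolecularGraph)  # bypass 78-dim validation
        g.node_features = X.astype(np.float64)
        g.adjacency = A.astype(np.float64)
        graphs.append(g)
    return graphs
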