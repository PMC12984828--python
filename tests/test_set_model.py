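"""Set-attention model: equivariance/invariance, oracles, parameter budget."""

import numpy as np
import pytest

import dysbioformer as d
from dysbioformer.set_model import DysbioNet, ModelConfig, _softmax_np, weighted_cross_entropy
from dysbioformer.tokens import TokenSet


def _token_set(features, phylo_dim=2, weights=None, mask=None, taxon_idx=None):
    B, T, F = features.shape
    if weights is None:
        weights = np.ones((B, T))
    if mask is None:
        mask = np.ones((B, T), dtype=bool)
    if taxon_idx is None:
        taxon_idx = np.where(mask, np.tile(np.arange(T), (B, 1)), -1)
    return TokenSet([f"s{i}" for i in range(B)], features, weights,
                    mask, taxon_idx, phylo_dim, normalized=True)


@pytest.fixture()
def square_net():
    """token_dim == feature_dim so projections can be overwritten by hand."""
    cfg = ModelConfig(token_dim=8, sab_layers=1, n_heads=2, pma_seeds=3,
                      ffn_dim=16, head_hidden=8, dropout=0.0, seed=3)
    return DysbioNet(feature_dim=8, phylo_dim=2, config=cfg)


# ---------------------------------------------------------------------------
# SAB scores
# ---------------------------------------------------------------------------

def test_sab_scores_single_token(square_net):
    z = np.random.default_rng(0).normal(size=(1, 8))
    A = square_net.sab_scores(z, layer=0, head=0)
    assert A.shape == (1, 1)
    assert _softmax_np(A)[0, 0] == pytest.approx(1.0)


def test_sab_scores_orthonormal_tokens_diagonal_dominant(square_net):
    # force Q = K = identity: scores become z_i . z_j / sqrt(d_k)
    for name in ("Wq", "Wk"):
        square_net.params[f"sab0.{name}"].data = np.eye(8)
        square_net.params[f"sab0.b{name[1]}"].data = np.zeros(8)
    z = np.zeros((2, 8))
    z[0, 0] = z[1, 1] = 1.0  # orthonormal equal-norm tokens
    d_k = square_net.config.d_k
    A = square_net.sab_scores(z, layer=0, head=0)
    assert A[0, 0] == pytest.approx(1.0 / np.sqrt(d_k))
    assert A[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert A[0, 0] > A[0, 1] and A[1, 1] > A[1, 0]


def test_sab_scores_scale_with_key_dimension():
    # fixed products, doubling d_k by 4 halves the scores
    prods = np.random.default_rng(1).normal(size=(5, 5))
    assert np.allclose(prods / np.sqrt(64), (prods / np.sqrt(16)) / 2.0)


def test_sab_scores_empty_raises(square_net):
    with pytest.raises(ValueError):
        square_net.sab_scores(np.zeros((0, 8)), 0, 0)


# ---------------------------------------------------------------------------
# SAB forward
# ---------------------------------------------------------------------------

def test_sab_identical_tokens_uniform_attention(square_net):
    z = np.tile(np.random.default_rng(2).normal(size=(1, 8)), (4, 1))
    from dysbioformer.autodiff import Tensor

    _, alpha = square_net.sab_forward_tensor(Tensor(z[None]), 0, np.ones((1, 4), bool))
    np.testing.assert_allclose(alpha, 0.25, atol=1e-12)
    out = square_net.sab_forward(z, 0)
    for i in range(1, 4):
        np.testing.assert_allclose(out[i], out[0], atol=1e-12)


def test_sab_permutation_equivariance(square_net):
    rng = np.random.default_rng(3)
    z = rng.normal(size=(5, 8))
    out = square_net.sab_forward(z, 0)
    perm = rng.permutation(5)
    out_p = square_net.sab_forward(z[perm], 0)
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_sab_attention_matches_bruteforce_oracle(square_net):
    """Attention sum h_i = sum_j alpha_ij V z_j recomputed with loops."""
    rng = np.random.default_rng(4)
    z = rng.normal(size=(3, 8))
    cfg = square_net.config
    p = square_net.params
    from dysbioformer.autodiff import Tensor

    attended, alpha = square_net._mha(
        Tensor(z[None]), Tensor(z[None]), np.ones((1, 3), bool), "sab0", False, None
    )
    q = z @ p["sab0.Wq"].data + p["sab0.bq"].data
    k = z @ p["sab0.Wk"].data + p["sab0.bk"].data
    v = z @ p["sab0.Wv"].data + p["sab0.bv"].data
    d_k = cfg.d_k
    heads_out = np.zeros((3, 8))
    for h in range(cfg.n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        A = q[:, sl] @ k[:, sl].T / np.sqrt(d_k)
        a = np.exp(A - A.max(axis=1, keepdims=True))
        a = a / a.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(alpha[0, h], a, atol=1e-10)
        for i in range(3):
            heads_out[i, sl] = sum(a[i, j] * v[j, sl] for j in range(3))
    expected = heads_out @ p["sab0.Wo"].data + p["sab0.bo"].data
    np.testing.assert_allclose(attended.data[0], expected, atol=1e-6)


# ---------------------------------------------------------------------------
# PMA
# ---------------------------------------------------------------------------

def test_pma_single_token_all_seeds_identical(square_net):
    rng = np.random.default_rng(5)
    z = rng.normal(size=(1, 8))
    from dysbioformer.autodiff import Tensor

    seeds = square_net.params["pma.seeds"].reshape(1, 3, 8)
    attended, gamma = square_net._mha(
        seeds, Tensor(z[None]), np.ones((1, 1), bool), "pma", False, None
    )
    np.testing.assert_allclose(gamma, 1.0)  # softmax over one token
    # every seed pools the same single value vector
    for s in range(1, 3):
        np.testing.assert_allclose(attended.data[0, s], attended.data[0, 0], atol=1e-12)


def test_pma_gamma_rows_are_probabilities(square_net, small_tokens):
    tokens, _, _ = small_tokens
    cfg = ModelConfig(token_dim=16, sab_layers=1, n_heads=4, pma_seeds=4,
                      ffn_dim=32, head_hidden=16, dropout=0.0, seed=1)
    net = DysbioNet(tokens.feature_dim, tokens.phylo_dim, cfg)
    _, trace = net.forward(tokens, trace=True)
    gamma = trace.pma_gamma  # (B, H, S, T)
    sums = gamma.sum(axis=-1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    # masked tokens receive exactly zero
    masked = ~tokens.mask
    for b in range(gamma.shape[0]):
        assert (gamma[b][:, :, masked[b]] == 0.0).all()


def test_pma_permutation_invariance(square_net):
    rng = np.random.default_rng(6)
    z = rng.normal(size=(6, 8))
    g = square_net.pma_forward(z)
    for _ in range(10):
        perm = rng.permutation(6)
        np.testing.assert_allclose(square_net.pma_forward(z[perm]), g, atol=1e-6)


# ---------------------------------------------------------------------------
# Classifier head and full forward
# ---------------------------------------------------------------------------

def test_softmax_symmetry_and_normalization(square_net):
    np.testing.assert_allclose(_softmax_np(np.zeros((1, 2))), 0.5)
    g = np.random.default_rng(7).normal(size=(3, 8))
    probs = square_net.classify(g)
    assert probs.sum() == pytest.approx(1.0)


def test_untrained_net_deterministic(small_tokens):
    tokens, state, _ = small_tokens
    cfg = ModelConfig(token_dim=16, sab_layers=2, n_heads=4, pma_seeds=4,
                      ffn_dim=32, head_hidden=16, seed=42)
    net1 = DysbioNet(tokens.feature_dim, tokens.phylo_dim, cfg, tokenizer_state=state)
    net2 = DysbioNet(tokens.feature_dim, tokens.phylo_dim, cfg, tokenizer_state=state)
    np.testing.assert_array_equal(net1.forward(tokens), net2.forward(tokens))


def test_full_model_permutation_invariance(tiny_net, small_tokens):
    tokens, _, _ = small_tokens
    probs = tiny_net.forward(tokens)
    rng = np.random.default_rng(8)
    shuffled = tokens
    for s in range(len(tokens.sample_ids)):
        shuffled = shuffled.permuted(s, rng)
    probs_p = tiny_net.forward(shuffled)
    rel = np.abs(probs_p - probs).max() / np.abs(probs).max()
    assert rel < 1e-5


def test_padding_invariance(tiny_net, small_tokens):
    tokens, _, _ = small_tokens
    probs = tiny_net.forward(tokens)
    B, T, F = tokens.features.shape
    padded = TokenSet(
        list(tokens.sample_ids),
        np.concatenate([tokens.features, np.zeros((B, 3, F))], axis=1),
        np.concatenate([tokens.weights, np.zeros((B, 3))], axis=1),
        np.concatenate([tokens.mask, np.zeros((B, 3), dtype=bool)], axis=1),
        np.concatenate([tokens.taxon_idx, -np.ones((B, 3), dtype=np.int64)], axis=1),
        tokens.phylo_dim,
        normalized=True,
    )
    np.testing.assert_allclose(tiny_net.forward(padded), probs, atol=1e-10)


def test_default_parameter_count_near_reported():
    net = DysbioNet(feature_dim=66, phylo_dim=64, config=ModelConfig())
    assert abs(net.n_parameters - 3.2e6) / 3.2e6 < 0.15


def test_gradients_reach_all_components(tiny_net, small_tokens):
    tokens, _, _ = small_tokens
    y = np.zeros(len(tokens.sample_ids), dtype=int)
    y[::2] = 1
    logits, _ = tiny_net.forward_logits(tokens, train=False)
    loss = weighted_cross_entropy(logits, y, np.ones(2))
    loss.backward()
    for key in ["We", "be", "Wp", "sab0.Wq", "sab1.Wv", "pma.seeds", "head.W1"]:
        grad = tiny_net.params[key].grad
        assert grad is not None and np.linalg.norm(grad) > 0, key


def test_empty_token_set_rejected(tiny_net):
    empty = _token_set(np.zeros((1, 2, 10)), mask=np.zeros((1, 2), dtype=bool),
                       taxon_idx=-np.ones((1, 2), dtype=np.int64))
    with pytest.raises(ValueError):
        tiny_net.forward_logits(empty)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(token_dim=10, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(pool_mode="sum")


def test_checkpoint_roundtrip(tmp_path, tiny_net, small_tokens):
    from dysbioformer.set_model import load_checkpoint, save_checkpoint

    tokens, state, _ = small_tokens
    probs = tiny_net.forward(tokens)
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_net, path, tokenizer_state=state)
    net2, state2 = load_checkpoint(path)
    assert net2.labels == tiny_net.labels
    assert net2.config == tiny_net.config
    np.testing.assert_array_equal(net2.forward(tokens), probs)
    np.testing.assert_array_equal(state2.mu, state.mu)


def test_mean_pooling_mode(small_tokens):
    tokens, _, _ = small_tokens
    cfg = ModelConfig(token_dim=16, sab_layers=1, n_heads=4, pma_seeds=4,
                      ffn_dim=32, head_hidden=16, pool_mode="mean", seed=2)
    net = DysbioNet(tokens.feature_dim, tokens.phylo_dim, cfg)
    probs = net.forward(tokens)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
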