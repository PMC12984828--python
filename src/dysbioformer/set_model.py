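"""The DysbioFormer network: a permutation-invariant multiset transformer.

Architecture, bottom to top:

* token projection z_i = w_i * (W_e e~_i + b_e + W_p h~_i) — the learnable
  taxon embedding maps the normalized token features (W_e) plus an additive
  map on the phylogenetic slice (W_p) into the latent token space, scaled by
  the compositional weight;
* a stack of Set Attention Blocks (SABs): multihead scaled dot-product
  self-attention over the token multiset, A_ij = (Q z_i).(K z_j)/sqrt(d_k),
  alpha = row-softmax(A), h_i = sum_j alpha_ij V z_j, with head
  concatenation, output projection, residual connection, layer
  normalization, and a per-token feed-forward sublayer (also residual +
  layer norm). SABs are permutation-EQUIVARIANT: permuting the tokens
  permutes the outputs identically;
* Pooling by Multihead Attention (PMA): S learnable seed vectors attend over
  the token set, beta_si = (Q s_s).(K z_i)/sqrt(d_k), gamma = softmax over
  tokens, g_s = sum_i gamma_si V z_i — the pooled embedding is permutation-
  INVARIANT because tokens enter only through a symmetric weighted sum;
* a two-layer feed-forward classifier head over the concatenated (default)
  or averaged seed outputs, softmax over the label set.

Padded tokens are excluded by additive -inf masking of attention keys, so
padding never changes any output. All randomness (initialization, dropout)
is governed by explicit seeds; inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, dropout, layer_norm, log_softmax, softmax
from .tokens import TokenSet, TokenizerState

#: Default hyperparameters of the full-scale model.
DEFAULTS = {
    "token_dim": 128,
    "sab_layers": 4,
    "n_heads": 8,
    "pma_seeds": 16,
    "ffn_dim": 2048,
    "head_hidden": 256,
    "dropout": 0.2,
}


@dataclass
class ModelConfig:
    token_dim: int = DEFAULTS["token_dim"]
    sab_layers: int = DEFAULTS["sab_layers"]
    n_heads: int = DEFAULTS["n_heads"]
    pma_seeds: int = DEFAULTS["pma_seeds"]
    ffn_dim: int = DEFAULTS["ffn_dim"]
    head_hidden: int = DEFAULTS["head_hidden"]
    dropout: float = DEFAULTS["dropout"]
    pool_mode: str = "concat"  # or "mean"
    n_classes: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.token_dim % self.n_heads != 0:
            raise ValueError("token_dim must be divisible by n_heads")
        if self.pool_mode not in ("concat", "mean"):
            raise ValueError("pool_mode must be 'concat' or 'mean'")

    @property
    def d_k(self) -> int:
        return self.token_dim // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AttentionTrace:
    """Detached attention weights captured during a traced forward pass.

    ``sab_alphas[l]`` is (B, heads, T, T): row-softmax weights per layer;
    ``pma_gamma`` is (B, heads, S, T): seed-to-token weights. Rows over
    unmasked tokens sum to 1; masked tokens receive exactly 0.
    """

    sab_alphas: list[np.ndarray]
    pma_gamma: np.ndarray
    taxon_idx: np.ndarray
    mask: np.ndarray


class DysbioNet:
    """Parameter container + forward pass for the multiset transformer."""

    def __init__(
        self,
        feature_dim: int,
        phylo_dim: int,
        config: ModelConfig | None = None,
        labels: tuple[str, ...] = ("control", "disease"),
        tokenizer_state: TokenizerState | None = None,
    ):
        self.config = config or ModelConfig()
        self.feature_dim = feature_dim
        self.phylo_dim = phylo_dim
        self.labels = tuple(labels)
        if len(self.labels) != self.config.n_classes:
            raise ValueError("label set size must equal n_classes")
        rng = np.random.default_rng(self.config.seed)
        D, c = self.config.token_dim, self.config
        p: dict[str, Tensor] = {}

        def xavier(n_in, n_out):
            limit = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-limit, limit, (n_in, n_out)), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        if tokenizer_state is not None:
            p["We"] = Tensor(tokenizer_state.W_e.copy(), requires_grad=True)
            p["be"] = Tensor(tokenizer_state.b_e.copy(), requires_grad=True)
        else:
            p["We"], p["be"] = xavier(feature_dim, D), zeros(D)
        p["Wp"], _ = xavier(phylo_dim, D), None  # Eq-8-style additive phylo map
        for l in range(c.sab_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"sab{l}.{name}"] = xavier(D, D)
                p[f"sab{l}.b{name[1]}"] = zeros(D)
            p[f"sab{l}.ln1_g"], p[f"sab{l}.ln1_b"] = ones(D), zeros(D)
            p[f"sab{l}.ln2_g"], p[f"sab{l}.ln2_b"] = ones(D), zeros(D)
            p[f"sab{l}.ffn_W1"], p[f"sab{l}.ffn_b1"] = xavier(D, c.ffn_dim), zeros(c.ffn_dim)
            p[f"sab{l}.ffn_W2"], p[f"sab{l}.ffn_b2"] = xavier(c.ffn_dim, D), zeros(D)
        p["pma.seeds"] = Tensor(rng.normal(0.0, 1.0, (c.pma_seeds, D)), requires_grad=True)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"pma.{name}"] = xavier(D, D)
            p[f"pma.b{name[1]}"] = zeros(D)
        p["pma.ln1_g"], p["pma.ln1_b"] = ones(D), zeros(D)
        p["pma.ln2_g"], p["pma.ln2_b"] = ones(D), zeros(D)
        p["pma.ffn_W1"], p["pma.ffn_b1"] = xavier(D, c.ffn_dim), zeros(c.ffn_dim)
        p["pma.ffn_W2"], p["pma.ffn_b2"] = xavier(c.ffn_dim, D), zeros(D)
        pooled = c.pma_seeds * D if c.pool_mode == "concat" else D
        p["head.W1"], p["head.b1"] = xavier(pooled, c.head_hidden), zeros(c.head_hidden)
        p["head.W2"], p["head.b2"] = xavier(c.head_hidden, c.n_classes), zeros(c.n_classes)
        self.params = p

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    # -- building blocks ---------------------------------------------------

    def _split_heads(self, x: Tensor, n_rows: int) -> Tensor:
        # (..., n_rows, D) -> (..., H, n_rows, d_k)
        c = self.config
        batch = x.shape[:-2]
        x = x.reshape(*batch, n_rows, c.n_heads, c.d_k)
        axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
        return x.transpose(axes)

    def _mha(self, x_q: Tensor, x_kv: Tensor, key_mask: np.ndarray, prefix: str,
             train: bool, rng) -> tuple[Tensor, np.ndarray]:
        """Multihead attention of ``x_q`` rows over ``x_kv`` rows.

        ``key_mask`` is (B, T) boolean; padded keys get -inf logits. Returns
        (output (B, S, D), attention weights (B, H, S, T) as numpy).
        """
        p, c = self.params, self.config
        q = self._split_heads(x_q @ p[f"{prefix}.Wq"] + p[f"{prefix}.bq"], x_q.shape[-2])
        k = self._split_heads(x_kv @ p[f"{prefix}.Wk"] + p[f"{prefix}.bk"], x_kv.shape[-2])
        v = self._split_heads(x_kv @ p[f"{prefix}.Wv"] + p[f"{prefix}.bv"], x_kv.shape[-2])
        kt = k.transpose(tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2))
        scores = (q @ kt) * (1.0 / np.sqrt(c.d_k))
        B, T = key_mask.shape
        additive = np.where(key_mask, 0.0, -np.inf)[:, None, None, :]
        alpha = softmax(scores, axis=-1, additive_mask=additive)
        out = alpha @ v  # (B, H, S, d_k)
        out = out.transpose(tuple(range(out.ndim - 3)) + (out.ndim - 2, out.ndim - 3, out.ndim - 1))
        out = out.reshape(*out.shape[:-2], c.n_heads * c.d_k)
        out = out @ p[f"{prefix}.Wo"] + p[f"{prefix}.bo"]
        out = dropout(out, c.dropout, rng, train)
        return out, alpha.data

    def _block_tail(self, x: Tensor, attended: Tensor, prefix: str, train: bool, rng) -> Tensor:
        p, c = self.params, self.config
        x = layer_norm(x + attended, p[f"{prefix}.ln1_g"], p[f"{prefix}.ln1_b"])
        ff = (x @ p[f"{prefix}.ffn_W1"] + p[f"{prefix}.ffn_b1"]).relu()
        ff = dropout(ff @ p[f"{prefix}.ffn_W2"] + p[f"{prefix}.ffn_b2"], c.dropout, rng, train)
        return layer_norm(x + ff, p[f"{prefix}.ln2_g"], p[f"{prefix}.ln2_b"])

    # -- forward -----------------------------------------------------------

    def embed(self, tokens: TokenSet) -> Tensor:
        """Project normalized token features into the latent token space."""
        if not tokens.normalized:
            raise ValueError("tokens must be normalized before embedding")
        p = self.params
        feats = Tensor(tokens.features)
        phylo = Tensor(tokens.features[..., : self.phylo_dim])
        w = Tensor(tokens.weights[..., None])
        z = (feats @ p["We"] + p["be"] + phylo @ p["Wp"]) * w
        return z

    def sab_forward_tensor(self, z: Tensor, layer: int, mask: np.ndarray,
                           train: bool = False, rng=None) -> tuple[Tensor, np.ndarray]:
        attended, alpha = self._mha(z, z, mask, f"sab{layer}", train, rng)
        return self._block_tail(z, attended, f"sab{layer}", train, rng), alpha

    def pma_forward_tensor(self, z: Tensor, mask: np.ndarray,
                           train: bool = False, rng=None) -> tuple[Tensor, np.ndarray]:
        p, c = self.params, self.config
        seeds = p["pma.seeds"].reshape(1, c.pma_seeds, c.token_dim)
        attended, gamma = self._mha(seeds, z, mask, "pma", train, rng)
        g = self._block_tail(seeds, attended, "pma", train, rng)
        return g, gamma

    def head_logits(self, g: Tensor, train: bool = False, rng=None) -> Tensor:
        p, c = self.params, self.config
        if c.pool_mode == "concat":
            pooled = g.reshape(g.shape[0], c.pma_seeds * c.token_dim)
        else:
            pooled = g.mean(axis=1)
        hidden = (pooled @ p["head.W1"] + p["head.b1"]).relu()
        hidden = dropout(hidden, c.dropout, rng, train)
        return hidden @ p["head.W2"] + p["head.b2"]

    def forward_logits(self, tokens: TokenSet, train: bool = False, rng=None,
                       trace: bool = False) -> tuple[Tensor, AttentionTrace | None]:
        if tokens.mask.sum() == 0:
            raise ValueError("empty token set")
        z = self.embed(tokens)
        sab_alphas: list[np.ndarray] = []
        for l in range(self.config.sab_layers):
            z, alpha = self.sab_forward_tensor(z, l, tokens.mask, train, rng)
            if trace:
                sab_alphas.append(alpha)
        g, gamma = self.pma_forward_tensor(z, tokens.mask, train, rng)
        logits = self.head_logits(g, train, rng)
        if np.isnan(logits.data).any():
            raise FloatingPointError("NaN in classifier logits")
        tr = AttentionTrace(sab_alphas, gamma, tokens.taxon_idx, tokens.mask) if trace else None
        return logits, tr

    def forward(self, tokens: TokenSet, trace: bool = False):
        """Inference pass: label probabilities (+ optional attention trace)."""
        logits, tr = self.forward_logits(tokens, train=False, trace=trace)
        probs = _softmax_np(logits.data)
        return (probs, tr) if trace else probs

    def predict_proba(self, tokens: TokenSet) -> np.ndarray:
        return self.forward(tokens)

    # -- numpy-facing wrappers used by diagnostics/tests --------------------

    def sab_scores(self, z: np.ndarray, layer: int, head: int) -> np.ndarray:
        """Raw pairwise attention scores A = (Q z)(K z)^T / sqrt(d_k)."""
        if z.size == 0:
            raise ValueError("empty token set")
        p, c = self.params, self.config
        q = z @ p[f"sab{layer}.Wq"].data + p[f"sab{layer}.bq"].data
        k = z @ p[f"sab{layer}.Wk"].data + p[f"sab{layer}.bk"].data
        sl = slice(head * c.d_k, (head + 1) * c.d_k)
        return q[..., sl] @ k[..., sl].T / np.sqrt(c.d_k)

    def sab_forward(self, z: np.ndarray, layer: int) -> np.ndarray:
        """Single-sample SAB pass on an unmasked (T, D) token array."""
        zt = Tensor(z[None])
        out, _ = self.sab_forward_tensor(zt, layer, np.ones((1, z.shape[0]), bool))
        return out.data[0]

    def pma_forward(self, z: np.ndarray) -> np.ndarray:
        """Single-sample PMA pooling on an unmasked (T, D) token array."""
        g, _ = self.pma_forward_tensor(Tensor(z[None]), np.ones((1, z.shape[0]), bool))
        return g.data[0]

    def classify(self, g: np.ndarray) -> np.ndarray:
        """Label probabilities from a pooled (S, D) embedding."""
        logits = self.head_logits(Tensor(g[None]))
        return _softmax_np(logits.data)[0]


def save_checkpoint(net: DysbioNet, path, tokenizer_state: TokenizerState | None = None) -> None:
    """Serialize config + parameters + label set (+ tokenizer state) to NPZ."""
    import json

    payload = {f"param:{k}": p.data for k, p in net.params.items()}
    header = {
        "config": net.config.to_dict(),
        "labels": list(net.labels),
        "feature_dim": net.feature_dim,
        "phylo_dim": net.phylo_dim,
    }
    payload["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    if tokenizer_state is not None:
        payload["tok:mu"] = tokenizer_state.mu
        payload["tok:sigma"] = tokenizer_state.sigma
        payload["tok:W_e"] = tokenizer_state.W_e
        payload["tok:b_e"] = tokenizer_state.b_e
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[DysbioNet, TokenizerState | None]:
    import json

    with np.load(path) as archive:
        header = json.loads(bytes(archive["header"]).decode())
        net = DysbioNet(
            header["feature_dim"],
            header["phylo_dim"],
            ModelConfig(**header["config"]),
            labels=tuple(header["labels"]),
        )
        net.load_state(
            {k[len("param:"):]: archive[k] for k in archive.files if k.startswith("param:")}
        )
        state = None
        if "tok:mu" in archive.files:
            state = TokenizerState(
                archive["tok:mu"], archive["tok:sigma"],
                archive["tok:W_e"], archive["tok:b_e"],
            )
    return net, state


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: Tensor, y: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Mean class-weighted cross-entropy over a batch."""
    logp = log_softmax(logits, axis=-1)
    B = logits.shape[0]
    picked = logp[np.arange(B), y]
    w = class_weights[y]
    return -(picked * Tensor(w)).sum() * (1.0 / float(w.sum()))
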