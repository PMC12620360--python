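"""DeepAttNet: bidirectional cross-attention classifier for two-channel
bilateral ear-EEG, plus its ablation variants.

Each 60-s ear-EEG epoch (2 x 7500 samples at 125 Hz) is split into left and
right streams.  Every stream passes through four coarse-to-fine temporal
blocks (1-D conv -> batch norm -> ELU, with average pooling after blocks
1-3; kernel lengths decrease from 125 to 20 samples), then a 1x1 pointwise
convolution compresses the feature maps to a single length-35 token
sequence.  Scalar tokens are lifted by learned linear maps into queries,
keys and values, and scaled dot-product cross-attention is applied
bidirectionally (left queries against right keys/values, then the reverse).
The two attended sequences are concatenated and fed to a shallow classifier
(linear -> batch norm -> ELU -> dropout -> linear) producing binary stress
logits (stress = class 1).

Variants: 'no_cross_attention' concatenates the compressed token streams
directly; 'no_pointwise' replaces the learned 1x1 compression with a uniform
average over feature maps (token count stays 35); 'no_both' combines the
two; 'self_attention' applies within-stream self-attention followed by
temporal averaging; 'lightweight_transformer' concatenates both token
streams, adds positional and channel embeddings, and applies a single
two-head Transformer encoder layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import InvalidConfigError, UnsupportedVariantError

VARIANTS = (
    "full",
    "no_cross_attention",
    "no_pointwise",
    "no_both",
    "self_attention",
    "lightweight_transformer",
)

DIRECTIONS = ("left_to_right", "right_to_left")

ATTENTION_VARIANTS = ("full", "no_pointwise")


@dataclass
class ModelConfig:
    """Pinned architecture hyperparameters.

    Defaults give 7500 -> 1500 -> 250 -> 35 temporal positions (T' = 35) and
    a parameter budget of roughly 0.06 M for the full variant.
    """

    kernel_lengths: tuple = (125, 63, 31, 20)
    filters: tuple = (8, 16, 16, 32)
    pool: tuple = ((5, 5), (6, 6), (7, 7))
    attention_dk: int = 8
    attention_dv: int = 1
    hidden_dim: int = 64
    dropout_p: float = 0.5
    share_streams: bool = False
    variant: str = "full"
    input_samples: int = 7500
    in_channels: int = 2
    n_classes: int = 2
    elu_alpha: float = 1.0
    expected_tokens: int = 35
    # attention-baseline widths (self-attention value dim / transformer model
    # dim and feed-forward dim)
    self_attention_dv: int = 8
    transformer_d_model: int = 32
    transformer_d_ff: int = 128
    transformer_heads: int = 2

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise UnsupportedVariantError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        ks = tuple(self.kernel_lengths)
        if any(a <= b for a, b in zip(ks, ks[1:])):
            raise InvalidConfigError("kernel lengths must be strictly decreasing")
        if len(self.filters) != len(ks):
            raise InvalidConfigError("filters and kernel_lengths length mismatch")
        if len(self.pool) != len(ks) - 1:
            raise InvalidConfigError("need one pooling stage per block except the last")
        if self.attention_dk < 1 or self.attention_dv < 1:
            raise InvalidConfigError("attention dimensions must be >= 1")
        if self.token_count() != self.expected_tokens:
            raise InvalidConfigError(
                f"pooling yields {self.token_count()} tokens, expected "
                f"{self.expected_tokens}"
            )

    def token_count(self) -> int:
        length = self.input_samples
        for size, stride in self.pool:
            if size != stride:
                raise InvalidConfigError(
                    "average pooling requires length == stride"
                )
            length //= size
        return length


@dataclass
class AttentionRecord:
    """A row-stochastic T' x T' cross-attention map for one direction."""

    direction: str
    map: np.ndarray
    t_prime: int = field(default=0)

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.map.ndim != 2 or self.map.shape[0] != self.map.shape[1]:
            raise InvalidConfigError("attention map must be square")
        self.t_prime = self.map.shape[0]
        if np.any(self.map < 0):
            raise InvalidConfigError("attention weights must be nonnegative")
        if not np.allclose(self.map.sum(axis=1), 1.0, atol=1e-6):
            raise InvalidConfigError("attention rows must sum to 1 within 1e-6")


def cross_attention(Q, K, V, direction: str = "left_to_right"):
    """softmax(Q K^T / sqrt(d_k)) V for one direction.

    Accepts unbatched (T' x d) arrays; returns (attended T' x d_v,
    AttentionRecord)."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise InvalidConfigError("Q, K, V must be 2-D (tokens x dim)")
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise InvalidConfigError(
            f"shape mismatch: Q{Q.shape}, K{K.shape}, V{V.shape}"
        )
    out, amap, _ = nn.attention_forward(Q[None], K[None], V[None])
    return out[0], AttentionRecord(direction=direction, map=amap[0])


class DeepAttNet:
    """Trainable classifier mapping (batch, 2, 7500) to (batch, 2) logits."""

    def __init__(self, config: ModelConfig, seed: int = 42):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 1])
        )
        self._layers: list = []
        self.last_attention: dict = {}
        self._build(rng)

    # -- construction ------------------------------------------------------

    def _add(self, layer):
        self._layers.append(layer)
        return layer

    def _make_encoder(self, rng, tag):
        cfg = self.config
        blocks = []
        c_in = 1
        for i, (k, c_out) in enumerate(zip(cfg.kernel_lengths, cfg.filters)):
            block = [
                self._add(nn.Conv1d(c_in, c_out, k, rng, name=f"{tag}.b{i}.conv",
                                    input_layer=(i == 0))),
                self._add(nn.BatchNorm1d(c_out, name=f"{tag}.b{i}.bn")),
                self._add(nn.ELU(cfg.elu_alpha)),
            ]
            if i < len(cfg.pool):
                block.append(self._add(nn.AvgPool1d(cfg.pool[i][0])))
            blocks.append(block)
            c_in = c_out
        return blocks

    def _build(self, rng):
        cfg = self.config
        self.t_prime = cfg.token_count()
        v = cfg.variant
        self.has_pointwise = v in ("full", "no_cross_attention",
                                   "self_attention", "lightweight_transformer")
        self.has_cross_attention = v in ATTENTION_VARIANTS

        if cfg.share_streams:
            enc = self._make_encoder(rng, "enc")
            self.encoders = {"L": enc, "R": enc}
        else:
            self.encoders = {"L": self._make_encoder(rng, "encL"),
                             "R": self._make_encoder(rng, "encR")}
        if self.has_pointwise:
            if cfg.share_streams:
                pw = self._add(nn.Conv1d(cfg.filters[-1], 1, 1, rng, name="pw"))
                self.pointwise = {"L": pw, "R": pw}
            else:
                self.pointwise = {
                    s: self._add(nn.Conv1d(cfg.filters[-1], 1, 1, rng,
                                           name=f"pw{s}"))
                    for s in ("L", "R")
                }

        t = self.t_prime
        if self.has_cross_attention:
            self.attn_proj = {}
            for d in DIRECTIONS:
                self.attn_proj[d] = {
                    "q": self._add(nn.Linear(1, cfg.attention_dk, rng, f"{d}.q")),
                    "k": self._add(nn.Linear(1, cfg.attention_dk, rng, f"{d}.k",
                                             bias=False)),
                    "v": self._add(nn.Linear(1, cfg.attention_dv, rng, f"{d}.v")),
                }
            clf_in = 2 * t * cfg.attention_dv
        elif v == "self_attention":
            self.sa_proj = {}
            for s in ("L", "R"):
                self.sa_proj[s] = {
                    "q": self._add(nn.Linear(1, cfg.attention_dk, rng, f"sa{s}.q")),
                    "k": self._add(nn.Linear(1, cfg.attention_dk, rng, f"sa{s}.k",
                                             bias=False)),
                    "v": self._add(nn.Linear(1, cfg.self_attention_dv, rng,
                                             f"sa{s}.v")),
                }
            clf_in = 2 * cfg.self_attention_dv
        elif v == "lightweight_transformer":
            dm, dff = cfg.transformer_d_model, cfg.transformer_d_ff
            self.tok_lift = self._add(nn.Linear(1, dm, rng, "tf.lift"))
            self.pos_emb = nn.Parameter(
                "tf.pos", 0.02 * rng.standard_normal((t, dm))
            )
            self.chan_emb = nn.Parameter(
                "tf.chan", 0.02 * rng.standard_normal((2, dm))
            )
            self.mha = {k: self._add(nn.Linear(dm, dm, rng, f"tf.{k}",
                                               bias=(k != "wk")))
                        for k in ("wq", "wk", "wv", "wo")}
            self.ln1 = self._add(nn.LayerNorm(dm, name="tf.ln1"))
            self.ffn1 = self._add(nn.Linear(dm, dff, rng, "tf.ffn1"))
            self.ffn_act = self._add(nn.ELU(cfg.elu_alpha))
            self.ffn2 = self._add(nn.Linear(dff, dm, rng, "tf.ffn2"))
            self.ln2 = self._add(nn.LayerNorm(dm, name="tf.ln2"))
            clf_in = dm
        else:  # no_cross_attention / no_both: direct concatenation
            clf_in = 2 * t

        self.classifier = [
            self._add(nn.Linear(clf_in, cfg.hidden_dim, rng, "clf.fc1")),
            self._add(nn.BatchNorm1d(cfg.hidden_dim, name="clf.bn")),
            self._add(nn.ELU(cfg.elu_alpha)),
            self._add(nn.Dropout(cfg.dropout_p, self._dropout_rng)),
            self._add(nn.Linear(cfg.hidden_dim, cfg.n_classes, rng, "clf.fc2")),
        ]

    # -- parameter plumbing ------------------------------------------------

    def parameters(self):
        seen = set()
        out = []
        extra = [self.pos_emb, self.chan_emb] \
            if self.config.variant == "lightweight_transformer" else []
        for layer in self._layers:
            for p in layer.params:
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out + extra

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def get_state(self):
        return (
            [p.value.copy() for p in self.parameters()],
            [{k: v.copy() for k, v in layer.buffers.items()}
             for layer in self._layers],
        )

    def set_state(self, state):
        values, buffers = state
        for p, v in zip(self.parameters(), values):
            p.value = v.copy()
        for layer, buf in zip(self._layers, buffers):
            layer.buffers = {k: v.copy() for k, v in buf.items()}

    def parameter_checksum(self) -> float:
        return float(sum(np.float64(np.abs(p.value)).sum()
                         for p in self.parameters()))

    # -- forward / backward ------------------------------------------------

    def _check_input(self, x):
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.in_channels \
                or x.shape[2] != cfg.input_samples:
            raise InvalidConfigError(
                f"expected input (batch, {cfg.in_channels}, "
                f"{cfg.input_samples}), got {x.shape}"
            )

    def _encode(self, x, training):
        """Per-stream encoding to scalar token sequences (B, T').

        With shared streams both channels run through the encoder as one
        stacked batch so layer caches stay valid for backward."""
        cfg = self.config
        if cfg.share_streams:
            B = x.shape[0]
            h = np.concatenate([x[:, 0:1, :], x[:, 1:2, :]], axis=0)
            h = self._run_blocks(self.encoders["L"], h, training)
            if self.has_pointwise:
                h = self.pointwise["L"].forward(h, training)[:, 0, :]
            else:
                self._nopw_channels = h.shape[1]
                h = h.mean(axis=1)
            return {"L": h[:B], "R": h[B:]}
        toks = {}
        for i, s in enumerate(("L", "R")):
            h = self._run_blocks(self.encoders[s], x[:, i:i + 1, :], training)
            if self.has_pointwise:
                h = self.pointwise[s].forward(h, training)[:, 0, :]
            else:
                self._nopw_channels = h.shape[1]
                h = h.mean(axis=1)
            toks[s] = h
        return toks

    @staticmethod
    def _run_blocks(blocks, h, training):
        for block in blocks:
            for layer in block:
                h = layer.forward(h, training)
        return h

    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=nn.DTYPE)
        self._check_input(x)
        cfg = self.config
        B = x.shape[0]
        toks = self._encode(x, training)
        self.last_attention = {}

        v = cfg.variant
        if self.has_cross_attention:
            t3 = {s: toks[s][..., None] for s in ("L", "R")}
            self._attn_cache = {}
            feats = []
            for d, (qs, ks) in zip(DIRECTIONS, (("L", "R"), ("R", "L"))):
                proj = self.attn_proj[d]
                Q = proj["q"].forward(t3[qs], training)
                K = proj["k"].forward(t3[ks], training)
                V = proj["v"].forward(t3[ks], training)
                out, amap, cache = nn.attention_forward(Q, K, V)
                self._attn_cache[d] = (cache, qs, ks, out.shape)
                self.last_attention[d] = amap
                feats.append(out.reshape(B, -1))
            feat = np.concatenate(feats, axis=1)
        elif v == "self_attention":
            t3 = {s: toks[s][..., None] for s in ("L", "R")}
            self._sa_cache = {}
            feats = []
            for s in ("L", "R"):
                proj = self.sa_proj[s]
                Q = proj["q"].forward(t3[s], training)
                K = proj["k"].forward(t3[s], training)
                V = proj["v"].forward(t3[s], training)
                out, _, cache = nn.attention_forward(Q, K, V)
                self._sa_cache[s] = (cache, out.shape)
                feats.append(out.mean(axis=1))
            feat = np.concatenate(feats, axis=1)
        elif v == "lightweight_transformer":
            feat = self._transformer_forward(toks, training)
        else:
            feat = np.concatenate([toks["L"], toks["R"]], axis=1)

        h = feat.astype(nn.DTYPE)
        for layer in self.classifier:
            h = layer.forward(h, training)
        return h

    def _transformer_forward(self, toks, training):
        cfg = self.config
        t = self.t_prime
        seq = np.concatenate([toks["L"][..., None], toks["R"][..., None]], axis=1)
        lifted = self.tok_lift.forward(seq, training)
        pos = np.concatenate([self.pos_emb.value, self.pos_emb.value], axis=0)
        chan = np.repeat(self.chan_emb.value, t, axis=0)
        h0 = lifted + pos + chan
        B, T2, dm = h0.shape
        nh = cfg.transformer_heads
        q = self._split_heads(self.mha["wq"].forward(h0, training), nh)
        k = self._split_heads(self.mha["wk"].forward(h0, training), nh)
        val = self._split_heads(self.mha["wv"].forward(h0, training), nh)
        out, _, cache = nn.attention_forward(q, k, val)
        self._tf_attn_cache = (cache, B, nh)
        attn = self.mha["wo"].forward(self._merge_heads(out, B, nh), training)
        h1 = self.ln1.forward(h0 + attn, training)
        f = self.ffn2.forward(
            self.ffn_act.forward(self.ffn1.forward(h1, training), training),
            training,
        )
        h2 = self.ln2.forward(h1 + f, training)
        self._tf_t2 = T2
        return h2.mean(axis=1)

    @staticmethod
    def _split_heads(x, nh):
        B, T, d = x.shape
        dh = d // nh
        return np.ascontiguousarray(
            x.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
        ).reshape(B * nh, T, dh)

    @staticmethod
    def _merge_heads(x, B, nh):
        Bh, T, dh = x.shape
        return np.ascontiguousarray(
            x.reshape(B, nh, T, dh).transpose(0, 2, 1, 3)
        ).reshape(B, T, nh * dh)

    def backward(self, dlogits):
        cfg = self.config
        d = np.asarray(dlogits, dtype=nn.DTYPE)
        for layer in reversed(self.classifier):
            d = layer.backward(d)
        B = d.shape[0]
        t = self.t_prime

        v = cfg.variant
        if self.has_cross_attention:
            dv_ = cfg.attention_dv
            d_lr = d[:, : t * dv_].reshape(B, t, dv_)
            d_rl = d[:, t * dv_:].reshape(B, t, dv_)
            dtok = {"L": np.zeros((B, t, 1), dtype=nn.DTYPE),
                    "R": np.zeros((B, t, 1), dtype=nn.DTYPE)}
            for dname, dout in zip(DIRECTIONS, (d_lr, d_rl)):
                cache, qs, ks, _ = self._attn_cache[dname]
                dQ, dK, dV = nn.attention_backward(dout, cache)
                proj = self.attn_proj[dname]
                dtok[qs] += proj["q"].backward(dQ)
                dtok[ks] += proj["k"].backward(dK)
                dtok[ks] += proj["v"].backward(dV)
            dtoks = {s: dtok[s][..., 0] for s in ("L", "R")}
        elif v == "self_attention":
            sdv = cfg.self_attention_dv
            dtoks = {}
            for i, s in enumerate(("L", "R")):
                dmean = d[:, i * sdv:(i + 1) * sdv]
                cache, out_shape = self._sa_cache[s]
                dout = np.repeat(dmean[:, None, :], t, axis=1) / t
                dQ, dK, dV = nn.attention_backward(dout.astype(nn.DTYPE), cache)
                proj = self.sa_proj[s]
                dt3 = proj["q"].backward(dQ) + proj["k"].backward(dK) \
                    + proj["v"].backward(dV)
                dtoks[s] = dt3[..., 0]
            dtoks = {s: dtoks[s] for s in ("L", "R")}
        elif v == "lightweight_transformer":
            dtoks = self._transformer_backward(d)
        else:
            dtoks = {"L": d[:, :t], "R": d[:, t:]}

        self._decode_backward(dtoks)

    def _transformer_backward(self, dfeat):
        cfg = self.config
        T2 = self._tf_t2
        t = self.t_prime
        dh2 = np.repeat(dfeat[:, None, :], T2, axis=1) / T2
        dh1f = self.ln2.backward(dh2.astype(nn.DTYPE))
        df = self.ffn1.backward(
            self.ffn_act.backward(self.ffn2.backward(dh1f))
        )
        dh1 = dh1f + df
        dh0a = self.ln1.backward(dh1)
        dattn = self.mha["wo"].backward(dh0a)
        cache, B, nh = self._tf_attn_cache
        dQ, dK, dV = nn.attention_backward(self._split_heads(dattn, nh), cache)
        dh0b = (
            self.mha["wq"].backward(self._merge_heads(dQ, B, nh))
            + self.mha["wk"].backward(self._merge_heads(dK, B, nh))
            + self.mha["wv"].backward(self._merge_heads(dV, B, nh))
        )
        dh0 = dh0a + dh0b
        dpos = dh0.sum(axis=0)
        self.pos_emb.grad += dpos[:t] + dpos[t:]
        self.chan_emb.grad += np.stack(
            [dpos[:t].sum(axis=0), dpos[t:].sum(axis=0)]
        )
        dseq = self.tok_lift.backward(dh0)
        return {"L": dseq[:, :t, 0], "R": dseq[:, t:, 0]}

    def _decode_backward(self, dtoks):
        cfg = self.config
        if cfg.share_streams:
            dtok = np.concatenate([dtoks["L"], dtoks["R"]], axis=0)
            dh = self._pointwise_backward("L", dtok)
            self._blocks_backward(self.encoders["L"], dh)
            return
        for s in ("L", "R"):
            dh = self._pointwise_backward(s, dtoks[s])
            self._blocks_backward(self.encoders[s], dh)

    def _pointwise_backward(self, stream, dtok):
        if self.has_pointwise:
            return self.pointwise[stream].backward(dtok[:, None, :])
        c = self._nopw_channels
        return np.broadcast_to(
            (dtok[:, None, :] / c).astype(nn.DTYPE), (dtok.shape[0], c, dtok.shape[1])
        ).copy()

    @staticmethod
    def _blocks_backward(blocks, dh):
        for block in reversed(blocks):
            for layer in reversed(block):
                dh = layer.backward(dh)
        return dh

    # -- inference helpers ---------------------------------------------------

    def predict_logits(self, x, batch_size: int = 64):
        """Evaluation-mode logits, computed in batches."""
        x = np.asarray(x, dtype=nn.DTYPE)
        outs = [self.forward(x[i:i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


def build_model(config: ModelConfig, seed: int = 42) -> DeepAttNet:
    """Build a trainable model; a fixed seed fixes the initial parameters."""
    return DeepAttNet(config, seed)


def build_variant(config: ModelConfig, variant: str, seed: int = 42) -> DeepAttNet:
    """Build one of the ablation variants on an otherwise identical config."""
    if variant not in VARIANTS:
        raise UnsupportedVariantError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    cfg = ModelConfig(**{**config.__dict__, "variant": variant})
    return DeepAttNet(cfg, seed)


def classify(model: DeepAttNet, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode logits for a (batch, 2, 7500) array (dropout off)."""
    return model.predict_logits(batch)


def save_checkpoint(model: DeepAttNet, path: str) -> None:
    """Serialize parameters and buffers (.npz) with a JSON config sidecar."""
    import json

    base = str(path)
    base = base[:-4] if base.endswith(".npz") else base
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    for i, layer in enumerate(model._layers):
        for k, v in layer.buffers.items():
            arrays[f"buffer_{i}_{k}"] = v
    np.savez(base + ".npz", **arrays)
    cfg = dict(model.config.__dict__)
    with open(base + ".json", "w") as fh:
        json.dump({"config": cfg, "seed": model.seed}, fh, indent=1)


def load_checkpoint(path: str) -> DeepAttNet:
    import json

    base = str(path)
    base = base[:-4] if base.endswith(".npz") else base
    with open(base + ".json") as fh:
        meta = json.load(fh)
    cfg_dict = meta["config"]
    for key in ("kernel_lengths", "filters", "betas"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    if isinstance(cfg_dict.get("pool"), list):
        cfg_dict["pool"] = tuple(tuple(p) for p in cfg_dict["pool"])
    model = DeepAttNet(ModelConfig(**cfg_dict), seed=meta["seed"])
    with np.load(base + ".npz") as data:
        for i, p in enumerate(model.parameters()):
            p.value = data[f"param_{i}"].copy()
        for i, layer in enumerate(model._layers):
            for k in layer.buffers:
                layer.buffers[k] = data[f"buffer_{i}_{k}"].copy()
    return model


def describe(config: ModelConfig, seed: int = 42) -> str:
    """Layer table and parameter count for a config."""
    model = build_model(config, seed)
    lines = [f"variant: {config.variant}", f"tokens (T'): {model.t_prime}"]
    for p in model.parameters():
        lines.append(f"  {p.name:24s} {str(p.value.shape):18s} {p.value.size}")
    lines.append(f"total trainable parameters: {model.num_parameters()}")
    return "\n".join(lines)
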