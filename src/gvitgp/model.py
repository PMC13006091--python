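"""The GViT-GP network and its ablation variants.

Dual-pathway design: SNP tokens pass through a Pre-LN transformer encoder
with learnable relative positional bias; in parallel, each individual's
genomic-relationship vector is projected by a small FFN into ``m_g`` GRM
tokens. A cross-attention block (queries from the SNP pathway, keys/values
from the GRM tokens, no positional term) fuses the pathways between a
pre-fusion and a post-fusion encoder stack, and an MLP regression head reads
the [CLS] state.

Variants:

* ``gvit_gp``    — full model (pre blocks -> cross-attention fusion -> post
  blocks -> head);
* ``gvit_base``  — encoder only, fusion skipped;
* ``grm_mlp``    — GRM pathway output (flattened) -> head, tokens ignored;
* ``gvit_concat``— encoder [CLS] concatenated with the flattened GRM pathway
  output -> widened head (static fusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    dropout,
    gelu,
    layer_norm,
    softmax,
    take_rel_bias,
)
from .exceptions import ContractError
from .tokenization import TokenBatch

VARIANTS = ("gvit_gp", "gvit_base", "grm_mlp", "gvit_concat")


@dataclass
class ModelConfig:
    D: int = 128
    n_heads: int = 8
    L_pre: int = 2
    L_post: int = 2
    ffn_mult: int = 4
    n_ref: int = 1            # GRM pathway input width (training-cohort size)
    grm_hidden: int = 512
    m_g: int = 1              # number of GRM tokens
    dropout: float = 0.1
    variant: str = "gvit_gp"

    def validate(self) -> None:
        if self.D % self.n_heads != 0:
            raise ContractError("D must be divisible by n_heads")
        if self.n_ref < 1 or self.m_g < 1:
            raise ContractError("n_ref and m_g must be >= 1")
        if self.variant not in VARIANTS:
            raise ContractError(f"unknown variant {self.variant!r}")

    @property
    def d_k(self) -> int:
        return self.D // self.n_heads

    @property
    def head_in(self) -> int:
        if self.variant == "grm_mlp":
            return self.m_g * self.D
        if self.variant == "gvit_concat":
            return self.D + self.m_g * self.D
        return self.D


@dataclass
class AttentionRecord:
    """Head-averaged [CLS] attention row of one self-attention layer."""

    layer: int | str
    cls_row: np.ndarray                    # (S,), sums to 1
    per_head: np.ndarray | None = None     # (n_heads, S)


def gelu_approx(x):
    """Tanh approximation 0.5 x (1 + tanh(sqrt(2/pi)(x + 0.044715 x^3)))."""
    x = np.asarray(x, dtype=float)
    inner = math.sqrt(2.0 / math.pi) * (x + 0.044715 * x ** 3)
    out = 0.5 * x * (1.0 + np.tanh(inner))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameter construction
# ---------------------------------------------------------------------------


def init_params(
    cfg: ModelConfig, patch_in: int, S_max: int, seed: int = 0
) -> dict[str, Tensor]:
    """All learnable parameters, N(0, 0.02^2) weights, zero biases/bias table."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    P: dict[str, Tensor] = {}

    def W(name, *shape):
        P[name] = Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)

    def Z(name, *shape):
        P[name] = Tensor(np.zeros(shape), requires_grad=True)

    def O(name, *shape):
        P[name] = Tensor(np.ones(shape), requires_grad=True)

    D, H = cfg.D, cfg.n_heads
    W("embed.W", patch_in, D)
    Z("embed.b", D)
    W("embed.cls", D)

    for i in range(cfg.L_pre + cfg.L_post):
        pre = f"block{i}."
        O(pre + "ln1.g", D); Z(pre + "ln1.b", D)
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            W(pre + nm, D, D)
        for nm in ("bq", "bk", "bv", "bo"):
            Z(pre + nm, D)
        Z(pre + "rel", H, 2 * S_max - 1)
        O(pre + "ln2.g", D); Z(pre + "ln2.b", D)
        W(pre + "ffn.W1", D, cfg.ffn_mult * D); Z(pre + "ffn.b1", cfg.ffn_mult * D)
        W(pre + "ffn.W2", cfg.ffn_mult * D, D); Z(pre + "ffn.b2", D)

    W("grm.W1", cfg.n_ref, cfg.grm_hidden); Z("grm.b1", cfg.grm_hidden)
    W("grm.W2", cfg.grm_hidden, cfg.m_g * D); Z("grm.b2", cfg.m_g * D)
    O("grm.ln.g", D); Z("grm.ln.b", D)

    O("fuse.ln.g", D); Z("fuse.ln.b", D)
    for nm in ("Wq", "Wk", "Wv", "Wo"):
        W("fuse." + nm, D, D)
    for nm in ("bq", "bk", "bv", "bo"):
        Z("fuse." + nm, D)
    O("fuse.ln2.g", D); Z("fuse.ln2.b", D)
    W("fuse.ffn.W1", D, cfg.ffn_mult * D); Z("fuse.ffn.b1", cfg.ffn_mult * D)
    W("fuse.ffn.W2", cfg.ffn_mult * D, D); Z("fuse.ffn.b2", D)

    h_in = cfg.head_in
    h_mid = max(1, h_in // 2)
    W("head.W1", h_in, h_mid); Z("head.b1", h_mid)
    W("head.W2", h_mid, 1); Z("head.b2", 1)
    return P


def param_count(cfg: ModelConfig, patch_in: int, S_max: int) -> int:
    """Closed-form learnable-parameter count for a config (pure function)."""
    D, H, F = cfg.D, cfg.n_heads, cfg.ffn_mult
    embed = patch_in * D + D + D
    per_block = (
        2 * D                       # ln1
        + 4 * (D * D + D)           # q,k,v,o
        + H * (2 * S_max - 1)       # relative bias table
        + 2 * D                     # ln2
        + D * F * D + F * D         # ffn W1,b1
        + F * D * D + D             # ffn W2,b2
    )
    grm = (cfg.n_ref * cfg.grm_hidden + cfg.grm_hidden
           + cfg.grm_hidden * cfg.m_g * D + cfg.m_g * D + 2 * D)
    fuse = 2 * D + 4 * (D * D + D) + 2 * D + D * F * D + F * D + F * D * D + D
    h_in = cfg.head_in
    h_mid = max(1, h_in // 2)
    head = h_in * h_mid + h_mid + h_mid * 1 + 1
    return embed + (cfg.L_pre + cfg.L_post) * per_block + grm + fuse + head


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _ln(x: Tensor, P: dict, prefix: str) -> Tensor:
    return layer_norm(x) * P[prefix + ".g"] + P[prefix + ".b"]


def _affine3(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """(B, S, D) @ (D, D') + b via one flat 2-D gemm."""
    B, S, D = x.shape
    return (x.reshape(B * S, D) @ W + b).reshape(B, S, W.shape[1])


def _split_heads(x: Tensor, B: int, S: int, H: int, dk: int) -> Tensor:
    return x.reshape(B, S, H, dk).transpose((0, 2, 1, 3))


def _merge_heads(x: Tensor, B: int, S: int, D: int) -> Tensor:
    return x.transpose((0, 2, 1, 3)).reshape(B, S, D)


def mhsa_relpos(
    x: Tensor,
    P: dict[str, Tensor],
    prefix: str,
    cfg: ModelConfig,
    S_max: int,
    record: bool = False,
) -> tuple[Tensor, np.ndarray | None]:
    """Multi-head self-attention with learnable relative positional bias.

    Per head i: softmax(Q K'/sqrt(d_k) + B_i) V, with (B_i)_{j,k} read from a
    per-head lookup table at relative index k - j.
    """
    B, S, D = x.shape
    if S > S_max:
        raise ContractError(f"sequence length {S} exceeds bias table capacity {S_max}")
    H, dk = cfg.n_heads, cfg.d_k
    q = _split_heads(_affine3(x, P[prefix + "Wq"], P[prefix + "bq"]), B, S, H, dk)
    k = _split_heads(_affine3(x, P[prefix + "Wk"], P[prefix + "bk"]), B, S, H, dk)
    v = _split_heads(_affine3(x, P[prefix + "Wv"], P[prefix + "bv"]), B, S, H, dk)
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk))
    rel_idx = (np.arange(S)[None, :] - np.arange(S)[:, None]) + (S_max - 1)
    bias = take_rel_bias(P[prefix + "rel"], rel_idx)          # (H, S, S)
    attn = softmax(scores + bias.reshape(1, H, S, S), axis=-1)
    out = _merge_heads(attn @ v, B, S, D)
    out = _affine3(out, P[prefix + "Wo"], P[prefix + "bo"])
    weights = attn.data.copy() if record else None
    return out, weights


def pre_ln_block(
    x: Tensor,
    P: dict[str, Tensor],
    i: int,
    cfg: ModelConfig,
    S_max: int,
    training: bool = False,
    rng: np.random.Generator | None = None,
    record: bool = False,
) -> tuple[Tensor, np.ndarray | None]:
    """x' = x + MHSA(LN(x)); out = x' + FFN(LN(x'))."""
    pre = f"block{i}."
    att, w = mhsa_relpos(_ln(x, P, pre + "ln1"), P, pre, cfg, S_max, record=record)
    if training and cfg.dropout > 0:
        att = dropout(att, cfg.dropout, rng, training)
    x1 = x + att
    h = _affine3(_ln(x1, P, pre + "ln2"), P[pre + "ffn.W1"], P[pre + "ffn.b1"])
    h = _affine3(gelu(h), P[pre + "ffn.W2"], P[pre + "ffn.b2"])
    if training and cfg.dropout > 0:
        h = dropout(h, cfg.dropout, rng, training)
    return x1 + h, w


def grm_pathway(v: np.ndarray | Tensor, P: dict[str, Tensor], cfg: ModelConfig) -> Tensor:
    """affine(n_ref -> hidden) -> GELU -> affine(-> m_g * D) -> per-token LN."""
    x = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))
    if x.shape[-1] != cfg.n_ref:
        raise ContractError(
            f"GRM vector length {x.shape[-1]} != model n_ref {cfg.n_ref} "
            "(was the model trained on a different reference cohort?)"
        )
    h = gelu(x @ P["grm.W1"] + P["grm.b1"]) @ P["grm.W2"] + P["grm.b2"]
    B = h.shape[0]
    tokens = h.reshape(B, cfg.m_g, cfg.D)
    return layer_norm(tokens) * P["grm.ln.g"] + P["grm.ln.b"]


def cross_attention_fuse(
    h_snp: Tensor,
    h_grm: Tensor,
    P: dict[str, Tensor],
    cfg: ModelConfig,
    record: bool = False,
) -> tuple[Tensor, np.ndarray | None]:
    """Queries from LN(SNP tokens); keys/values from the GRM tokens.

    No positional term: the GRM tokens are not an ordered genomic sequence.
    Residual + Pre-LN FFN wrap the attention output.
    """
    B, S, D = h_snp.shape
    H, dk = cfg.n_heads, cfg.d_k
    m_g = h_grm.shape[1]
    q = _split_heads(_affine3(_ln(h_snp, P, "fuse.ln"), P["fuse.Wq"], P["fuse.bq"]),
                     B, S, H, dk)
    k = _split_heads(_affine3(h_grm, P["fuse.Wk"], P["fuse.bk"]), B, m_g, H, dk)
    v = _split_heads(_affine3(h_grm, P["fuse.Wv"], P["fuse.bv"]), B, m_g, H, dk)
    attn = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dk)), axis=-1)
    out = _affine3(_merge_heads(attn @ v, B, S, D), P["fuse.Wo"], P["fuse.bo"])
    x1 = h_snp + out
    h = _affine3(_ln(x1, P, "fuse.ln2"), P["fuse.ffn.W1"], P["fuse.ffn.b1"])
    h = _affine3(gelu(h), P["fuse.ffn.W2"], P["fuse.ffn.b2"])
    weights = attn.data.copy() if record else None
    return x1 + h, weights


def regression_head(
    cls_state: Tensor,
    P: dict[str, Tensor],
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """affine(-> head_in/2) -> GELU -> dropout -> affine(-> 1)."""
    h = gelu(cls_state @ P["head.W1"] + P["head.b1"])
    if training and cfg.dropout > 0:
        h = dropout(h, cfg.dropout, rng, training)
    out = h @ P["head.W2"] + P["head.b2"]
    return out.reshape(out.shape[0])


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


class GViTGP:
    """Parameter container + forward pass for one variant."""

    def __init__(self, cfg: ModelConfig, patch_in: int, S_max: int, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        self.patch_in = patch_in
        self.S_max = S_max
        self.params = init_params(cfg, patch_in, S_max, seed=seed)

    def forward(
        self,
        tokens: TokenBatch | None,
        grm_vectors: np.ndarray | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
        record_attention: bool = False,
    ) -> tuple[Tensor, list[AttentionRecord]]:
        cfg, P = self.cfg, self.params
        needs_grm = cfg.variant in ("gvit_gp", "grm_mlp", "gvit_concat")
        if needs_grm and grm_vectors is None:
            raise ContractError(f"variant {cfg.variant} requires grm_vectors")
        if cfg.variant != "grm_mlp" and tokens is None:
            raise ContractError(f"variant {cfg.variant} requires tokens")
        records: list[AttentionRecord] = []

        if cfg.variant == "grm_mlp":
            h_grm = grm_pathway(grm_vectors, P, cfg)
            flat = h_grm.reshape(h_grm.shape[0], cfg.m_g * cfg.D)
            return regression_head(flat, P, cfg, training, rng), records

        x = tokens.tokens
        layer = 0
        for i in range(cfg.L_pre):
            x, w = pre_ln_block(x, P, layer, cfg, self.S_max, training, rng,
                                record=record_attention)
            if w is not None:
                records.append(_cls_record(layer, w))
            layer += 1

        if cfg.variant == "gvit_gp":
            h_grm = grm_pathway(grm_vectors, P, cfg)
            x, w = cross_attention_fuse(x, h_grm, P, cfg, record=record_attention)
            if w is not None:
                records.append(_cls_record("fusion", w))

        for i in range(cfg.L_post):
            x, w = pre_ln_block(x, P, layer, cfg, self.S_max, training, rng,
                                record=record_attention)
            if w is not None:
                records.append(_cls_record(layer, w))
            layer += 1

        cls_state = x[:, 0, :]
        if cfg.variant == "gvit_concat":
            h_grm = grm_pathway(grm_vectors, P, cfg)
            flat = h_grm.reshape(h_grm.shape[0], cfg.m_g * cfg.D)
            cls_state = concat([cls_state, flat], axis=1)
        return regression_head(cls_state, P, cfg, training, rng), records


def _cls_record(layer, attn_weights: np.ndarray) -> AttentionRecord:
    """Average the [CLS] query row over batch and heads."""
    # attn_weights: (B, H, S, S_kv); CLS is query index 0
    cls_rows = attn_weights[:, :, 0, :]          # (B, H, S_kv)
    per_head = cls_rows.mean(axis=0)             # (H, S_kv)
    return AttentionRecord(layer=layer, cls_row=per_head.mean(axis=0),
                           per_head=per_head)


def zero_fusion_branch(model: GViTGP) -> None:
    """Weight surgery: silence the fusion block's contribution.

    With the cross-attention output projection and the fusion FFN's second
    affine zeroed, the fusion block is the identity on the SNP tokens, so a
    ``gvit_gp`` forward reproduces ``gvit_base`` exactly under shared weights.
    """
    for nm in ("fuse.Wo", "fuse.bo", "fuse.ffn.W2", "fuse.ffn.b2"):
        model.params[nm].data[...] = 0.0
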