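"""The convolution-gated, rotary dual cross-attention ddG regressor.

Pipeline, applied to the four per-residue embedding matrices of a complex
(wild-type / mutant antibody and antigen):

1. optional learned input projection d -> d_model;
2. *convolutional position gating*: spatial weights from a kernel-1 (or any
   odd-kernel) 1-D convolution over the layer-normalized matrix, softmaxed
   across sequence positions and multiplied back in,
   ``H' = softmax(Conv1D(LN(H))) * LN(H)``;
3. rotary-position-embedded Q/K projections (V carries no rotation),
   ``Q = RoPE(H' Wq), K = RoPE(H' Wk), V = H' Wv``;
4. *dual multi-head cross-attention*: antibody queries attend over antigen
   keys/values and symmetrically antigen queries over antibody keys/values,
   separately for the wild-type and mutant pairs; per head
   ``A = softmax(Q K^T / scale)``, with ``scale = d_head`` by default
   (``sqrt_d`` selects the conventional ``sqrt(d_head)``);
5. heads concatenated and projected by ``Wo``;
6. *convolutional pooling*: a per-position scalar score over ``LN(Ho)``,
   softmaxed across positions, gives an attention-weighted sum -> one vector
   per stream;
7. prediction head on ``f = concat(f_ab_wt + f_ag_wt, f_ab_mt + f_ag_mt)``:
   ``y = W3 tanh(W2 relu(dropout(W1 f)))``.

One set of gate / projection / pooling weights is shared by all four streams
(the same operation applied in parallel).  All operations accept a batch
dimension and a padding mask; every softmax is computed over valid positions
only, with max-subtraction for stability.

Ablation variants: ``no_attention`` skips steps 3-5 entirely (pooling applies
to the gated streams); ``mlp_replacement`` swaps them for a position-wise
two-layer MLP of comparable parameter count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from ._autodiff import (
    Tensor,
    as_tensor,
    concat,
    layer_norm_op,
    masked_softmax_op,
    rope_rotate_op,
)
from .data_io import ComplexRecord
from .embedding import (
    ComplexEmbeddings,
    EmbedderSpec,
    embed_complex,
)

LN_EPS = 1e-5
STREAMS = ("ab_wt", "ag_wt", "ab_mt", "ag_mt")
VARIANTS = ("full", "no_attention", "mlp_replacement")


class ShapeError(ValueError):
    pass


class MaskError(ValueError):
    """Raised when a sequence has no valid (unmasked) position."""


@dataclass(frozen=True)
class AttentionConfig:
    """Architecture hyperparameters.

    Defaults: 8 heads over a 256-wide model, dropout 0.1, rotary base 1e4,
    kernel-1 gating convolution, one attention block.  ``scale_mode``
    "d_head" divides attention logits by the head dimension itself;
    "sqrt_d" uses its square root.
    """

    d_model: int = 256
    n_heads: int = 8
    scale_mode: str = "d_head"
    dropout_rate: float = 0.1
    conv_kernel: int = 1
    rope_base: float = 10000.0
    head_hidden: tuple[int, int] = (64, 32)
    variant: str = "full"

    def __post_init__(self):
        if self.d_model <= 0 or self.d_model % 2 != 0:
            raise ShapeError(f"d_model must be a positive even integer, got {self.d_model}")
        if self.n_heads <= 0 or self.d_model % self.n_heads != 0:
            raise ShapeError(
                f"n_heads ({self.n_heads}) must divide d_model ({self.d_model})"
            )
        if (self.d_model // self.n_heads) % 2 != 0:
            raise ShapeError("head dimension must be even for rotary pairs")
        if self.scale_mode not in ("d_head", "sqrt_d"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            raise ShapeError("conv_kernel must be odd")
        if self.rope_base <= 0:
            raise ValueError("rope_base must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "AttentionConfig":
        payload = json.loads(text)
        payload["head_hidden"] = tuple(payload["head_hidden"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ModelParameters:
    """All trainable tensors, keyed by name; the frozen embedder owns none."""

    def __init__(self, tensors: dict[str, Tensor], config: AttentionConfig, d_in: int):
        self.tensors = tensors
        self.config = config
        self.d_in = d_in

    @classmethod
    def initialize(
        cls, config: AttentionConfig, d_in: int, seed: int = 0
    ) -> "ModelParameters":
        rng = np.random.default_rng(seed)
        d = config.d_model
        t: dict[str, np.ndarray] = {}
        if d_in != d:
            t["in_proj"] = _glorot(rng, d_in, d, (d_in, d))
            t["in_bias"] = np.zeros(d)
        t["gate_ln_gain"] = np.ones(d)
        t["gate_ln_bias"] = np.zeros(d)
        t["gate_conv_w"] = _glorot(rng, d * config.conv_kernel, 1, (config.conv_kernel, d))
        t["gate_conv_b"] = np.zeros(1)
        if config.variant == "full":
            for name in ("Wq", "Wk", "Wv", "Wo"):
                t[name] = _glorot(rng, d, d, (d, d))
        elif config.variant == "mlp_replacement":
            # two-layer position-wise MLP with hidden width 2*d matches the
            # 4*d^2 weights of {Wq, Wk, Wv, Wo} exactly
            h = 2 * d
            t["mlp_W1"] = _glorot(rng, d, h, (d, h))
            t["mlp_W2"] = _glorot(rng, h, d, (h, d))
        t["pool_ln_gain"] = np.ones(d)
        t["pool_ln_bias"] = np.zeros(d)
        t["pool_wc"] = _glorot(rng, d, 1, (d, 1))
        t["pool_b"] = np.zeros(1)
        h1, h2 = config.head_hidden
        t["head_W1"] = _glorot(rng, 2 * d, h1, (2 * d, h1))
        t["head_b1"] = np.zeros(h1)
        t["head_W2"] = _glorot(rng, h1, h2, (h1, h2))
        t["head_b2"] = np.zeros(h2)
        t["head_W3"] = _glorot(rng, h2, 1, (h2, 1))
        t["head_b3"] = np.zeros(1)
        tensors = {k: Tensor(v, requires_grad=True) for k, v in t.items()}
        return cls(tensors, config, d_in)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tensors

    def items(self):
        return self.tensors.items()

    def n_params(self, prefix: str | tuple = "") -> int:
        return sum(
            t.data.size for k, t in self.tensors.items() if k.startswith(prefix)
        )

    def interaction_param_count(self) -> int:
        """Parameters of the swappable interaction block (attention or MLP)."""
        return self.n_params(("Wq", "Wk", "Wv", "Wo", "mlp_"))

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.zero_grad()

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.tensors):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.tensors[k].data).tobytes())
        return h.hexdigest()

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            {k: Tensor(t.data.copy(), requires_grad=True) for k, t in self.items()},
            self.config,
            self.d_in,
        )

    def save(self, path: str | Path) -> None:
        """Parameter archive (.npz) with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{k: t.data for k, t in self.tensors.items()})
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"schema": 1, "d_in": self.d_in,
                        "config": json.loads(self.config.to_json())})
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if meta.get("schema") != 1:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfg = meta["config"]
        cfg["head_hidden"] = tuple(cfg["head_hidden"])
        with np.load(path) as archive:
            tensors = {k: Tensor(archive[k], requires_grad=True) for k in archive.files}
        return cls(tensors, AttentionConfig(**cfg), meta["d_in"])


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def _slice_batch(x: Tensor, start: int, stop: int) -> Tensor:
    return x.slice0(start, stop)


def _batched(x) -> tuple[Tensor, bool]:
    x = as_tensor(x)
    if x.ndim == 2:
        return x.reshape(1, *x.shape), True
    if x.ndim != 3:
        raise ShapeError(f"expected (L, d) or (B, L, d), got shape {x.shape}")
    return x, False


def _batched_mask(mask, B: int, L: int) -> np.ndarray:
    if mask is None:
        return np.ones((B, L))
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, (B, L)).copy()
    if mask.shape != (B, L):
        raise ShapeError(f"mask shape {mask.shape} does not match batch ({B}, {L})")
    if np.any(mask.sum(axis=-1) < 1):
        raise MaskError("every sequence needs at least one valid position")
    return mask


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = LN_EPS) -> Tensor:
    return layer_norm_op(x, gain, bias, eps)


def masked_softmax(logits: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over `axis` restricted to mask==1 positions (max-subtracted).

    Masked entries come out exactly zero; each valid slice sums to 1.
    """
    if np.any(np.sum(mask, axis=axis) < 1):
        raise MaskError("softmax over an all-masked axis")
    return masked_softmax_op(logits, mask, axis=axis)


@lru_cache(maxsize=64)
def _shift_matrix(L: int, offset: int) -> np.ndarray:
    """S such that (S @ X)[l] = X[l + offset] with zero padding."""
    S = np.zeros((L, L))
    for l in range(L):
        if 0 <= l + offset < L:
            S[l, l + offset] = 1.0
    return S


def conv_gate(H, mask, params: ModelParameters) -> Tensor:
    """Eq-style position gating: H' = softmax(Conv1D(LN(H))) * LN(H)."""
    x, squeeze = _batched(H)
    B, L, d = x.shape
    m = _batched_mask(mask, B, L)
    ln = layer_norm(x, params["gate_ln_gain"], params["gate_ln_bias"])
    ln = ln * m[..., None]
    scores = _conv_scores(ln, params, L)
    weights = masked_softmax(scores, m, axis=-1)
    out = ln * weights.reshape(B, L, 1)
    return out.reshape(*out.shape[1:]) if squeeze else out


def _conv_scores(ln: Tensor, params: ModelParameters, L: int) -> Tensor:
    """Single-channel odd-kernel 1-D convolution over positions (zero padded)."""
    k = params["gate_conv_w"].shape[0]
    r = k // 2
    scores = None
    for j in range(k):
        w_j = as_tensor(_one_hot_row(k, j)) @ params["gate_conv_w"]  # row j: (d,)
        term = ln @ w_j  # (B, L)
        if j != r:
            term = term @ as_tensor(_shift_matrix(L, j - r).T)
        scores = term if scores is None else scores + term
    return scores + params["gate_conv_b"]


@lru_cache(maxsize=16)
def _one_hot_row(n: int, j: int) -> np.ndarray:
    v = np.zeros(n)
    v[j] = 1.0
    return v


def gate_weights(H, mask, params: ModelParameters) -> np.ndarray:
    """The softmax position weights of the gating step (for inspection)."""
    x, squeeze = _batched(H)
    B, L, _ = x.shape
    m = _batched_mask(mask, B, L)
    ln = layer_norm(x, params["gate_ln_gain"], params["gate_ln_bias"]) * m[..., None]
    w = masked_softmax(_conv_scores(ln, params, L), m, axis=-1).data
    return w[0] if squeeze else w


def apply_rope(X, positions=None, base: float = 10000.0) -> Tensor:
    """Rotate consecutive dimension pairs of row m by m * base^(-2i/d).

    Norm of every pair is preserved; dot products of rotated query/key rows
    depend only on relative positions.
    """
    x, squeeze = _batched(X)
    B, L, d = x.shape
    if d % 2 != 0:
        raise ShapeError(f"rotary embedding needs an even width, got {d}")
    half = d // 2
    if positions is None:
        positions = np.arange(L, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    theta = base ** (-2.0 * np.arange(half) / d)  # (half,)
    ang = positions[:, None] * theta[None, :]  # (L, half)
    out = rope_rotate_op(x, np.cos(ang), np.sin(ang))
    return out.reshape(L, d) if squeeze else out


def project_qkv(Hp, params: ModelParameters, config: AttentionConfig, positions=None):
    """Q = RoPE(H' Wq), K = RoPE(H' Wk), V = H' Wv (V carries no rotation)."""
    x, squeeze = _batched(Hp)
    L = x.shape[1]
    if positions is None:
        positions = np.arange(L, dtype=np.float64)
    q = apply_rope(x @ params["Wq"], positions, config.rope_base)
    k = apply_rope(x @ params["Wk"], positions, config.rope_base)
    v = x @ params["Wv"]
    if squeeze:
        return q.reshape(L, -1), k.reshape(L, -1), v.reshape(L, -1)
    return q, k, v


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    B, L, d = x.shape
    return x.reshape(B, L, n_heads, d // n_heads).transpose((0, 2, 1, 3))


def _merge_heads(x: Tensor) -> Tensor:
    B, H, L, dh = x.shape
    return x.transpose((0, 2, 1, 3)).reshape(B, L, H * dh)


def cross_attend(Q, K, V, mask_k, config: AttentionConfig):
    """Multi-head scaled dot-product attention of one stream over its partner.

    Returns the per-head contexts stacked as (B, H, Lq, d_head) and the
    attention weights as a detached (B, H, Lq, Lk) array; each weight row
    sums to 1 over unmasked keys.
    """
    q, squeeze = _batched(Q)
    k, _ = _batched(K)
    v, _ = _batched(V)
    if k.shape[:2] != v.shape[:2]:
        raise ShapeError("key and value lengths must agree")
    B, Lk = k.shape[0], k.shape[1]
    mk = _batched_mask(mask_k, B, Lk)
    qh = _split_heads(q, config.n_heads)
    kh = _split_heads(k, config.n_heads)
    vh = _split_heads(v, config.n_heads)
    scale = float(config.d_head) if config.scale_mode == "d_head" else float(
        np.sqrt(config.d_head)
    )
    logits = (qh @ kh.swapaxes(-1, -2)) / scale
    attn = masked_softmax(logits, mk[:, None, None, :], axis=-1)
    context = attn @ vh
    weights = attn.data.copy()
    if squeeze:
        return context, weights[0]
    return context, weights


def multi_head_merge(context_heads: Tensor, params: ModelParameters) -> Tensor:
    """Concatenate head contexts along features and project by Wo."""
    x = context_heads
    squeeze = False
    if x.ndim == 3:  # (H, L, dh) single sequence
        x = x.reshape(1, *x.shape)
        squeeze = True
    out = _merge_heads(x) @ params["Wo"]
    return out.reshape(*out.shape[1:]) if squeeze else out


def position_mlp(Hp, params: ModelParameters) -> Tensor:
    """Position-wise MLP used by the `mlp_replacement` ablation variant."""
    x, squeeze = _batched(Hp)
    out = ((x @ params["mlp_W1"]).relu()) @ params["mlp_W2"]
    return out.reshape(*out.shape[1:]) if squeeze else out


def conv_pool(Ho, mask, params: ModelParameters) -> Tensor:
    """Attention-weighted sum over positions: scalar score per position,
    softmax across valid positions, weighted sum of the normalized rows."""
    x, squeeze = _batched(Ho)
    B, L, d = x.shape
    m = _batched_mask(mask, B, L)
    ln = layer_norm(x, params["pool_ln_gain"], params["pool_ln_bias"])
    scores = (ln @ params["pool_wc"]).reshape(B, L) + params["pool_b"]
    weights = masked_softmax(scores, m, axis=-1)
    f = (ln * weights.reshape(B, L, 1)).sum(axis=1)
    return f.reshape(d) if squeeze else f


def pool_weights(Ho, mask, params: ModelParameters) -> np.ndarray:
    x, squeeze = _batched(Ho)
    B, L, _ = x.shape
    m = _batched_mask(mask, B, L)
    ln = layer_norm(x, params["pool_ln_gain"], params["pool_ln_bias"])
    scores = (ln @ params["pool_wc"]).reshape(B, L) + params["pool_b"]
    w = masked_softmax(scores, m, axis=-1).data
    return w[0] if squeeze else w


def predict_head(
    f_ab_wt,
    f_ag_wt,
    f_ab_mt,
    f_ag_mt,
    params: ModelParameters,
    training: bool = False,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """y = W3 tanh(W2 relu(dropout(W1 concat(f_wt_sum, f_mt_sum))))."""
    fs = [as_tensor(f) for f in (f_ab_wt, f_ag_wt, f_ab_mt, f_ag_mt)]
    squeeze = fs[0].ndim == 1
    if squeeze:
        fs = [f.reshape(1, -1) for f in fs]
    widths = {f.shape[-1] for f in fs}
    if len(widths) != 1:
        raise ShapeError(f"pooled vectors have inconsistent widths {widths}")
    f = concat([fs[0] + fs[1], fs[2] + fs[3]], axis=-1)
    z = f @ params["head_W1"] + params["head_b1"]
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = (rng.random(z.shape) >= dropout_rate) / (1.0 - dropout_rate)
        z = z * keep
    y = ((z.relu() @ params["head_W2"] + params["head_b2"]).tanh()) @ params[
        "head_W3"
    ] + params["head_b3"]
    y = y.reshape(y.shape[0])
    return y.reshape(()) if squeeze else y


# ---------------------------------------------------------------------------
# fused forward pass
# ---------------------------------------------------------------------------

@dataclass
class AttentionState:
    """Everything the forward pass produced, for diagnostics and interpretation.

    Attention weights are keyed ``(direction, variant)`` with direction in
    {"ab2ag", "ag2ab"} and variant in {"wt", "mt"}; each entry is a
    (n_heads, L_query, L_key) array of row-stochastic per-head weights.
    """

    gated: dict[str, np.ndarray] = field(default_factory=dict)
    attention: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    refined: dict[str, np.ndarray] = field(default_factory=dict)
    pooled: dict[str, np.ndarray] = field(default_factory=dict)
    gate_w: dict[str, np.ndarray] = field(default_factory=dict)
    pool_w: dict[str, np.ndarray] = field(default_factory=dict)
    prediction: float | np.ndarray | None = None


def forward_embedded(
    embeddings: dict[str, Tensor | np.ndarray],
    masks: dict[str, np.ndarray] | None,
    params: ModelParameters,
    config: AttentionConfig | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
    capture: bool = False,
) -> tuple[Tensor, AttentionState | None]:
    """Run the regressor on already-embedded streams.

    `embeddings` maps the four stream names to (B, L, d_in) arrays (or
    (L, d_in) for a single complex); `masks` maps the same names to (B, L)
    validity masks.  Returns the prediction tensor (shape (B,) or scalar)
    and, when `capture` is set, the full :class:`AttentionState`.
    """
    config = config or params.config
    xs: dict[str, Tensor] = {}
    squeeze = False
    for name in STREAMS:
        x, sq = _batched(embeddings[name])
        squeeze = squeeze or sq
        if "in_proj" in params:
            x = x @ params["in_proj"] + params["in_bias"]
        elif x.shape[-1] != config.d_model:
            raise ShapeError(
                f"stream {name}: width {x.shape[-1]} != d_model {config.d_model} "
                "and no input projection was initialized"
            )
        xs[name] = x
    ms = {
        name: _batched_mask(
            None if masks is None else masks.get(name), xs[name].shape[0],
            xs[name].shape[1]
        )
        for name in STREAMS
    }
    state = AttentionState() if capture else None
    B = xs["ab_wt"].shape[0]

    def _stored(arr: np.ndarray) -> np.ndarray:
        return arr[0].copy() if squeeze else arr.copy()

    stackable = (
        xs["ab_wt"].shape == xs["ab_mt"].shape
        and xs["ag_wt"].shape == xs["ag_mt"].shape
    )
    if not stackable:
        y = _forward_per_stream(xs, ms, params, config, training, rng,
                                capture, state, _stored)
        if squeeze and y.ndim == 1:
            y = y.reshape(())
        if capture:
            state.prediction = float(y.data) if y.ndim == 0 else y.data.copy()
        return y, state

    # The wild-type/mutant pair of each side shares its length and all
    # weights, so the two variants are stacked along the batch axis and every
    # shared operation runs once per side instead of once per stream.
    sides = {
        "ab": concat([xs["ab_wt"], xs["ab_mt"]], axis=0),
        "ag": concat([xs["ag_wt"], xs["ag_mt"]], axis=0),
    }
    side_masks = {
        "ab": np.concatenate([ms["ab_wt"], ms["ab_mt"]], axis=0),
        "ag": np.concatenate([ms["ag_wt"], ms["ag_mt"]], axis=0),
    }

    def _per_stream(side_arrays: dict) -> dict:
        out = {}
        for side, arr in side_arrays.items():
            out[f"{side}_wt"] = arr[:B]
            out[f"{side}_mt"] = arr[B:]
        return out

    gated = {side: conv_gate(sides[side], side_masks[side], params)
             for side in ("ab", "ag")}
    if capture:
        gated_streams = _per_stream({s: g.data for s, g in gated.items()})
        gate_streams = _per_stream(
            {s: gate_weights(sides[s], side_masks[s], params) for s in sides}
        )
        for name in STREAMS:
            state.gated[name] = _stored(gated_streams[name])
            state.gate_w[name] = _stored(gate_streams[name])

    if config.variant == "full":
        qkv = {side: project_qkv(gated[side], params, config)
               for side in ("ab", "ag")}
        ctx_ab, w_ab = cross_attend(
            qkv["ab"][0], qkv["ag"][1], qkv["ag"][2], side_masks["ag"], config
        )
        ctx_ag, w_ag = cross_attend(
            qkv["ag"][0], qkv["ab"][1], qkv["ab"][2], side_masks["ab"], config
        )
        refined = {
            "ab": multi_head_merge(ctx_ab, params),
            "ag": multi_head_merge(ctx_ag, params),
        }
        if capture:
            for variant, sl in (("wt", slice(None, B)), ("mt", slice(B, None))):
                state.attention[("ab2ag", variant)] = _stored(w_ab[sl])
                state.attention[("ag2ab", variant)] = _stored(w_ag[sl])
    elif config.variant == "mlp_replacement":
        refined = {side: position_mlp(gated[side], params) for side in gated}
    else:  # no_attention
        refined = gated

    if capture:
        refined_streams = _per_stream({s: r.data for s, r in refined.items()})
        for name in STREAMS:
            state.refined[name] = _stored(refined_streams[name])

    pooled = {side: conv_pool(refined[side], side_masks[side], params)
              for side in ("ab", "ag")}
    if capture:
        pooled_streams = _per_stream({s: p.data for s, p in pooled.items()})
        pool_streams = _per_stream(
            {s: pool_weights(refined[s], side_masks[s], params) for s in pooled}
        )
        for name in STREAMS:
            state.pooled[name] = _stored(pooled_streams[name])
            state.pool_w[name] = _stored(pool_streams[name])

    f_ab, f_ag = pooled["ab"], pooled["ag"]
    y = predict_head(
        _slice_batch(f_ab, 0, B), _slice_batch(f_ag, 0, B),
        _slice_batch(f_ab, B, 2 * B), _slice_batch(f_ag, B, 2 * B),
        params, training=training, dropout_rate=config.dropout_rate, rng=rng,
    )
    if squeeze and y.ndim == 1:
        y = y.reshape(())
    if capture:
        state.prediction = float(y.data) if y.ndim == 0 else y.data.copy()
    return y, state


def _forward_per_stream(xs, ms, params, config, training, rng, capture,
                        state, stored):
    """Per-stream pipeline for streams whose wt/mt shapes differ."""
    gated = {name: conv_gate(xs[name], ms[name], params) for name in STREAMS}
    if capture:
        for name in STREAMS:
            state.gated[name] = stored(gated[name].data)
            state.gate_w[name] = stored(gate_weights(xs[name], ms[name], params))
    if config.variant == "full":
        qkv = {name: project_qkv(gated[name], params, config) for name in STREAMS}
        refined = {}
        for variant, ab, ag in (("wt", "ab_wt", "ag_wt"), ("mt", "ab_mt", "ag_mt")):
            ctx_ab, w_ab = cross_attend(
                qkv[ab][0], qkv[ag][1], qkv[ag][2], ms[ag], config
            )
            ctx_ag, w_ag = cross_attend(
                qkv[ag][0], qkv[ab][1], qkv[ab][2], ms[ab], config
            )
            refined[ab] = multi_head_merge(ctx_ab, params)
            refined[ag] = multi_head_merge(ctx_ag, params)
            if capture:
                state.attention[("ab2ag", variant)] = stored(w_ab)
                state.attention[("ag2ab", variant)] = stored(w_ag)
    elif config.variant == "mlp_replacement":
        refined = {name: position_mlp(gated[name], params) for name in STREAMS}
    else:
        refined = gated
    if capture:
        for name in STREAMS:
            state.refined[name] = stored(refined[name].data)
    pooled = {name: conv_pool(refined[name], ms[name], params) for name in STREAMS}
    if capture:
        for name in STREAMS:
            state.pooled[name] = stored(pooled[name].data)
            state.pool_w[name] = stored(
                pool_weights(refined[name], ms[name], params)
            )
    return predict_head(
        pooled["ab_wt"], pooled["ag_wt"], pooled["ab_mt"], pooled["ag_mt"],
        params, training=training, dropout_rate=config.dropout_rate, rng=rng,
    )


def forward(
    record: ComplexRecord,
    spec: EmbedderSpec,
    params: ModelParameters,
    config: AttentionConfig | None = None,
    cache=None,
    embedder=None,
    capture: bool = True,
) -> tuple[float, AttentionState | None]:
    """Embed one record and run the full pipeline; returns (y_hat, state)."""
    emb = embed_complex(record, spec, cache=cache, embedder=embedder)
    tensors = {name: m.values for name, m in emb.as_dict().items()}
    y, state = forward_embedded(tensors, None, params, config, capture=capture)
    return float(y.data), state


def pad_batch(
    embeddings: list[ComplexEmbeddings],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Stack per-record embeddings into padded (B, L_max, d) arrays + masks."""
    out: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    B = len(embeddings)
    for name in STREAMS:
        mats = [getattr(e, name).values for e in embeddings]
        L = max(m.shape[0] for m in mats)
        d = mats[0].shape[1]
        arr = np.zeros((B, L, d))
        msk = np.zeros((B, L))
        for i, m in enumerate(mats):
            arr[i, : m.shape[0]] = m
            msk[i, : m.shape[0]] = 1.0
        out[name] = arr
        masks[name] = msk
    return out, masks
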