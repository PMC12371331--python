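"""Straight-line, loop-based re-implementation of the model's forward pass.

Deliberately written with explicit per-position / per-head Python loops and
no shared code with the package's tensor engine, so it can serve as an
independent oracle for the fused forward pass: gating softmax over
positions, rotary Q/K projection, dual multi-head cross-attention scaled by
the head dimension, convolutional pooling, and the three-layer prediction
head.
"""

import numpy as np

LN_EPS = 1e-5


def ln_rows(X, gain, bias):
    out = np.empty_like(X)
    for l in range(X.shape[0]):
        row = X[l]
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        out[l] = (row - mu) / np.sqrt(var + LN_EPS) * gain + bias
    return out


def softmax_vec(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def gate(H, p):
    ln = ln_rows(H, p["gate_ln_gain"], p["gate_ln_bias"])
    L = H.shape[0]
    kernel = p["gate_conv_w"]
    k = kernel.shape[0]
    r = k // 2
    scores = np.zeros(L)
    for l in range(L):
        for j in range(k):
            src = l + j - r
            if 0 <= src < L:
                scores[l] += float(kernel[j] @ ln[src])
        scores[l] += float(p["gate_conv_b"][0])
    w = softmax_vec(scores)
    out = np.empty_like(ln)
    for l in range(L):
        out[l] = w[l] * ln[l]
    return out


def rope_rows(X, base):
    L, d = X.shape
    out = np.empty_like(X)
    for m in range(L):
        for i in range(d // 2):
            theta = base ** (-2.0 * i / d)
            a = m * theta
            x1, x2 = X[m, 2 * i], X[m, 2 * i + 1]
            out[m, 2 * i] = x1 * np.cos(a) - x2 * np.sin(a)
            out[m, 2 * i + 1] = x1 * np.sin(a) + x2 * np.cos(a)
    return out


def attend(Q, K, V, n_heads, scale_mode):
    Lq, d = Q.shape
    dh = d // n_heads
    scale = dh if scale_mode == "d_head" else np.sqrt(dh)
    ctx = np.zeros((Lq, d))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(Lq):
            logits = np.array([Q[i, sl] @ K[j, sl] / scale for j in range(K.shape[0])])
            w = softmax_vec(logits)
            ctx[i, sl] = sum(w[j] * V[j, sl] for j in range(K.shape[0]))
    return ctx


def pool(Ho, p):
    ln = ln_rows(Ho, p["pool_ln_gain"], p["pool_ln_bias"])
    scores = np.array(
        [float(ln[l] @ p["pool_wc"][:, 0]) + float(p["pool_b"][0])
         for l in range(Ho.shape[0])]
    )
    w = softmax_vec(scores)
    return sum(w[l] * ln[l] for l in range(Ho.shape[0]))


def oracle_forward(embeddings, params, config):
    """embeddings: dict stream -> (L, d_in) array; params: name -> ndarray."""
    p = params
    streams = {}
    for name, H in embeddings.items():
        X = np.asarray(H, dtype=float)
        if "in_proj" in p:
            X = X @ p["in_proj"] + p["in_bias"]
        streams[name] = gate(X, p)
    qkv = {}
    for name, Hp in streams.items():
        qkv[name] = (
            rope_rows(Hp @ p["Wq"], config.rope_base),
            rope_rows(Hp @ p["Wk"], config.rope_base),
            Hp @ p["Wv"],
        )
    pooled = {}
    for ab, ag in (("ab_wt", "ag_wt"), ("ab_mt", "ag_mt")):
        ctx_ab = attend(qkv[ab][0], qkv[ag][1], qkv[ag][2],
                        config.n_heads, config.scale_mode)
        ctx_ag = attend(qkv[ag][0], qkv[ab][1], qkv[ab][2],
                        config.n_heads, config.scale_mode)
        pooled[ab] = pool(ctx_ab @ p["Wo"], p)
        pooled[ag] = pool(ctx_ag @ p["Wo"], p)
    f = np.concatenate(
        [pooled["ab_wt"] + pooled["ag_wt"], pooled["ab_mt"] + pooled["ag_mt"]]
    )
    z = f @ p["head_W1"] + p["head_b1"]
    a = np.maximum(z, 0.0)
    t = np.tanh(a @ p["head_W2"] + p["head_b2"])
    return float(t @ p["head_W3"][:, 0] + p["head_b3"][0])
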