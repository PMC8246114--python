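"""Minimal NumPy encoder-decoder transformer with explicit backpropagation.

Implements exactly the architecture family used for reaction product
prediction: pre-norm multi-head self/cross attention, position-wise ReLU
feed-forward blocks, sinusoidal position encoding, a shared input
embedding for source and target (one combined vocabulary), and an untied
output projection. Forward passes cache the intermediates needed by the
hand-written backward passes; parameters and Adam state live in flat
``dict[str, ndarray]`` maps keyed hierarchically (``enc0.Wq`` ...).

All math is float32. Gradients are exact (verified against numerical
differentiation in the test suite).
"""

from __future__ import annotations

import numpy as np

EPS_LN = 1e-5
NEG_INF = np.float32(-1e9)


# ---------------------------------------------------------------------------
# primitive layers


def linear_fwd(x, W, b):
    return x @ W + b


def linear_bwd(g, x, W):
    x2 = x.reshape(-1, x.shape[-1])
    g2 = g.reshape(-1, g.shape[-1])
    dW = x2.T @ g2
    db = g2.sum(axis=0)
    dx = g @ W.T
    return dx, dW, db


def layernorm_fwd(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + EPS_LN)
    xhat = (x - mu) * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def layernorm_bwd(g, cache):
    xhat, inv, gamma = cache
    d = xhat.shape[-1]
    gg = g * gamma
    dg = (g * xhat).reshape(-1, d).sum(axis=0)
    db = g.reshape(-1, d).sum(axis=0)
    mean_gg = gg.mean(axis=-1, keepdims=True)
    mean_gg_x = (gg * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (gg - mean_gg - xhat * mean_gg_x)
    return dx, dg, db


def softmax(x, axis=-1):
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def dropout_fwd(x, rate, rng, train):
    if not train or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape, dtype=np.float32) >= rate).astype(np.float32)
    mask /= np.float32(1.0 - rate)
    return x * mask, mask


def dropout_bwd(g, mask):
    return g if mask is None else g * mask


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len, dtype=np.float32)[:, None]
    i = np.arange(dim // 2, dtype=np.float32)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.zeros((max_len, dim), dtype=np.float32)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


# ---------------------------------------------------------------------------
# attention


def _split_heads(x, n_heads):
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def attention_fwd(q_in, kv_in, p, prefix, n_heads, mask_bias):
    """Multi-head attention. ``mask_bias``: additive (B or 1, 1, Tq, Tk)."""
    Q = linear_fwd(q_in, p[f"{prefix}.Wq"], p[f"{prefix}.bq"])
    K = linear_fwd(kv_in, p[f"{prefix}.Wk"], p[f"{prefix}.bk"])
    V = linear_fwd(kv_in, p[f"{prefix}.Wv"], p[f"{prefix}.bv"])
    Qh, Kh, Vh = (_split_heads(t, n_heads) for t in (Q, K, V))
    dh = Qh.shape[-1]
    scale = np.float32(1.0 / np.sqrt(dh))
    scores = np.matmul(Qh, Kh.transpose(0, 1, 3, 2)) * scale
    if mask_bias is not None:
        scores = scores + mask_bias
    A = softmax(scores, axis=-1)
    ctx = np.matmul(A, Vh)
    merged = _merge_heads(ctx)
    out = linear_fwd(merged, p[f"{prefix}.Wo"], p[f"{prefix}.bo"])
    cache = (q_in, kv_in, Qh, Kh, Vh, A, merged, scale)
    return out, cache


def attention_bwd(g, cache, p, prefix, n_heads, grads):
    q_in, kv_in, Qh, Kh, Vh, A, merged, scale = cache
    dmerged, dWo, dbo = linear_bwd(g, merged, p[f"{prefix}.Wo"])
    grads[f"{prefix}.Wo"] += dWo
    grads[f"{prefix}.bo"] += dbo
    B, T, D = dmerged.shape
    dh = D // n_heads
    dctx = dmerged.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
    dA = np.matmul(dctx, Vh.transpose(0, 1, 3, 2))
    dVh = np.matmul(A.transpose(0, 1, 3, 2), dctx)
    dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dscores *= scale
    dQh = np.matmul(dscores, Kh)
    dKh = np.matmul(dscores.transpose(0, 1, 3, 2), Qh)
    dQ, dK, dV = (_merge_heads(t) for t in (dQh, dKh, dVh))
    dq_in, dWq, dbq = linear_bwd(dQ, q_in, p[f"{prefix}.Wq"])
    dk_in, dWk, dbk = linear_bwd(dK, kv_in, p[f"{prefix}.Wk"])
    dv_in, dWv, dbv = linear_bwd(dV, kv_in, p[f"{prefix}.Wv"])
    grads[f"{prefix}.Wq"] += dWq
    grads[f"{prefix}.bq"] += dbq
    grads[f"{prefix}.Wk"] += dWk
    grads[f"{prefix}.bk"] += dbk
    grads[f"{prefix}.Wv"] += dWv
    grads[f"{prefix}.bv"] += dbv
    return dq_in, dk_in + dv_in


def ff_fwd(x, p, prefix):
    h_pre = linear_fwd(x, p[f"{prefix}.W1"], p[f"{prefix}.b1"])
    h = np.maximum(h_pre, 0.0)
    out = linear_fwd(h, p[f"{prefix}.W2"], p[f"{prefix}.b2"])
    return out, (x, h_pre, h)


def ff_bwd(g, cache, p, prefix, grads):
    x, h_pre, h = cache
    dh, dW2, db2 = linear_bwd(g, h, p[f"{prefix}.W2"])
    grads[f"{prefix}.W2"] += dW2
    grads[f"{prefix}.b2"] += db2
    dh_pre = dh * (h_pre > 0)
    dx, dW1, db1 = linear_bwd(dh_pre, x, p[f"{prefix}.W1"])
    grads[f"{prefix}.W1"] += dW1
    grads[f"{prefix}.b1"] += db1
    return dx


# ---------------------------------------------------------------------------
# parameter initialization


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def init_params(vocab_size, dim, ff_dim, n_enc, n_dec, rng):
    """Glorot-uniform initialization of every weight matrix, zero biases."""
    p: dict[str, np.ndarray] = {}
    p["emb"] = (rng.standard_normal((vocab_size, dim)) * (dim**-0.5)).astype(np.float32)

    def attn_block(prefix):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"{prefix}.{name}"] = _glorot(rng, (dim, dim))
        for name in ("bq", "bk", "bv", "bo"):
            p[f"{prefix}.{name}"] = np.zeros(dim, dtype=np.float32)

    def ln_block(prefix):
        p[f"{prefix}.g"] = np.ones(dim, dtype=np.float32)
        p[f"{prefix}.b"] = np.zeros(dim, dtype=np.float32)

    def ff_block(prefix):
        p[f"{prefix}.W1"] = _glorot(rng, (dim, ff_dim))
        p[f"{prefix}.b1"] = np.zeros(ff_dim, dtype=np.float32)
        p[f"{prefix}.W2"] = _glorot(rng, (ff_dim, dim))
        p[f"{prefix}.b2"] = np.zeros(dim, dtype=np.float32)

    for i in range(n_enc):
        ln_block(f"enc{i}.ln1")
        attn_block(f"enc{i}.self")
        ln_block(f"enc{i}.ln2")
        ff_block(f"enc{i}.ff")
    ln_block("enc.ln")
    for i in range(n_dec):
        ln_block(f"dec{i}.ln1")
        attn_block(f"dec{i}.self")
        ln_block(f"dec{i}.ln2")
        attn_block(f"dec{i}.cross")
        ln_block(f"dec{i}.ln3")
        ff_block(f"dec{i}.ff")
    ln_block("dec.ln")
    p["gen.W"] = _glorot(rng, (dim, vocab_size))
    p["gen.b"] = np.zeros(vocab_size, dtype=np.float32)
    return p


# ---------------------------------------------------------------------------
# model


class Seq2SeqTransformer:
    """Pre-norm encoder-decoder transformer over a shared vocabulary."""

    def __init__(self, vocab_size, dim, ff_dim, heads, n_enc, n_dec,
                 dropout=0.1, pad_id=0, max_len=512, rng=None):
        if dim % heads:
            raise ValueError("model_dim must be divisible by heads")
        rng = rng or np.random.default_rng(0)
        self.vocab_size = vocab_size
        self.dim = dim
        self.ff_dim = ff_dim
        self.heads = heads
        self.n_enc = n_enc
        self.n_dec = n_dec
        self.dropout = dropout
        self.pad_id = pad_id
        self.pe = sinusoidal_positions(max_len, dim)
        self.params = init_params(vocab_size, dim, ff_dim, n_enc, n_dec, rng)

    # -- embedding ----------------------------------------------------------

    def _embed(self, ids):
        x = self.params["emb"][ids] * np.float32(np.sqrt(self.dim))
        return x + self.pe[: ids.shape[1]][None]

    def _pad_bias(self, ids):
        # (B, 1, 1, T) additive bias masking PAD keys
        return np.where(ids[:, None, None, :] == self.pad_id, NEG_INF, np.float32(0.0))

    @staticmethod
    def _causal_bias(T):
        m = np.triu(np.full((T, T), NEG_INF, dtype=np.float32), k=1)
        return m[None, None]

    # -- encoder ------------------------------------------------------------

    def encode_fwd(self, src_ids, train=False, rng=None):
        p = self.params
        x = self._embed(src_ids)
        x, emb_mask = dropout_fwd(x, self.dropout, rng, train)
        bias = self._pad_bias(src_ids)
        caches = []
        for i in range(self.n_enc):
            h1, ln1c = layernorm_fwd(x, p[f"enc{i}.ln1.g"], p[f"enc{i}.ln1.b"])
            a, ac = attention_fwd(h1, h1, p, f"enc{i}.self", self.heads, bias)
            a, am = dropout_fwd(a, self.dropout, rng, train)
            x1 = x + a
            h2, ln2c = layernorm_fwd(x1, p[f"enc{i}.ln2.g"], p[f"enc{i}.ln2.b"])
            f, fc = ff_fwd(h2, p, f"enc{i}.ff")
            f, fm = dropout_fwd(f, self.dropout, rng, train)
            x = x1 + f
            caches.append((ln1c, ac, am, ln2c, fc, fm))
        out, lnfc = layernorm_fwd(x, p["enc.ln.g"], p["enc.ln.b"])
        return out, (src_ids, emb_mask, bias, caches, lnfc)

    def encode_bwd(self, g, cache, grads):
        p = self.params
        src_ids, emb_mask, bias, caches, lnfc = cache
        dx, dgam, dbet = layernorm_bwd(g, lnfc)
        grads["enc.ln.g"] += dgam
        grads["enc.ln.b"] += dbet
        for i in reversed(range(self.n_enc)):
            ln1c, ac, am, ln2c, fc, fm = caches[i]
            df = dropout_bwd(dx, fm)
            dh2 = ff_bwd(df, fc, p, f"enc{i}.ff", grads)
            dx1, dgam, dbet = layernorm_bwd(dh2, ln2c)
            grads[f"enc{i}.ln2.g"] += dgam
            grads[f"enc{i}.ln2.b"] += dbet
            dx1 = dx1 + dx
            da = dropout_bwd(dx1, am)
            dq, dkv = attention_bwd(da, ac, p, f"enc{i}.self", self.heads, grads)
            dh1 = dq + dkv
            dx0, dgam, dbet = layernorm_bwd(dh1, ln1c)
            grads[f"enc{i}.ln1.g"] += dgam
            grads[f"enc{i}.ln1.b"] += dbet
            dx = dx0 + dx1
        demb = dropout_bwd(dx, emb_mask)
        demb = demb * np.float32(np.sqrt(self.dim))
        np.add.at(grads["emb"], src_ids, demb)

    # -- decoder ------------------------------------------------------------

    def decode_fwd(self, tgt_ids, enc_out, src_ids, train=False, rng=None):
        p = self.params
        y = self._embed(tgt_ids)
        y, emb_mask = dropout_fwd(y, self.dropout, rng, train)
        T = tgt_ids.shape[1]
        self_bias = self._causal_bias(T) + self._pad_bias(tgt_ids)
        cross_bias = self._pad_bias(src_ids)
        caches = []
        for i in range(self.n_dec):
            h1, ln1c = layernorm_fwd(y, p[f"dec{i}.ln1.g"], p[f"dec{i}.ln1.b"])
            a, ac = attention_fwd(h1, h1, p, f"dec{i}.self", self.heads, self_bias)
            a, am = dropout_fwd(a, self.dropout, rng, train)
            y1 = y + a
            h2, ln2c = layernorm_fwd(y1, p[f"dec{i}.ln2.g"], p[f"dec{i}.ln2.b"])
            c, cc = attention_fwd(h2, enc_out, p, f"dec{i}.cross", self.heads, cross_bias)
            c, cm = dropout_fwd(c, self.dropout, rng, train)
            y2 = y1 + c
            h3, ln3c = layernorm_fwd(y2, p[f"dec{i}.ln3.g"], p[f"dec{i}.ln3.b"])
            f, fc = ff_fwd(h3, p, f"dec{i}.ff")
            f, fm = dropout_fwd(f, self.dropout, rng, train)
            y = y2 + f
            caches.append((ln1c, ac, am, ln2c, cc, cm, ln3c, fc, fm))
        out, lnfc = layernorm_fwd(y, p["dec.ln.g"], p["dec.ln.b"])
        logits = linear_fwd(out, p["gen.W"], p["gen.b"])
        return logits, (tgt_ids, emb_mask, caches, lnfc, out)

    def decode_bwd(self, dlogits, cache, grads):
        """Backward through the decoder; returns gradient w.r.t. enc_out."""
        p = self.params
        tgt_ids, emb_mask, caches, lnfc, dec_out = cache
        dout, dW, db = linear_bwd(dlogits, dec_out, p["gen.W"])
        grads["gen.W"] += dW
        grads["gen.b"] += db
        dy, dgam, dbet = layernorm_bwd(dout, lnfc)
        grads["dec.ln.g"] += dgam
        grads["dec.ln.b"] += dbet
        denc = None
        for i in reversed(range(self.n_dec)):
            ln1c, ac, am, ln2c, cc, cm, ln3c, fc, fm = caches[i]
            df = dropout_bwd(dy, fm)
            dh3 = ff_bwd(df, fc, p, f"dec{i}.ff", grads)
            dy2, dgam, dbet = layernorm_bwd(dh3, ln3c)
            grads[f"dec{i}.ln3.g"] += dgam
            grads[f"dec{i}.ln3.b"] += dbet
            dy2 = dy2 + dy
            dc = dropout_bwd(dy2, cm)
            dq, dkv = attention_bwd(dc, cc, p, f"dec{i}.cross", self.heads, grads)
            denc = dkv if denc is None else denc + dkv
            dh2 = dq
            dy1, dgam, dbet = layernorm_bwd(dh2, ln2c)
            grads[f"dec{i}.ln2.g"] += dgam
            grads[f"dec{i}.ln2.b"] += dbet
            dy1 = dy1 + dy2
            da = dropout_bwd(dy1, am)
            dq, dkv = attention_bwd(da, ac, p, f"dec{i}.self", self.heads, grads)
            dh1 = dq + dkv
            dy0, dgam, dbet = layernorm_bwd(dh1, ln1c)
            grads[f"dec{i}.ln1.g"] += dgam
            grads[f"dec{i}.ln1.b"] += dbet
            dy = dy0 + dy1
        demb = dropout_bwd(dy, emb_mask)
        demb = demb * np.float32(np.sqrt(self.dim))
        np.add.at(grads["emb"], tgt_ids, demb)
        return denc

    # -- loss ---------------------------------------------------------------

    def loss_and_grads(self, src_ids, tgt_in, tgt_out, train=True, rng=None,
                       label_smoothing=0.0):
        """Token cross-entropy (normalized by non-pad token count) + grads."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        enc_out, enc_cache = self.encode_fwd(src_ids, train=train, rng=rng)
        logits, dec_cache = self.decode_fwd(tgt_ids=tgt_in, enc_out=enc_out,
                                            src_ids=src_ids, train=train, rng=rng)
        B, T, V = logits.shape
        mask = (tgt_out != self.pad_id).astype(np.float32)
        ntok = max(mask.sum(), 1.0)
        probs = softmax(logits, axis=-1)
        idx = (np.arange(B)[:, None], np.arange(T)[None, :], tgt_out)
        logp = np.log(np.maximum(probs[idx], 1e-12))
        if label_smoothing > 0.0:
            smooth = label_smoothing
            mean_logp = np.log(np.maximum(probs, 1e-12)).mean(axis=-1)
            nll = -((1 - smooth) * logp + smooth * mean_logp)
            dlogits = probs.copy()
            dlogits[idx] -= 1 - smooth
            dlogits -= smooth / V
        else:
            nll = -logp
            dlogits = probs.copy()
            dlogits[idx] -= 1.0
        loss = float((nll * mask).sum() / ntok)
        dlogits *= (mask / ntok)[:, :, None]
        denc = self.decode_bwd(dlogits, dec_cache, grads)
        self.encode_bwd(denc, enc_cache, grads)
        # token-level accuracy of the teacher-forced argmax, for monitoring
        acc = float(((logits.argmax(-1) == tgt_out) * mask).sum() / ntok)
        return loss, grads, acc

    def next_token_logprobs(self, tgt_ids, enc_out, src_ids):
        """Log-probabilities of the next token after each prefix (inference)."""
        logits, _ = self.decode_fwd(tgt_ids, enc_out, src_ids, train=False)
        last = logits[:, -1, :]
        last = last - last.max(axis=-1, keepdims=True)
        lse = np.log(np.exp(last).sum(axis=-1, keepdims=True))
        return last - lse


class Adam:
    """Adam with external (noam) learning-rate control."""

    def __init__(self, params, betas=(0.9, 0.998), eps=1e-9):
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            params[k] -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
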