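"""Minimal numpy neural-network core for the TCR classifier.

Implements exactly the pieces the classifier topology needs — token
embedding, 1-D residual convolution blocks, multi-layer bidirectional LSTM
with inter-layer dropout, gene embedding, dense head with logistic output —
with hand-written backpropagation and an Adam optimiser.  Default compute
dtype is float32; everything is fully deterministic given a seed.

Embedding row 0 (the shared padding/mask token) is pinned to the zero
vector so that zeroing a token genuinely removes the residue's contribution
at the input.

LSTM gate layout is [input, forget, output, candidate] so the three
sigmoid gates occupy one contiguous block; input projections for all
timesteps are computed in a single matmul outside the recurrence.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, shape, fan_in, fan_out, dtype):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape).astype(dtype)


class Network:
    """CNN + BiLSTM + gene-embedding binary scorer.

    Parameters live in a flat dict so the optimiser and serialisation stay
    trivial.  ``forward`` returns probabilities plus (optionally) the cache
    needed by ``backward``.
    """

    def __init__(
        self,
        n_tokens: int,
        n_genes: int,
        embed_dim: int,
        conv_blocks: int,
        conv_channels: int,
        kernel_size: int,
        lstm_layers: int,
        lstm_hidden: int,
        dropout: float,
        gene_embed_dim: int,
        dense_dim: int,
        use_gene: bool,
        seed: int,
        dtype=np.float32,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padded convolution)")
        self.n_tokens, self.n_genes = n_tokens, n_genes
        self.D, self.C, self.K = embed_dim, conv_channels, kernel_size
        self.NB, self.NL, self.H = conv_blocks, lstm_layers, lstm_hidden
        self.p_drop = dropout
        self.GD = gene_embed_dim if use_gene else 0
        self.DD = dense_dim
        self.use_gene = use_gene and gene_embed_dim > 0
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        P: Params = {}
        P["emb"] = _glorot(rng, (n_tokens, self.D), n_tokens, self.D, self.dtype)
        P["emb"][0] = 0.0
        cin = self.D
        for i in range(self.NB):
            P[f"conv{i}_W"] = _glorot(
                rng, (self.K, cin, self.C), self.K * cin, self.C, self.dtype
            )
            P[f"conv{i}_b"] = np.zeros(self.C, self.dtype)
            if cin != self.C:
                P[f"conv{i}_P"] = _glorot(rng, (cin, self.C), cin, self.C, self.dtype)
            cin = self.C
        din = self.D
        for l in range(self.NL):
            for d in ("f", "b"):
                P[f"lstm{l}{d}_Wx"] = _glorot(
                    rng, (din, 4 * self.H), din + self.H, 4 * self.H, self.dtype
                )
                P[f"lstm{l}{d}_Wh"] = _glorot(
                    rng, (self.H, 4 * self.H), din + self.H, 4 * self.H, self.dtype
                )
                b = np.zeros(4 * self.H, self.dtype)
                b[self.H: 2 * self.H] = 1.0  # forget-gate bias
                P[f"lstm{l}{d}_b"] = b
            din = 2 * self.H
        if self.use_gene:
            P["gene_emb"] = _glorot(rng, (n_genes, self.GD), n_genes, self.GD, self.dtype)
        feat = self.C + 2 * self.H + self.GD
        P["dense_W"] = _glorot(rng, (feat, self.DD), feat, self.DD, self.dtype)
        P["dense_b"] = np.zeros(self.DD, self.dtype)
        P["out_W"] = _glorot(rng, (self.DD, 1), self.DD, 1, self.dtype)
        P["out_b"] = np.zeros(1, self.dtype)
        self.params = P

    # ---------------------------------------------------------------- conv
    @staticmethod
    def _conv(x, W, b):
        B, T, Cin = x.shape
        K = W.shape[0]
        pad = K // 2
        xp = np.zeros((B, T + 2 * pad, Cin), x.dtype)
        xp[:, pad: pad + T] = x
        y = np.broadcast_to(b, (B, T, W.shape[2])).copy()
        for k in range(K):
            y += xp[:, k: k + T] @ W[k]
        return y

    @staticmethod
    def _conv_back(dy, x, W):
        B, T, Cin = x.shape
        K = W.shape[0]
        pad = K // 2
        xp = np.zeros((B, T + 2 * pad, Cin), x.dtype)
        xp[:, pad: pad + T] = x
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for k in range(K):
            dW[k] = np.tensordot(xp[:, k: k + T], dy, axes=([0, 1], [0, 1]))
            dxp[:, k: k + T] += dy @ W[k].T
        db = dy.sum(axis=(0, 1))
        return dxp[:, pad: pad + T], dW, db

    # ---------------------------------------------------------------- lstm
    def _lstm_dir(self, x, Wx, Wh, b, reverse):
        """One direction of one layer; returns (h sequence, cache)."""
        B, T, Din = x.shape
        H = self.H
        zx = x.reshape(B * T, Din) @ Wx
        zx = (zx + b).reshape(B, T, 4 * H)
        hs = np.zeros((B, T, H), x.dtype)
        gates = np.zeros((B, T, 4 * H), x.dtype)   # post-activation i,f,o,g
        cs = np.zeros((B, T, H), x.dtype)
        h = np.zeros((B, H), x.dtype)
        c = np.zeros((B, H), x.dtype)
        times = range(T - 1, -1, -1) if reverse else range(T)
        for t in times:
            z = zx[:, t] + h @ Wh
            act = np.empty_like(z)
            act[:, : 3 * H] = sigmoid(z[:, : 3 * H])
            act[:, 3 * H:] = np.tanh(z[:, 3 * H:])
            i, f = act[:, :H], act[:, H: 2 * H]
            o, g = act[:, 2 * H: 3 * H], act[:, 3 * H:]
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t] = act
            cs[:, t] = c
            hs[:, t] = h
        return hs, {"gates": gates, "c": cs, "h": hs, "x": x, "reverse": reverse}

    def _lstm_dir_back(self, dh_seq, Wx, Wh, cache):
        B, T, Din = cache["x"].shape
        H = self.H
        gates, cs, hs = cache["gates"], cache["c"], cache["h"]
        reverse = cache["reverse"]
        dz_all = np.zeros((B, T, 4 * H), dh_seq.dtype)
        dh_next = np.zeros((B, H), dh_seq.dtype)
        dc_next = np.zeros((B, H), dh_seq.dtype)
        # iterate in reverse of the forward order
        times = range(T) if reverse else range(T - 1, -1, -1)
        for t in times:
            act = gates[:, t]
            i, f = act[:, :H], act[:, H: 2 * H]
            o, g = act[:, 2 * H: 3 * H], act[:, 3 * H:]
            c = cs[:, t]
            t_prev = t + 1 if reverse else t - 1
            cprev = cs[:, t_prev] if 0 <= t_prev < T else np.zeros_like(c)
            dh = dh_seq[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = dz_all[:, t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H: 2 * H] = dc * cprev * f * (1 - f)
            dz[:, 2 * H: 3 * H] = do * o * (1 - o)
            dz[:, 3 * H:] = dc * i * (1 - g * g)
            dc_next = dc * f
            dh_next = dz @ Wh.T
        x2 = cache["x"].reshape(B * T, Din)
        dz2 = dz_all.reshape(B * T, 4 * H)
        dWx = x2.T @ dz2
        db = dz2.sum(axis=0)
        dx = (dz2 @ Wx.T).reshape(B, T, Din)
        # h_prev sequence: hs shifted one step along the forward order
        hprev = np.zeros_like(hs)
        if reverse:
            hprev[:, :-1] = hs[:, 1:]
        else:
            hprev[:, 1:] = hs[:, :-1]
        dWh = hprev.reshape(B * T, H).T @ dz2
        return dx, dWx, dWh, db

    # ------------------------------------------------------------- forward
    def forward(self, tokens, genes=None, train=False, rng=None, want_cache=False):
        """Score a batch.

        tokens: (B, T) int array; genes: (B,) int array or None.
        Returns (probs, cache); cache is None unless requested.
        """
        P = self.params
        B, T = tokens.shape
        emb = P["emb"][tokens]  # (B, T, D)
        cache: dict = {"tokens": tokens, "genes": genes, "emb": emb}

        # CNN branch with additive residual skips
        x = emb
        conv_caches = []
        for i in range(self.NB):
            y = self._conv(x, P[f"conv{i}_W"], P[f"conv{i}_b"])
            if f"conv{i}_P" in P:
                y = y + x @ P[f"conv{i}_P"]
            else:
                y = y + x
            h = np.maximum(y, 0.0)
            conv_caches.append((x, y))
            x = h
        pool_idx = x.argmax(axis=1)  # (B, C)
        pooled = np.take_along_axis(x, pool_idx[:, None, :], axis=1)[:, 0, :]
        cache["conv"] = conv_caches
        cache["pool_idx"] = pool_idx
        cache["conv_out_shape"] = x.shape

        # BiLSTM branch
        xl = emb
        lstm_caches = []
        drop_masks = []
        for l in range(self.NL):
            hf, cf = self._lstm_dir(
                xl, P[f"lstm{l}f_Wx"], P[f"lstm{l}f_Wh"], P[f"lstm{l}f_b"], False
            )
            hb, cb = self._lstm_dir(
                xl, P[f"lstm{l}b_Wx"], P[f"lstm{l}b_Wh"], P[f"lstm{l}b_b"], True
            )
            seq = np.concatenate([hf, hb], axis=2)
            lstm_caches.append((cf, cb))
            if l < self.NL - 1 and train and self.p_drop > 0:
                if rng is None:
                    rng = np.random.default_rng()
                mask = (
                    (rng.random(seq.shape) >= self.p_drop) / (1.0 - self.p_drop)
                ).astype(seq.dtype)
                seq = seq * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
            xl = seq
        summary = np.concatenate([hf[:, -1], hb[:, 0]], axis=1)  # (B, 2H)
        cache["lstm"] = lstm_caches
        cache["drop"] = drop_masks

        feats = [pooled, summary]
        if self.use_gene:
            gvec = P["gene_emb"][genes]
            feats.append(gvec)
        feat = np.concatenate(feats, axis=1)
        z1_pre = feat @ P["dense_W"] + P["dense_b"]
        z1 = np.maximum(z1_pre, 0.0)
        logit = (z1 @ P["out_W"] + P["out_b"])[:, 0]
        probs = sigmoid(logit.astype(np.float64))
        cache.update(feat=feat, z1_pre=z1_pre, z1=z1)
        return probs, (cache if want_cache else None)

    # ------------------------------------------------------------ backward
    def backward(self, cache, dlogit) -> Params:
        """Backpropagate d(loss)/d(logit) (shape (B,)) to parameter grads."""
        P = self.params
        G: Params = {}
        z1, feat = cache["z1"], cache["feat"]
        dl = dlogit[:, None].astype(self.dtype)
        G["out_W"] = z1.T @ dl
        G["out_b"] = dl.sum(axis=0)
        dz1 = (dl @ P["out_W"].T) * (cache["z1_pre"] > 0)
        G["dense_W"] = feat.T @ dz1
        G["dense_b"] = dz1.sum(axis=0)
        dfeat = dz1 @ P["dense_W"].T
        dpooled = dfeat[:, : self.C]
        dsummary = dfeat[:, self.C: self.C + 2 * self.H]
        if self.use_gene:
            dg = dfeat[:, self.C + 2 * self.H:]
            G["gene_emb"] = np.zeros_like(P["gene_emb"])
            np.add.at(G["gene_emb"], cache["genes"], dg)

        # CNN branch backward
        B, T, C = cache["conv_out_shape"]
        dh = np.zeros((B, T, C), self.dtype)
        np.put_along_axis(dh, cache["pool_idx"][:, None, :], dpooled[:, None, :], axis=1)
        for i in range(self.NB - 1, -1, -1):
            x, y = cache["conv"][i]
            dy = dh * (y > 0)
            dx, dW, db = self._conv_back(dy, x, P[f"conv{i}_W"])
            G[f"conv{i}_W"], G[f"conv{i}_b"] = dW, db
            if f"conv{i}_P" in P:
                G[f"conv{i}_P"] = np.tensordot(x, dy, axes=([0, 1], [0, 1]))
                dx = dx + dy @ P[f"conv{i}_P"].T
            else:
                dx = dx + dy
            dh = dx
        demb_cnn = dh  # (B, T, D)

        # BiLSTM branch backward
        H = self.H
        dseq = np.zeros((B, T, 2 * H), self.dtype)
        dseq[:, -1, :H] += dsummary[:, :H]
        dseq[:, 0, H:] += dsummary[:, H:]
        for l in range(self.NL - 1, -1, -1):
            if cache["drop"][l] is not None:
                dseq = dseq * cache["drop"][l]
            cf, cb = cache["lstm"][l]
            dxf, dWxf, dWhf, dbf = self._lstm_dir_back(
                np.ascontiguousarray(dseq[:, :, :H]), P[f"lstm{l}f_Wx"],
                P[f"lstm{l}f_Wh"], cf
            )
            dxb, dWxb, dWhb, dbb = self._lstm_dir_back(
                np.ascontiguousarray(dseq[:, :, H:]), P[f"lstm{l}b_Wx"],
                P[f"lstm{l}b_Wh"], cb
            )
            G[f"lstm{l}f_Wx"], G[f"lstm{l}f_Wh"], G[f"lstm{l}f_b"] = dWxf, dWhf, dbf
            G[f"lstm{l}b_Wx"], G[f"lstm{l}b_Wh"], G[f"lstm{l}b_b"] = dWxb, dWhb, dbb
            dseq = dxf + dxb
        demb_lstm = dseq

        demb = demb_cnn + demb_lstm
        G["emb"] = np.zeros_like(P["emb"])
        np.add.at(
            G["emb"], cache["tokens"].ravel(), demb.reshape(-1, self.D)
        )
        G["emb"][0] = 0.0  # padding/mask embedding stays pinned at zero
        return G


class Adam:
    """Standard Adam over a parameter dict."""

    def __init__(self, params: Params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
        if "emb" in params:
            params["emb"][0] = 0.0


def weighted_bce(probs: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted binary cross-entropy; returns (mean loss, d loss/d logit)."""
    eps = 1e-12
    loss = -(w * (y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))).mean()
    dlogit = w * (probs - y) / len(y)
    return loss, dlogit
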