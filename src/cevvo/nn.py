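"""NumPy implementation of the two-headed static/temporal network.

Static head: dense encoder (default 32 -> 33 -> 25, tanh) trained jointly with
an auxiliary linear decoder back to the input width under a mean-squared
reconstruction loss.  Temporal head: a pointwise (1x1) convolution with tanh
expands the 8 perfusion channels to the filter width, then an LSTM consumes the
sequence and emits its final hidden state.  The two head outputs are
concatenated (default width 25 + 1024 = 1049) into a single sigmoid output
neuron trained with binary cross-entropy.

All forward/backward passes are hand-written and vectorized over the batch;
gradients are exact (verified against numerical differentiation in the test
suite).  Everything runs in float64 on the CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CevvoNetwork", "Adam", "sigmoid"]


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class CevvoNetwork:
    """Two-headed classifier over (static vector, T x V series) pairs."""

    def __init__(self, static_dim: int = 32, static_widths=(32, 33, 25),
                 n_channels: int = 8, conv_filters: int = 1024,
                 lstm_units: int = 1024, recon_weight: float = 0.1,
                 rng: np.random.Generator | None = None):
        if min(static_widths) < 1 or conv_filters < 1 or lstm_units < 1:
            raise ValueError("all layer widths must be >= 1")
        if len(static_widths) != 3:
            raise ValueError("static head has exactly three dense layers")
        rng = np.random.default_rng() if rng is None else rng
        self.static_dim = static_dim
        self.static_widths = tuple(static_widths)
        self.n_channels = n_channels
        self.conv_filters = conv_filters
        self.lstm_units = lstm_units
        self.recon_weight = float(recon_weight)

        w1, w2, w3 = static_widths
        D, V, C, H = static_dim, n_channels, conv_filters, lstm_units
        p = {}
        p["W1"], p["b1"] = _glorot(rng, D, w1), np.zeros(w1)
        p["W2"], p["b2"] = _glorot(rng, w1, w2), np.zeros(w2)
        p["W3"], p["b3"] = _glorot(rng, w2, w3), np.zeros(w3)
        p["Wdec"], p["bdec"] = _glorot(rng, w3, D), np.zeros(D)
        p["Wc"], p["bc"] = _glorot(rng, V, C), np.zeros(C)
        p["Wx"] = _glorot(rng, C, 4 * H, (C, 4 * H))
        p["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        p["blstm"] = np.zeros(4 * H)
        p["blstm"][H:2 * H] = 1.0  # forget-gate bias
        p["Wout"], p["bout"] = _glorot(rng, w3 + H, 1), np.zeros(1)
        self.params = p

    # -- architecture bookkeeping -------------------------------------------
    @property
    def fusion_width(self) -> int:
        """Width of the concatenated head outputs feeding the output neuron."""
        return self.static_widths[-1] + self.lstm_units

    @property
    def fusion_parameter_count(self) -> int:
        """Trainable parameters from the fusion layer onward (weights + bias)."""
        return self.fusion_width + 1

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    # -- forward -------------------------------------------------------------
    def forward(self, S: np.ndarray, X: np.ndarray, cache: bool = False):
        """Forward pass; returns (scores, reconstruction[, cache])."""
        p = self.params
        H = self.lstm_units
        B, T, V = X.shape
        if V != self.n_channels or S.shape[1] != self.static_dim:
            raise ValueError("input widths do not match the network configuration")

        h1 = np.tanh(S @ p["W1"] + p["b1"])
        h2 = np.tanh(h1 @ p["W2"] + p["b2"])
        enc = np.tanh(h2 @ p["W3"] + p["b3"])
        recon = enc @ p["Wdec"] + p["bdec"]

        U = np.tanh(X @ p["Wc"] + p["bc"])              # (B, T, C)
        Ax = U @ p["Wx"] + p["blstm"]                    # (B, T, 4H)
        hs = np.zeros((B, T + 1, H))
        cs = np.zeros((B, T + 1, H))
        gates = np.empty((B, T, 4 * H))
        tanh_c = np.empty((B, T, H))
        h = hs[:, 0]
        c = cs[:, 0]
        for t in range(T):
            A = Ax[:, t] + h @ p["Wh"]
            i = sigmoid(A[:, :H])
            f = sigmoid(A[:, H:2 * H])
            g = np.tanh(A[:, 2 * H:3 * H])
            o = sigmoid(A[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t + 1] = h
            cs[:, t + 1] = c
            gates[:, t, :H], gates[:, t, H:2 * H] = i, f
            gates[:, t, 2 * H:3 * H], gates[:, t, 3 * H:] = g, o
            tanh_c[:, t] = tc

        z = np.concatenate([enc, h], axis=1)
        logit = (z @ p["Wout"] + p["bout"]).ravel()
        scores = sigmoid(logit)
        if not cache:
            return scores, recon
        return scores, recon, dict(S=S, X=X, h1=h1, h2=h2, enc=enc, recon=recon,
                                   U=U, hs=hs, cs=cs, gates=gates, tanh_c=tanh_c,
                                   z=z, scores=scores)

    def loss(self, S, X, y, cache: bool = False):
        """Total loss = BCE + recon_weight * reconstruction MSE."""
        out = self.forward(S, X, cache=cache)
        scores, recon = out[0], out[1]
        eps = 1e-12
        p_clip = np.clip(scores, eps, 1.0 - eps)
        bce = -np.mean(y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip))
        rec = np.mean((recon - S) ** 2)
        total = bce + self.recon_weight * rec
        if not cache:
            return total
        return total, out[2]

    # -- backward ------------------------------------------------------------
    def gradients(self, S, X, y):
        """Analytic gradients of the total loss w.r.t. every parameter."""
        p = self.params
        H = self.lstm_units
        w3 = self.static_widths[-1]
        total, cc = self.loss(S, X, y, cache=True)
        B, T, _ = X.shape
        D = self.static_dim
        g = {}

        dlogit = (cc["scores"] - y)[:, None] / B
        g["Wout"] = cc["z"].T @ dlogit
        g["bout"] = dlogit.sum(axis=0)
        dz = dlogit @ p["Wout"].T
        denc = dz[:, :w3].copy()
        dhT = dz[:, w3:]

        drecon = self.recon_weight * 2.0 * (cc["recon"] - S) / (B * D)
        g["Wdec"] = cc["enc"].T @ drecon
        g["bdec"] = drecon.sum(axis=0)
        denc += drecon @ p["Wdec"].T

        da3 = denc * (1 - cc["enc"] ** 2)
        g["W3"], g["b3"] = cc["h2"].T @ da3, da3.sum(axis=0)
        dh2 = da3 @ p["W3"].T
        da2 = dh2 * (1 - cc["h2"] ** 2)
        g["W2"], g["b2"] = cc["h1"].T @ da2, da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (1 - cc["h1"] ** 2)
        g["W1"], g["b1"] = S.T @ da1, da1.sum(axis=0)

        # LSTM backward through time
        gates, tanh_c = cc["gates"], cc["tanh_c"]
        hs, cs = cc["hs"], cc["cs"]
        dA_all = np.empty((B, T, 4 * H))
        dWh = np.zeros_like(p["Wh"])
        dh = dhT.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H:2 * H]
            gg = gates[:, t, 2 * H:3 * H]
            o = gates[:, t, 3 * H:]
            tc = tanh_c[:, t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di, df, dg = dc * gg, dc * cs[:, t], dc * i
            dA = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - gg ** 2), do * o * (1 - o)], axis=1)
            dA_all[:, t] = dA
            dWh += hs[:, t].T @ dA
            dh = dA @ p["Wh"].T
            dc = dc * f
        g["Wh"] = dWh
        g["blstm"] = dA_all.sum(axis=(0, 1))
        U = cc["U"]
        g["Wx"] = U.reshape(B * T, -1).T @ dA_all.reshape(B * T, -1)
        dU = dA_all @ p["Wx"].T
        dpre = dU * (1 - U ** 2)
        g["Wc"] = X.reshape(B * T, -1).T @ dpre.reshape(B * T, -1)
        g["bc"] = dpre.sum(axis=(0, 1))
        return total, g


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk ** 2
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
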