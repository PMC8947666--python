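"""Minimal recurrent one-step regressors in NumPy.

Three architectures — simple RNN, GRU and LSTM — each as a single recurrent
layer over a univariate window plus a linear read-out of the last hidden
state, trained full-batch with Adam on squared error.  Backpropagation
through time is written out by hand; its correctness is pinned down by
finite-difference gradient checks in the test suite.

At the problem sizes used here (window ≈ 7, a few hundred training windows,
a few dozen hidden units) full-batch NumPy training takes well under a
second per model, so no mini-batching or acceleration is needed.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    """Standard Adam with bias correction over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _clip_global(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class RecurrentRegressor:
    """Base class: one recurrent layer + linear output, univariate windows."""

    def __init__(
        self,
        hidden_units: int = 32,
        epochs: int = 200,
        learning_rate: float = 0.01,
        seed: int = 0,
        clip_norm: float = 5.0,
        input_noise: float = 0.03,
    ):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.clip_norm = clip_norm
        self.input_noise = input_noise
        rng = np.random.default_rng(seed)
        self.params = self._init_params(rng)
        self.loss_history: list[float] = []

    # -- architecture-specific -------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def _backward(self, cache: dict, d_out: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # -- shared -----------------------------------------------------------
    @staticmethod
    def _uniform(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        s = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-s, s, size=shape)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y, _ = self._forward(X)
        return y.ravel()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RecurrentRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        if len(X) < 1:
            raise ValueError("need at least one training pair")
        opt = _Adam(self.params, self.learning_rate)
        noise_rng = np.random.default_rng(self.seed + 0x5EED)
        B = len(X)
        for _ in range(self.epochs):
            if self.input_noise > 0:
                # jitter the inputs each epoch: stabilises recursive multi-step
                # use, where the model must behave sensibly on windows that
                # contain its own (slightly off) predictions
                Xe = X + noise_rng.normal(0.0, self.input_noise, X.shape)
            else:
                Xe = X
            pred, cache = self._forward(Xe)
            resid = pred - y
            loss = float((resid**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite training loss (learning rate too large?)"
                )
            self.loss_history.append(loss)
            grads = self._backward(cache, 2.0 * resid / B)
            _clip_global(grads, self.clip_norm)
            opt.step(self.params, grads)
        return self

    def gradients(self, X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Loss gradients at the current parameters (for gradient checks)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        pred, cache = self._forward(X)
        return self._backward(cache, 2.0 * (pred - y) / len(X))

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred, _ = self._forward(np.asarray(X, dtype=float))
        return float(((pred - np.asarray(y, dtype=float).reshape(-1, 1)) ** 2).mean())


class SimpleRNNRegressor(RecurrentRegressor):
    """h_t = tanh(x_t·Wx + h_{t-1}·Wh + b); y = h_n·Wo + bo."""

    def _init_params(self, rng):
        H = self.hidden_units
        return {
            "Wx": self._uniform(rng, 1, (1, H)),
            "Wh": self._uniform(rng, H, (H, H)),
            "b": np.zeros(H),
            "Wo": self._uniform(rng, H, (H, 1)),
            "bo": np.zeros(1),
        }

    def _forward(self, X):
        p = self.params
        B, n = X.shape
        h = np.zeros((B, self.hidden_units))
        hs = [h]
        for t in range(n):
            h = np.tanh(X[:, t : t + 1] @ p["Wx"] + h @ p["Wh"] + p["b"])
            hs.append(h)
        y = h @ p["Wo"] + p["bo"]
        return y, {"X": X, "hs": hs}

    def _backward(self, cache, d_out):
        p = self.params
        X, hs = cache["X"], cache["hs"]
        n = X.shape[1]
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = hs[-1].T @ d_out
        g["bo"] = d_out.sum(axis=0)
        dh = d_out @ p["Wo"].T
        for t in range(n - 1, -1, -1):
            da = dh * (1.0 - hs[t + 1] ** 2)
            g["Wx"] += X[:, t : t + 1].T @ da
            g["Wh"] += hs[t].T @ da
            g["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
        return g


class GRURegressor(RecurrentRegressor):
    """Gated recurrent unit: update/reset gates, candidate state."""

    def _init_params(self, rng):
        H = self.hidden_units
        p = {}
        for gate in ("z", "r", "c"):
            p[f"Wx{gate}"] = self._uniform(rng, 1, (1, H))
            p[f"Wh{gate}"] = self._uniform(rng, H, (H, H))
            p[f"b{gate}"] = np.zeros(H)
        p["Wo"] = self._uniform(rng, H, (H, 1))
        p["bo"] = np.zeros(1)
        return p

    def _forward(self, X):
        p = self.params
        B, n = X.shape
        h = np.zeros((B, self.hidden_units))
        steps = []
        for t in range(n):
            x = X[:, t : t + 1]
            z = _sigmoid(x @ p["Wxz"] + h @ p["Whz"] + p["bz"])
            r = _sigmoid(x @ p["Wxr"] + h @ p["Whr"] + p["br"])
            c = np.tanh(x @ p["Wxc"] + (r * h) @ p["Whc"] + p["bc"])
            h_new = (1.0 - z) * c + z * h
            steps.append({"x": x, "h_prev": h, "z": z, "r": r, "c": c})
            h = h_new
        y = h @ p["Wo"] + p["bo"]
        return y, {"steps": steps, "h_last": h}

    def _backward(self, cache, d_out):
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = cache["h_last"].T @ d_out
        g["bo"] = d_out.sum(axis=0)
        dh = d_out @ p["Wo"].T
        for st in reversed(cache["steps"]):
            x, h_prev, z, r, c = st["x"], st["h_prev"], st["z"], st["r"], st["c"]
            dc = dh * (1.0 - z)
            dz = dh * (h_prev - c)
            dh_prev = dh * z
            dac = dc * (1.0 - c**2)
            g["Wxc"] += x.T @ dac
            g["Whc"] += (r * h_prev).T @ dac
            g["bc"] += dac.sum(axis=0)
            drh = dac @ p["Whc"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            daz = dz * z * (1.0 - z)
            g["Wxz"] += x.T @ daz
            g["Whz"] += h_prev.T @ daz
            g["bz"] += daz.sum(axis=0)
            dh_prev = dh_prev + daz @ p["Whz"].T
            dar = dr * r * (1.0 - r)
            g["Wxr"] += x.T @ dar
            g["Whr"] += h_prev.T @ dar
            g["br"] += dar.sum(axis=0)
            dh_prev = dh_prev + dar @ p["Whr"].T
            dh = dh_prev
        return g


class LSTMRegressor(RecurrentRegressor):
    """Long short-term memory cell with input/forget/output gates.

    Gate biases are ``bi``/``bf``/``bog``/``bg`` (the output-gate bias is
    ``bog`` to keep it distinct from the read-out bias ``bo``); the forget
    gate starts open (bias 1), the standard initialisation.
    """

    def _init_params(self, rng):
        H = self.hidden_units
        p = {}
        for gate, bias in (("i", "bi"), ("f", "bf"), ("o", "bog"), ("g", "bg")):
            p[f"Wx{gate}"] = self._uniform(rng, 1, (1, H))
            p[f"Wh{gate}"] = self._uniform(rng, H, (H, H))
            p[bias] = np.zeros(H)
        p["bf"] += 1.0
        p["Wo"] = self._uniform(rng, H, (H, 1))
        p["bo"] = np.zeros(1)
        return p

    def _forward(self, X):
        p = self.params
        B, n = X.shape
        h = np.zeros((B, self.hidden_units))
        c = np.zeros((B, self.hidden_units))
        steps = []
        for t in range(n):
            x = X[:, t : t + 1]
            i = _sigmoid(x @ p["Wxi"] + h @ p["Whi"] + p["bi"])
            f = _sigmoid(x @ p["Wxf"] + h @ p["Whf"] + p["bf"])
            o = _sigmoid(x @ p["Wxo"] + h @ p["Who"] + p["bog"])
            g = np.tanh(x @ p["Wxg"] + h @ p["Whg"] + p["bg"])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append(
                {"x": x, "h_prev": h, "c_prev": c, "i": i, "f": f, "o": o, "g": g, "c": c_new}
            )
            h, c = h_new, c_new
        y = h @ p["Wo"] + p["bo"]
        return y, {"steps": steps, "h_last": h}

    def _backward(self, cache, d_out):
        p = self.params
        g_ = {k: np.zeros_like(v) for k, v in p.items()}
        g_["Wo"] = cache["h_last"].T @ d_out
        g_["bo"] = d_out.sum(axis=0)
        dh = d_out @ p["Wo"].T
        dc = np.zeros_like(dh)
        for st in reversed(cache["steps"]):
            x, h_prev, c_prev = st["x"], st["h_prev"], st["c_prev"]
            i, f, o, g, c = st["i"], st["f"], st["o"], st["g"], st["c"]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f
            dai = di * i * (1.0 - i)
            daf = df * f * (1.0 - f)
            dao = do * o * (1.0 - o)
            dag = dg * (1.0 - g**2)
            for name, da, bias in (
                ("i", dai, "bi"),
                ("f", daf, "bf"),
                ("o", dao, "bog"),
                ("g", dag, "bg"),
            ):
                g_[f"Wx{name}"] += x.T @ da
                g_[f"Wh{name}"] += h_prev.T @ da
                g_[bias] += da.sum(axis=0)
            dh = (
                dai @ p["Whi"].T
                + daf @ p["Whf"].T
                + dao @ p["Who"].T
                + dag @ p["Whg"].T
            )
            dc = dc_prev
        return g_


class PersistencePredictor:
    """Naive baseline: predict the last value of the input window."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PersistencePredictor":
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, -1].copy()
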