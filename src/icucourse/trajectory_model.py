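"""Token-embedded recurrent model producing ordinal outcome trajectories.

Architecture, in three learned stages:

1. *Token embedding with positive relevance weights.*  Each vocabulary token
   i carries a vector ``v_i`` and a relevance weight ``w_i > 0`` (softplus of
   a free parameter, initialised near 1).  A time window containing token
   set S is summarised as the relevance-weighted average
   ``x_t = sum_i w_i v_i / sum_i w_i`` over the unique tokens in S.

2. *Recurrent core.*  The sequence ``x_1..x_T`` feeds a single-layer GRU or
   LSTM, giving a hidden state per window; outputs at window t depend only
   on windows <= t.

3. *Ordinal decoder.*  The "constrained sigmoid" head maps hidden state h to
   a scalar score ``s = b·h`` and emits threshold probabilities
   ``q(k) = sigmoid(s - theta_k)`` with cut points ``theta_1 < ... < theta_6``
   enforced by cumulative softplus increments, so q is monotone decreasing
   in k by construction.  Class probabilities follow by differencing.  A
   multinomial (softmax over the 7 categories) head is also available; its
   threshold probabilities are the upper-tail sums of the class
   probabilities.

The loss is the mean negative log-likelihood of the true outcome category
over every (patient, window) cell, optimised with Adam, early-stopped on a
validation set.  All parameters live in plain NumPy arrays with
hand-derived gradients; a numerical-gradient test guards the derivation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .cohort_io import N_OUTCOME_CATEGORIES, N_THRESHOLDS
from .tokenise import TokenisedStay

EMBED_DIMS = (16, 32, 64, 128)
RNN_TYPES = ("GRU", "LSTM")
HEADS = ("multinomial", "ordinal")


def softplus(x):
    return np.logaddexp(0.0, x)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


@dataclass
class ModelConfig:
    embed_dim: int = 32
    rnn_type: str = "GRU"
    head: str = "ordinal"
    hidden_dim: int = 32
    learning_rate: float = 0.01
    epochs: int = 150
    batch_size: int = 64
    patience: int = 12
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim not in EMBED_DIMS:
            raise ValueError(f"embed_dim must be one of {EMBED_DIMS}")
        if self.rnn_type not in RNN_TYPES:
            raise ValueError(f"rnn_type must be one of {RNN_TYPES}")
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")


@dataclass
class Trajectory:
    """Per-window ordinal prognosis for one stay."""

    patient_id: str
    class_probs: np.ndarray  # (T, 7), rows on the simplex
    threshold_probs: np.ndarray  # (T, 6), monotone non-increasing across k
    outcome_index: int

    @property
    def n_windows(self) -> int:
        return self.class_probs.shape[0]

    @property
    def expected_index(self) -> np.ndarray:
        return expected_index(self.class_probs)


def expected_index(p: np.ndarray) -> np.ndarray:
    """Expected ordinal outcome index, sum_c c*p(c) with c in 0..6."""
    return np.asarray(p) @ np.arange(N_OUTCOME_CATEGORIES, dtype=float)


def embed_window(token_ids: np.ndarray, vectors: np.ndarray, relevance: np.ndarray):
    """Relevance-weighted mean of the unique token vectors in one window."""
    ids = np.unique(np.asarray(token_ids))
    if ids.size == 0:
        raise ValueError("empty token set: violates the tokeniser contract")
    w = relevance[ids]
    return (w[:, None] * vectors[ids]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------


def _init_params(cfg: ModelConfig, vocab_size: int, rng: np.random.Generator):
    d, H = cfg.embed_dim, cfg.hidden_dim
    p: dict[str, np.ndarray] = {}
    p["emb"] = rng.normal(0.0, 0.1, size=(vocab_size, d))
    p["rel"] = np.full(vocab_size, inv_softplus(1.0))  # w ~= 1 at init
    gates = ("z", "r", "h") if cfg.rnn_type == "GRU" else ("i", "f", "o", "g")
    for g in gates:
        p[f"W{g}"] = rng.normal(0.0, 1.0 / math.sqrt(d), size=(d, H))
        p[f"U{g}"] = rng.normal(0.0, 1.0 / math.sqrt(H), size=(H, H))
        p[f"b{g}"] = np.zeros(H)
    if cfg.head == "ordinal":
        p["beta"] = rng.normal(0.0, 0.1, size=H)
        theta0 = np.full(N_THRESHOLDS, inv_softplus(0.5))
        theta0[0] = -1.25  # spread initial cuts around 0
        p["theta_raw"] = theta0
    else:
        p["Wout"] = rng.normal(0.0, 0.1, size=(H, N_OUTCOME_CATEGORIES))
        p["bout"] = np.zeros(N_OUTCOME_CATEGORIES)
    return p


def params_checksum(params: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------


class _Batch:
    """Padded (B, T) layout with flat token/segment arrays for scatter ops."""

    def __init__(self, window_lists: list[list[np.ndarray]]):
        self.B = len(window_lists)
        self.lengths = np.array([len(wl) for wl in window_lists])
        self.T = int(self.lengths.max())
        self.mask = np.arange(self.T)[None, :] < self.lengths[:, None]  # (B,T)
        flat_ids, seg = [], []
        for b, wl in enumerate(window_lists):
            for t, ids in enumerate(wl):
                flat_ids.append(ids)
                seg.append(np.full(len(ids), b * self.T + t, dtype=np.int64))
        self.flat_ids = np.concatenate(flat_ids)
        self.seg = np.concatenate(seg)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class TrajectoryModel:
    """Embedding + recurrent core + ordinal/multinomial decoder."""

    def __init__(
        self,
        config: ModelConfig,
        vocab_size: int,
        vocab_checksum: str = "",
        params: dict[str, np.ndarray] | None = None,
    ):
        self.config = config
        self.vocab_size = vocab_size
        self.vocab_checksum = vocab_checksum
        rng = np.random.default_rng(config.seed)
        self.params = params if params is not None else _init_params(
            config, vocab_size, rng
        )
        self.training_log: list[dict] = []

    # -- forward -----------------------------------------------------------

    def _embed(self, batch: _Batch, params):
        d = self.config.embed_dim
        w = softplus(params["rel"])
        wf = w[batch.flat_ids]
        num = np.zeros((batch.B * batch.T, d))
        np.add.at(num, batch.seg, wf[:, None] * params["emb"][batch.flat_ids])
        den = np.zeros(batch.B * batch.T)
        np.add.at(den, batch.seg, wf)
        den_safe = np.where(den > 0, den, 1.0)
        X = (num / den_safe[:, None]).reshape(batch.B, batch.T, d)
        cache = (batch, w, wf, num, den_safe)
        return X, cache

    def _embed_backward(self, dX, cache, grads):
        batch, w, wf, num, den = cache
        dXf = dX.reshape(batch.B * batch.T, -1)
        dnum = dXf / den[:, None]
        x = num / den[:, None]
        dden = -np.einsum("nd,nd->n", x, dXf) / den
        ids = batch.flat_ids
        emb = self.params["emb"]
        dv = wf[:, None] * dnum[batch.seg]
        np.add.at(grads["emb"], ids, dv)
        dw = (
            np.einsum("nd,nd->n", emb[ids], dnum[batch.seg]) + dden[batch.seg]
        )
        drel_flat = dw * sigmoid(self.params["rel"][ids])
        np.add.at(grads["rel"], ids, drel_flat)

    def _rnn_forward(self, X, params):
        B, T, d = X.shape
        H = self.config.hidden_dim
        h = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        cache = []
        if self.config.rnn_type == "GRU":
            for t in range(T):
                x = X[:, t]
                z = sigmoid(x @ params["Wz"] + h @ params["Uz"] + params["bz"])
                r = sigmoid(x @ params["Wr"] + h @ params["Ur"] + params["br"])
                rh = r * h
                c = np.tanh(x @ params["Wh"] + rh @ params["Uh"] + params["bh"])
                h_new = (1 - z) * h + z * c
                cache.append((x, h, z, r, c))
                h = h_new
                Hs[:, t] = h
        else:  # LSTM
            cst = np.zeros((B, H))
            for t in range(T):
                x = X[:, t]
                i = sigmoid(x @ params["Wi"] + h @ params["Ui"] + params["bi"])
                f = sigmoid(x @ params["Wf"] + h @ params["Uf"] + params["bf"])
                o = sigmoid(x @ params["Wo"] + h @ params["Uo"] + params["bo"])
                g = np.tanh(x @ params["Wg"] + h @ params["Ug"] + params["bg"])
                c_new = f * cst + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                cache.append((x, h, cst, i, f, o, g, tc))
                cst = c_new
                h = h_new
                Hs[:, t] = h
        return Hs, cache

    def _rnn_backward(self, dHs, cache, grads):
        params = self.params
        B, T, H = dHs.shape
        dh = np.zeros((B, H))
        dX = np.empty((B, T, self.config.embed_dim))
        if self.config.rnn_type == "GRU":
            for t in range(T - 1, -1, -1):
                x, h_prev, z, r, c = cache[t]
                dht = dh + dHs[:, t]
                dz = dht * (c - h_prev)
                dc = dht * z
                dh = dht * (1 - z)
                da_c = dc * (1 - c * c)
                grads["Wh"] += x.T @ da_c
                grads["Uh"] += (r * h_prev).T @ da_c
                grads["bh"] += da_c.sum(0)
                drh = da_c @ params["Uh"].T
                dr = drh * h_prev
                dh += drh * r
                da_r = dr * r * (1 - r)
                grads["Wr"] += x.T @ da_r
                grads["Ur"] += h_prev.T @ da_r
                grads["br"] += da_r.sum(0)
                dh += da_r @ params["Ur"].T
                da_z = dz * z * (1 - z)
                grads["Wz"] += x.T @ da_z
                grads["Uz"] += h_prev.T @ da_z
                grads["bz"] += da_z.sum(0)
                dh += da_z @ params["Uz"].T
                dX[:, t] = (
                    da_c @ params["Wh"].T
                    + da_r @ params["Wr"].T
                    + da_z @ params["Wz"].T
                )
        else:
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x, h_prev, c_prev, i, f, o, g, tc = cache[t]
                dht = dh + dHs[:, t]
                do = dht * tc
                dc = dht * o * (1 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dh = np.zeros((B, H))
                dXt = np.zeros_like(x)
                for name, dgate, act in (
                    ("i", di, i),
                    ("f", df, f),
                    ("o", do, o),
                ):
                    da = dgate * act * (1 - act)
                    grads[f"W{name}"] += x.T @ da
                    grads[f"U{name}"] += h_prev.T @ da
                    grads[f"b{name}"] += da.sum(0)
                    dh += da @ params[f"U{name}"].T
                    dXt += da @ params[f"W{name}"].T
                da_g = dg * (1 - g * g)
                grads["Wg"] += x.T @ da_g
                grads["Ug"] += h_prev.T @ da_g
                grads["bg"] += da_g.sum(0)
                dh += da_g @ params["Ug"].T
                dXt += da_g @ params["Wg"].T
                dX[:, t] = dXt
        return dX

    def _thresholds(self, params):
        raw = params["theta_raw"]
        return raw[0] + np.concatenate(([0.0], np.cumsum(softplus(raw[1:]))))

    def _decode(self, Hs, params):
        """Hidden states -> (class probs p, threshold probs q, cache)."""
        if self.config.head == "ordinal":
            s = Hs @ params["beta"]  # (B, T)
            theta = self._thresholds(params)
            q = sigmoid(s[..., None] - theta)  # (B, T, 6)
            p = threshold_to_class(q)
            return p, q, (s, theta)
        logits = Hs @ params["Wout"] + params["bout"]
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=-1, keepdims=True)
        q = class_to_threshold(p)
        return p, q, (p,)

    def _decode_backward(self, dp, q, dcache, Hs, grads):
        params = self.params
        if self.config.head == "ordinal":
            s, theta = dcache
            # q_k enters p_{k-1} with -1 and p_k with +1 (p index = k, k=1..6)
            dq = dp[..., 1:] - dp[..., :-1]  # (B, T, 6)
            qp = q * (1 - q)
            ds = (dq * qp).sum(-1)
            dtheta = -(dq * qp).sum(axis=(0, 1))
            grads["beta"] += np.einsum("bth,bt->h", Hs, ds)
            dHs = ds[..., None] * params["beta"]
            raw = params["theta_raw"]
            grads["theta_raw"][0] += dtheta.sum()
            grads["theta_raw"][1:] += sigmoid(raw[1:]) * np.cumsum(
                dtheta[::-1]
            )[::-1][1:]
            return dHs
        (p,) = dcache
        # softmax backward: dlogits = p * (dp - sum(dp*p))
        dot = (dp * p).sum(-1, keepdims=True)
        dlogits = p * (dp - dot)
        grads["Wout"] += np.einsum("bth,btc->hc", Hs, dlogits)
        grads["bout"] += dlogits.sum(axis=(0, 1))
        return dlogits @ params["Wout"].T

    # -- public forward ----------------------------------------------------

    def predict_windows(self, window_lists: list[list[np.ndarray]]):
        """Class/threshold probabilities for raw per-window token-id lists."""
        batch = _Batch(window_lists)
        X, _ = self._embed(batch, self.params)
        Hs, _ = self._rnn_forward(X, self.params)
        p, q, _ = self._decode(Hs, self.params)
        return p, q, batch.mask

    def predict(self, stays: list[TokenisedStay]) -> list[Trajectory]:
        out: list[Trajectory] = []
        bs = max(1, self.config.batch_size)
        for lo in range(0, len(stays), bs):
            chunk = stays[lo : lo + bs]
            p, q, mask = self.predict_windows([s.windows for s in chunk])
            for b, s in enumerate(chunk):
                T = s.n_windows
                out.append(
                    Trajectory(
                        patient_id=s.patient_id,
                        class_probs=p[b, :T].copy(),
                        threshold_probs=q[b, :T].copy(),
                        outcome_index=s.outcome_index,
                    )
                )
        return out

    # -- loss & gradients --------------------------------------------------

    def loss_and_grads(self, stays: list[TokenisedStay], compute_grads=True):
        batch = _Batch([s.windows for s in stays])
        y = np.array([s.outcome_index for s in stays])
        X, emb_cache = self._embed(batch, self.params)
        Hs, rnn_cache = self._rnn_forward(X, self.params)
        p, q, dec_cache = self._decode(Hs, self.params)
        mask = batch.mask
        n_valid = mask.sum()
        py = np.take_along_axis(p, y[:, None, None], axis=2)[..., 0]  # (B,T)
        py_c = np.clip(py, 1e-12, None)
        loss = -(np.log(py_c) * mask).sum() / n_valid
        if not compute_grads:
            return loss, None
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dp = np.zeros_like(p)
        coef = -(mask / py_c) / n_valid
        np.put_along_axis(dp, y[:, None, None], coef[..., None], axis=2)
        dHs = self._decode_backward(dp, q, dec_cache, Hs, grads)
        dX = self._rnn_backward(dHs, rnn_cache, grads)
        self._embed_backward(dX, emb_cache, grads)
        return loss, grads

    # -- training ----------------------------------------------------------

    def fit(
        self,
        train_stays: list[TokenisedStay],
        val_stays: list[TokenisedStay],
        verbose: bool = False,
    ) -> list[dict]:
        """Adam training with early stopping on validation NLL.

        Deterministic given ``config.seed``: one generator drives
        initialisation (done in __init__) and epoch shuffling.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        stall = 0
        self.training_log = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_stays))
            ep_loss = 0.0
            n_b = 0
            for lo in range(0, len(order), cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                loss, grads = self.loss_and_grads([train_stays[i] for i in idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}"
                    )
                step += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mhat = m[k] / (1 - b1**step)
                    vhat = v[k] / (1 - b2**step)
                    self.params[k] -= cfg.learning_rate * mhat / (
                        np.sqrt(vhat) + eps
                    )
                ep_loss += loss
                n_b += 1
            val_loss, _ = self.loss_and_grads(val_stays, compute_grads=False)
            self.training_log.append(
                {
                    "epoch": epoch,
                    "train_loss": float(ep_loss / max(n_b, 1)),
                    "val_loss": float(val_loss),
                }
            )
            if verbose:
                print(
                    f"epoch {epoch:3d}  train {ep_loss / max(n_b, 1):.4f}  "
                    f"val {val_loss:.4f}"
                )
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params = best_params
        return self.training_log

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab_size": self.vocab_size,
            "vocab_checksum": self.vocab_checksum,
            "format": "icucourse-model-v1",
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str, expected_vocab_checksum: str | None = None):
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        if (
            expected_vocab_checksum is not None
            and meta["vocab_checksum"]
            and meta["vocab_checksum"] != expected_vocab_checksum
        ):
            raise ValueError(
                "model checkpoint was trained against a different vocabulary "
                f"({meta['vocab_checksum']} != {expected_vocab_checksum})"
            )
        cfg = ModelConfig(**meta["config"])
        return cls(cfg, meta["vocab_size"], meta["vocab_checksum"], params)


# ---------------------------------------------------------------------------
# Head algebra shared with the evaluation code
# ---------------------------------------------------------------------------


def threshold_to_class(q: np.ndarray) -> np.ndarray:
    """Class probabilities from monotone threshold probabilities.

    p(0) = 1 - q(1); p(c) = q(c) - q(c+1); p(6) = q(6).
    """
    q = np.asarray(q)
    parts = [1.0 - q[..., :1], q[..., :-1] - q[..., 1:], q[..., -1:]]
    return np.concatenate(parts, axis=-1)


def class_to_threshold(p: np.ndarray) -> np.ndarray:
    """Threshold probabilities q(k) = P(outcome above cut k) from classes."""
    p = np.asarray(p)
    rev_cum = np.cumsum(p[..., ::-1], axis=-1)[..., ::-1]
    return rev_cum[..., 1:]


def trajectories_to_frame(trajectories: list[Trajectory]):
    """Tidy export: one row per (patient, window)."""
    import pandas as pd

    rows = []
    for tr in trajectories:
        e = tr.expected_index
        for t in range(tr.n_windows):
            row = {"patient_id": tr.patient_id, "window": t}
            for c in range(N_OUTCOME_CATEGORIES):
                row[f"p{c}"] = tr.class_probs[t, c]
            for k in range(N_THRESHOLDS):
                row[f"q{k + 1}"] = tr.threshold_probs[t, k]
            row["expected_index"] = e[t]
            row["outcome_index"] = tr.outcome_index
            rows.append(row)
    return pd.DataFrame(rows)
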