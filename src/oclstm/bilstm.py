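"""Bidirectional two-layer LSTM over per-residue CNN features.

The window CNN sees only a fixed local context; helices and strands are
segments whose ends depend on residues far outside any window.  This stage
runs two stacked bidirectional LSTM layers over each protein's ordered
sequence of fully-connected CNN features and classifies every residue with
a softmax head, capturing that long-distance dependence.

The cell follows the standard gate equations -- i, f, o are sigmoids of
affine maps of (h_{t-1}, F_t), the candidate is a tanh, the cell state
mixes elementwise -- with separate input and recurrent weight blocks per
gate.  Forward and backward directions have independent parameters; their
per-residue hidden states are merged (concatenation by default) before the
next layer or the head.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .io_encoding import SS3_STATES

log = logging.getLogger(__name__)

_GATES = ("i", "f", "o", "c")  # input, forget, output, candidate


@dataclass
class LSTMCellParams:
    """Per-gate weight blocks applied jointly to (h_prev, x), plus biases.

    ``W[g]`` has shape ``(hidden + input_dim, hidden)``: the first
    ``hidden`` rows act on h_{t-1}, the rest on the input vector.
    """

    W: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "LSTMCellParams":
        scale = 1.0 / np.sqrt(hidden + input_dim)
        W = {g: rng.uniform(-scale, scale, size=(hidden + input_dim, hidden))
             for g in _GATES}
        b = {g: np.zeros(hidden) for g in _GATES}
        b["f"][:] = 1.0  # standard forget-gate bias: remember by default
        return cls(W, b)

    @property
    def hidden(self) -> int:
        return self.W["i"].shape[1]

    @property
    def input_dim(self) -> int:
        return self.W["i"].shape[0] - self.hidden


@dataclass
class LSTMState:
    """Hidden and cell vectors carried between time steps."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zero(cls, hidden: int, batch: int | None = None) -> "LSTMState":
        shape = (hidden,) if batch is None else (batch, hidden)
        return cls(np.zeros(shape), np.zeros(shape))


def lstm_cell_step(params: LSTMCellParams, F_t: np.ndarray,
                   prev: LSTMState) -> LSTMState:
    """One LSTM step: gate sigmoids, tanh candidate, elementwise cell mix.

    Accepts a single vector or a batch (leading batch axis on both ``F_t``
    and the state).
    """
    if F_t.shape[-1] != params.input_dim:
        raise ValueError(
            f"input dim {F_t.shape[-1]} != cell input dim {params.input_dim}"
        )
    z = np.concatenate([prev.h, F_t], axis=-1)
    i = _nn.sigmoid(z @ params.W["i"] + params.b["i"])
    f = _nn.sigmoid(z @ params.W["f"] + params.b["f"])
    o = _nn.sigmoid(z @ params.W["o"] + params.b["o"])
    g = np.tanh(z @ params.W["c"] + params.b["c"])
    c = f * prev.c + i * g
    h = o * np.tanh(c)
    return LSTMState(h, c)


@dataclass
class BiLSTMSpec:
    """Shape of the bidirectional classifier."""

    input_dim: int = 50
    layer1_hidden: int = 64
    layer2_hidden: int = 64
    merge: str = "concat"      # 'concat' | 'sum'
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.merge not in ("concat", "sum"):
            raise ValueError(f"merge must be 'concat' or 'sum', got {self.merge!r}")

    def merged_dim(self, hidden: int) -> int:
        return 2 * hidden if self.merge == "concat" else hidden


def published_optimal_bilstm_spec(input_dim: int = 50) -> BiLSTMSpec:
    """The published best cell sizes (layer1=1000, layer2=800)."""
    return BiLSTMSpec(input_dim=input_dim, layer1_hidden=1000, layer2_hidden=800)


class _DirectionalLSTM:
    """One direction of one layer, batched over (T, B, input_dim)."""

    def __init__(self, cell: LSTMCellParams):
        self.cell = cell
        self.grads = {f"W{g}": np.zeros_like(cell.W[g]) for g in _GATES}
        self.grads.update({f"b{g}": np.zeros_like(cell.b[g]) for g in _GATES})

    def forward(self, x: np.ndarray) -> np.ndarray:
        T, B, _ = x.shape
        H = self.cell.hidden
        state = LSTMState.zero(H, B)
        self._cache = []
        hs = np.empty((T, B, H))
        for t in range(T):
            z = np.concatenate([state.h, x[t]], axis=-1)
            i = _nn.sigmoid(z @ self.cell.W["i"] + self.cell.b["i"])
            f = _nn.sigmoid(z @ self.cell.W["f"] + self.cell.b["f"])
            o = _nn.sigmoid(z @ self.cell.W["o"] + self.cell.b["o"])
            g = np.tanh(z @ self.cell.W["c"] + self.cell.b["c"])
            c = f * state.c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._cache.append((z, i, f, o, g, state.c, tc))
            state = LSTMState(h, c)
            hs[t] = h
        return hs

    def backward(self, dh_all: np.ndarray) -> np.ndarray:
        T, B, H = dh_all.shape
        in_dim = self.cell.input_dim
        dx = np.empty((T, B, in_dim))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for key in self.grads:
            self.grads[key][...] = 0.0
        for t in range(T - 1, -1, -1):
            z, i, f, o, g, c_prev, tc = self._cache[t]
            dh = dh_all[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = {
                "i": di * i * (1.0 - i),
                "f": df * f * (1.0 - f),
                "o": do * o * (1.0 - o),
                "c": dg * (1.0 - g ** 2),
            }
            dz = np.zeros_like(z)
            for gate in _GATES:
                self.grads[f"W{gate}"] += z.T @ da[gate]
                self.grads[f"b{gate}"] += da[gate].sum(axis=0)
                dz += da[gate] @ self.cell.W[gate].T
            dh_next = dz[:, :H]
            dx[t] = dz[:, H:]
        return dx


def _reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse the first ``lengths[b]`` steps of each sequence (an involution)."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        out[:L, b] = x[:L, b][::-1]
    return out


class TrainingDivergedError(RuntimeError):
    pass


class BiLSTMClassifier:
    """Two stacked bidirectional LSTM layers with a per-residue softmax head."""

    def __init__(self, spec: BiLSTMSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        s = spec
        self.cells = {
            "l1f": LSTMCellParams.init(s.input_dim, s.layer1_hidden, rng),
            "l1b": LSTMCellParams.init(s.input_dim, s.layer1_hidden, rng),
            "l2f": LSTMCellParams.init(s.merged_dim(s.layer1_hidden), s.layer2_hidden, rng),
            "l2b": LSTMCellParams.init(s.merged_dim(s.layer1_hidden), s.layer2_hidden, rng),
        }
        head_in = s.merged_dim(s.layer2_hidden)
        self.head_W = np.zeros((head_in, s.n_classes))
        self.head_b = np.zeros(s.n_classes)
        self.training_log: list[dict] = []
        self.train_config: dict = {}

    # -- parameter plumbing (flat dicts for the optimizer) -------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params = {"head_W": self.head_W, "head_b": self.head_b}
        for name, cell in self.cells.items():
            for g in _GATES:
                params[f"{name}_W{g}"] = cell.W[g]
                params[f"{name}_b{g}"] = cell.b[g]
        return params

    # -- forward -------------------------------------------------------------

    def _merge(self, fwd: np.ndarray, bwd: np.ndarray) -> np.ndarray:
        if self.spec.merge == "concat":
            return np.concatenate([fwd, bwd], axis=-1)
        return fwd + bwd

    def _forward_batch(self, x: np.ndarray, lengths: np.ndarray,
                       keep_cache: bool = False):
        """x: (T, B, input_dim) tail-padded.  Returns logits (T, B, 3)."""
        runs = {name: _DirectionalLSTM(cell) for name, cell in self.cells.items()}
        xr = _reverse_padded(x, lengths)
        h1f = runs["l1f"].forward(x)
        h1b = _reverse_padded(runs["l1b"].forward(xr), lengths)
        m1 = self._merge(h1f, h1b)
        m1r = _reverse_padded(m1, lengths)
        h2f = runs["l2f"].forward(m1)
        h2b = _reverse_padded(runs["l2b"].forward(m1r), lengths)
        m2 = self._merge(h2f, h2b)
        logits = m2 @ self.head_W + self.head_b
        if keep_cache:
            self._runs = runs
            self._fwd_cache = (x, lengths, m2)
        return logits, m2

    def _backward_batch(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        x, lengths, m2 = self._fwd_cache
        runs = self._runs
        grads: dict[str, np.ndarray] = {}
        grads["head_W"] = m2.reshape(-1, m2.shape[-1]).T @ dlogits.reshape(-1, dlogits.shape[-1])
        grads["head_b"] = dlogits.reshape(-1, dlogits.shape[-1]).sum(axis=0)
        dm2 = dlogits @ self.head_W.T
        if self.spec.merge == "concat":
            h2 = self.spec.layer2_hidden
            d2f, d2b = dm2[..., :h2], dm2[..., h2:]
        else:
            d2f = d2b = dm2
        dm1 = runs["l2f"].backward(d2f)
        dm1 += _reverse_padded(runs["l2b"].backward(_reverse_padded(d2b, lengths)), lengths)
        if self.spec.merge == "concat":
            h1 = self.spec.layer1_hidden
            d1f, d1b = dm1[..., :h1], dm1[..., h1:]
        else:
            d1f = d1b = dm1
        runs["l1f"].backward(d1f)
        runs["l1b"].backward(_reverse_padded(d1b, lengths))
        for name in self.cells:
            for key, g in runs[name].grads.items():
                grads[f"{name}_{key}"] = g
        return grads

    # -- public single-sequence API -------------------------------------------

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Per-residue class probabilities for one feature sequence (N, input_dim)."""
        feats = np.asarray(features, dtype=float)
        if feats.ndim != 2 or feats.shape[0] == 0:
            raise ValueError("feature sequence must be nonempty (N, input_dim)")
        logits, _ = self._forward_batch(feats[:, None, :], np.array([feats.shape[0]]))
        return _nn.softmax(logits[:, 0, :])

    def merged_states(self, features: np.ndarray) -> np.ndarray:
        """Pre-head merged bidirectional states for one sequence (N, merged_dim)."""
        feats = np.asarray(features, dtype=float)
        _, m2 = self._forward_batch(feats[:, None, :], np.array([feats.shape[0]]))
        return m2[:, 0, :]

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, str]:
        probs = self.forward(features)
        return probs, "".join(SS3_STATES[k] for k in probs.argmax(axis=1))

    # -- training --------------------------------------------------------------

    def fit(self, sequences: Sequence[np.ndarray], labels: Sequence[np.ndarray],
            epochs: int = 10, lr: float = 1e-2, clip_norm: float = 5.0,
            batch_size: int = 32, seed: int = 0,
            valid: tuple[Sequence[np.ndarray], Sequence[np.ndarray]] | None = None
            ) -> "BiLSTMClassifier":
        """Minimize mean per-residue cross-entropy with Adam and gradient clipping.

        ``sequences[k]`` is an (N_k, input_dim) feature sequence from the CNN
        stage; ``labels[k]`` its (N_k,) integer 3-state labels.  Sequences
        are padded per batch and padded positions are excluded from the loss.
        """
        if len(sequences) == 0 or len(sequences) != len(labels):
            raise ValueError("need equally many nonempty sequences and label arrays")
        self.train_config = dict(epochs=epochs, lr=lr, clip_norm=clip_norm,
                                 batch_size=batch_size, seed=seed)
        opt = _nn.Adam(lr=lr)
        rng = np.random.default_rng(seed)
        n = len(sequences)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self._batch_loss_and_grads([sequences[k] for k in idx],
                                                         [labels[k] for k in idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
                _nn.clip_grad_norm(grads, clip_norm)
                opt.step(self.parameters(), grads)
                losses.append(loss)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if valid is not None:
                entry["valid_q3"] = self.score_q3(*valid)
            self.training_log.append(entry)
            log.info("bilstm epoch %d: %s", epoch, entry)
        return self

    def _batch_loss_and_grads(self, seqs, labs):
        B = len(seqs)
        lengths = np.array([s.shape[0] for s in seqs])
        T = int(lengths.max())
        x = np.zeros((T, B, self.spec.input_dim))
        y = np.zeros((T, B), dtype=np.int64)
        mask = np.zeros((T, B))
        for b, (s, l) in enumerate(zip(seqs, labs)):
            x[:lengths[b], b] = s
            y[:lengths[b], b] = l
            mask[:lengths[b], b] = 1.0
        logits, _ = self._forward_batch(x, lengths, keep_cache=True)
        probs = _nn.softmax(logits)
        eps = 1e-12
        picked = np.take_along_axis(probs, y[..., None], axis=-1)[..., 0]
        n_res = mask.sum()
        loss = float(-(mask * np.log(picked + eps)).sum() / n_res)
        dlogits = probs.copy()
        np.put_along_axis(dlogits, y[..., None],
                          np.take_along_axis(dlogits, y[..., None], axis=-1) - 1.0,
                          axis=-1)
        dlogits *= mask[..., None] / n_res
        grads = self._backward_batch(dlogits)
        return loss, grads

    def score_q3(self, sequences, labels) -> float:
        correct = total = 0
        for s, l in zip(sequences, labels):
            probs = self.forward(s)
            correct += int(np.sum(probs.argmax(axis=1) == l))
            total += len(l)
        return 100.0 * correct / total

    # -- persistence ------------------------------------------------------------

    CKPT_VERSION = 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.parameters())
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = {
            "ckpt_version": self.CKPT_VERSION,
            "spec": self.spec.__dict__,
            "seed": self.seed,
            "training_log": self.training_log,
            "train_config": self.train_config,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMClassifier":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta.get("ckpt_version") != cls.CKPT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        model = cls(BiLSTMSpec(**meta["spec"]), seed=meta.get("seed", 0))
        params = model.parameters()
        with np.load(path) as npz:
            for key, arr in params.items():
                arr[...] = npz[key]
        model.training_log = meta.get("training_log", [])
        model.train_config = meta.get("train_config", {})
        return model


def train_bilstm(spec: BiLSTMSpec, sequences, labels, seed: int = 0,
                 **train_kwargs) -> BiLSTMClassifier:
    """Train a fresh bidirectional classifier on CNN feature sequences."""
    model = BiLSTMClassifier(spec, seed=seed)
    model.fit(sequences, labels, seed=seed, **train_kwargs)
    return model
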