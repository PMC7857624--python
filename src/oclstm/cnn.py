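"""Depth-parameterized convolutional window classifier.

The network family is controlled by a single depth parameter: it has four
parts, each holding ``part_depth`` convolutional layers (ReLU after each),
with a pooling layer after each part, then one fully-connected layer and a
3-class softmax head.  Filter counts scale as ``round(256 / sqrt(part_depth))``
so different depths spend roughly the same parameter budget.  The
fully-connected activations double as the per-residue feature sequence the
bidirectional LSTM stage consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _nn
from .io_encoding import SS3_STATES, WindowDataset

log = logging.getLogger(__name__)

N_PARTS = 4
MIN_PART_DEPTH, MAX_PART_DEPTH = 1, 7


@dataclass
class ArchitectureSpec:
    """The depth-parameterized CNN family.

    ``filters_per_part`` normally follows ``round(filter_base / sqrt(part_depth))``
    with ``filter_base = 256``; desk-scale configs may lower ``filter_base``
    or pin per-part counts explicitly (the published optimum uses 94/94/128/128,
    which the rule does not generate -- see :func:`published_optimal_architecture`).
    """

    window_len: int
    part_depth: int
    kernel_sizes: tuple[int, int, int, int]
    pooling: str = "max"                       # 'max' | 'average'
    pool_size: int = 2
    pool_after: str = "each_part"              # 'each_part' | 'every_4_conv'
    fc_width: int = 50
    filter_base: int = 256
    filters_per_part: tuple[int, int, int, int] | None = None
    fc_post_activation: bool = True            # extract FC features after ReLU
    n_classes: int = 3
    n_parts: int = N_PARTS

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.window_len % 2 == 0:
            raise ValueError(f"window_len must be odd, got {self.window_len}")
        if not (MIN_PART_DEPTH <= self.part_depth <= MAX_PART_DEPTH):
            raise ValueError(
                f"part_depth must be in [{MIN_PART_DEPTH}, {MAX_PART_DEPTH}], "
                f"got {self.part_depth}"
            )
        if len(self.kernel_sizes) != self.n_parts:
            raise ValueError("kernel_sizes must list one extent per part")
        if self.pooling not in ("max", "average"):
            raise ValueError(f"pooling must be 'max' or 'average', got {self.pooling!r}")
        if self.pool_after not in ("each_part", "every_4_conv"):
            raise ValueError(f"bad pool_after {self.pool_after!r}")
        if self.filters_per_part is None:
            f = self.filters_for(self.part_depth, self.filter_base)
            self.filters_per_part = (f,) * self.n_parts
        # check pooling never erases the spatial axis
        for part, width in enumerate(self.part_widths()[1:], start=1):
            if width < 1:
                raise ValueError(f"pooling after part {part} reduces spatial size below 1")

    @staticmethod
    def filters_for(part_depth: int, filter_base: int = 256) -> int:
        return int(round(filter_base / np.sqrt(part_depth)))

    @property
    def filters_per_layer(self) -> int:
        return self.filters_per_part[0]

    @property
    def conv_layer_count(self) -> int:
        return self.n_parts * self.part_depth

    @property
    def total_layer_count(self) -> int:
        """All layers: input, conv+ReLU pairs, pools, FC, softmax."""
        return 1 + 2 * self.conv_layer_count + self._n_pools() + 1 + 1

    @property
    def table_layer_count(self) -> int:
        """Layer-count convention of the published trial tables (4*depth + 6)."""
        return 4 * self.part_depth + 6

    def _n_pools(self) -> int:
        return sum(self._pool_here(p) for p in range(self.n_parts))

    def _pool_here(self, part: int) -> bool:
        if self.pool_after == "each_part":
            return True
        # pool after every 4 convolutional layers
        return ((part + 1) * self.part_depth) % 4 == 0

    def part_widths(self) -> list[int]:
        """Spatial width entering each part (index 0) and after each pool."""
        widths = [self.window_len]
        w = self.window_len
        for part in range(self.n_parts):
            if self._pool_here(part):
                w = _nn.Pool1d.out_width(w, self.pool_size)
            widths.append(w)
        return widths

    def parameter_count(self) -> int:
        total = 0
        in_ch = 20
        for part in range(self.n_parts):
            k = self.kernel_sizes[part]
            out_ch = self.filters_per_part[part]
            for _ in range(self.part_depth):
                total += k * in_ch * out_ch + out_ch
                in_ch = out_ch
        final_width = self.part_widths()[-1]
        flat = final_width * in_ch
        total += flat * self.fc_width + self.fc_width
        total += self.fc_width * self.n_classes + self.n_classes
        return total


def default_kernel_sizes(window_len: int) -> tuple[int, int, int, int]:
    """Wide kernels (the full window) for the first two parts, 8 for the last two."""
    return (window_len, window_len, 8, 8)


def build_architecture(part_depth: int,
                       window_len: int,
                       pooling: str = "max",
                       kernel_sizes: tuple[int, int, int, int] | None = None,
                       fc_width: int = 50,
                       filter_base: int = 256,
                       **kwargs) -> ArchitectureSpec:
    """Build the spec for one member of the depth-parameterized family."""
    if kernel_sizes is None:
        kernel_sizes = default_kernel_sizes(window_len)
    return ArchitectureSpec(
        window_len=window_len,
        part_depth=part_depth,
        kernel_sizes=tuple(kernel_sizes),
        pooling=pooling,
        fc_width=fc_width,
        filter_base=filter_base,
        **kwargs,
    )


def published_optimal_architecture() -> ArchitectureSpec:
    """The published window-19 optimum, verbatim.

    8 convolutional layers: four of kernel 19 with 94 filters, four of
    kernel 8 with 128 filters, max pooling after every four conv layers.
    Note these filter counts do not follow the 256/sqrt(depth) rule; the
    preset reproduces the printed network rather than the rule.
    """
    return ArchitectureSpec(
        window_len=19,
        part_depth=2,
        kernel_sizes=(19, 19, 8, 8),
        pooling="max",
        pool_after="every_4_conv",
        filters_per_part=(94, 94, 128, 128),
        fc_width=50,
    )


@dataclass
class Prediction:
    """Per-sample class probabilities and the argmax label."""

    probs: np.ndarray  # (3,)
    label: str


class TrainingDivergedError(RuntimeError):
    pass


class CNNClassifier:
    """A concrete network instance: weights, training and feature extraction."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        in_ch = 20
        for part in range(spec.n_parts):
            k = spec.kernel_sizes[part]
            out_ch = spec.filters_per_part[part]
            for _ in range(spec.part_depth):
                layers.append(_nn.Conv1dSame(in_ch, out_ch, k, rng))
                layers.append(_nn.ReLU())
                in_ch = out_ch
            if spec._pool_here(part):
                layers.append(_nn.Pool1d(spec.pool_size, spec.pooling))
        layers.append(_nn.Flatten())
        flat = spec.part_widths()[-1] * in_ch
        self.fc = _nn.Dense(flat, spec.fc_width, rng)
        self.fc_act = _nn.ReLU()
        # zero-init head: an untrained model is exactly uniform over classes
        self.head = _nn.Dense(spec.fc_width, spec.n_classes, rng, zero_init=True)
        self.backbone = layers
        self.layers = layers + [self.fc, self.fc_act, self.head]
        self.training_log: list[dict] = []
        self.train_config: dict = {}

    # -- forward ------------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray,
                      class_weights: np.ndarray | None = None) -> float:
        logits = self._forward(x, train=True)
        loss, dlogits = _nn.softmax_cross_entropy(logits, labels, class_weights)
        self._backward(dlogits)
        return loss

    # -- training -----------------------------------------------------------

    def fit(self, train: WindowDataset, valid: WindowDataset | None,
            lr: float, momentum: float = 0.9, l2: float = 0.0,
            epochs: int = 10, batch_size: int = 128, seed: int = 0,
            class_weights: np.ndarray | None = None) -> "CNNClassifier":
        if len(train) == 0:
            raise ValueError("training dataset is empty")
        if train.window_len != self.spec.window_len:
            raise ValueError(
                f"dataset window {train.window_len} != architecture window "
                f"{self.spec.window_len}"
            )
        self.train_config = dict(lr=lr, momentum=momentum, l2=l2, epochs=epochs,
                                 batch_size=batch_size, seed=seed)
        opt = _nn.SGDMomentum(lr, momentum, l2)
        rng = np.random.default_rng(seed)
        x = train.features.astype(np.float64)
        y = train.labels.astype(np.int64)
        for epoch in range(epochs):
            order = rng.permutation(len(train))
            losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start:start + batch_size]
                loss = self.loss_and_grad(x[idx], y[idx], class_weights)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} with "
                        f"lr={lr}, momentum={momentum}, l2={l2}"
                    )
                opt.step(self.layers)
                losses.append(loss)
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if valid is not None and len(valid) > 0:
                vloss, vq3 = self.evaluate(valid)
                entry.update(valid_loss=vloss, valid_q3=vq3)
            self.training_log.append(entry)
            log.info("cnn epoch %d: %s", epoch, entry)
        return self

    def evaluate(self, data: WindowDataset) -> tuple[float, float]:
        """Mean cross-entropy and Q3 (percent) on a dataset."""
        probs = self.predict_proba(data)
        y = data.labels.astype(np.int64)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
        q3 = float(100.0 * np.mean(probs.argmax(axis=1) == y))
        return loss, q3

    @property
    def final_valid_loss(self) -> float:
        if not self.training_log or "valid_loss" not in self.training_log[-1]:
            raise ValueError("model has no recorded validation loss")
        return float(self.training_log[-1]["valid_loss"])

    # -- inference ----------------------------------------------------------

    def predict_proba(self, data: WindowDataset | np.ndarray,
                      batch_size: int = 4096) -> np.ndarray:
        x = data.features if isinstance(data, WindowDataset) else data
        if x.shape[1] != self.spec.window_len or x.shape[2] != 20:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match architecture "
                f"({self.spec.window_len}, 20)"
            )
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(x[start:start + batch_size].astype(np.float64))
            out.append(_nn.softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, data: WindowDataset) -> list[Prediction]:
        probs = self.predict_proba(data)
        labels = probs.argmax(axis=1)  # ties break toward lower index = H,E,C order
        return [Prediction(p, SS3_STATES[i]) for p, i in zip(probs, labels)]

    # -- feature extraction (input to the BiLSTM stage) ----------------------

    def extract_features(self, data: WindowDataset,
                         batch_size: int = 4096) -> dict[str, np.ndarray]:
        """Per-protein ordered sequences of fully-connected activations.

        Returns ``{protein_id: (N, fc_width) array}`` ordered by residue
        index, regardless of sample order in the dataset.
        """
        if data.protein_idx is None or data.center_index is None:
            raise ValueError("dataset lacks protein/position provenance")
        x = data.features.astype(np.float64)
        feats = []
        for start in range(0, x.shape[0], batch_size):
            h = x[start:start + batch_size]
            for layer in self.backbone:
                h = layer.forward(h)
            h = self.fc.forward(h)
            if self.spec.fc_post_activation:
                h = self.fc_act.forward(h)
            feats.append(h)
        flat = np.concatenate(feats, axis=0)
        out: dict[str, np.ndarray] = {}
        for pid_idx, pid in enumerate(data.protein_ids):
            mask = data.protein_idx == pid_idx
            if not mask.any():
                continue
            order = np.argsort(data.center_index[mask])
            centers = data.center_index[mask][order]
            if not np.array_equal(centers, np.arange(len(centers))):
                raise ValueError(f"{pid}: incomplete residue coverage in dataset")
            out[pid] = flat[mask][order]
        return out

    # -- persistence ---------------------------------------------------------

    CKPT_VERSION = 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                arrays[f"layer{li}_{key}"] = val
        np.savez(path, **arrays)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        spec_d = asdict(self.spec)
        spec_d["kernel_sizes"] = list(self.spec.kernel_sizes)
        spec_d["filters_per_part"] = list(self.spec.filters_per_part)
        meta = {
            "ckpt_version": self.CKPT_VERSION,
            "spec": spec_d,
            "seed": self.seed,
            "training_log": self.training_log,
            "train_config": self.train_config,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta.get("ckpt_version") != cls.CKPT_VERSION:
            raise ValueError(f"{path}: unsupported checkpoint version")
        spec_d = dict(meta["spec"])
        spec_d["kernel_sizes"] = tuple(spec_d["kernel_sizes"])
        spec_d["filters_per_part"] = tuple(spec_d["filters_per_part"])
        model = cls(ArchitectureSpec(**spec_d), seed=meta.get("seed", 0))
        with np.load(path) as npz:
            for li, layer in enumerate(model.layers):
                for key in layer.params:
                    layer.params[key][...] = npz[f"layer{li}_{key}"]
        model.training_log = meta.get("training_log", [])
        model.train_config = meta.get("train_config", {})
        return model


def train_cnn(spec: ArchitectureSpec, train: WindowDataset,
              valid: WindowDataset | None, hp, epochs: int = 20,
              batch_size: int = 128, seed: int = 0,
              class_weights: np.ndarray | None = None) -> CNNClassifier:
    """Train a fresh network of ``spec`` with the hyperparameters in ``hp``.

    ``hp`` is any object with ``lr``, ``momentum`` and ``l2`` attributes
    (typically a :class:`~oclstm.bayes_opt.HyperparamPoint`).
    """
    model = CNNClassifier(spec, seed=seed)
    model.fit(train, valid, lr=hp.lr, momentum=hp.momentum, l2=hp.l2,
              epochs=epochs, batch_size=batch_size, seed=seed,
              class_weights=class_weights)
    return model
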