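"""Q3 and per-class accuracies for 3-state secondary-structure prediction.

Q3 is the percentage of residues whose predicted state matches the true
one; Q_H, Q_E, Q_C are the per-true-class recalls (correct within a class
over that class's true count), so Q3 is exactly their count-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_encoding import SS3_INDEX, SS3_STATES


@dataclass
class ConfusionTable:
    """3x3 counts: rows = true state (H, E, C), columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError(f"confusion table must be 3x3, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, true: Iterable[str | int], pred: Iterable[str | int]) -> "ConfusionTable":
        counts = np.zeros((3, 3), dtype=np.int64)
        true = _as_indices(true)
        pred = _as_indices(pred)
        if len(true) != len(pred):
            raise ValueError("true and predicted label sequences differ in length")
        np.add.at(counts, (true, pred), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.counts + other.counts)


def _as_indices(labels: Iterable[str | int]) -> np.ndarray:
    labels = list(labels)
    if labels and isinstance(labels[0], str):
        return np.array([SS3_INDEX[s] for s in labels], dtype=np.int64)
    return np.asarray(labels, dtype=np.int64)


def q3(confusion: ConfusionTable) -> float:
    """Overall 3-state accuracy as a percentage: 100 * trace / total."""
    if confusion.total == 0:
        raise ValueError("empty confusion table")
    return float(100.0 * np.trace(confusion.counts) / confusion.total)


def per_class_accuracy(confusion: ConfusionTable) -> dict[str, float | None]:
    """Per-true-class recall in percent; classes never observed map to None."""
    out: dict[str, float | None] = {}
    for i, state in enumerate(SS3_STATES):
        row = confusion.counts[i].sum()
        out[state] = float(100.0 * confusion.counts[i, i] / row) if row > 0 else None
    return out


def score_report(confusion: ConfusionTable) -> dict:
    """JSON-ready report: Q3, Q_H/Q_E/Q_C and the raw table."""
    per_class = per_class_accuracy(confusion)
    return {
        "q3": q3(confusion),
        "q_h": per_class["H"],
        "q_e": per_class["E"],
        "q_c": per_class["C"],
        "confusion": confusion.counts.tolist(),
        "n_residues": confusion.total,
    }
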