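"""Sequence, label and PSSM input/output, DSSP-state reduction and window encoding.

Protein chains arrive as FASTA sequences paired with per-residue secondary
structure strings (8-state DSSP letters or 3-state H/E/C) and one PSI-BLAST
ASCII PSSM profile per chain.  This module reduces 8-state labels to the
3-state alphabet, aligns profiles with sequences and cuts the 20-channel
profile into centered, zero-padded sliding windows -- one training sample
per residue.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, in PSI-BLAST column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AMINO_ACIDS = frozenset(PSSM_ALPHABET)

#: 8-state DSSP alphabet accepted on input.
SS8_LETTERS = frozenset("HBEGITSL")

#: 3-state output alphabet, fixed class order used everywhere downstream.
SS3_STATES = "HEC"
SS3_INDEX = {s: i for i, s in enumerate(SS3_STATES)}

_SS8_TO_SS3 = {"G": "H", "H": "H", "I": "H", "B": "E", "E": "E"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ProteinRecord:
    """One protein chain: sequence plus optional 8- and 3-state labels."""

    id: str
    sequence: str
    ss8: str | None = None
    ss3: str | None = None

    def __post_init__(self) -> None:
        if self.ss8 is not None and len(self.ss8) != len(self.sequence):
            raise ValueError(
                f"{self.id}: ss8 length {len(self.ss8)} != sequence length "
                f"{len(self.sequence)}"
            )
        if self.ss3 is not None and len(self.ss3) != len(self.sequence):
            raise ValueError(
                f"{self.id}: ss3 length {len(self.ss3)} != sequence length "
                f"{len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_ss3(self) -> "ProteinRecord":
        """Return a copy whose ss3 is filled in (derived from ss8 if needed)."""
        if self.ss3 is not None:
            return self
        if self.ss8 is None:
            raise ValueError(f"{self.id}: no secondary-structure labels present")
        return ProteinRecord(self.id, self.sequence, self.ss8, map_ss8_to_ss3(self.ss8))


@dataclass
class ProfileMatrix:
    """20 x N evolutionary profile (PSI-BLAST log-odds) for one chain.

    Rows follow :data:`PSSM_ALPHABET`; column ``i`` scores residue ``i``.
    """

    id: str
    scores: np.ndarray
    residues: str | None = None  # letters read from the profile file, if any

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[0] != 20:
            raise ValueError(
                f"{self.id}: profile must be 20 x N, got shape {self.scores.shape}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[1]


@dataclass
class WindowSample:
    """One per-residue sample: a window_len x 20 feature slab and its label."""

    features: np.ndarray
    label: str
    protein_id: str
    center_index: int


@dataclass
class WindowDataset:
    """Per-residue window samples with provenance, stored column-dense.

    ``features[k]`` is the ``window_len x 20`` slab for sample ``k``;
    ``labels[k]`` indexes :data:`SS3_STATES`; ``protein_idx[k]`` and
    ``center_index[k]`` record which chain and residue the sample came from.
    """

    features: np.ndarray          # (n, window_len, 20) float32
    labels: np.ndarray            # (n,) uint8 into SS3_STATES
    protein_ids: list[str]
    protein_idx: np.ndarray       # (n,) int32 into protein_ids
    center_index: np.ndarray      # (n,) int32, 0-based residue index
    window_len: int

    FORMAT_VERSION = 1

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=3)
        return {s: int(counts[i]) for i, s in enumerate(SS3_STATES)}

    def __getitem__(self, k: int) -> WindowSample:
        return WindowSample(
            features=self.features[k],
            label=SS3_STATES[self.labels[k]],
            protein_id=self.protein_ids[self.protein_idx[k]],
            center_index=int(self.center_index[k]),
        )

    def samples(self) -> Iterator[WindowSample]:
        for k in range(len(self)):
            yield self[k]

    def subset(self, mask_or_index: np.ndarray) -> "WindowDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return WindowDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            protein_ids=self.protein_ids,
            protein_idx=self.protein_idx[idx],
            center_index=self.center_index[idx],
            window_len=self.window_len,
        )

    def subset_by_proteins(self, ids: Iterable[str]) -> "WindowDataset":
        wanted = {self.protein_ids.index(i) for i in ids}
        mask = np.isin(self.protein_idx, sorted(wanted))
        return self.subset(mask)


# ---------------------------------------------------------------------------
# FASTA sequences and FASTA-like label files
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA.

    Sequences are uppercased; letters outside the 20-letter alphabet (and
    outside 'X') are mapped to 'X' with a warning.  Duplicate ids and empty
    files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        cleaned = []
        n_mapped = 0
        for ch in seq:
            if ch in AMINO_ACIDS or ch == "X":
                cleaned.append(ch)
            else:
                cleaned.append("X")
                n_mapped += 1
        if n_mapped:
            log.warning(
                "%s: %d non-standard letter(s) in %s mapped to 'X'",
                path, n_mapped, entry.id,
            )
        records.append(ProteinRecord(entry.id, "".join(cleaned)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path, records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Attach secondary-structure labels from a FASTA-like label file.

    The label file holds one entry per chain whose "sequence" lines are the
    8-state or 3-state letter string.  Entries are matched to ``records`` by
    id; 8-state strings are reduced to 3-state automatically.
    """
    path = Path(path)
    label_map: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in label_map:
            raise FormatError(f"{path}: duplicate label id {entry.id!r}")
        label_map[entry.id] = str(entry.seq).upper()
    if not label_map:
        raise FormatError(f"{path}: no label records found")
    out: list[ProteinRecord] = []
    for rec in records:
        if rec.id not in label_map:
            raise FormatError(f"{path}: no labels for protein {rec.id!r}")
        lab = label_map[rec.id]
        if len(lab) != len(rec.sequence):
            raise FormatError(
                f"{path}: label length {len(lab)} != sequence length "
                f"{len(rec.sequence)} for {rec.id!r}"
            )
        if set(lab) <= set(SS3_STATES):
            out.append(ProteinRecord(rec.id, rec.sequence, None, lab))
        else:
            out.append(ProteinRecord(rec.id, rec.sequence, lab, map_ss8_to_ss3(lab)))
    return out


def write_labels(records: Sequence[ProteinRecord], path: str | Path,
                 states: str = "ss3") -> None:
    with open(path, "w") as fh:
        for rec in records:
            lab = rec.ss3 if states == "ss3" else rec.ss8
            if lab is None:
                raise ValueError(f"{rec.id}: no {states} labels to write")
            fh.write(f">{rec.id}\n{lab}\n")


# ---------------------------------------------------------------------------
# DSSP 8-state -> 3-state reduction
# ---------------------------------------------------------------------------

def map_ss8_to_ss3(ss8: str) -> str:
    """Reduce an 8-state DSSP string to 3 states.

    G/H/I (helices) -> H; B/E (strands/bridges) -> E; everything else --
    T, S, L, and any dialect letter such as 'C' or '-' -- -> C.  Letters
    outside the 8-state alphabet are accepted (they fall into the C
    catch-all) but warned about.
    """
    out = []
    unknown: set[str] = set()
    for ch in ss8.upper():
        mapped = _SS8_TO_SS3.get(ch)
        if mapped is None:
            if ch not in SS8_LETTERS and ch not in {"C", "-"}:
                unknown.add(ch)
            mapped = "C"
        out.append(mapped)
    if unknown:
        log.warning("unknown DSSP letter(s) %s mapped to C", sorted(unknown))
    return "".join(out)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(.*)$")


def read_pssm_ascii(path: str | Path, record: ProteinRecord | None = None) -> ProfileMatrix:
    """Read a PSI-BLAST ``-out_ascii_pssm`` profile.

    Only the first 20-column block (the log-odds scores) is kept, transposed
    to 20 x N in :data:`PSSM_ALPHABET` order.  Each data row must carry 40
    numeric columns (20 log-odds + 20 percentages); shorter rows raise a
    :class:`FormatError` naming the line.  If ``record`` is given, the
    residue letters in the file are checked against its sequence.
    """
    path = Path(path)
    columns: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            m = _ROW_RE.match(line)
            if not m:
                if columns and not line.strip():
                    break  # blank line after the matrix: trailing statistics follow
                continue
            pos, letter, rest = int(m.group(1)), m.group(2), m.group(3)
            if pos != expected_pos:
                # not a matrix row (e.g. a numbered header); ignore until rows start
                if not columns:
                    continue
                raise FormatError(f"{path}:{lineno}: expected position {expected_pos}, got {pos}")
            try:
                values = [float(tok) for tok in rest.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score column ({exc})") from None
            if len(values) != 40:
                raise FormatError(
                    f"{path}:{lineno}: expected 40 numeric columns, found {len(values)}"
                )
            columns.append(values[:20])
            residues.append(letter.upper())
            expected_pos += 1
    if not columns:
        raise FormatError(f"{path}: no PSSM rows found")
    scores = np.array(columns, dtype=np.float64).T  # 20 x N
    resid_str = "".join(residues)
    prof_id = record.id if record is not None else path.stem
    if record is not None:
        if len(resid_str) != len(record.sequence):
            raise FormatError(
                f"{path}: profile has {len(resid_str)} residues but sequence "
                f"{record.id!r} has {len(record.sequence)}"
            )
        for i, (a, b) in enumerate(zip(resid_str, record.sequence)):
            if a != b and "X" not in (a, b):
                raise FormatError(
                    f"{path}: residue mismatch at position {i + 1}: "
                    f"profile {a!r} vs sequence {b!r}"
                )
    return ProfileMatrix(prof_id, scores, resid_str)


def write_pssm_ascii(profile: ProfileMatrix, sequence: str, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect :func:`read_pssm_ascii` consumes.

    The second 20-column block (weighted percentages) is filled with zeros;
    scores are printed with 6 decimals, so real-valued synthetic profiles
    round-trip at that precision and integer profiles round-trip exactly.
    """
    scores = profile.scores
    if scores.shape[1] != len(sequence):
        raise ValueError(
            f"{profile.id}: profile length {scores.shape[1]} != sequence length {len(sequence)}"
        )
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        header = " ".join(f"{a:>9}" for a in PSSM_ALPHABET)
        fh.write(f"          {header} {header}\n")
        for i, letter in enumerate(sequence):
            vals = " ".join(_fmt_score(v) for v in scores[:, i])
            zeros = " ".join(f"{0:9d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {letter} {vals} {zeros}\n")
        fh.write("\n")


def _fmt_score(v: float) -> str:
    if float(v).is_integer():
        return f"{int(v):9d}"
    return f"{v:9.6f}"


def read_pssm_dir(directory: str | Path, records: Sequence[ProteinRecord],
                  suffix: str = ".pssm") -> list[ProfileMatrix]:
    """Read ``<id><suffix>`` profiles for every record from a directory."""
    directory = Path(directory)
    profiles = []
    for rec in records:
        profiles.append(read_pssm_ascii(directory / f"{rec.id}{suffix}", rec))
    return profiles


# ---------------------------------------------------------------------------
# Window encoding
# ---------------------------------------------------------------------------

def encode_windows(profiles: Sequence[ProfileMatrix],
                   records: Sequence[ProteinRecord],
                   window_len: int) -> WindowDataset:
    """Cut profiles into centered sliding windows, one sample per residue.

    For residue ``i`` the sample is profile columns ``[i-p, i+p]`` with
    ``p = (window_len - 1) // 2``; positions outside the chain are zero
    vectors, so a window of 13 pads 6 zero columns before the first and
    after the last residue.  The label is the 3-state letter at ``i``.
    """
    if window_len < 1 or window_len % 2 == 0:
        raise ValueError(f"window_len must be odd and >= 1, got {window_len}")
    prof_by_id = {p.id: p for p in profiles}
    p = (window_len - 1) // 2

    feats, labels, prot_idx, centers = [], [], [], []
    ids: list[str] = []
    for rec in records:
        rec = rec.with_ss3()
        if rec.id not in prof_by_id:
            raise ValueError(f"no profile for protein {rec.id!r}")
        prof = prof_by_id[rec.id]
        n = len(rec)
        if prof.length != n:
            raise ValueError(
                f"{rec.id}: profile length {prof.length} != sequence length {n}"
            )
        ids.append(rec.id)
        pid = len(ids) - 1
        # pad once per chain, then take contiguous slices
        padded = np.zeros((n + 2 * p, 20), dtype=np.float32)
        padded[p:p + n] = prof.scores.T
        for i in range(n):
            feats.append(padded[i:i + window_len])
            labels.append(SS3_INDEX[rec.ss3[i]])
            prot_idx.append(pid)
            centers.append(i)
    return WindowDataset(
        features=np.stack(feats).astype(np.float32),
        labels=np.array(labels, dtype=np.uint8),
        protein_ids=ids,
        protein_idx=np.array(prot_idx, dtype=np.int32),
        center_index=np.array(centers, dtype=np.int32),
        window_len=window_len,
    )


# ---------------------------------------------------------------------------
# Per-channel standardization (fit on training data only)
# ---------------------------------------------------------------------------

@dataclass
class ChannelStandardizer:
    """Per-amino-acid-channel mean/sd learned from a training dataset."""

    mean: np.ndarray  # (20,)
    std: np.ndarray   # (20,)

    @classmethod
    def fit(cls, dataset: WindowDataset) -> "ChannelStandardizer":
        flat = dataset.features.reshape(-1, 20).astype(np.float64)
        std = flat.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=flat.mean(axis=0), std=std)

    def transform(self, dataset: WindowDataset) -> WindowDataset:
        feats = (dataset.features - self.mean.astype(np.float32)) / self.std.astype(np.float32)
        return WindowDataset(feats, dataset.labels, dataset.protein_ids,
                             dataset.protein_idx, dataset.center_index,
                             dataset.window_len)


# ---------------------------------------------------------------------------
# Dataset serialization: .npz container + JSON sidecar
# ---------------------------------------------------------------------------

def write_dataset(dataset: WindowDataset, path: str | Path) -> None:
    """Write a dataset as an ``.npz`` container plus a ``.json`` sidecar."""
    path = Path(path)
    np.savez(
        path,
        features=dataset.features,
        labels=dataset.labels,
        protein_idx=dataset.protein_idx,
        center_index=dataset.center_index,
    )
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "format_version": WindowDataset.FORMAT_VERSION,
        "window_len": dataset.window_len,
        "protein_ids": dataset.protein_ids,
        "n_samples": len(dataset),
        "class_counts": dataset.class_counts,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(path: str | Path) -> WindowDataset:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: dataset sidecar missing")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format_version") != WindowDataset.FORMAT_VERSION:
        raise FormatError(
            f"{path}: unsupported dataset format version {meta.get('format_version')!r}"
        )
    try:
        with np.load(path) as npz:
            ds = WindowDataset(
                features=npz["features"],
                labels=npz["labels"],
                protein_ids=list(meta["protein_ids"]),
                protein_idx=npz["protein_idx"],
                center_index=npz["center_index"],
                window_len=int(meta["window_len"]),
            )
    except Exception as exc:  # corrupted container
        raise FormatError(f"{path}: cannot read dataset container ({exc})") from exc
    if ds.class_counts != meta["class_counts"]:
        raise FormatError(f"{path}: stored class counts disagree with contents")
    return ds
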