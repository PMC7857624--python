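"""End-to-end orchestration: encode, optimize, train, extract, label, score.

A run takes a config (YAML or :class:`RunConfig`), generates or loads a
corpus, and per cross-validation fold: tunes the CNN training
hyperparameters with the GP/EI optimizer on an inner train/validation
split, trains the final CNN, extracts per-residue features, trains the
BiLSTM, and scores both the CNN alone and the full CNN+BiLSTM model on the
held-out fold.  Test-fold proteins are never visible to optimization or
training (enforced by protein-id bookkeeping and asserted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import bayes_opt, cnn as cnn_mod, bilstm as bilstm_mod
from .io_encoding import (
    ChannelStandardizer, ProfileMatrix, ProteinRecord, SS3_INDEX,
    encode_windows, read_fasta, read_labels, read_pssm_dir,
)
from .metrics import ConfusionTable, q3, score_report
from .synthetic import SyntheticConfig, cv_folds, generate_proteins, majority_class_rate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


@dataclass
class SearchSettings:
    n_init: int = 6
    n_iter: int = 6
    depth_range: tuple[int, int] = (1, 3)
    epochs_per_trial: int = 2
    n_candidates: int = 1024


@dataclass
class CNNSettings:
    filter_base: int = 32
    epochs: int = 4
    batch_size: int = 128
    fc_width: int = 50
    pooling: str = "max"
    kernel_sizes: tuple[int, int, int, int] | None = None
    class_weighting: bool = False
    # fallback training hyperparameters, used when the search budget is zero
    lr: float = 3e-3
    momentum: float = 0.9
    l2: float = 1e-6


@dataclass
class BiLSTMSettings:
    layer1_hidden: int = 32
    layer2_hidden: int = 32
    epochs: int = 8
    lr: float = 0.01
    clip_norm: float = 5.0
    batch_size: int = 32
    merge: str = "concat"


@dataclass
class RunConfig:
    """All settings for one end-to-end run; defaults are the desk-scale study."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    data_dir: str | None = None      # if set, read fasta/labels/pssm instead of synth
    window_len: int = 13
    standardize: bool = False
    valid_fraction: float = 0.2      # inner split of the training fold
    search: SearchSettings = field(default_factory=SearchSettings)
    cnn: CNNSettings = field(default_factory=CNNSettings)
    bilstm: BiLSTMSettings = field(default_factory=BiLSTMSettings)
    n_folds: int = 3
    n_repeats: int = 1
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTION_TYPES = {
    "synth": SyntheticConfig,
    "search": SearchSettings,
    "cnn": CNNSettings,
    "bilstm": BiLSTMSettings,
}

_TUPLE_FIELDS = {"length_range", "state_prior", "depth_range", "kernel_sizes"}


def validate_config(source: str | Path | dict) -> RunConfig:
    """Build a :class:`RunConfig` from YAML (path) or a dict, with all
    defaults materialized; unknown keys and out-of-range values are
    aggregated into one :class:`ConfigError`."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    cfg = RunConfig()
    top_fields = {f for f in RunConfig.__dataclass_fields__}
    for key, value in raw.items():
        if key not in top_fields:
            errors.append(f"unknown key {key!r}")
            continue
        if key in _SECTION_TYPES:
            section_cls = _SECTION_TYPES[key]
            section = getattr(cfg, key)
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            known = set(section_cls.__dataclass_fields__)
            for k2, v2 in value.items():
                if k2 not in known:
                    errors.append(f"{key}.{k2}: unknown key")
                else:
                    if k2 in _TUPLE_FIELDS and isinstance(v2, (list, tuple)):
                        v2 = tuple(v2)
                    setattr(section, k2, v2)
        else:
            setattr(cfg, key, value)
    errors.extend(_range_errors(cfg))
    if errors:
        raise ConfigError(errors)
    log.info("validated config (hash %s): %s", cfg.config_hash(), asdict(cfg))
    return cfg


def _range_errors(cfg: RunConfig) -> list[str]:
    errors: list[str] = []
    if cfg.window_len < 1 or cfg.window_len % 2 == 0:
        errors.append(f"window_len: must be odd and >= 1, got {cfg.window_len}")
    if not (0.0 < cfg.valid_fraction < 1.0):
        errors.append(f"valid_fraction: must be in (0, 1), got {cfg.valid_fraction}")
    if cfg.n_folds < 2:
        errors.append(f"n_folds: must be >= 2, got {cfg.n_folds}")
    if cfg.n_repeats < 1:
        errors.append(f"n_repeats: must be >= 1, got {cfg.n_repeats}")
    lo, hi = cfg.search.depth_range
    if not (1 <= lo <= hi <= 7):
        errors.append(f"search.depth_range: must satisfy 1 <= lo <= hi <= 7, got {cfg.search.depth_range}")
    if cfg.cnn.pooling not in ("max", "average"):
        errors.append(f"cnn.pooling: must be 'max' or 'average', got {cfg.cnn.pooling!r}")
    if not (0.0 < cfg.cnn.momentum < 1.0):
        errors.append(f"cnn.momentum: must be in (0, 1), got {cfg.cnn.momentum}")
    if cfg.cnn.lr <= 0:
        errors.append(f"cnn.lr: must be positive, got {cfg.cnn.lr}")
    if cfg.cnn.l2 < 0:
        errors.append(f"cnn.l2: must be nonnegative, got {cfg.cnn.l2}")
    if cfg.bilstm.merge not in ("concat", "sum"):
        errors.append(f"bilstm.merge: must be 'concat' or 'sum', got {cfg.bilstm.merge!r}")
    try:
        cfg.synth.validate()
    except ValueError as exc:
        errors.append(f"synth: {exc}")
    return errors


def load_corpus(cfg: RunConfig) -> tuple[list[ProteinRecord], list[ProfileMatrix]]:
    if cfg.data_dir is not None:
        d = Path(cfg.data_dir)
        records = read_labels(d / "labels.fasta", read_fasta(d / "proteins.fasta"))
        profiles = read_pssm_dir(d / "pssm", records)
        return records, profiles
    return generate_proteins(cfg.synth)


@dataclass
class FoldResult:
    fold: int
    repeat: int
    best_hp: dict
    cnn_report: dict
    oclstm_report: dict
    n_trials: int


def _protein_split(ids: Sequence[int], frac_valid: float, seed: int):
    order = np.random.default_rng(seed).permutation(len(ids))
    n_valid = max(1, int(round(frac_valid * len(ids))))
    valid = [ids[i] for i in order[:n_valid]]
    train = [ids[i] for i in order[n_valid:]]
    if not train:
        raise ValueError("training split is empty")
    return train, valid


def run_fold(cfg: RunConfig, records, profiles, train_idx, test_idx,
             fold: int = 0, repeat: int = 0, out_dir: Path | None = None) -> FoldResult:
    """Optimize, train and score one cross-validation fold."""
    train_ids = {records[i].id for i in train_idx}
    test_ids = {records[i].id for i in test_idx}
    assert not (train_ids & test_ids), "train and test folds overlap"

    inner_train, inner_valid = _protein_split(list(train_idx), cfg.valid_fraction,
                                              cfg.seed + 101 * fold + repeat)

    def encode(idx):
        recs = [records[i] for i in idx]
        profs = [profiles[i] for i in idx]
        return encode_windows(profs, recs, cfg.window_len), recs

    ds_train, recs_train = encode(inner_train)
    ds_valid, recs_valid = encode(inner_valid)
    ds_test, recs_test = encode(list(test_idx))
    if cfg.standardize:
        scaler = ChannelStandardizer.fit(ds_train)
        ds_train, ds_valid, ds_test = (scaler.transform(d)
                                       for d in (ds_train, ds_valid, ds_test))

    class_weights = None
    if cfg.cnn.class_weighting:
        counts = np.bincount(ds_train.labels, minlength=3).astype(float)
        class_weights = counts.sum() / (3.0 * np.maximum(counts, 1.0))

    space = bayes_opt.default_space(cfg.search.depth_range)
    trial_counter = {"k": 0}

    if cfg.search.n_init + cfg.search.n_iter == 0:
        best_hp = bayes_opt.HyperparamPoint(cfg.cnn.lr, cfg.cnn.momentum,
                                            cfg.cnn.l2, cfg.search.depth_range[0])
        ledger = bayes_opt.TrialLedger()
        return _finish_fold(cfg, best_hp, ledger, ds_train, ds_valid, ds_test,
                            recs_train, recs_valid, recs_test, class_weights,
                            fold, repeat, out_dir)

    def objective(hp: bayes_opt.HyperparamPoint) -> float:
        trial_counter["k"] += 1
        spec = cnn_mod.build_architecture(
            hp.part_depth, cfg.window_len, pooling=cfg.cnn.pooling,
            kernel_sizes=cfg.cnn.kernel_sizes, fc_width=cfg.cnn.fc_width,
            filter_base=cfg.cnn.filter_base)
        try:
            model = cnn_mod.train_cnn(
                spec, ds_train, ds_valid, hp,
                epochs=cfg.search.epochs_per_trial,
                batch_size=cfg.cnn.batch_size,
                seed=cfg.seed + trial_counter["k"],
                class_weights=class_weights)
        except cnn_mod.TrainingDivergedError:
            return float("nan")
        return model.final_valid_loss

    best_hp, ledger = bayes_opt.optimize(
        objective, space, n_init=cfg.search.n_init, n_iter=cfg.search.n_iter,
        seed=cfg.seed + 977 * fold + repeat, n_candidates=cfg.search.n_candidates)
    return _finish_fold(cfg, best_hp, ledger, ds_train, ds_valid, ds_test,
                        recs_train, recs_valid, recs_test, class_weights,
                        fold, repeat, out_dir)


def _finish_fold(cfg, best_hp, ledger, ds_train, ds_valid, ds_test,
                 recs_train, recs_valid, recs_test, class_weights,
                 fold, repeat, out_dir) -> FoldResult:
    spec = cnn_mod.build_architecture(
        best_hp.part_depth, cfg.window_len, pooling=cfg.cnn.pooling,
        kernel_sizes=cfg.cnn.kernel_sizes, fc_width=cfg.cnn.fc_width,
        filter_base=cfg.cnn.filter_base)
    model = cnn_mod.train_cnn(spec, ds_train, ds_valid, best_hp,
                              epochs=cfg.cnn.epochs, batch_size=cfg.cnn.batch_size,
                              seed=cfg.seed, class_weights=class_weights)

    # BiLSTM consumes whole-protein sequences of FC features from the CNN
    feats_train = model.extract_features(ds_train)
    feats_valid = model.extract_features(ds_valid)
    seqs, labs = [], []
    for rec in recs_train + recs_valid:
        feats = feats_train.get(rec.id)
        if feats is None:
            feats = feats_valid[rec.id]
        seqs.append(feats)
        labs.append(np.array([SS3_INDEX[s] for s in rec.with_ss3().ss3]))
    bspec = bilstm_mod.BiLSTMSpec(input_dim=cfg.cnn.fc_width,
                                  layer1_hidden=cfg.bilstm.layer1_hidden,
                                  layer2_hidden=cfg.bilstm.layer2_hidden,
                                  merge=cfg.bilstm.merge)
    bmodel = bilstm_mod.train_bilstm(
        bspec, seqs, labs, seed=cfg.seed,
        epochs=cfg.bilstm.epochs, lr=cfg.bilstm.lr,
        clip_norm=cfg.bilstm.clip_norm, batch_size=cfg.bilstm.batch_size)

    # score the held-out fold, never touched above
    cnn_conf, oclstm_conf = score_models(model, bmodel, ds_test, recs_test)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        tag = f"r{repeat}f{fold}"
        model.save(out_dir / f"cnn_{tag}.ckpt")
        bmodel.save(out_dir / f"bilstm_{tag}.ckpt")
        ledger.save(out_dir / f"ledger_{tag}.json")

    return FoldResult(
        fold=fold, repeat=repeat, best_hp=best_hp.as_dict(),
        cnn_report=score_report(cnn_conf),
        oclstm_report=score_report(oclstm_conf),
        n_trials=len(ledger.trials),
    )


def score_models(model, bmodel, ds_test, recs_test):
    """Confusion tables for the CNN alone and the CNN+BiLSTM on a test set."""
    cnn_probs = model.predict_proba(ds_test)
    cnn_conf = ConfusionTable.from_labels(ds_test.labels, cnn_probs.argmax(axis=1))
    feats_test = model.extract_features(ds_test)
    true_all, pred_all = [], []
    for rec in recs_test:
        probs = bmodel.forward(feats_test[rec.id])
        pred_all.extend(probs.argmax(axis=1).tolist())
        true_all.extend(SS3_INDEX[s] for s in rec.with_ss3().ss3)
    return cnn_conf, ConfusionTable.from_labels(true_all, pred_all)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Repeated protein-level cross-validation; returns and writes the summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    results: list[FoldResult] = []
    records = []
    stage = "load-corpus"
    try:
        records, profiles = load_corpus(cfg)
        for repeat in range(cfg.n_repeats):
            stage = f"cv-repeat-{repeat}"
            folds = cv_folds(len(records), cfg.n_folds, cfg.seed + repeat)
            for f, test_idx in enumerate(folds):
                stage = f"repeat {repeat} fold {f}"
                train_idx = np.concatenate([folds[g] for g in range(cfg.n_folds) if g != f])
                results.append(run_fold(cfg, records, profiles, train_idx, test_idx,
                                        fold=f, repeat=repeat, out_dir=out_dir))
    except Exception:
        (out_dir / "FAILED").write_text(f"failed during stage: {stage}\n")
        _write_summary(cfg, records, results, out_dir, t0, failed_stage=stage)
        log.exception("pipeline failed during %s", stage)
        raise
    return _write_summary(cfg, records, results, out_dir, t0)


def _write_summary(cfg, records, results, out_dir, t0, failed_stage=None):
    pooled_cnn = ConfusionTable(np.zeros((3, 3), dtype=int))
    pooled_oclstm = ConfusionTable(np.zeros((3, 3), dtype=int))
    for r in results:
        pooled_cnn = pooled_cnn + ConfusionTable(np.array(r.cnn_report["confusion"]))
        pooled_oclstm = pooled_oclstm + ConfusionTable(np.array(r.oclstm_report["confusion"]))
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "majority_class_rate": 100.0 * majority_class_rate(records) if records else None,
        "folds": [asdict(r) for r in results],
        "pooled": {
            "cnn": score_report(pooled_cnn) if results else None,
            "oclstm": score_report(pooled_oclstm) if results else None,
        },
        "wall_time_s": time.perf_counter() - t0,
    }
    if failed_stage is not None:
        summary["failed_stage"] = failed_stage
    (Path(out_dir) / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
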