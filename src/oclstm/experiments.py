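"""Reduced-scale experiments: CNN-alone vs CNN+BiLSTM, depth/pooling sweeps.

These mirror the published trial tables in spirit -- same axes (network
depth, pooling variant, feature dimension, LSTM widths), run on the
synthetic corpus at sizes a single CPU handles -- and back both the
acceptance checks and exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bilstm as bilstm_mod, cnn as cnn_mod
from .bayes_opt import HyperparamPoint
from .io_encoding import SS3_INDEX, encode_windows
from .metrics import ConfusionTable, q3
from .synthetic import (
    SyntheticConfig, generate_proteins, majority_class_rate, train_valid_test_split,
)

DEFAULT_HP = HyperparamPoint(lr=3e-3, momentum=0.9, l2=1e-6, part_depth=1)


@dataclass
class SingleSplitResult:
    majority_q3: float
    cnn_q3: float
    oclstm_q3: float
    n_residues_test: int


def run_single_split(synth: SyntheticConfig | None = None,
                     window_len: int = 13,
                     hp: HyperparamPoint = DEFAULT_HP,
                     filter_base: int = 32,
                     cnn_epochs: int = 4,
                     bilstm_hidden: int = 32,
                     bilstm_epochs: int = 8,
                     seed: int = 0,
                     split_seed: int = 11) -> SingleSplitResult:
    """Train CNN then CNN+BiLSTM on one train/valid/test split; score the test set."""
    synth = synth or SyntheticConfig()
    recs, profs = generate_proteins(synth)
    (tr_r, tr_p), (va_r, va_p), (te_r, te_p) = train_valid_test_split(
        recs, profs, (0.6, 0.2, 0.2), seed=split_seed)
    ds_tr = encode_windows(tr_p, tr_r, window_len)
    ds_va = encode_windows(va_p, va_r, window_len)
    ds_te = encode_windows(te_p, te_r, window_len)

    spec = cnn_mod.build_architecture(hp.part_depth, window_len, filter_base=filter_base)
    model = cnn_mod.train_cnn(spec, ds_tr, ds_va, hp, epochs=cnn_epochs, seed=seed)
    cnn_probs = model.predict_proba(ds_te)
    cnn_conf = ConfusionTable.from_labels(ds_te.labels, cnn_probs.argmax(axis=1))

    feats = {**model.extract_features(ds_tr), **model.extract_features(ds_va)}
    seqs = [feats[r.id] for r in tr_r + va_r]
    labs = [np.array([SS3_INDEX[s] for s in r.ss3]) for r in tr_r + va_r]
    bspec = bilstm_mod.BiLSTMSpec(input_dim=spec.fc_width,
                                  layer1_hidden=bilstm_hidden,
                                  layer2_hidden=bilstm_hidden)
    bmodel = bilstm_mod.train_bilstm(bspec, seqs, labs, seed=seed, epochs=bilstm_epochs)
    feats_te = model.extract_features(ds_te)
    true_all, pred_all = [], []
    for r in te_r:
        probs = bmodel.forward(feats_te[r.id])
        pred_all.extend(probs.argmax(axis=1).tolist())
        true_all.extend(SS3_INDEX[s] for s in r.ss3)
    oclstm_conf = ConfusionTable.from_labels(true_all, pred_all)

    return SingleSplitResult(
        majority_q3=100.0 * majority_class_rate(te_r),
        cnn_q3=q3(cnn_conf),
        oclstm_q3=q3(oclstm_conf),
        n_residues_test=cnn_conf.total,
    )


def cnn_vs_bilstm(seeds=(0, 1, 2), synth: SyntheticConfig | None = None,
                  **kwargs) -> dict:
    """Paired CNN vs CNN+BiLSTM comparison over seeds; reports the means."""
    results = [run_single_split(synth=synth, seed=s, **kwargs) for s in seeds]
    return {
        "seeds": list(seeds),
        "majority_q3": float(np.mean([r.majority_q3 for r in results])),
        "cnn_q3": [r.cnn_q3 for r in results],
        "oclstm_q3": [r.oclstm_q3 for r in results],
        "cnn_q3_mean": float(np.mean([r.cnn_q3 for r in results])),
        "oclstm_q3_mean": float(np.mean([r.oclstm_q3 for r in results])),
        "n_residues_test": results[0].n_residues_test,
    }


def depth_sweep(depths=(1, 2, 3), pooling: str = "max",
                synth: SyntheticConfig | None = None,
                window_len: int = 13, filter_base: int = 32,
                epochs: int = 3, seed: int = 0) -> dict[int, float]:
    """Test-set Q3 of the CNN at several part depths (trial-table analogue)."""
    synth = synth or SyntheticConfig()
    recs, profs = generate_proteins(synth)
    (tr_r, tr_p), (va_r, va_p), (te_r, te_p) = train_valid_test_split(
        recs, profs, (0.6, 0.2, 0.2), seed=11)
    ds_tr = encode_windows(tr_p, tr_r, window_len)
    ds_va = encode_windows(va_p, va_r, window_len)
    ds_te = encode_windows(te_p, te_r, window_len)
    out = {}
    for depth in depths:
        hp = HyperparamPoint(DEFAULT_HP.lr, DEFAULT_HP.momentum, DEFAULT_HP.l2, depth)
        spec = cnn_mod.build_architecture(depth, window_len, pooling=pooling,
                                          filter_base=filter_base)
        model = cnn_mod.train_cnn(spec, ds_tr, ds_va, hp, epochs=epochs, seed=seed)
        _, q3_test = model.evaluate(ds_te)
        out[depth] = q3_test
    return out
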