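"""Tensor assembly for trajectory classification.

Turns variable-length 6-column trajectory sequences into fixed-length
(N, 6, T) tensors by linear-time resampling, splits them into stratified
train/validation/test subsets, and standardizes channels with statistics
fitted on the training set only (stored for exact reuse at test time).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


def resample_sequence(seq: np.ndarray, T: int) -> np.ndarray:
    """Linear-time resampling of a (Ti, C) sequence to (T, C)."""
    seq = np.asarray(seq, dtype=float)
    Ti = len(seq)
    if Ti < 2:
        raise ValueError("sequence too short to resample")
    s_old = np.linspace(0.0, 1.0, Ti)
    s_new = np.linspace(0.0, 1.0, T)
    return np.column_stack([np.interp(s_new, s_old, seq[:, c])
                            for c in range(seq.shape[1])])


@dataclass
class SplitArrays:
    X: np.ndarray        # (N, C, T), standardized
    y: np.ndarray        # (N,) int class index
    indices: np.ndarray  # positions in the source dataset


@dataclass
class AssembledData:
    train: SplitArrays
    val: SplitArrays
    test: SplitArrays
    classes: list
    channel_mean: np.ndarray
    channel_std: np.ndarray
    T: int
    meta: dict = dc_field(default_factory=dict)


def assemble_training_arrays(dataset, split=(0.7, 0.15, 0.15), seed: int = 0,
                             T: int = 128) -> AssembledData:
    """Stratified split + resampling + train-fitted standardization.

    ``dataset`` is a :class:`ctcflow.dataset.TrajectoryDataset` (or any
    object with ``sequences`` and ``labels``). Every class must appear in
    every split.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    classes = sorted(set(dataset.labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    y_all = np.array([classes.index(l) for l in dataset.labels])
    X_all = np.stack([resample_sequence(s, T).T for s in dataset.sequences])

    rng = np.random.default_rng(seed)
    idx_tr, idx_va, idx_te = [], [], []
    for k in range(len(classes)):
        idx = np.where(y_all == k)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(split[0] * n))
        n_va = int(round(split[1] * n))
        idx_tr.append(idx[:n_tr])
        idx_va.append(idx[n_tr:n_tr + n_va])
        idx_te.append(idx[n_tr + n_va:])
    idx_tr = np.concatenate(idx_tr)
    idx_va = np.concatenate(idx_va)
    idx_te = np.concatenate(idx_te)
    for name, idx in (("train", idx_tr), ("val", idx_va), ("test", idx_te)):
        if len(set(y_all[idx])) < len(classes):
            raise ValueError(f"class missing from the {name} split")

    mean = X_all[idx_tr].mean(axis=(0, 2))
    std = X_all[idx_tr].std(axis=(0, 2))
    std = np.where(std > 0, std, 1.0)

    def standardize(idx):
        X = (X_all[idx] - mean[None, :, None]) / std[None, :, None]
        return SplitArrays(X=X, y=y_all[idx], indices=idx)

    return AssembledData(
        train=standardize(idx_tr), val=standardize(idx_va),
        test=standardize(idx_te), classes=classes,
        channel_mean=mean, channel_std=std, T=T,
        meta={"split": tuple(split), "seed": seed})
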