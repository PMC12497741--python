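"""Time-resolved two-class decoding of trial labels.

Per subject and timepoint, a linear support vector machine is trained on the
pattern across all electrodes. To raise the signal-to-noise ratio, trials of
each class are first randomly partitioned into ``n_bins`` near-equal groups
and averaged into pseudo-trials. Cross-validation leaves one bin of *each*
class out per fold (fold k tests on bin k of both classes, trains on the
rest), and the whole binning + CV procedure is repeated ``n_iterations``
times with fresh random partitions; reported accuracy is the mean over folds
and iterations. Epochs are first downsampled by adjacent averaging to
``target_rate`` (default 100 Hz).

Binned partitions are redrawn per iteration and shared across timepoints
(the classifier itself sees one timepoint at a time). Everything is
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .design import ConfigurationError, EmptyResultError, match_cells
from .epochs_core import EpochSet, downsample_by_averaging

_LABEL_COLUMNS = {"validity": ("validity", ("valid", "invalid")),
                  "orientation": ("target_orientation", ("left", "right"))}


@dataclass(frozen=True)
class DecodingConfig:
    label_name: str = "validity"
    cells: Tuple[Mapping[str, str], ...] = ()   # partial cell filters; () = all trials
    n_bins: int = 8
    n_iterations: int = 100
    n_folds: int = 8
    svm_c: float = 1.0
    target_rate: float = 100.0
    zscore: bool = False          # per-fold feature standardisation (off by default)
    correct_only: bool = False    # decoding uses all kept trials by default
    seed: int = 0

    def __post_init__(self):
        if self.label_name not in _LABEL_COLUMNS:
            raise ConfigurationError(
                f"label_name must be one of {tuple(_LABEL_COLUMNS)}")
        if self.n_folds != self.n_bins:
            raise ConfigurationError(
                "n_folds must equal n_bins (leave-one-bin-per-class-out)")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


@dataclass
class DecodingResult:
    subject: str
    label_name: str
    cells: Tuple[Mapping[str, str], ...]
    times: np.ndarray             # ms at target_rate
    accuracy: np.ndarray          # (n_times,), in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject": self.subject, "time_ms": self.times,
                             "accuracy": self.accuracy,
                             "label": self.label_name})


def bin_average(trials: np.ndarray, n_bins: int,
                rng: np.random.Generator) -> np.ndarray:
    """Randomly partition same-class trials into ``n_bins`` near-equal groups
    and average within each: returns (n_bins, ...) pseudo-trials.

    Group sizes differ by at most one and every trial is used exactly once,
    so the mean of the pseudo-trials equals the grand mean exactly when the
    trial count divides evenly.
    """
    n = trials.shape[0]
    if n < n_bins:
        raise EmptyResultError(f"cannot form {n_bins} bins from {n} trials")
    perm = rng.permutation(n)
    groups = np.array_split(perm, n_bins)
    return np.stack([trials[g].mean(axis=0) for g in groups])


def _fit_predict(train_x, train_y, test_x, svm_c):
    # degenerate features: identical training vectors -> fixed fallback class
    if np.allclose(train_x, train_x[0]):
        return np.full(test_x.shape[0], train_y[0])
    clf = SVC(kernel="linear", C=svm_c, shrinking=False)
    clf.fit(train_x, train_y)
    return clf.predict(test_x)


def decode_timepoint(pseudo_a: np.ndarray, pseudo_b: np.ndarray,
                     svm_c: float = 1.0, zscore: bool = False) -> float:
    """Leave-one-bin-per-class-out accuracy at one timepoint.

    ``pseudo_a``/``pseudo_b``: (n_bins, n_channels) pseudo-trials of the two
    classes. Fold k trains on all bins but k of each class and tests on bin
    k of each, so every fold's test set is balanced.
    """
    if pseudo_a.shape != pseudo_b.shape:
        raise ConfigurationError("both classes need the same number of bins")
    n_bins = pseudo_a.shape[0]
    correct = 0
    for k in range(n_bins):
        tr = np.ones(n_bins, dtype=bool)
        tr[k] = False
        train_x = np.vstack([pseudo_a[tr], pseudo_b[tr]])
        train_y = np.array([0] * (n_bins - 1) + [1] * (n_bins - 1))
        test_x = np.vstack([pseudo_a[k], pseudo_b[k]])
        if zscore:
            mu = train_x.mean(axis=0)
            sd = train_x.std(axis=0)
            sd[sd == 0] = 1.0
            train_x = (train_x - mu) / sd
            test_x = (test_x - mu) / sd
        pred = _fit_predict(train_x, train_y, test_x, svm_c)
        correct += int(pred[0] == 0) + int(pred[1] == 1)
    return correct / (2 * n_bins)


def _select_classes(epochs: EpochSet, table: pd.DataFrame,
                    config: DecodingConfig) -> Tuple[np.ndarray, np.ndarray]:
    table = table.reset_index(drop=True)
    mask = match_cells(table, config.cells) if config.cells \
        else np.ones(len(table), dtype=bool)
    if "kept" in table.columns:
        mask &= table["kept"].to_numpy(dtype=bool)
    if config.correct_only and "correct" in table.columns:
        mask &= table["correct"].to_numpy(dtype=bool)
    col, (lvl_a, lvl_b) = _LABEL_COLUMNS[config.label_name]
    a_idx = np.flatnonzero(mask & (table[col] == lvl_a).to_numpy())
    b_idx = np.flatnonzero(mask & (table[col] == lvl_b).to_numpy())
    if a_idx.size < config.n_bins or b_idx.size < config.n_bins:
        raise EmptyResultError(
            f"decoding {config.label_name!r} in cells {config.cells}: "
            f"class counts {lvl_a}={a_idx.size}, {lvl_b}={b_idx.size} "
            f"< n_bins={config.n_bins}")
    return a_idx, b_idx


def decode_timecourse(epochs: EpochSet, table: pd.DataFrame,
                      config: DecodingConfig,
                      rng: Optional[np.random.Generator] = None,
                      ) -> DecodingResult:
    """Per-timepoint decoding accuracy for one subject.

    Downsamples to ``config.target_rate`` if needed, selects trials by the
    cell filters, then averages accuracy over ``n_iterations`` random
    binnings. Deterministic for a given config seed (or supplied ``rng``).
    """
    if abs(epochs.sampling_rate - config.target_rate) > 1e-9:
        epochs = downsample_by_averaging(epochs, config.target_rate)
    a_idx, b_idx = _select_classes(epochs, table, config)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0xDEC0,)))
    n_times = epochs.times.size
    acc = np.zeros(n_times)
    xa = epochs.data[a_idx]     # (na, C, T)
    xb = epochs.data[b_idx]
    for _ in range(config.n_iterations):
        pa = bin_average(xa, config.n_bins, rng)   # (bins, C, T)
        pb = bin_average(xb, config.n_bins, rng)
        for t in range(n_times):
            acc[t] += decode_timepoint(pa[:, :, t], pb[:, :, t],
                                       svm_c=config.svm_c, zscore=config.zscore)
    acc /= config.n_iterations
    return DecodingResult(subject=epochs.subject_id, label_name=config.label_name,
                          cells=config.cells, times=epochs.times.copy(),
                          accuracy=acc)


def decode_group(epochs_list: Sequence[EpochSet],
                 tables: Sequence[pd.DataFrame],
                 config: DecodingConfig) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Decode every subject; returns (subjects x times accuracy matrix,
    times, subject ids). Each subject gets an independent stream spawned
    from the config seed."""
    if len(epochs_list) != len(tables):
        raise ConfigurationError("epochs and tables lists differ in length")
    curves, subjects = [], []
    times = None
    for i, (ep, tab) in enumerate(zip(epochs_list, tables)):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0xDEC0, i)))
        res = decode_timecourse(ep, tab, config, rng=rng)
        curves.append(res.accuracy)
        subjects.append(res.subject or f"S{i:02d}")
        times = res.times
    return np.vstack(curves), times, subjects
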