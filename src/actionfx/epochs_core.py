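"""Epoch container, channel layout, cleaning and I/O.

An :class:`EpochSet` holds trials x channels x timepoints data in microvolts
with a millisecond time axis (0 ms = search-array onset) and a channel layout
that knows which electrodes form left/right homolog pairs — the substrate for
lateralized (contralateral/ipsilateral) analyses.

Conventions fixed here and used throughout the package:

* window selections are inclusive of both endpoints, ``start <= t <= end``;
* threshold rejection drops a trial iff any sample on any channel has
  ``|v| > threshold`` (strict: a sample at exactly the threshold survives);
* downsampling averages consecutive non-overlapping blocks of samples and
  drops a trailing remainder; the new time stamp is the mean of the block's
  time stamps, so block-aligned interval means are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .design import (
    EmptyResultError,
    ConfigurationError,
    FormatError,
    LabelingError,
    UnsupportedVersionError,
    validate_trial_table,
)

FILE_FORMAT_VERSION = 1

# 26 left/right homolog pairs + 8 midline electrodes = 60 channels,
# 10-10 system names; includes the parieto-occipital montage used for the
# ERP components (P3/4, P7/8, PO3/4, PO5/6, PO7/8). Posterior pairs come
# first so reduced layouts (truncated from the end) keep the ERP montage.
_STANDARD_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("PO7", "PO8"), ("PO5", "PO6"), ("PO3", "PO4"), ("P3", "P4"),
    ("P7", "P8"), ("P5", "P6"), ("P1", "P2"), ("O1", "O2"),
    ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"), ("TP7", "TP8"),
    ("C5", "C6"), ("C3", "C4"), ("C1", "C2"), ("T7", "T8"),
    ("FC5", "FC6"), ("FC3", "FC4"), ("FC1", "FC2"), ("FT7", "FT8"),
    ("F7", "F8"), ("F5", "F6"), ("F3", "F4"), ("F1", "F2"),
    ("AF7", "AF8"), ("AF3", "AF4"),
)
_STANDARD_MIDLINE: Tuple[str, ...] = ("Fpz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz")


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names plus homolog-pair / hemisphere semantics."""

    names: Tuple[str, ...]
    homolog_pairs: Tuple[Tuple[str, str], ...]
    hemisphere: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("channel names must be unique")
        hemi = dict(self.hemisphere)
        for left, right in self.homolog_pairs:
            if left not in self.names or right not in self.names:
                raise ConfigurationError(
                    f"homolog pair ({left}, {right}) references unknown channels")
            hemi.setdefault(left, "left")
            hemi.setdefault(right, "right")
        for name in self.names:
            hemi.setdefault(name, "midline")
        object.__setattr__(self, "hemisphere", hemi)

    @classmethod
    def standard_60(cls) -> "ChannelLayout":
        """The default 60-channel layout (26 homolog pairs + 8 midline)."""
        names = tuple(n for pair in _STANDARD_PAIRS for n in pair) + _STANDARD_MIDLINE
        return cls(names=names, homolog_pairs=_STANDARD_PAIRS)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise LabelingError(f"unknown electrode {name!r}") from None

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def pair(self, left: str, right: str) -> Tuple[str, str]:
        """Return the (left, right) homolog pair, validating membership."""
        if (left, right) in self.homolog_pairs:
            return (left, right)
        if (right, left) in self.homolog_pairs:
            return (right, left)
        raise LabelingError(
            f"({left}, {right}) is not a homolog pair of this layout; "
            "lateralized analysis requires a left/right electrode pair")

    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class EpochSet:
    """Trials x channels x timepoints epoched EEG in microvolts."""

    data: np.ndarray          # (n_trials, n_channels, n_times), μV
    times: np.ndarray         # ms, uniform step, contains 0
    layout: ChannelLayout
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConfigurationError("epoch data must be trials x channels x timepoints")
        if self.data.shape[1] != self.layout.n_channels():
            raise ConfigurationError(
                f"data has {self.data.shape[1]} channels but layout has "
                f"{self.layout.n_channels()}")
        if self.data.shape[2] != self.times.size:
            raise ConfigurationError("time axis length does not match data")
        steps = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(steps, steps[0]):
            raise ConfigurationError("time axis must have a uniform step")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sampling_rate(self) -> float:
        """Hz, from the uniform time step in ms."""
        return 1000.0 / float(self.times[1] - self.times[0])

    def time_mask(self, window: Tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples with ``start <= t <= end`` (inclusive)."""
        start, end = window
        if end < start:
            raise ConfigurationError(f"window {window} has end before start")
        mask = (self.times >= start) & (self.times <= end)
        if not mask.any():
            raise ConfigurationError(
                f"window {window} ms contains no samples of the epoch "
                f"({self.times[0]:g}..{self.times[-1]:g} ms)")
        return mask

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[index], self.times.copy(), self.layout,
                        self.subject_id)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.times.copy(), self.layout,
                        self.subject_id)


def reject_by_threshold(
    epochs: EpochSet, table: pd.DataFrame, threshold: float = 80.0,
) -> Tuple[EpochSet, pd.DataFrame, int]:
    """Drop trials whose amplitude exceeds ``±threshold`` μV on any electrode.

    A trial is dropped iff any sample at any channel satisfies
    ``|v| > threshold``. Surviving trials keep their order. Returns the
    filtered epochs, the filtered table (with ``kept`` set) and the number of
    rejected trials.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0 μV")
    if len(table) != epochs.n_trials:
        raise ConfigurationError("trial table length does not match epochs")
    keep = ~(np.abs(epochs.data) > threshold).any(axis=(1, 2))
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError(
            f"all {epochs.n_trials} trials exceeded ±{threshold:g} μV")
    out_table = table.loc[keep].copy().reset_index(drop=True)
    out_table["kept"] = True
    return epochs.select_trials(keep), out_table, n_rejected


def baseline_correct(
    epochs: EpochSet, window: Tuple[float, float] = (-200.0, 0.0),
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (inclusive)."""
    mask = epochs.time_mask(window)
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def downsample_by_averaging(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Downsample by averaging adjacent samples in non-overlapping blocks.

    The source rate must be an integer multiple of ``target_rate``; trailing
    samples that do not fill a block are dropped.
    """
    src = epochs.sampling_rate
    factor = src / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ConfigurationError(
            f"source rate {src:g} Hz is not an integer multiple of "
            f"target rate {target_rate:g} Hz")
    factor = int(round(factor))
    if factor == 1:
        return epochs.copy()
    n_blocks = epochs.times.size // factor
    n_keep = n_blocks * factor
    data = epochs.data[:, :, :n_keep]
    data = data.reshape(data.shape[0], data.shape[1], n_blocks, factor).mean(axis=3)
    times = epochs.times[:n_keep].reshape(n_blocks, factor).mean(axis=1)
    return EpochSet(data, times, epochs.layout, epochs.subject_id)


# ---------------------------------------------------------------------------
# HDF5 container: /data (float32), /times, /channels, /homolog_pairs,
# /subject_id, /version, /table/<column>
# ---------------------------------------------------------------------------

_TABLE_STRING_COLUMNS = ("subject", "congruency", "action", "validity",
                         "target_hemifield", "target_orientation")


def save_epochs(path, epochs: EpochSet, table: pd.DataFrame) -> None:
    """Write one subject's epochs + trial table to an HDF5 container."""
    if len(table) != epochs.n_trials:
        raise ConfigurationError("trial table length does not match epochs")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array(epochs.layout.names, dtype="S16"))
        f.create_dataset("homolog_pairs",
                         data=np.array(epochs.layout.homolog_pairs, dtype="S16"))
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["version"] = FILE_FORMAT_VERSION
        g = f.create_group("table")
        for col in table.columns:
            vals = table[col]
            if col in _TABLE_STRING_COLUMNS:
                g.create_dataset(col,
                                 data=np.array(vals.astype(str).tolist(), dtype="S32"))
            elif vals.dtype == bool:
                g.create_dataset(col, data=vals.to_numpy(dtype=np.uint8))
                g[col].attrs["bool"] = 1
            else:
                g.create_dataset(col, data=vals.to_numpy(dtype=np.float64))


def load_epochs(path) -> Tuple[EpochSet, pd.DataFrame]:
    """Read an HDF5 container written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version is None:
            raise FormatError(f"{path}: missing 'version' attribute")
        if int(version) != FILE_FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"{path}: format version {version} unsupported "
                f"(expected {FILE_FORMAT_VERSION})")
        for name in ("data", "times", "channels"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '/{name}'")
        if "table" not in f:
            raise FormatError(f"{path}: missing group '/table' (trial table)")
        names = tuple(n.decode() for n in f["channels"][()])
        pairs = tuple((l.decode(), r.decode()) for l, r in f["homolog_pairs"][()]) \
            if "homolog_pairs" in f else ()
        layout = ChannelLayout(names=names, homolog_pairs=pairs)
        epochs = EpochSet(
            data=f["data"][()].astype(np.float64),
            times=f["times"][()],
            layout=layout,
            subject_id=str(f.attrs.get("subject_id", "")),
        )
        cols = {}
        for col, ds in f["table"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                cols[col] = np.array([v.decode() for v in vals])
            elif ds.attrs.get("bool"):
                cols[col] = vals.astype(bool)
            else:
                cols[col] = vals
        table = pd.DataFrame(cols)
    order = [c for c in ("subject", "congruency", "action", "validity",
                         "target_hemifield", "target_orientation", "rt",
                         "correct", "kept") if c in table.columns]
    table = table[order + [c for c in table.columns if c not in order]]
    validate_trial_table(table)
    if len(table) != epochs.n_trials:
        raise FormatError(f"{path}: trial table length does not match data")
    return epochs, table
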