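"""ERP component amplitudes and validity effects.

Three components are measured over parieto-occipital electrodes:

* **N2pc** — lateralized: the per-trial contralateral-minus-ipsilateral
  difference at the PO7/PO8 pair, averaged over 180-300 ms; validity effect
  = invalid - valid (a more negative contralateral deflection in valid
  trials yields a positive effect).
* **P300b** — mean amplitude over ten parieto-occipital electrodes,
  300-500 ms; validity effect = valid - invalid.
* **late LPC** — same montage, 500-700 ms; validity effect = valid -
  invalid (larger values = greater response-selection facilitation).

"Contralateral" means the hemisphere opposite the target hemifield: a
left-hemifield target is contralateral to the *right* electrode of a pair.
The contra/ipsi assignment is resolved per trial before any averaging.
Window endpoints are inclusive, so a sample at exactly 300 ms contributes to
both the N2pc and the P300b windows. By default only correct-response
trials enter the cell means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import CELLS, EmptyResultError, LabelingError
from .epochs_core import EpochSet
from .synthetic_data import (
    LATE_LPC_WINDOW_MS,
    N2PC_ELECTRODES,
    N2PC_WINDOW_MS,
    P300B_WINDOW_MS,
    PARIETO_OCCIPITAL_10,
)


@dataclass(frozen=True)
class ComponentSpec:
    """Electrode set, window, laterality and validity-effect sign of a component."""

    name: str
    electrodes: Tuple[str, ...]
    window: Tuple[float, float]
    lateralized: bool
    validity_sign: str  # 'invalid_minus_valid' or 'valid_minus_invalid'

    def __post_init__(self):
        if self.validity_sign not in ("invalid_minus_valid", "valid_minus_invalid"):
            raise ValueError(f"unknown validity_sign {self.validity_sign!r}")


N2PC = ComponentSpec("N2pc", N2PC_ELECTRODES, N2PC_WINDOW_MS,
                     lateralized=True, validity_sign="invalid_minus_valid")
P300B = ComponentSpec("P300b", PARIETO_OCCIPITAL_10, P300B_WINDOW_MS,
                      lateralized=False, validity_sign="valid_minus_invalid")
LATE_LPC = ComponentSpec("lateLPC", PARIETO_OCCIPITAL_10, LATE_LPC_WINDOW_MS,
                         lateralized=False, validity_sign="valid_minus_invalid")

COMPONENTS: Dict[str, ComponentSpec] = {c.name.lower(): c
                                        for c in (N2PC, P300B, LATE_LPC)}


def mean_amplitude(epochs: EpochSet, electrodes: Sequence[str],
                   window: Tuple[float, float]) -> np.ndarray:
    """Per-trial mean over the given channels and all samples in ``window``."""
    idx = epochs.layout.indices(electrodes)
    mask = epochs.time_mask(window)
    return epochs.data[:, idx, :][:, :, mask].mean(axis=(1, 2))


def lateralized_difference(epochs: EpochSet, table: pd.DataFrame,
                           pair: Tuple[str, str]) -> np.ndarray:
    """Per-trial contra-minus-ipsi waveform (n_trials, n_times) at a pair."""
    left, right = epochs.layout.pair(*pair)
    hemi = table["target_hemifield"].to_numpy()
    bad = set(hemi) - {"left", "right"}
    if bad:
        raise LabelingError(f"target_hemifield has non-lateral values {sorted(bad)}")
    il, ir = epochs.layout.index(left), epochs.layout.index(right)
    contra_idx = np.where(hemi == "left", ir, il)
    ipsi_idx = np.where(hemi == "left", il, ir)
    rows = np.arange(epochs.n_trials)
    return epochs.data[rows, contra_idx, :] - epochs.data[rows, ipsi_idx, :]


def lateralized_waveform(epochs: EpochSet, table: pd.DataFrame,
                         pair: Tuple[str, str]) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-averaged (contralateral, ipsilateral) waveforms at a homolog pair."""
    left, right = epochs.layout.pair(*pair)
    hemi = table["target_hemifield"].to_numpy()
    bad = set(hemi) - {"left", "right"}
    if bad:
        raise LabelingError(f"target_hemifield has non-lateral values {sorted(bad)}")
    il, ir = epochs.layout.index(left), epochs.layout.index(right)
    contra_idx = np.where(hemi == "left", ir, il)
    ipsi_idx = np.where(hemi == "left", il, ir)
    rows = np.arange(epochs.n_trials)
    contra = epochs.data[rows, contra_idx, :].mean(axis=0)
    ipsi = epochs.data[rows, ipsi_idx, :].mean(axis=0)
    return contra, ipsi


def component_trial_values(epochs: EpochSet, table: pd.DataFrame,
                           spec: ComponentSpec) -> np.ndarray:
    """Per-trial component amplitude (contra-ipsi in-window mean if lateralized)."""
    if spec.lateralized:
        diff = lateralized_difference(epochs, table, spec.electrodes)
        mask = epochs.time_mask(spec.window)
        return diff[:, mask].mean(axis=1)
    return mean_amplitude(epochs, spec.electrodes, spec.window)


def component_cell_means(epochs: EpochSet, table: pd.DataFrame,
                         spec: ComponentSpec,
                         correct_only: bool = True) -> pd.DataFrame:
    """One mean amplitude per subject x congruency x action x validity cell.

    Tidy frame with columns subject, congruency, action, validity,
    component, amplitude (μV). Raises :class:`EmptyResultError` naming the
    first empty cell.
    """
    if len(table) != epochs.n_trials:
        raise ValueError("trial table length does not match epochs")
    table = table.reset_index(drop=True)  # align positionally with epochs
    values = component_trial_values(epochs, table, spec)
    keep = np.ones(len(table), dtype=bool)
    if "kept" in table.columns:
        keep &= table["kept"].to_numpy(dtype=bool)
    if correct_only and "correct" in table.columns:
        keep &= table["correct"].to_numpy(dtype=bool)
    rows = []
    for subject, sub in table.groupby("subject", sort=True):
        for cell in CELLS:
            m = keep[sub.index.to_numpy()] \
                & (sub["congruency"] == cell[0]).to_numpy() \
                & (sub["action"] == cell[1]).to_numpy() \
                & (sub["validity"] == cell[2]).to_numpy()
            if not m.any():
                raise EmptyResultError(
                    f"subject {subject}: no usable trials in cell "
                    f"{cell[0]}/{cell[1]}/{cell[2]} for component {spec.name}")
            rows.append((subject, *cell, spec.name,
                         float(values[sub.index.to_numpy()[m]].mean())))
    return pd.DataFrame(rows, columns=["subject", "congruency", "action",
                                       "validity", "component", "amplitude"])


def validity_effect(cells: pd.DataFrame, spec: ComponentSpec,
                    value_col: str = "amplitude") -> pd.DataFrame:
    """Signed validity effect per subject x congruency x action.

    The sign follows ``spec.validity_sign``: invalid-minus-valid for the
    N2pc, valid-minus-invalid for P300b and the late LPC.
    """
    wide = cells.pivot_table(index=["subject", "congruency", "action"],
                             columns="validity", values=value_col)
    for level in ("valid", "invalid"):
        if level not in wide.columns or wide[level].isna().any():
            raise EmptyResultError(f"missing {level!r} cells for validity effect")
    if spec.validity_sign == "invalid_minus_valid":
        eff = wide["invalid"] - wide["valid"]
    else:
        eff = wide["valid"] - wide["invalid"]
    out = eff.rename("effect").reset_index()
    out["component"] = spec.name
    return out
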