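"""Synthetic multi-subject epoched EEG with known injected ground truth.

The generator emulates the study design that all downstream stages analyse:
26 subjects, 60 trials in each of the 8 congruency x action x validity cells,
60 scalp channels at 500 Hz, epochs -200..800 ms around search-array onset.
Within every cell, target hemifield and target orientation are balanced.

Signal model
------------
Each trial is a sum of

* additive Gaussian noise with power spectral density ∝ 1/f^exponent per
  channel, optionally correlated across channels through a shared-noise
  component;
* ERP components: a raised-cosine (Hann) temporal bump confined to the
  component's window, normalised so that the *mean* amplitude over the
  window's samples equals the injected cell amplitude exactly. Lateralized
  components (N2pc) are written only to the electrode contralateral to the
  target hemifield (left-hemifield target -> right electrode of the pair);
* multivariate class patterns: a fixed random unit-norm spatial weight
  vector per labeling, added with sign +1 for one class and -1 for the
  other, constant within the pattern's time window, with amplitude
  ``snr * noise_sd`` μV. Pattern vectors are drawn orthogonal to the
  parieto-occipital ERP montage average so that injected decodable signal
  does not bias univariate component means.

Behavioral data: per-cell RT from a zero-truncated normal and per-cell
Bernoulli correctness. Default cell means are the study's reported condition
means, so the generated datasets reproduce the reported validity-effect
surface (e.g. a 98 ms RT validity effect and a 2.7 μV N2pc validity effect
in congruent action cells) in expectation.

Reproducibility: one master seed; independent per-subject and per-purpose
streams are spawned from it, so the same config yields bit-identical data
and turning one ingredient off does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import CELLS, Cell, ConfigurationError
from .epochs_core import ChannelLayout, EpochSet

# ---------------------------------------------------------------------------
# Study-condition constants (reported condition means used as defaults)
# ---------------------------------------------------------------------------

#: per-cell mean RT in ms (congruency, action, validity)
DEFAULT_RT_MEAN_MS: Dict[Cell, float] = {
    ("congruent", "action", "valid"): 522.0,
    ("congruent", "action", "invalid"): 620.0,
    ("congruent", "no_action", "valid"): 601.0,
    ("congruent", "no_action", "invalid"): 553.0,
    ("incongruent", "action", "valid"): 524.0,
    ("incongruent", "action", "invalid"): 622.0,
    ("incongruent", "no_action", "valid"): 571.0,
    ("incongruent", "no_action", "invalid"): 572.0,
}

#: per-cell RT spread in ms (trial-level scale of the truncated normal)
DEFAULT_RT_SD_MS: Dict[Cell, float] = {
    ("congruent", "action", "valid"): 59.0,
    ("congruent", "action", "invalid"): 81.0,
    ("congruent", "no_action", "valid"): 74.0,
    ("congruent", "no_action", "invalid"): 70.0,
    ("incongruent", "action", "valid"): 61.0,
    ("incongruent", "action", "invalid"): 84.0,
    ("incongruent", "no_action", "valid"): 70.0,
    ("incongruent", "no_action", "invalid"): 74.0,
}

#: per-cell probability of a correct response
DEFAULT_ACCURACY: Dict[Cell, float] = {
    ("congruent", "action", "valid"): 0.984,
    ("congruent", "action", "invalid"): 0.954,
    ("congruent", "no_action", "valid"): 0.968,
    ("congruent", "no_action", "invalid"): 0.978,
    ("incongruent", "action", "valid"): 0.984,
    ("incongruent", "action", "invalid"): 0.954,
    ("incongruent", "no_action", "valid"): 0.968,
    ("incongruent", "no_action", "invalid"): 0.978,
}

#: N2pc contra-minus-ipsi mean amplitude per cell, μV
DEFAULT_N2PC_UV: Dict[Cell, float] = {
    ("congruent", "action", "valid"): -1.69,
    ("congruent", "action", "invalid"): 1.01,
    ("congruent", "no_action", "valid"): 0.34,
    ("congruent", "no_action", "invalid"): -1.10,
    ("incongruent", "action", "valid"): -1.65,
    ("incongruent", "action", "invalid"): 1.08,
    ("incongruent", "no_action", "valid"): -0.51,
    ("incongruent", "no_action", "invalid"): -0.35,
}

# P300b cell means: only validity effects (valid - invalid) are reported;
# cells are reconstructed around a 4 μV parieto-occipital positivity.
_P300B_BASE = 4.0
_P300B_EFFECT = {  # valid - invalid, μV
    ("congruent", "action"): 0.38,
    ("incongruent", "action"): 0.88,
    ("congruent", "no_action"): -0.79,
    ("incongruent", "no_action"): -0.43,
}
DEFAULT_P300B_UV: Dict[Cell, float] = {
    (c, a, v): _P300B_BASE + (0.5 if v == "valid" else -0.5) * _P300B_EFFECT[(c, a)]
    for c, a, v in CELLS
}

#: late LPC mean amplitude per cell, μV (action/no-action means, both congruencies)
DEFAULT_LATE_LPC_UV: Dict[Cell, float] = {
    (c, a, v): {("action", "valid"): 2.83, ("action", "invalid"): 4.77,
                ("no_action", "valid"): 3.63, ("no_action", "invalid"): 3.61}[(a, v)]
    for c, a, v in CELLS
}

N2PC_ELECTRODES: Tuple[str, str] = ("PO7", "PO8")
PARIETO_OCCIPITAL_10: Tuple[str, ...] = (
    "P3", "P4", "P7", "P8", "PO3", "PO4", "PO5", "PO6", "PO7", "PO8")

N2PC_WINDOW_MS: Tuple[float, float] = (180.0, 300.0)
P300B_WINDOW_MS: Tuple[float, float] = (300.0, 500.0)
LATE_LPC_WINDOW_MS: Tuple[float, float] = (500.0, 700.0)

#: decodable validity signal is present in action cells only
VALIDITY_PATTERN_WINDOW_MS: Tuple[float, float] = (320.0, 790.0)
ORIENTATION_PATTERN_WINDOW_MS: Tuple[float, float] = (200.0, 790.0)


# ---------------------------------------------------------------------------
# Config dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedComponent:
    """An ERP component to inject: Hann bump over a window on a channel set.

    ``amplitude_by_cell`` maps each design cell to the *mean* in-window
    amplitude in μV (the temporal kernel is normalised so the window mean
    equals this value exactly). If ``lateralized``, ``electrodes`` must be a
    left/right homolog pair and the amplitude is written only to the
    electrode contralateral to the trial's target hemifield.
    """

    name: str
    electrodes: Tuple[str, ...]
    window: Tuple[float, float]
    amplitude_by_cell: Dict[Cell, float]
    lateralized: bool = False
    kernel: str = "half_cosine"


@dataclass(frozen=True)
class InjectedPattern:
    """A decodable two-class multivariate pattern.

    ``label_name`` selects which trial label splits the classes ('validity'
    or 'orientation'); the first level of the labeling gets ``+w`` and the
    second ``-w``, where w is a fixed unit-norm spatial vector drawn once per
    dataset. Amplitude is ``snr * noise_sd`` μV, constant inside ``window``.
    ``cells`` are partial cell filters (factor -> level); the pattern is
    injected only in matching trials.
    """

    label_name: str
    window: Tuple[float, float]
    snr: float
    cells: Tuple[Mapping[str, str], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 26
    n_trials_per_cell: int = 60
    n_channels: int = 60
    sampling_rate: float = 500.0
    epoch_window: Tuple[float, float] = (-200.0, 800.0)
    noise_sd: float = 10.0
    noise_spectral_exponent: float = 1.0
    spatial_smoothing: float = 0.2
    component_params: Tuple[InjectedComponent, ...] = ()
    pattern_params: Tuple[InjectedPattern, ...] = ()
    rt_mean_ms: Dict[Cell, float] = field(default_factory=lambda: dict(DEFAULT_RT_MEAN_MS))
    rt_sd_ms: Dict[Cell, float] = field(default_factory=lambda: dict(DEFAULT_RT_SD_MS))
    accuracy: Dict[Cell, float] = field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    seed: int = 0

    def n_samples(self) -> int:
        span_s = (self.epoch_window[1] - self.epoch_window[0]) / 1000.0
        n = self.sampling_rate * span_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate x epoch window must give an integer sample count")
        return int(round(n))

    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.epoch_window[0] + step * np.arange(self.n_samples())

    def validate(self, layout: ChannelLayout) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_trials_per_cell < 8:
            raise ConfigurationError(
                "n_trials_per_cell must be >= 8 (decoding needs >= 8 trials per class)")
        if not (self.epoch_window[0] < 0.0 < self.epoch_window[1]):
            raise ConfigurationError("epoch_window must span a negative..positive range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.spatial_smoothing < 1.0):
            raise ConfigurationError("spatial_smoothing must be in [0, 1)")
        self.n_samples()
        for comp in self.component_params:
            if comp.window[0] < self.epoch_window[0] or comp.window[1] > self.epoch_window[1]:
                raise ConfigurationError(
                    f"component {comp.name!r}: window outside epoch_window")
            for e in comp.electrodes:
                layout.index(e)
            if comp.lateralized:
                if len(comp.electrodes) != 2:
                    raise ConfigurationError(
                        f"component {comp.name!r}: lateralized components need a homolog pair")
                layout.pair(*comp.electrodes)
            missing = set(CELLS) - set(comp.amplitude_by_cell)
            if missing:
                raise ConfigurationError(
                    f"component {comp.name!r}: amplitude_by_cell missing cells {sorted(missing)}")
        for pat in self.pattern_params:
            if pat.snr < 0:
                raise ConfigurationError(f"pattern {pat.label_name!r}: snr must be >= 0")
            if pat.label_name not in ("validity", "orientation"):
                raise ConfigurationError(
                    f"pattern label_name must be 'validity' or 'orientation', "
                    f"got {pat.label_name!r}")


@dataclass
class GroundTruth:
    """The injected truth, serialisable alongside every generated dataset."""

    components: List[Dict]
    patterns: List[Dict]
    rt_mean_ms: Dict[str, float]
    rt_sd_ms: Dict[str, float]
    accuracy: Dict[str, float]
    noise_sd: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def default_components() -> Tuple[InjectedComponent, ...]:
    """N2pc, P300b and late LPC with the reported cell-mean amplitudes."""
    return (
        InjectedComponent("N2pc", N2PC_ELECTRODES, N2PC_WINDOW_MS,
                          dict(DEFAULT_N2PC_UV), lateralized=True),
        InjectedComponent("P300b", PARIETO_OCCIPITAL_10, P300B_WINDOW_MS,
                          dict(DEFAULT_P300B_UV), lateralized=False),
        InjectedComponent("lateLPC", PARIETO_OCCIPITAL_10, LATE_LPC_WINDOW_MS,
                          dict(DEFAULT_LATE_LPC_UV), lateralized=False),
    )


def default_patterns() -> Tuple[InjectedPattern, ...]:
    """Decodable validity signal in action cells only; orientation everywhere."""
    return (
        InjectedPattern("validity", VALIDITY_PATTERN_WINDOW_MS, snr=0.6,
                        cells=({"action": "action"},)),
        InjectedPattern("orientation", ORIENTATION_PATTERN_WINDOW_MS, snr=0.6,
                        cells=({},)),
    )


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-conditions configuration with all default injections."""
    kwargs = dict(
        component_params=default_components(),
        pattern_params=default_patterns(),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def make_layout(n_channels: int) -> ChannelLayout:
    """The standard 60-channel layout, truncated from the midline end if fewer
    channels are requested (homolog pairs are kept first)."""
    full = ChannelLayout.standard_60()
    if n_channels == full.n_channels():
        return full
    if n_channels > full.n_channels():
        raise ConfigurationError(
            f"n_channels={n_channels} exceeds the standard layout (60)")
    names = full.names[:n_channels]
    pairs = tuple(p for p in full.homolog_pairs if p[0] in names and p[1] in names)
    if ("PO7", "PO8") not in pairs:
        raise ConfigurationError(
            "n_channels too small: the layout must retain the PO7/PO8 pair")
    return ChannelLayout(names=names, homolog_pairs=pairs)


_STREAMS = {"design": 1, "noise": 2, "behavior": 3}


def _subject_rng(master_seed: int, purpose: str, subject: int) -> np.random.Generator:
    # fixed spawn keys: independent, reproducible streams per subject/purpose
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[purpose], subject))
    return np.random.default_rng(ss)


def generate_trial_table(config: SimConfig, subject: int) -> pd.DataFrame:
    """One subject's trial table: 8 cells x n_trials_per_cell, hemifield and
    orientation balanced within cell (stratum counts differ by <= 1), trial
    order shuffled."""
    rng = _subject_rng(config.seed, "design", subject)
    rows = []
    for cell in CELLS:
        n = config.n_trials_per_cell
        strata = [(h, o) for h in ("left", "right") for o in ("left", "right")]
        # round-robin fill keeps every hemifield x orientation stratum within 1
        assignment = [strata[i % 4] for i in range(n)]
        rng.shuffle(assignment)
        for hemi, orient in assignment:
            rows.append((f"S{subject:02d}", *cell, hemi, orient))
    table = pd.DataFrame(rows, columns=[
        "subject", "congruency", "action", "validity",
        "target_hemifield", "target_orientation"])
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table["kept"] = True
    return table


def generate_noise(
    config: SimConfig, n_trials: int, rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean noise, PSD ∝ f^(-exponent) per channel, shared-noise spatial
    correlation of ``spatial_smoothing`` between channels.

    Returns (n_trials, n_channels, n_samples) in μV with per-channel variance
    ``noise_sd**2`` in expectation (DC is removed, so each trial's time
    average is exactly zero).
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    n_s = config.n_samples()
    n_c = config.n_channels
    if config.noise_sd == 0:
        return np.zeros((n_trials, n_c, n_s))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    e = config.noise_spectral_exponent

    freqs = np.fft.rfftfreq(n_s, d=1.0 / config.sampling_rate)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-e / 2.0)
    # two-sided Parseval normalisation so filtered white noise has unit variance
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_s % 2 == 0:
        weights[-1] = 1.0
    norm = np.sqrt((weights * h ** 2).sum() / n_s)

    def shaped(shape):
        white = rng.normal(size=shape)
        spec = np.fft.rfft(white, axis=-1) * h
        return np.fft.irfft(spec, n=n_s, axis=-1) / norm

    x = shaped((n_trials, n_c, n_s))
    s = config.spatial_smoothing
    if s > 0:
        shared = shaped((n_trials, 1, n_s))
        x = np.sqrt(1.0 - s) * x + np.sqrt(s) * shared
    return config.noise_sd * x


def _hann_kernel(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    """Raised-cosine bump over ``window`` normalised to unit in-window mean."""
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ConfigurationError(f"component window {window} contains no samples")
    k = np.zeros_like(times)
    span = window[1] - window[0]
    if span <= 0 or mask.sum() == 1:
        k[mask] = 1.0
        return k
    u = (times[mask] - window[0]) / span
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    m = bump.mean()
    if m <= 0:  # degenerate sampling (only endpoints hit): fall back to boxcar
        bump = np.ones_like(bump)
        m = 1.0
    k[mask] = bump / m
    return k


def _inject_components(data, times, table, config, layout) -> None:
    for comp in config.component_params:
        kernel = _hann_kernel(times, comp.window)
        amps = np.array([comp.amplitude_by_cell[
            (r.congruency, r.action, r.validity)] for r in table.itertuples()])
        if comp.lateralized:
            left, right = layout.pair(*comp.electrodes)
            il, ir = layout.index(left), layout.index(right)
            # contralateral electrode: opposite the target hemifield
            contra = np.where(table["target_hemifield"].to_numpy() == "left", ir, il)
            data[np.arange(len(table)), contra, :] += amps[:, None] * kernel[None, :]
        else:
            idx = layout.indices(comp.electrodes)
            data[:, idx, :] += amps[:, None, None] * kernel[None, None, :]


_PATTERN_CLASS_COLUMN = {"validity": "validity", "orientation": "target_orientation"}
_PATTERN_CLASS_LEVELS = {"validity": ("valid", "invalid"),
                         "orientation": ("left", "right")}


def _draw_pattern_vectors(config: SimConfig, layout: ChannelLayout,
                          rng: np.random.Generator) -> Dict[int, np.ndarray]:
    """One fixed unit-norm spatial vector per pattern, orthogonal to the
    parieto-occipital montage average (keeps univariate ERP means unbiased)."""
    vectors = {}
    po = [e for e in PARIETO_OCCIPITAL_10 if e in layout.names]
    indicator = np.zeros(layout.n_channels())
    if po:
        indicator[layout.indices(po)] = 1.0
        indicator /= np.linalg.norm(indicator)
    for i, _pat in enumerate(config.pattern_params):
        w = rng.normal(size=layout.n_channels())
        if po:
            w -= (w @ indicator) * indicator
        w /= np.linalg.norm(w)
        vectors[i] = w
    return vectors


def _inject_patterns(data, times, table, config, layout, vectors) -> None:
    from .design import match_cells

    for i, pat in enumerate(config.pattern_params):
        amp = pat.snr * config.noise_sd
        if amp == 0:
            continue
        mask_t = (times >= pat.window[0]) & (times <= pat.window[1])
        in_cells = match_cells(table, pat.cells) if pat.cells else np.ones(len(table), bool)
        col = _PATTERN_CLASS_COLUMN[pat.label_name]
        first_level = _PATTERN_CLASS_LEVELS[pat.label_name][0]
        sign = np.where(table[col].to_numpy() == first_level, 1.0, -1.0)
        sign = sign * in_cells
        w = vectors[i]
        data[:, :, mask_t] += (amp * sign)[:, None, None] * w[None, :, None]


def generate_behavior(
    config: SimConfig, table: pd.DataFrame, rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill ``rt`` (zero-truncated normal per cell) and ``correct`` (Bernoulli
    per cell) on a copy of ``table``."""
    from scipy import stats

    out = table.copy()
    rt = np.empty(len(out))
    correct = np.empty(len(out), dtype=bool)
    for cell in CELLS:
        m = (out["congruency"] == cell[0]) & (out["action"] == cell[1]) \
            & (out["validity"] == cell[2])
        n = int(m.sum())
        if n == 0:
            continue
        mu = config.rt_mean_ms[cell]
        sd = config.rt_sd_ms[cell]
        if sd == 0:
            rt[m.to_numpy()] = mu
        else:
            a = (0.0 - mu) / sd  # truncate at zero
            rt[m.to_numpy()] = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)
        correct[m.to_numpy()] = rng.random(n) < config.accuracy[cell]
    out["rt"] = rt
    out["correct"] = correct
    return out


def generate_subject(config: SimConfig, subject: int,
                     layout: ChannelLayout,
                     pattern_vectors: Dict[int, np.ndarray],
                     ) -> Tuple[EpochSet, pd.DataFrame]:
    table = generate_trial_table(config, subject)
    noise_rng = _subject_rng(config.seed, "noise", subject)
    data = generate_noise(config, len(table), noise_rng)
    times = config.times()
    _inject_components(data, times, table, config, layout)
    _inject_patterns(data, times, table, config, layout, pattern_vectors)
    behav_rng = _subject_rng(config.seed, "behavior", subject)
    table = generate_behavior(config, table, behav_rng)
    epochs = EpochSet(data, times, layout, subject_id=f"S{subject:02d}")
    return epochs, table


def generate_dataset(
    config: SimConfig,
) -> Tuple[List[EpochSet], List[pd.DataFrame], GroundTruth]:
    """Generate the full multi-subject dataset plus its ground truth."""
    layout = make_layout(config.n_channels)
    config.validate(layout)
    pattern_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0xBEEF,)))
    vectors = _draw_pattern_vectors(config, layout, pattern_rng)
    epochs_list, tables = [], []
    for s in range(config.n_subjects):
        epochs, table = generate_subject(config, s, layout, vectors)
        epochs_list.append(epochs)
        tables.append(table)
    truth = GroundTruth(
        components=[{
            "name": c.name, "electrodes": list(c.electrodes),
            "window_ms": list(c.window), "lateralized": c.lateralized,
            "amplitude_by_cell": {"_".join(k): v for k, v in c.amplitude_by_cell.items()},
        } for c in config.component_params],
        patterns=[{
            "label_name": p.label_name, "window_ms": list(p.window),
            "snr": p.snr, "cells": [dict(f) for f in p.cells],
        } for p in config.pattern_params],
        rt_mean_ms={"_".join(k): v for k, v in config.rt_mean_ms.items()},
        rt_sd_ms={"_".join(k): v for k, v in config.rt_sd_ms.items()},
        accuracy={"_".join(k): v for k, v in config.accuracy.items()},
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return epochs_list, tables, truth
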