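"""Cluster-based sign-flip permutation tests on subject x time statistics.

First stage: a pointwise one-sample t-test of the subject curves against a
reference value (chance level for decoding accuracy, 0 for paired
differences). Second stage: contiguous runs of suprathreshold timepoints
are merged into clusters whose mass is the sum of member t-values, and each
observed cluster mass is compared against the permutation distribution of
the *maximum* cluster mass obtained by flipping the sign of each subject's
deviation curve independently (the exchangeability move for a symmetric
null). Cluster p-values use the add-one rule

    p = (1 + #{null >= observed}) / (1 + n_permutations)

so p is never zero and the test is valid at finite permutation counts.

Defaults follow the dominant convention for this family: the
cluster-forming threshold is the two-sided pointwise p < 0.05 t-quantile,
10,000 permutations, one-sided (greater) testing against chance for
accuracy curves and two-sided testing for condition differences. A
timepoint with zero variance across subjects gets ``±inf`` t and counts as
suprathreshold (flagged, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import ConfigurationError

TAILS = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int          # inclusive
    summed_t: float
    p: float = float("nan")


@dataclass
class ClusterTestResult:
    clusters: List[Cluster]
    t_obs: np.ndarray
    times: np.ndarray
    threshold_t: float
    n_permutations: int
    tail: str
    null_max_mass: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> List[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "start_ms": c.start_ms, "end_ms": c.end_ms,
            "summed_t": c.summed_t, "p": c.p} for c in self.clusters])


def pointwise_t(sample: np.ndarray, mu0: float = 0.0,
                ) -> Tuple[np.ndarray, np.ndarray]:
    """One-sample t (and two-sided p) against ``mu0`` per timepoint.

    ``sample``: subjects x timepoints. Zero-variance timepoints yield
    ``±inf`` t (sign of the mean deviation; 0 if the deviation is also 0).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[0] < 3:
        raise ConfigurationError("need a subjects x timepoints matrix with >= 3 subjects")
    if np.isnan(sample).any():
        raise ConfigurationError("sample contains missing values")
    n = sample.shape[0]
    d = sample - mu0
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    with np.errstate(invalid="ignore"):
        t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[np.isinf(t)] = 0.0
    return t, p


def default_threshold(n_subjects: int, cluster_alpha: float = 0.05) -> float:
    """Two-sided pointwise-p cluster-forming t threshold, df = n-1."""
    return float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n_subjects - 1))


def form_clusters(t: np.ndarray, threshold_t: float, tail: str = "greater",
                  times: Optional[np.ndarray] = None) -> List[Cluster]:
    """Maximal contiguous runs of suprathreshold timepoints with summed-t mass.

    ``tail='greater'`` clusters t > threshold, ``'less'`` clusters
    t < -threshold, ``'two-sided'`` clusters each sign separately (clusters
    never mix signs). Adjacency is consecutive samples.
    """
    if threshold_t <= 0:
        raise ConfigurationError("threshold_t must be > 0")
    if tail not in TAILS:
        raise ConfigurationError(f"tail must be one of {TAILS}")
    t = np.asarray(t, dtype=float)
    if times is None:
        times = np.arange(t.size, dtype=float)
    clusters: List[Cluster] = []
    masks = []
    if tail in ("greater", "two-sided"):
        masks.append(t > threshold_t)
    if tail in ("less", "two-sided"):
        masks.append(t < -threshold_t)
    for mask in masks:
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            clusters.append(Cluster(
                start_ms=float(times[start]), end_ms=float(times[stop - 1]),
                start_idx=int(start), end_idx=int(stop - 1),
                summed_t=float(t[start:stop].sum())))
    clusters.sort(key=lambda c: c.start_idx)
    return clusters


def _max_cluster_mass(t_rows: np.ndarray, threshold_t: float, tail: str,
                      ) -> np.ndarray:
    """Maximum |cluster mass| per row of a permutations x timepoints t matrix."""
    out = np.zeros(t_rows.shape[0])
    for i in range(t_rows.shape[0]):
        cl = form_clusters(t_rows[i], threshold_t, tail)
        if cl:
            out[i] = max(abs(c.summed_t) for c in cl)
    return out


def permutation_null(sample: np.ndarray, threshold_t: float,
                     n_permutations: int, rng: np.random.Generator,
                     mu0: float = 0.0, tail: str = "greater") -> np.ndarray:
    """Null distribution of the maximum |cluster mass| under sign flipping.

    Each permutation flips the sign of each subject's deviation-from-``mu0``
    curve independently with probability 1/2, recomputes the pointwise t and
    records the maximum absolute cluster mass (0 when no cluster forms).
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    sample = np.asarray(sample, dtype=float)
    n, n_t = sample.shape
    d = sample - mu0
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    return _null_from_signs(d, signs, threshold_t, tail)


def _null_from_signs(d: np.ndarray, signs: np.ndarray, threshold_t: float,
                     tail: str) -> np.ndarray:
    """Vectorised t over sign-flip patterns, then per-row max cluster mass.

    Uses sum(x^2) invariance under sign flips: only the mean changes, so
    var = (ss - n*mean^2)/(n-1) per permutation without re-touching the data.
    """
    n, n_t = d.shape
    ss = (d * d).sum(axis=0)                      # (T,), flip-invariant
    mean = signs @ d / n                          # (P, T)
    var = (ss[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[np.isnan(t)] = 0.0                          # 0/0: all-zero deviations
    return _max_cluster_mass(t, threshold_t, tail)


def cluster_test(sample: np.ndarray, mu0: float = 0.0,
                 threshold_t: Optional[float] = None,
                 n_permutations: int = 10000, tail: str = "greater",
                 times: Optional[np.ndarray] = None,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = 0) -> ClusterTestResult:
    """Cluster-based permutation test of subject curves against ``mu0``."""
    sample = np.asarray(sample, dtype=float)
    if tail not in TAILS:
        raise ConfigurationError(f"tail must be one of {TAILS}")
    n = sample.shape[0]
    if threshold_t is None:
        threshold_t = default_threshold(n)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC105,)))
    if times is None:
        times = np.arange(sample.shape[1], dtype=float)
    t_obs, _ = pointwise_t(sample, mu0)
    clusters = form_clusters(t_obs, threshold_t, tail, times)
    null = permutation_null(sample, threshold_t, n_permutations, rng,
                            mu0=mu0, tail=tail)
    out = []
    for c in clusters:
        # tolerance so exact ties (e.g. identity sign patterns reproducing the
        # observed statistic via a different summation order) are counted
        mass = abs(c.summed_t)
        tol = 1e-9 * max(1.0, mass)
        exceed = int((null >= mass - tol).sum())
        p = (1 + exceed) / (1 + n_permutations)
        out.append(Cluster(start_ms=c.start_ms, end_ms=c.end_ms,
                           start_idx=c.start_idx, end_idx=c.end_idx,
                           summed_t=c.summed_t, p=p))
    return ClusterTestResult(clusters=out, t_obs=t_obs, times=np.asarray(times),
                             threshold_t=float(threshold_t),
                             n_permutations=n_permutations, tail=tail,
                             null_max_mass=null)


def compare_conditions(sample_a: np.ndarray, sample_b: np.ndarray,
                       threshold_t: Optional[float] = None,
                       n_permutations: int = 10000, tail: str = "two-sided",
                       times: Optional[np.ndarray] = None,
                       rng: Optional[np.random.Generator] = None,
                       seed: Optional[int] = 0) -> ClusterTestResult:
    """Paired cluster test of condition a vs b (test on a-b difference curves)."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.shape != sample_b.shape:
        raise ConfigurationError("paired comparison needs matching subject x time shapes")
    return cluster_test(sample_a - sample_b, mu0=0.0, threshold_t=threshold_t,
                        n_permutations=n_permutations, tail=tail, times=times,
                        rng=rng, seed=seed)
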