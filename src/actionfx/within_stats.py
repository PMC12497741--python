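"""Exact fully within-subject 2x2x2 factorial inference via contrast scores.

In a 2^k within-subject design every omnibus effect has one numerator degree
of freedom and is equivalent to a paired t-test on a per-subject contrast
score: the mean of the subject's 8 cell means weighted +1/-1 by the effect's
sign pattern (divided by 4, so a main-effect score is the difference of two
4-cell means). Then

    F = t^2,   t = mean(score) / (sd(score)/sqrt(n)),   df = (1, n-1),

with p from the F distribution and partial eta squared
``F / (F + df_error)`` (identical to SS_effect/(SS_effect+SS_error) here).
This reproduces the classical repeated-measures ANOVA table exactly while
remaining a few lines of arithmetic that an independent general-linear-model
decomposition can verify.

Sign conventions: the *second* level of each factor carries weight +1
(factor level orders: congruent < incongruent, action < no_action,
valid < invalid), so the validity main-effect score is mean(invalid cells)
minus mean(valid cells) — the same orientation as the behavioral validity
effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import CELLS, FACTORS, ConfigurationError, DegenerateDataError

FACTOR_NAMES: Tuple[str, ...] = tuple(FACTORS)  # congruency, action, validity

#: the 7 canonical effects of the 2x2x2 design
EFFECTS: Tuple[str, ...] = (
    "congruency", "action", "validity",
    "congruency:action", "congruency:validity", "action:validity",
    "congruency:action:validity",
)


@dataclass
class FactorialDataset:
    """Subjects x 8 design cells of one dependent measure."""

    values: np.ndarray              # (n_subjects, 8), CELLS order
    subjects: Tuple[str, ...]
    measure: str = "value"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(CELLS):
            raise ConfigurationError("factorial dataset must be subjects x 8 cells")
        if self.values.shape[0] < 3:
            raise ConfigurationError("factorial inference needs >= 3 subjects")
        if np.isnan(self.values).any():
            raise ConfigurationError("factorial dataset has missing cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_table(cls, table: pd.DataFrame, value_col: str) -> "FactorialDataset":
        """Build from a tidy frame with subject/congruency/action/validity columns."""
        wide = table.pivot_table(index="subject",
                                 columns=["congruency", "action", "validity"],
                                 values=value_col)
        try:
            wide = wide[list(CELLS)]
        except KeyError as exc:
            raise ConfigurationError(f"missing design cells: {exc}") from exc
        return cls(wide.to_numpy(), tuple(map(str, wide.index)), measure=value_col)


@dataclass(frozen=True)
class EffectResult:
    effect: str
    F: float
    df: Tuple[int, int]
    p: float
    partial_eta_sq: float
    mean_diff: float          # mean contrast score (units of the measure)
    ci95: Tuple[float, float]
    t: float


def effect_weights(effect: str) -> np.ndarray:
    """+1/-1 weight per design cell for a canonical effect."""
    if effect not in EFFECTS:
        raise ConfigurationError(f"unknown effect {effect!r}; one of {EFFECTS}")
    parts = effect.split(":")
    w = np.ones(len(CELLS))
    for i, factor in enumerate(FACTOR_NAMES):
        if factor in parts:
            codes = np.array([1.0 if cell[i] == FACTORS[factor][1] else -1.0
                              for cell in CELLS])
            w *= codes
    return w


def contrast_score(dataset: FactorialDataset, effect: str) -> np.ndarray:
    """Per-subject contrast score: weighted cell mean (weights ±1, /4)."""
    w = effect_weights(effect)
    return dataset.values @ w / (len(CELLS) / 2)


def _paired_t_result(effect: str, scores: np.ndarray) -> EffectResult:
    n = scores.size
    sd = scores.std(ddof=1)
    mean = scores.mean()
    if sd == 0:
        raise DegenerateDataError(
            f"effect {effect!r}: zero contrast variance, F undefined")
    se = sd / np.sqrt(n)
    t = mean / se
    F = t * t
    df = (1, n - 1)
    p = float(stats.f.sf(F, *df))
    eta = F / (F + df[1])
    tcrit = stats.t.ppf(0.975, df[1])
    return EffectResult(effect=effect, F=float(F), df=df, p=p,
                        partial_eta_sq=float(eta), mean_diff=float(mean),
                        ci95=(float(mean - tcrit * se), float(mean + tcrit * se)),
                        t=float(t))


def rm_anova_2x2x2(dataset: FactorialDataset) -> List[EffectResult]:
    """All 7 effects of the within-subject 2x2x2 ANOVA."""
    return [_paired_t_result(e, contrast_score(dataset, e)) for e in EFFECTS]


def rm_anova_table(dataset: FactorialDataset) -> pd.DataFrame:
    res = rm_anova_2x2x2(dataset)
    return pd.DataFrame([{
        "effect": r.effect, "F": r.F, "df1": r.df[0], "df2": r.df[1],
        "p": r.p, "partial_eta_sq": r.partial_eta_sq,
        "mean_diff": r.mean_diff, "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
    } for r in res])


def simple_effects(dataset: FactorialDataset, factor: str, by: str,
                   fix: Optional[Mapping[str, str]] = None,
                   correction: str = "bonferroni") -> List[EffectResult]:
    """Paired t-test on ``factor`` within each level of ``by``.

    ``fix`` optionally pins remaining factors to one level (otherwise they
    are averaged over). The family = the comparisons produced by one call;
    with Bonferroni correction each p is multiplied by the family size and
    capped at 1.
    """
    if factor not in FACTOR_NAMES or by not in FACTOR_NAMES or factor == by:
        raise ConfigurationError("factor and by must be distinct design factors")
    if correction not in ("bonferroni", "none"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    fix = dict(fix or {})
    results = []
    fi = FACTOR_NAMES.index(factor)
    bi = FACTOR_NAMES.index(by)
    for level in FACTORS[by]:
        sel_hi, sel_lo = [], []
        for j, cell in enumerate(CELLS):
            if cell[bi] != level:
                continue
            if any(cell[FACTOR_NAMES.index(f)] != v for f, v in fix.items()):
                continue
            (sel_hi if cell[fi] == FACTORS[factor][1] else sel_lo).append(j)
        if not sel_hi or not sel_lo:
            raise ConfigurationError("simple-effects slice selects no cells")
        diff = dataset.values[:, sel_hi].mean(axis=1) \
            - dataset.values[:, sel_lo].mean(axis=1)
        res = _paired_t_result(f"{factor}|{by}={level}", diff)
        results.append(res)
    if correction == "bonferroni":
        k = len(results)
        results = [EffectResult(effect=r.effect, F=r.F, df=r.df,
                                p=min(1.0, r.p * k),
                                partial_eta_sq=r.partial_eta_sq,
                                mean_diff=r.mean_diff, ci95=r.ci95, t=r.t)
                   for r in results]
    return results


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """Multiply each p by the family size and cap at 1."""
    if len(p_values) == 0:
        raise ConfigurationError("empty comparison family")
    k = len(p_values)
    return [min(1.0, p * k) for p in p_values]


def cohens_d(x: np.ndarray, y: np.ndarray) -> Dict[str, float]:
    """Paired Cohen's d under both common conventions.

    ``d_z`` = mean(x-y)/sd(x-y); ``d_av`` = mean(x-y) divided by the mean of
    the two condition SDs. Reported effect sizes in the literature are often
    ambiguous between the two, so both are returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ConfigurationError("cohens_d needs >= 2 paired values")
    diff = x - y
    sd_diff = diff.std(ddof=1)
    sd_av = 0.5 * (x.std(ddof=1) + y.std(ddof=1))
    if sd_diff == 0 or sd_av == 0:
        raise DegenerateDataError("zero variance: Cohen's d undefined")
    return {"d_z": float(diff.mean() / sd_diff),
            "d_av": float(diff.mean() / sd_av)}
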