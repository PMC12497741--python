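"""Behavioral preprocessing and RT / accuracy validity effects.

RT analyses keep only correct trials whose RT lies within ±k standard
deviations (default 2.5) of the participant's mean RT, where mean and SD are
computed per subject over all correct trials pooled across conditions, in a
single pass with inclusive bounds. Incorrect trials never enter RT analyses
but always count toward accuracy; RT trimming is an RT-analysis device only
and does not affect accuracy.

The RT validity effect is invalid minus valid (positive = faster responses
on valid trials), computed per subject for each congruency x action
combination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CELLS, DegenerateDataError, EmptyResultError


def trim_rts(table: pd.DataFrame, k_sd: float = 2.5) -> pd.DataFrame:
    """Flag correct trials with RT within ±``k_sd`` subject SDs of the
    subject mean (column ``rt_kept``); returns a copy.

    Mean/SD are computed over the subject's correct trials (pooled across
    cells, ddof=1). Subjects with fewer than two correct trials have no
    defined SD and raise :class:`DegenerateDataError`.
    """
    out = table.copy().reset_index(drop=True)
    if "rt" not in out.columns or "correct" not in out.columns:
        raise EmptyResultError("trial table lacks 'rt'/'correct' columns")
    rt_kept = np.zeros(len(out), dtype=bool)
    for subject, sub in out.groupby("subject", sort=True):
        correct = sub["correct"].to_numpy(dtype=bool)
        if "kept" in sub.columns:
            correct &= sub["kept"].to_numpy(dtype=bool)
        rts = sub["rt"].to_numpy()[correct]
        if rts.size < 2:
            raise DegenerateDataError(
                f"subject {subject}: fewer than 2 correct trials, RT SD undefined")
        mean, sd = rts.mean(), rts.std(ddof=1)
        within = np.abs(sub["rt"].to_numpy() - mean) <= k_sd * sd
        rt_kept[sub.index.to_numpy()] = correct & within
    out["rt_kept"] = rt_kept
    return out


def behavior_cell_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x cell: mean RT over trimmed-correct trials, accuracy over
    all kept trials, and kept-trial counts.

    Expects a table processed by :func:`trim_rts` (falls back to correct
    trials if ``rt_kept`` is absent). Raises on empty cells.
    """
    t = table.reset_index(drop=True)
    if "rt_kept" not in t.columns:
        t = t.copy()
        t["rt_kept"] = t["correct"].to_numpy(dtype=bool)
    rows = []
    for subject, sub in t.groupby("subject", sort=True):
        kept = sub["kept"].to_numpy(dtype=bool) if "kept" in sub.columns \
            else np.ones(len(sub), dtype=bool)
        for cell in CELLS:
            m = kept & (sub["congruency"] == cell[0]).to_numpy() \
                & (sub["action"] == cell[1]).to_numpy() \
                & (sub["validity"] == cell[2]).to_numpy()
            if not m.any():
                raise EmptyResultError(
                    f"subject {subject}: empty cell {'/'.join(cell)}")
            rt_m = m & sub["rt_kept"].to_numpy(dtype=bool)
            if not rt_m.any():
                raise EmptyResultError(
                    f"subject {subject}: no RT-analysable trials in cell "
                    f"{'/'.join(cell)}")
            rows.append((subject, *cell,
                         float(sub["rt"].to_numpy()[rt_m].mean()),
                         float(sub["correct"].to_numpy(dtype=bool)[m].mean()),
                         int(m.sum())))
    return pd.DataFrame(rows, columns=["subject", "congruency", "action",
                                       "validity", "mean_rt", "accuracy",
                                       "n_kept"])


def accuracy_cell_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per subject x cell over all kept trials."""
    t = table.reset_index(drop=True)
    rows = []
    for subject, sub in t.groupby("subject", sort=True):
        kept = sub["kept"].to_numpy(dtype=bool) if "kept" in sub.columns \
            else np.ones(len(sub), dtype=bool)
        for cell in CELLS:
            m = kept & (sub["congruency"] == cell[0]).to_numpy() \
                & (sub["action"] == cell[1]).to_numpy() \
                & (sub["validity"] == cell[2]).to_numpy()
            if not m.any():
                raise EmptyResultError(
                    f"subject {subject}: empty cell {'/'.join(cell)}")
            rows.append((subject, *cell,
                         float(sub["correct"].to_numpy(dtype=bool)[m].mean()),
                         int(m.sum())))
    return pd.DataFrame(rows, columns=["subject", "congruency", "action",
                                       "validity", "accuracy", "n_kept"])


def rt_validity_effect(stats: pd.DataFrame,
                       value_col: str = "mean_rt") -> pd.DataFrame:
    """Invalid-minus-valid mean RT per subject x congruency x action (ms)."""
    wide = stats.pivot_table(index=["subject", "congruency", "action"],
                             columns="validity", values=value_col)
    for level in ("valid", "invalid"):
        if level not in wide.columns or wide[level].isna().any():
            raise EmptyResultError(f"missing {level!r} cells for validity effect")
    out = (wide["invalid"] - wide["valid"]).rename("effect").reset_index()
    return out
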