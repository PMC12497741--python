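"""Factor vocabularies and design-cell bookkeeping for the 2x2x2 design.

Every trial belongs to one cell of congruency x action x validity; target
hemifield and target orientation are balanced nuisance/label factors nested
within each cell.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Tuple

CONGRUENCY_LEVELS: Tuple[str, str] = ("congruent", "incongruent")
ACTION_LEVELS: Tuple[str, str] = ("action", "no_action")
VALIDITY_LEVELS: Tuple[str, str] = ("valid", "invalid")
HEMIFIELD_LEVELS: Tuple[str, str] = ("left", "right")
ORIENTATION_LEVELS: Tuple[str, str] = ("left", "right")

FACTORS: Dict[str, Tuple[str, str]] = {
    "congruency": CONGRUENCY_LEVELS,
    "action": ACTION_LEVELS,
    "validity": VALIDITY_LEVELS,
}

#: canonical fixed ordering of the 8 design cells
Cell = Tuple[str, str, str]
CELLS: Tuple[Cell, ...] = tuple(
    (c, a, v)
    for c in CONGRUENCY_LEVELS
    for a in ACTION_LEVELS
    for v in VALIDITY_LEVELS
)

#: required TrialTable columns and their allowed values (None = free)
TRIAL_COLUMNS: Dict[str, object] = {
    "subject": None,
    "congruency": CONGRUENCY_LEVELS,
    "action": ACTION_LEVELS,
    "validity": VALIDITY_LEVELS,
    "target_hemifield": HEMIFIELD_LEVELS,
    "target_orientation": ORIENTATION_LEVELS,
    "rt": None,
    "correct": None,
    "kept": None,
}


class ActionfxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ActionfxError):
    """An invalid configuration value; the message names the field."""


class FormatError(ActionfxError):
    """A malformed on-disk container."""


class UnsupportedVersionError(FormatError):
    """A container written by an incompatible format version."""


class EmptyResultError(ActionfxError):
    """An operation left no data to work with (e.g. all trials rejected)."""


class LabelingError(ActionfxError):
    """A trial carries a label outside the fixed vocabulary."""


class DegenerateDataError(ActionfxError):
    """Zero-variance or otherwise degenerate input where a statistic is undefined."""


def cell_label(cell: Cell) -> str:
    """Human/file-friendly name of a design cell."""
    return "_".join(cell)


def validate_trial_table(table, require_rt: bool = False) -> None:
    """Raise :class:`LabelingError` if a trial table violates the vocabulary."""
    for col in ("subject", "congruency", "action", "validity",
                "target_hemifield", "target_orientation"):
        if col not in table.columns:
            raise FormatError(f"trial table is missing required column {col!r}")
    for col, levels in (("congruency", CONGRUENCY_LEVELS),
                        ("action", ACTION_LEVELS),
                        ("validity", VALIDITY_LEVELS),
                        ("target_hemifield", HEMIFIELD_LEVELS),
                        ("target_orientation", ORIENTATION_LEVELS)):
        bad = set(table[col].unique()) - set(levels)
        if bad:
            raise LabelingError(f"column {col!r} contains unknown levels {sorted(bad)}")
    if require_rt:
        if "rt" not in table.columns:
            raise FormatError("trial table is missing required column 'rt'")


def match_cells(table, cells: Iterable[Mapping[str, str]]):
    """Boolean mask of trials matching any of the given partial cell filters.

    Each filter is a mapping factor-name -> level; a trial matches a filter
    when every named factor has the given level. Unknown factor names raise
    :class:`ConfigurationError`.
    """
    import numpy as np

    mask = np.zeros(len(table), dtype=bool)
    for filt in cells:
        sub = np.ones(len(table), dtype=bool)
        for factor, level in filt.items():
            if factor not in TRIAL_COLUMNS:
                raise ConfigurationError(f"unknown design factor {factor!r} in cell filter")
            allowed = TRIAL_COLUMNS[factor]
            if allowed is not None and level not in allowed:
                raise ConfigurationError(
                    f"unknown level {level!r} for factor {factor!r} in cell filter")
            sub &= (table[factor] == level).to_numpy()
        mask |= sub
    return mask


def iter_condition_splits(factors: List[str]):
    """Yield cell filters for every combination of the named factors."""
    from itertools import product

    levelsets = [FACTORS[f] for f in factors]
    for combo in product(*levelsets):
        yield dict(zip(factors, combo))
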