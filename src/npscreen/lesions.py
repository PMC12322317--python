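"""Neuropathology lesion panel: binarization rules and load scoring.

The panel holds 14 autopsy lesions grouped into three pathology domains:

* ``amyloid`` (5): ADNC, Braak stage, diffuse plaques, neuritic plaques, CAA
* ``cerebrovascular`` (6): infarcts, microinfarcts, hemorrhages/microbleeds,
  arteriolosclerosis, circle-of-Willis atherosclerosis, white matter rarefaction
* ``other`` (3): Lewy body disease, hippocampal/MTL sclerosis, TDP-43

Each lesion's ordinal grade scale is dichotomized into ``low`` / ``high``
(e.g. Braak none-II vs III-VI; severity none/mild vs moderate/severe).
Neuropathology *load* is the count of high-grade lesions, computed for the
whole panel and within the amyloid and cerebrovascular domains, then binned
into three burden levels (none/low, medium, high) by cohort-level cutoffs.

The rule table ships as a versioned JSON resource (``data/lesion_rules.json``)
so that grade scales and cut points are inspectable and replaceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lesion",
    "LoadProfile",
    "LESION_PANEL",
    "LESION_CODES",
    "DOMAINS",
    "codes_in_domain",
    "binarize_lesion",
    "binarize_panel",
    "compute_load",
    "compute_load_table",
    "load_labels",
    "fit_load_cutoffs",
    "assign_load_levels",
    "LOAD_LEVELS",
]

DOMAINS = ("amyloid", "cerebrovascular", "other")
LOAD_LEVELS = ("none_low", "medium", "high")

LOW, HIGH, MISSING = "low", "high", "missing"


class GradeError(ValueError):
    """A raw grade outside the lesion's grade scale."""


@dataclass(frozen=True)
class Lesion:
    """One panel lesion with its binarization rule.

    ``low_values`` and ``high_values`` are disjoint and together cover the
    full grade scale; a missing grade maps to neither.
    """

    code: str
    name: str
    domain: str
    scale: tuple[str, ...]
    low_values: frozenset[str]
    high_values: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.code}")
        if self.low_values & self.high_values:
            raise ValueError(f"{self.code}: low/high grade sets overlap")
        if self.low_values | self.high_values != set(self.scale):
            raise ValueError(f"{self.code}: low/high sets do not cover the scale")


def _load_panel() -> dict[str, Lesion]:
    raw = json.loads(
        resources.files("npscreen.data").joinpath("lesion_rules.json").read_text()
    )
    panel: dict[str, Lesion] = {}
    for row in raw["lesions"]:
        panel[row["code"]] = Lesion(
            code=row["code"],
            name=row["name"],
            domain=row["domain"],
            scale=tuple(row["scale"]),
            low_values=frozenset(row["low"]),
            high_values=frozenset(row["high"]),
        )
    return panel


LESION_PANEL: dict[str, Lesion] = _load_panel()
LESION_CODES: tuple[str, ...] = tuple(LESION_PANEL)


def codes_in_domain(domain: str) -> tuple[str, ...]:
    """Lesion codes belonging to one pathology domain, in panel order."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    return tuple(c for c, l in LESION_PANEL.items() if l.domain == domain)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def binarize_lesion(code: str, raw_grade: object) -> str:
    """Map one raw lesion grade to ``'low'``, ``'high'`` or ``'missing'``.

    Grades are matched case-insensitively against the lesion's scale; a grade
    outside the scale raises :class:`GradeError` naming the lesion and grade.
    """
    try:
        lesion = LESION_PANEL[code]
    except KeyError:
        raise KeyError(f"unknown lesion code {code!r}") from None
    if _is_missing(raw_grade):
        return MISSING
    grade = str(raw_grade).strip()
    # Roman-numeral Braak stages are case-sensitive in spirit but we accept
    # any casing; everything else is lowercase on the canonical scale.
    matches = [g for g in lesion.scale if g.lower() == grade.lower()]
    if not matches:
        raise GradeError(
            f"lesion {code}: grade {raw_grade!r} not on scale {list(lesion.scale)}"
        )
    return HIGH if matches[0] in lesion.high_values else LOW


def binarize_panel(neuropathology: pd.DataFrame) -> pd.DataFrame:
    """Binarize a raw neuropathology table into a 0/1/NaN status matrix.

    Parameters
    ----------
    neuropathology
        One row per autopsy participant; a ``participant_id`` column plus one
        raw-grade column per lesion code.

    Returns
    -------
    DataFrame indexed by participant with one float column per lesion:
    1.0 = high, 0.0 = low, NaN = missing grade.
    """
    df = neuropathology.set_index("participant_id") if "participant_id" in neuropathology else neuropathology
    out = {}
    for code in LESION_CODES:
        if code not in df.columns:
            raise KeyError(f"neuropathology table lacks column {code!r}")
        status = df[code].map(lambda g, c=code: binarize_lesion(c, g))
        out[code] = status.map({LOW: 0.0, HIGH: 1.0, MISSING: np.nan})
    return pd.DataFrame(out, index=df.index)


@dataclass
class LoadProfile:
    """Lesion counts and 3-level burden labels for one participant.

    Counts are numbers of high-grade lesions among observed grades; levels
    are filled in by :func:`assign_load_levels` once cohort cutoffs exist.
    """

    total_load: int
    amyloid_load: int
    cerebrovascular_load: int
    n_missing: int = 0
    usable: bool = True
    total_level: str | None = None
    amyloid_level: str | None = None
    cerebrovascular_level: str | None = None
    levels: dict = field(default_factory=dict, repr=False)


def compute_load(statuses: Mapping[str, str], max_missing: int = 2) -> LoadProfile:
    """Count high-grade lesions overall and per domain.

    ``statuses`` maps each of the 14 lesion codes to 'low'/'high'/'missing'.
    Counts run over observed lesions only; a profile with more than
    ``max_missing`` missing grades is flagged ``usable=False`` (kept, so the
    caller decides whether to drop it from label construction).
    """
    missing_codes = set(LESION_CODES) - set(statuses)
    if missing_codes:
        raise KeyError(f"statuses lack lesion codes: {sorted(missing_codes)}")
    counts = {d: 0 for d in DOMAINS}
    n_missing = 0
    for code in LESION_CODES:
        s = statuses[code]
        if s == MISSING:
            n_missing += 1
        elif s == HIGH:
            counts[LESION_PANEL[code].domain] += 1
        elif s != LOW:
            raise ValueError(f"lesion {code}: invalid status {s!r}")
    return LoadProfile(
        total_load=sum(counts.values()),
        amyloid_load=counts["amyloid"],
        cerebrovascular_load=counts["cerebrovascular"],
        n_missing=n_missing,
        usable=n_missing <= max_missing,
    )


def compute_load_table(status_matrix: pd.DataFrame, max_missing: int = 2) -> pd.DataFrame:
    """Vectorized :func:`compute_load` over a binarized 0/1/NaN status matrix.

    Returns a DataFrame with ``total_load``, ``amyloid_load``,
    ``cerebrovascular_load``, ``n_missing`` and ``usable`` columns, indexed
    like ``status_matrix``.
    """
    amy = list(codes_in_domain("amyloid"))
    cvd = list(codes_in_domain("cerebrovascular"))
    high = status_matrix[list(LESION_CODES)]
    n_missing = high.isna().sum(axis=1)
    out = pd.DataFrame(
        {
            "total_load": high.sum(axis=1, skipna=True).astype(int),
            "amyloid_load": high[amy].sum(axis=1, skipna=True).astype(int),
            "cerebrovascular_load": high[cvd].sum(axis=1, skipna=True).astype(int),
            "n_missing": n_missing.astype(int),
            "usable": n_missing <= max_missing,
        },
        index=status_matrix.index,
    )
    return out


def load_labels(
    neuropathology: pd.DataFrame,
    max_missing: int = 2,
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Binarize a raw panel and attach 3-level load labels for all targets.

    Returns (table, cutoffs): the table holds the three load counts plus
    ``total_level`` / ``amyloid_level`` / ``cerebrovascular_level`` columns
    for participants with a usable panel (at most ``max_missing`` missing
    grades).  Cutoffs are empirical tertiles fitted here unless supplied
    (e.g. frozen ones from a run manifest).
    """
    status = binarize_panel(neuropathology)
    loads = compute_load_table(status, max_missing=max_missing)
    usable = loads[loads["usable"]].copy()
    fitted: dict[str, tuple[float, float]] = {}
    for target in ("total_load", "amyloid_load", "cerebrovascular_load"):
        cuts = cutoffs[target] if cutoffs is not None else fit_load_cutoffs(usable[target])
        fitted[target] = tuple(cuts)
        level_col = target.replace("_load", "_level")
        usable[level_col] = assign_load_levels(usable[target], fitted[target])
    return usable, fitted


def fit_load_cutoffs(loads: Sequence[float]) -> tuple[float, float]:
    """Empirical tertile cutoffs (1/3, 2/3 quantiles) of a load distribution.

    Used to bin integer lesion counts into none/low, medium and high burden;
    the fitted pair is frozen per run and recorded in the run manifest.
    """
    arr = np.asarray(loads, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot fit load cutoffs on an empty distribution")
    lo, hi = np.quantile(arr, [1 / 3, 2 / 3])
    return float(lo), float(hi)


def assign_load_levels(loads: Sequence[float], cutoffs: tuple[float, float]) -> np.ndarray:
    """Bin load counts into the three burden levels using fixed cutoffs.

    A load ``<= cutoffs[0]`` is 'none_low', ``<= cutoffs[1]`` is 'medium',
    anything above is 'high'.
    """
    lo, hi = cutoffs
    if lo > hi:
        raise ValueError(f"cutoffs must be ordered, got {cutoffs}")
    arr = np.asarray(loads, dtype=float)
    levels = np.where(arr <= lo, LOAD_LEVELS[0], np.where(arr <= hi, LOAD_LEVELS[1], LOAD_LEVELS[2]))
    return levels.astype(object)
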