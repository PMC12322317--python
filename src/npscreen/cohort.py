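"""Cohort construction: inclusion filters, longitudinal features, preprocessing.

Two analysis sets mirror the study design:

* the *generalized* set — participants without autopsy, aged 60+, one
  randomly selected clinical visit each (a cross-section of the clinical
  landscape, used for clustering and as the unlabeled pool);
* the *t_minus* set — autopsy participants (autopsy at or after a
  configurable age threshold, default 65) with three to seven roughly
  annual visits indexed by years before death.

For longitudinal analyses each numeric feature is summarized per
participant as {baseline value, most recent value, least-squares slope per
year toward death, across-visit standard deviation}; categorical features
contribute {mode, changed indicator}.  Slopes are reported per year of
elapsed time, so a value rising as death approaches has a positive slope.

:class:`FeaturePreprocessor` is a fit/transform step (training-fold
statistics only): it drops features with excessive missingness or zero
variance, median/mode-imputes, standardizes numerics and one-hot encodes
categoricals, and keeps a report of everything it dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURES, get_feature
from .synthetic import Cohort

__all__ = [
    "apply_inclusion_filters",
    "select_single_visit",
    "derive_longitudinal_features",
    "FeaturePreprocessor",
    "MIN_AGE",
    "AUTOPSY_AGE_THRESHOLD",
]

MIN_AGE = 60.0
#: Methods-text default; the figure legend of the source design used 70.
AUTOPSY_AGE_THRESHOLD = 65.0

_META_COLS = ("participant_id", "visit_index", "years_before_death", "cognitive_status")


class EmptyCohortWarning(UserWarning):
    pass


def select_single_visit(visits: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One randomly selected visit per participant (seeded)."""
    rng = np.random.default_rng(seed)
    picked = visits.groupby("participant_id", sort=True).sample(
        n=1, random_state=np.random.RandomState(rng.integers(2**31))
    )
    return picked.reset_index(drop=True)


def apply_inclusion_filters(
    cohort: Cohort,
    dataset_kind: str,
    seed: int = 0,
    min_age: float = MIN_AGE,
    autopsy_age_threshold: float = AUTOPSY_AGE_THRESHOLD,
    min_visits: int = 3,
    max_visits: int = 7,
) -> pd.DataFrame:
    """Build the generalized or t_minus analysis set from a cohort.

    ``generalized``: non-autopsy participants with at least one visit at or
    after ``min_age``; returns one randomly selected eligible visit per
    participant.  ``t_minus``: autopsy participants with autopsy at or after
    ``autopsy_age_threshold`` and between ``min_visits`` and ``max_visits``
    visits; returns all their visits.  The filters are idempotent.
    """
    if dataset_kind not in ("generalized", "t_minus"):
        raise ValueError(f"dataset_kind must be 'generalized' or 't_minus', got {dataset_kind!r}")
    parts, visits = cohort.participants, cohort.visits
    if dataset_kind == "generalized":
        keep_ids = set(parts.loc[~parts["autopsy"].astype(bool), "participant_id"])
        eligible = visits[
            visits["participant_id"].isin(keep_ids) & (visits["age_at_visit"] >= min_age)
        ]
        out = select_single_visit(eligible, seed) if len(eligible) else eligible.copy()
    else:
        auto = parts[parts["autopsy"].astype(bool)]
        auto = auto[auto["age_at_death"] >= autopsy_age_threshold]
        keep_ids = set(auto["participant_id"])
        v = visits[visits["participant_id"].isin(keep_ids)]
        counts = v.groupby("participant_id")["visit_index"].size()
        ok = counts[(counts >= min_visits) & (counts <= max_visits)].index
        out = v[v["participant_id"].isin(ok)].copy()
    if out.empty:
        warnings.warn(
            f"inclusion filters produced an empty {dataset_kind} set", EmptyCohortWarning
        )
    return out.reset_index(drop=True)


def _ols_slope(t: np.ndarray, x: np.ndarray) -> float:
    mask = ~(np.isnan(t) | np.isnan(x))
    if mask.sum() < 2:
        return np.nan
    t, x = t[mask], x[mask]
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0.0:
        return np.nan
    return float((tc * (x - x.mean())).sum() / denom)


def derive_longitudinal_features(
    visits: pd.DataFrame, min_visits: int = 3
) -> pd.DataFrame:
    """Per-participant trend/variability summaries over visits.

    Only participants with at least ``min_visits`` visits are summarized.
    Numeric feature ``f`` yields ``f__baseline``, ``f__recent``,
    ``f__slope`` (per year toward death) and ``f__sd``; categorical ``f``
    yields ``f__mode`` and ``f__changed``.  The time axis is
    ``-years_before_death`` where available (autopsy participants) and
    years since first visit otherwise, so slopes share units either way.
    An all-missing feature produces missing derived entries.
    """
    counts = visits.groupby("participant_id")["visit_index"].size()
    keep = counts[counts >= min_visits].index
    visits = visits[visits["participant_id"].isin(keep)]
    feat_defs = [f for f in FEATURES if f.name in visits.columns]

    rows = []
    for pid, g in visits.groupby("participant_id", sort=True):
        g = g.sort_values("visit_index")
        ybd = g["years_before_death"].to_numpy(dtype=float)
        if np.isnan(ybd).all():
            t = g["age_at_visit"].to_numpy(dtype=float)
            t = t - t[0]
        else:
            t = -ybd
        rec: dict[str, object] = {"participant_id": pid}
        for f in feat_defs:
            col = g[f.name]
            if f.kind == "categorical":
                observed = col.dropna()
                rec[f"{f.name}__mode"] = (
                    observed.mode().iloc[0] if len(observed) else np.nan
                )
                rec[f"{f.name}__changed"] = (
                    float(observed.nunique() > 1) if len(observed) else np.nan
                )
            else:
                x = col.to_numpy(dtype=float)
                obs = x[~np.isnan(x)]
                rec[f"{f.name}__baseline"] = x[~np.isnan(x)][0] if obs.size else np.nan
                rec[f"{f.name}__recent"] = obs[-1] if obs.size else np.nan
                rec[f"{f.name}__slope"] = _ols_slope(t, x)
                rec[f"{f.name}__sd"] = float(np.std(obs, ddof=1)) if obs.size >= 2 else (
                    0.0 if obs.size == 1 else np.nan
                )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("participant_id") if rows else pd.DataFrame()


def _base_feature(column: str):
    name = column.split("__")[0]
    try:
        return get_feature(name)
    except KeyError:
        return None


@dataclass
class FeaturePreprocessor:
    """Leakage-safe feature matrix builder.

    Fit on training rows only; ``transform`` then applies the frozen
    statistics to any rows.  Features whose training missingness exceeds
    ``missing_threshold`` and zero-variance features are dropped and listed
    in ``report``.
    """

    tiers: frozenset[int] = frozenset({1, 2, 3})
    missing_threshold: float = 0.3
    standardize: bool = True
    #: keep numeric columns that are not part of the clinical schema
    #: (ad-hoc matrices, e.g. designed simulation features)
    include_unknown: bool = False
    report: dict = field(default_factory=dict, init=False)
    _numeric: list = field(default_factory=list, init=False)
    _categorical: list = field(default_factory=list, init=False)
    _stats: dict = field(default_factory=dict, init=False)
    _categories: dict = field(default_factory=dict, init=False)
    _fitted: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        tiers = set(self.tiers)
        if not tiers:
            raise ValueError("tier selection must be nonempty")
        if tiers - {1, 2, 3}:
            raise ValueError(f"unknown tiers {sorted(tiers - {1, 2, 3})}")
        self.tiers = frozenset(tiers)

    def _candidate_columns(self, df: pd.DataFrame) -> list[str]:
        cols = []
        for c in df.columns:
            if c in _META_COLS:
                continue
            f = _base_feature(c)
            if f is not None and f.tier in self.tiers:
                cols.append(c)
            elif f is None and self.include_unknown:
                cols.append(c)
        return cols

    def fit(self, train: pd.DataFrame) -> "FeaturePreprocessor":
        dropped: list[tuple[str, str]] = []
        self._numeric, self._categorical = [], []
        self._stats, self._categories = {}, {}
        for c in self._candidate_columns(train):
            f = _base_feature(c)
            col = train[c]
            miss = float(col.isna().mean())
            if miss > self.missing_threshold:
                dropped.append((c, f"missingness {miss:.2f} > {self.missing_threshold}"))
                continue
            kind = f.kind if f is not None else (
                "categorical" if col.dtype == object else "numeric"
            )
            if kind == "categorical" and not c.endswith("__changed"):
                observed = col.dropna()
                if observed.nunique() <= 1:
                    dropped.append((c, "zero variance"))
                    continue
                self._categorical.append(c)
                self._categories[c] = sorted(observed.unique().tolist())
                self._stats[c] = {"mode": observed.mode().iloc[0]}
            else:
                vals = pd.to_numeric(col, errors="coerce")
                sd = float(vals.std(ddof=0))
                if not np.isfinite(sd) or sd == 0.0:
                    dropped.append((c, "zero variance"))
                    continue
                self._numeric.append(c)
                self._stats[c] = {
                    "median": float(vals.median()),
                    "mean": float(vals.mean()),
                    "sd": sd,
                }
        self.report = {
            "dropped": dropped,
            "n_numeric": len(self._numeric),
            "n_categorical": len(self._categorical),
            "tiers": sorted(self.tiers),
        }
        self._fitted = True
        return self

    @property
    def feature_names_(self) -> list[str]:
        names = list(self._numeric)
        for c in self._categorical:
            names.extend(f"{c}={cat}" for cat in self._categories[c])
        return names

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("preprocessor not fitted")
        blocks = []
        for c in self._numeric:
            vals = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
            s = self._stats[c]
            vals = np.where(np.isnan(vals), s["median"], vals)
            if self.standardize:
                vals = (vals - s["mean"]) / s["sd"]
            blocks.append(vals[:, None])
        for c in self._categorical:
            col = df[c].fillna(self._stats[c]["mode"])
            for cat in self._categories[c]:
                blocks.append((col == cat).to_numpy(dtype=float)[:, None])
        if not blocks:
            raise ValueError("no usable features after preprocessing")
        return np.hstack(blocks)

    def fit_transform(self, train: pd.DataFrame) -> np.ndarray:
        return self.fit(train).transform(train)
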