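"""Feature importance: leave-one-covariate-out (LOCO) and permutation.

LOCO importance of a feature is the cross-validated drop in macro ROC-AUC
when the model is *retrained* without that feature, normalized by the full
model's AUC: ``(AUC_full - AUC_without) / AUC_full`` per fold.  A feature
is deemed important when the 95% confidence interval of its importance
lies entirely above the chance line at zero — removing it reliably costs
performance.  The cheaper permutation comparator shuffles one feature at a
time on held-out folds without retraining; both methods share the same
normalization so their rankings are directly comparable.

Confidence intervals are percentile intervals over fold-level replicates
(LOCO) or repeat-level replicates (permutation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import FeaturePreprocessor
from .features import get_feature
from .prediction import macro_ovr_auc, make_model

__all__ = ["loco_importance", "permutation_importance"]


def _mean_percentile_ci(
    vals: np.ndarray, ci: float, rng: np.random.Generator, n_boot: int = 2000
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean over replicate values.

    Used for both fold-level (LOCO) and repeat-level (permutation)
    replicates; its width shrinks with the number of replicates.
    """
    vals = np.asarray(vals, dtype=float)
    if len(vals) == 1:
        return float(vals[0]), float(vals[0])
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _tier_of(column: str) -> int | None:
    try:
        return get_feature(column.split("__")[0]).tier
    except KeyError:
        return None  # ad-hoc feature outside the clinical schema


def _usable_features(features: pd.DataFrame, tiers: frozenset[int]) -> list[str]:
    names = []
    for c in features.columns:
        base = c.split("__")[0]
        try:
            f = get_feature(base)
        except KeyError:
            continue
        if f.tier in tiers:
            names.append(c)
    return names


def _fold_models(features, y, tiers, model_name, nfolds, seed, model_kwargs,
                 drop: str | None = None):
    """Per-fold (model, preprocessor, test ids, auc); optionally omit a column."""
    cols = [c for c in features.columns if c != drop]
    X_df = features[cols]
    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    out = []
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        pp = FeaturePreprocessor(tiers=tiers, include_unknown=True).fit(X_df.iloc[tr])
        model = make_model(model_name, seed + k, **(model_kwargs or {}))
        model.fit(pp.transform(X_df.iloc[tr]), np.asarray(y)[tr])
        proba = model.predict_proba(pp.transform(X_df.iloc[te]))
        order = [list(model.classes_).index(c) for c in classes]
        auc = macro_ovr_auc(np.asarray(y)[te], proba[:, order], classes)
        out.append({"model": model, "pp": pp, "te": te, "auc": auc})
    return out


def loco_importance(
    features: pd.DataFrame,
    y: pd.Series | np.ndarray,
    feature_list: list[str] | None = None,
    tiers: frozenset[int] = frozenset({1, 2, 3}),
    model_name: str = "logistic",
    nfolds: int = 5,
    seed: int = 0,
    ci: float = 0.95,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-covariate-out importance with per-feature 95% CIs.

    For every feature the model is retrained on each training fold without
    it and scored on the paired test fold; the table has one row per
    feature with mean relative importance, CI bounds and the significance
    flag (CI lower bound above zero).
    """
    if nfolds < 2:
        raise ValueError("need at least 2 folds")
    feats = feature_list or _usable_features(features, tiers)
    missing = [f for f in feats if f not in features.columns]
    if missing:
        raise KeyError(f"features absent from schema: {missing}")
    full = _fold_models(features, y, tiers, model_name, nfolds, seed, model_kwargs)
    full_aucs = np.array([f["auc"] for f in full])
    ci_rng = np.random.default_rng(seed)
    rows = []
    for name in feats:
        wo = _fold_models(features, y, tiers, model_name, nfolds, seed,
                          model_kwargs, drop=name)
        wo_aucs = np.array([f["auc"] for f in wo])
        imp = (full_aucs - wo_aucs) / full_aucs
        lo, hi = _mean_percentile_ci(imp, ci, ci_rng)
        rows.append(
            {
                "feature": name,
                "tier": _tier_of(name),
                "importance": float(imp.mean()),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "significant": bool(lo > 0),
                "method": "loco",
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("importance", ascending=False).reset_index(drop=True)


def permutation_importance(
    features: pd.DataFrame,
    y: pd.Series | np.ndarray,
    feature_list: list[str] | None = None,
    tiers: frozenset[int] = frozenset({1, 2, 3}),
    model_name: str = "logistic",
    nfolds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    ci: float = 0.95,
    model_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Permutation importance on held-out folds (no retraining).

    Each repeat shuffles one raw feature column within the test fold before
    preprocessing, so derived one-hot columns stay consistent; importance
    shares LOCO's normalization.  CIs are percentile intervals over
    repeat-level replicates.
    """
    feats = feature_list or _usable_features(features, tiers)
    missing = [f for f in feats if f not in features.columns]
    if missing:
        raise KeyError(f"features absent from schema: {missing}")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    classes = np.unique(y)
    full = _fold_models(features, y, tiers, model_name, nfolds, seed, model_kwargs)
    full_aucs = np.array([f["auc"] for f in full])
    ci_rng = np.random.default_rng(seed)
    rows = []
    for name in feats:
        rep_imps = np.empty(n_repeats)
        for r in range(n_repeats):
            drops = []
            for f in full:
                te = f["te"]
                test_df = features.iloc[te].copy()
                test_df[name] = test_df[name].sample(
                    frac=1.0, random_state=int(rng.integers(2**31))
                ).to_numpy()
                proba = f["model"].predict_proba(f["pp"].transform(test_df))
                order = [list(f["model"].classes_).index(c) for c in classes]
                drops.append(macro_ovr_auc(y[te], proba[:, order], classes))
            rep_imps[r] = float(((full_aucs - np.array(drops)) / full_aucs).mean())
        lo, hi = _mean_percentile_ci(rep_imps, ci, ci_rng)
        rows.append(
            {
                "feature": name,
                "tier": _tier_of(name),
                "importance": float(rep_imps.mean()),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "significant": bool(lo > 0),
                "method": "permutation",
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
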