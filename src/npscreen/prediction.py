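"""Prediction tasks, evaluation, the condition grid, and repeated-measures ANOVA.

The prediction problem is 3-class: none/low vs medium vs high neuropathology
load, for each of the three load targets (total, amyloid, cerebrovascular).
Performance is summarized as macro one-vs-rest ROC-AUC — the mean of the
per-class AUCs treating each load level against the rest — alongside
per-class precision (PPV), recall and F1 from the pooled confusion matrix.

``run_condition_grid`` evaluates the semi-supervised classifier over the
full factorial design of 3 feature-tier sets x 2 visit modes x 3 targets
with one shared stratified fold partition per target, so that fold-level
AUCs are paired across conditions.  The tier x visit design is then tested
with a two-way repeated-measures ANOVA (folds as the blocking unit; with 5
folds the tier effect has df (2, 8) and the visit effect df (1, 4)),
followed by post-hoc one-way ANOVAs on the tier effect within each visit
mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort import FeaturePreprocessor, derive_longitudinal_features
from .ssl import SemiSupervisedVAEClassifier

__all__ = [
    "PredictionTask",
    "EvaluationResult",
    "AnovaResult",
    "macro_ovr_auc",
    "evaluate_predictions",
    "fit_baselines",
    "make_model",
    "run_condition_grid",
    "GridResult",
    "rm_anova",
    "posthoc_tier_anova",
]

TARGETS = ("total_load", "amyloid_load", "cerebrovascular_load")
TIER_SETS = (frozenset({1}), frozenset({1, 2}), frozenset({1, 2, 3}))
VISIT_MODES = ("single", "longitudinal")


@dataclass(frozen=True)
class PredictionTask:
    target: str
    tiers: frozenset[int]
    visit_mode: str

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.visit_mode not in VISIT_MODES:
            raise ValueError(f"unknown visit mode {self.visit_mode!r}")

    @property
    def tier_label(self) -> str:
        return "".join(str(t) for t in sorted(self.tiers))


@dataclass
class EvaluationResult:
    task: PredictionTask
    model_name: str
    fold_aucs: list[float]
    per_class: pd.DataFrame  # precision/recall/f1/support per load level
    confusion: np.ndarray
    classes: list[str]
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float


def macro_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Macro one-vs-rest ROC-AUC over the classes present in ``y_true``.

    Classes absent from the fold are skipped with a warning (their
    one-vs-rest AUC is undefined) and the macro average runs over the rest.
    """
    y_true = np.asarray(y_true)
    aucs = []
    for i, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c!r} absent from fold; skipped in macro AUC")
            continue
        aucs.append(roc_auc_score(pos.astype(int), proba[:, i]))
    if not aucs:
        raise ValueError("no class with both positives and negatives in fold")
    return float(np.mean(aucs))


def evaluate_predictions(
    y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray
) -> dict:
    """AUC plus per-class PPV/recall/F1 and the confusion matrix."""
    y_pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    return {
        "auc": macro_ovr_auc(y_true, proba, classes),
        "per_class": pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=list(classes),
        ),
        "confusion": confusion_matrix(y_true, y_pred, labels=classes),
    }


def make_model(name: str, seed: int, **kwargs):
    """Instantiate one of the pipeline's classifiers by name."""
    if name == "ssl":
        return SemiSupervisedVAEClassifier(seed=seed, **kwargs)
    if name == "logistic":
        return LogisticRegression(max_iter=5000, random_state=seed, **kwargs)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=400, min_samples_leaf=3, random_state=seed, **kwargs
        )
    if name == "gradient_boosting":
        return HistGradientBoostingClassifier(
            max_depth=3, learning_rate=0.08, max_iter=250, min_samples_leaf=20,
            l2_regularization=1.0, random_state=seed, **kwargs
        )
    raise ValueError(f"unknown model {name!r}")


def fit_baselines(X: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """Fit the three supervised baselines on one training set."""
    out = {}
    for name in ("logistic", "random_forest", "gradient_boosting"):
        out[name] = make_model(name, seed).fit(X, y)
    return out


# ----------------------------------------------------------------------
# condition grid


def _single_visit_features(visits: pd.DataFrame, seed: int) -> pd.DataFrame:
    rng = np.random.RandomState(seed)
    picked = visits.groupby("participant_id", sort=True).sample(1, random_state=rng)
    return picked.set_index("participant_id")


def _longitudinal_features(visits: pd.DataFrame) -> pd.DataFrame:
    return derive_longitudinal_features(visits)


@dataclass
class GridResult:
    """Fold-level AUC table plus full evaluations for the condition grid."""

    cells: pd.DataFrame  # target, tiers, visit_mode, fold, auc
    evaluations: list[EvaluationResult] = field(default_factory=list)

    def mean_table(self) -> pd.DataFrame:
        return (
            self.cells.groupby(["target", "tiers", "visit_mode"])["auc"]
            .mean()
            .reset_index()
        )


def run_condition_grid(
    labeled_visits: pd.DataFrame,
    labels: pd.DataFrame,
    unlabeled_visits: pd.DataFrame | None = None,
    targets=TARGETS,
    tier_sets=TIER_SETS,
    visit_modes=VISIT_MODES,
    nfolds: int = 5,
    seed: int = 0,
    model_name: str = "ssl",
    model_kwargs: dict | None = None,
) -> GridResult:
    """Evaluate the full tier x visit x target grid with shared folds.

    Parameters
    ----------
    labeled_visits
        All visits of the autopsy (t_minus) participants.
    labels
        Load-label table indexed by participant (``load_labels`` output).
    unlabeled_visits
        Visits of non-autopsy participants; the unlabeled pool for the
        semi-supervised model (ignored by supervised baselines).  Single
        mode uses one random visit per participant, longitudinal mode the
        participants with at least three visits.

    The fold partition is computed once per target on participant labels
    and reused across all tier/visit conditions (repeated-measures
    pairing); the single-visit draw is likewise frozen per participant.
    """
    model_kwargs = dict(model_kwargs or {})
    rng = np.random.default_rng(seed)
    ids = labels.index.to_numpy()
    labeled_visits = labeled_visits[labeled_visits["participant_id"].isin(set(ids))]

    # frozen per-mode feature tables (shared across targets and tiers)
    feat: dict[str, pd.DataFrame] = {}
    unlab: dict[str, pd.DataFrame | None] = {}
    sv_seed = int(rng.integers(2**31))
    for mode in visit_modes:
        if mode == "single":
            feat[mode] = _single_visit_features(labeled_visits, sv_seed)
            unlab[mode] = (
                _single_visit_features(unlabeled_visits, sv_seed)
                if unlabeled_visits is not None and len(unlabeled_visits)
                else None
            )
        else:
            feat[mode] = _longitudinal_features(labeled_visits)
            unlab[mode] = (
                _longitudinal_features(unlabeled_visits)
                if unlabeled_visits is not None and len(unlabeled_visits)
                else None
            )
    for mode in visit_modes:
        n_missing = len(labels.index.difference(feat[mode].index))
        if n_missing:
            warnings.warn(
                f"{n_missing} labeled participants have no {mode}-mode visits "
                "(e.g. removed by inclusion filters); they are dropped from "
                "the grid"
            )

    cells = []
    evaluations = []
    for target in targets:
        level_col = target.replace("_load", "_level")
        y_all = labels[level_col]
        folds_of: dict[str, np.ndarray] = {}
        skf = StratifiedKFold(
            n_splits=nfolds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        # one partition per target, defined on participants
        fold_assign = pd.Series(index=y_all.index, dtype=int)
        for k, (_, te) in enumerate(skf.split(np.zeros(len(y_all)), y_all)):
            fold_assign.iloc[te] = k
        classes = np.unique(y_all)

        for tiers in tier_sets:
            for mode in visit_modes:
                X_df = feat[mode]
                common = y_all.index.intersection(X_df.index)
                y = y_all.loc[common]
                fa = fold_assign.loc[common]
                fold_aucs = []
                y_true_all, proba_all = [], []
                for k in range(nfolds):
                    tr_ids = common[(fa != k).to_numpy()]
                    te_ids = common[(fa == k).to_numpy()]
                    pp = FeaturePreprocessor(tiers=tiers).fit(X_df.loc[tr_ids])
                    Xtr = pp.transform(X_df.loc[tr_ids])
                    Xte = pp.transform(X_df.loc[te_ids])
                    mseed = int(rng.integers(2**31))
                    model = make_model(model_name, mseed, **model_kwargs)
                    if model_name == "ssl":
                        Xu = (
                            pp.transform(unlab[mode])
                            if unlab[mode] is not None
                            else None
                        )
                        model.fit(Xtr, y.loc[tr_ids].to_numpy(), Xu)
                    else:
                        model.fit(Xtr, y.loc[tr_ids].to_numpy())
                    proba = model.predict_proba(Xte)
                    # align column order to the global class list
                    order = [list(model.classes_).index(c) for c in classes]
                    proba = proba[:, order]
                    fold_aucs.append(
                        macro_ovr_auc(y.loc[te_ids].to_numpy(), proba, classes)
                    )
                    y_true_all.append(y.loc[te_ids].to_numpy())
                    proba_all.append(proba)
                ev = evaluate_predictions(
                    np.concatenate(y_true_all), np.vstack(proba_all), classes
                )
                task = PredictionTask(target, tiers, mode)
                evaluations.append(
                    EvaluationResult(
                        task=task,
                        model_name=model_name,
                        fold_aucs=fold_aucs,
                        per_class=ev["per_class"],
                        confusion=ev["confusion"],
                        classes=list(classes),
                        seed=seed,
                    )
                )
                for k, a in enumerate(fold_aucs):
                    cells.append(
                        {
                            "target": target,
                            "tiers": task.tier_label,
                            "visit_mode": mode,
                            "fold": k,
                            "auc": a,
                        }
                    )
    return GridResult(pd.DataFrame(cells), evaluations)


# ----------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova(cell_table: pd.DataFrame) -> list[AnovaResult]:
    """Two-way repeated-measures ANOVA on fold-level AUCs.

    ``cell_table`` needs columns ``tiers``, ``visit_mode``, ``fold`` and
    ``auc`` for one target, with every (tier, visit) cell holding the same
    folds (balanced, paired).  Folds are the blocking unit; each effect is
    tested against its own effect x fold interaction, the standard
    within-subject error term.
    """
    pivot = cell_table.pivot_table(
        index="fold", columns=["tiers", "visit_mode"], values="auc"
    )
    if pivot.isna().any().any():
        raise ValueError("unbalanced grid: every cell must contain every fold")
    tiers = sorted({c[0] for c in pivot.columns})
    modes = sorted({c[1] for c in pivot.columns})
    a, b, n = len(tiers), len(modes), pivot.shape[0]
    if a < 2 or b < 2 or n < 2:
        raise ValueError("need at least 2 levels per factor and 2 folds")
    y = np.empty((n, a, b))
    for i, t in enumerate(tiers):
        for j, m in enumerate(modes):
            y[:, i, j] = pivot[(t, m)].to_numpy()

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * ((m_a - gm) ** 2).sum()
    ss_b = n * a * ((m_b - gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = b * ((m_as - m_s[:, None] - m_a[None, :] + gm) ** 2).sum()
    ss_bs = a * ((m_bs - m_s[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_tot = ((y - gm) ** 2).sum()
    ss_s = a * b * ((m_s - gm) ** 2).sum()
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    out = []
    # sums of squares below this are floating-point residue of a constant
    # table, not real variation
    tiny = 1e-12 * max(1.0, gm**2)
    for effect, ss, df1, ss_err, df2 in (
        ("tier", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        ("visit", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms, ms_err = ss / df1, ss_err / df2
        if ms_err <= tiny:
            F = 0.0 if ms <= tiny else np.inf
            p = 1.0 if ms <= tiny else 0.0
        else:
            F = ms / ms_err
            p = float(stats.f.sf(F, df1, df2))
        out.append(AnovaResult(effect, float(F), df1, df2, p))
    return out


def posthoc_tier_anova(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Post-hoc one-way ANOVA of the tier effect within each visit mode."""
    rows = []
    for mode, g in cell_table.groupby("visit_mode"):
        groups = [gg["auc"].to_numpy() for _, gg in g.groupby("tiers")]
        F, p = stats.f_oneway(*groups)
        df1 = len(groups) - 1
        df2 = sum(len(x) for x in groups) - len(groups)
        rows.append({"visit_mode": mode, "F": float(F), "df1": df1, "df2": df2, "p": float(p)})
    return pd.DataFrame(rows)
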