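"""Canonical evaluation protocols on synthetic cohorts.

Two fixed experimental recipes used as the package's standard controls:

* :func:`null_chance_auc` — the negative control: cross-validated macro
  ROC-AUC of the semi-supervised classifier on a cohort whose features are
  statistically independent of the load labels.  Chance is 0.5.
* :func:`planted_signal_grid` — the positive control: the full 3 targets x
  3 tier sets x 2 visit modes condition grid on a cohort with the default
  planted feature-pathology associations (standardized informative-feature
  shift of about 0.8 between the none/low and high load classes).

Both derive every random choice from a single seed.
"""

from __future__ import annotations

import zlib

import numpy as np

from .cohort import apply_inclusion_filters
from .config import CohortConfig
from .lesions import load_labels
from .prediction import GridResult, run_condition_grid
from .synthetic import generate_cohort, generate_null_cohort

__all__ = ["null_chance_auc", "planted_signal_grid"]


def _sub_seed(seed: int, tag: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def _prepare(config: CohortConfig, null: bool, seed: int):
    cohort = (generate_null_cohort if null else generate_cohort)(config)
    labels, _ = load_labels(cohort.neuropathology)
    t_minus = apply_inclusion_filters(cohort, "t_minus", seed=_sub_seed(seed, "tm"))
    auto = set(cohort.participants.loc[cohort.participants["autopsy"], "participant_id"])
    unlabeled_visits = cohort.visits[~cohort.visits["participant_id"].isin(auto)]
    return t_minus, labels, unlabeled_visits


def null_chance_auc(
    seed: int,
    n_labeled: int = 800,
    n_unlabeled: int = 3000,
    nfolds: int = 5,
    target: str = "total_load",
    epochs: int = 60,
) -> dict:
    """Cross-validated macro ROC-AUC of the SSL model on a null cohort.

    All feature-side effect sizes are zero, so the expected value is the
    chance level 0.5.
    """
    cfg = CohortConfig(n_unlabeled=n_unlabeled, n_labeled=n_labeled,
                       seed=_sub_seed(seed, "cohort"))
    t_minus, labels, unl = _prepare(cfg, null=True, seed=seed)
    grid = run_condition_grid(
        t_minus, labels, unl,
        targets=(target,),
        tier_sets=(frozenset({1, 2, 3}),),
        visit_modes=("single",),
        nfolds=nfolds,
        seed=_sub_seed(seed, "grid"),
        model_name="ssl",
        model_kwargs={"epochs": epochs},
    )
    fold_aucs = grid.evaluations[0].fold_aucs
    return {
        "mean_auc": float(np.mean(fold_aucs)),
        "fold_aucs": fold_aucs,
        "n_labeled": int(len(labels)),
    }


def planted_signal_grid(
    seed: int,
    n_labeled: int = 800,
    n_unlabeled: int = 3000,
    nfolds: int = 5,
    epochs: int = 40,
) -> tuple[GridResult, float]:
    """The full condition grid on a planted-signal cohort.

    Returns the grid result and the minimum of the 18 mean macro ROC-AUCs.
    """
    cfg = CohortConfig(n_unlabeled=n_unlabeled, n_labeled=n_labeled,
                       seed=_sub_seed(seed, "cohort"))
    t_minus, labels, unl = _prepare(cfg, null=False, seed=seed)
    grid = run_condition_grid(
        t_minus, labels, unl,
        nfolds=nfolds,
        seed=_sub_seed(seed, "grid"),
        model_name="ssl",
        model_kwargs={"epochs": epochs},
    )
    min_auc = float(grid.mean_table()["auc"].min())
    return grid, min_auc
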