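"""Config-driven end-to-end runs with a manifest.

``run_pipeline`` executes simulate -> prepare -> cluster -> enrich ->
predict -> importance -> associate on one synthetic cohort, writing plain
CSV/JSON artifacts to a run directory.  A single global seed determines
every stochastic choice (generation, visit selection, folds, network
initialization, bootstrap), and the run manifest records the config hash,
derived seeds, load-level cutoffs, dropped features and stage runtimes.
Stages are resumable: existing outputs are reused unless ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, bootstrap, clustering, prediction
from .cohort import apply_inclusion_filters
from .config import CohortConfig
from .importance import loco_importance, permutation_importance
from .lesions import LESION_CODES, binarize_panel, load_labels
from .synthetic import Cohort, generate_cohort, generate_null_cohort, read_cohort, write_cohort

__all__ = ["run_pipeline", "PIPELINE_STAGES"]

log = logging.getLogger("npscreen")

PIPELINE_STAGES = (
    "simulate", "prepare", "cluster", "enrich", "predict", "importance", "associate",
)


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(
    config: CohortConfig | str | Path,
    out: str | Path,
    seed: int = 0,
    stages=PIPELINE_STAGES,
    null_cohort: bool = False,
    bootstrap_B: int = 30000,
    confidence: float = 0.999,
    nfolds: int = 5,
    model_name: str = "ssl",
    cluster_tiers: frozenset[int] = frozenset({1}),
    importance_model: str = "logistic",
    importance_method: str = "loco",
    force: bool = False,
) -> dict:
    """Run the pipeline stages and return the manifest dictionary."""
    cfg = config if isinstance(config, CohortConfig) else CohortConfig.from_file(config)
    cfg = cfg.replace(seed=_stage_seed(seed, "simulate"))
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {
        "seed": seed,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "null_cohort": null_cohort,
        "stages": {},
    }

    cohort: Cohort | None = None

    def need(stage: str) -> bool:
        return stage in stages

    def get_cohort() -> Cohort:
        nonlocal cohort
        if cohort is None:
            cohort = read_cohort(out)
        return cohort

    # -- simulate -------------------------------------------------------
    if need("simulate"):
        t0 = time.time()
        if force or not (out / "participants.csv").exists():
            gen = generate_null_cohort if null_cohort else generate_cohort
            cohort = gen(cfg)
            write_cohort(cohort, out)
            log.info("simulate: wrote cohort to %s", out)
        else:
            log.info("simulate: reusing existing cohort in %s", out)
        manifest["stages"]["simulate"] = {"runtime_s": round(time.time() - t0, 2)}

    # -- prepare --------------------------------------------------------
    if need("prepare"):
        t0 = time.time()
        c = get_cohort()
        labels, cutoffs = load_labels(c.neuropathology)
        labels.to_csv(out / "loads.csv")
        gen_set = apply_inclusion_filters(c, "generalized", seed=_stage_seed(seed, "generalized"))
        t_minus = apply_inclusion_filters(c, "t_minus", seed=_stage_seed(seed, "t_minus"))
        gen_set.to_csv(out / "generalized.csv", index=False)
        t_minus.to_csv(out / "t_minus.csv", index=False)
        from .cohort import FeaturePreprocessor

        pp_report = FeaturePreprocessor(tiers=frozenset({1, 2, 3})).fit(gen_set).report
        manifest["stages"]["prepare"] = {
            "runtime_s": round(time.time() - t0, 2),
            "load_cutoffs": {k: list(v) for k, v in cutoffs.items()},
            "dropped_features": pp_report["dropped"],
            "n_generalized": int(gen_set["participant_id"].nunique()),
            "n_t_minus": int(t_minus["participant_id"].nunique()),
            "n_labeled_usable": int(len(labels)),
        }

    # -- cluster --------------------------------------------------------
    if need("cluster"):
        t0 = time.time()
        gen_set = pd.read_csv(out / "generalized.csv")
        t_minus = pd.read_csv(out / "t_minus.csv")
        model = clustering.fit_cluster_model(
            gen_set, tiers=cluster_tiers, seed=_stage_seed(seed, "cluster")
        )
        clustering.rank_clusters(model, gen_set)
        traj = clustering.assign_trajectory(model, t_minus)
        traj.assignments.to_csv(out / "trajectories.csv", index=False)
        traj.visit_ranks.to_csv(out / "visit_ranks.csv", index=False)
        model.save(out / "cluster_model.json")
        manifest["stages"]["cluster"] = {
            "runtime_s": round(time.time() - t0, 2),
            "cluster_ranks": model.ranks,
            "unimpaired_proportions": model.rank_proportions,
            "group_sizes": traj.assignments["group"].value_counts().to_dict(),
            "n_excluded": traj.n_excluded,
        }

    # -- enrich ---------------------------------------------------------
    if need("enrich"):
        t0 = time.time()
        c = get_cohort()
        assignments = pd.read_csv(out / "trajectories.csv")
        statuses = binarize_panel(c.neuropathology)
        report = bootstrap.enrichment_table(
            assignments, statuses, B=bootstrap_B, confidence=confidence,
            seed=_stage_seed(seed, "enrich"),
        )
        report.lesions.to_csv(out / "enrichment.csv", index=False)
        report.domains.to_csv(out / "enrichment_domains.csv", index=False)
        manifest["stages"]["enrich"] = {
            "runtime_s": round(time.time() - t0, 2),
            "B": bootstrap_B,
            "confidence": confidence,
            "n_significant": int(report.lesions["significant"].sum()),
        }

    # -- predict --------------------------------------------------------
    if need("predict"):
        t0 = time.time()
        c = get_cohort()
        labels = pd.read_csv(out / "loads.csv", index_col=0)
        t_minus = pd.read_csv(out / "t_minus.csv")
        auto_ids = set(c.participants.loc[c.participants["autopsy"], "participant_id"])
        unl_visits = c.visits[~c.visits["participant_id"].isin(auto_ids)]
        grid = prediction.run_condition_grid(
            t_minus, labels, unl_visits, nfolds=nfolds,
            seed=_stage_seed(seed, "predict"), model_name=model_name,
        )
        grid.cells.to_csv(out / "grid_cells.csv", index=False)
        grid.mean_table().to_csv(out / "grid_means.csv", index=False)
        anova_rows = []
        for target, g in grid.cells.groupby("target"):
            for res in prediction.rm_anova(g):
                anova_rows.append({"target": target, **res.__dict__})
            ph = prediction.posthoc_tier_anova(g)
            ph.insert(0, "target", target)
            ph.to_csv(out / f"posthoc_{target}.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        manifest["stages"]["predict"] = {
            "runtime_s": round(time.time() - t0, 2),
            "model": model_name,
            "nfolds": nfolds,
            "min_mean_auc": float(grid.mean_table()["auc"].min()),
        }

    # -- importance -----------------------------------------------------
    if need("importance"):
        t0 = time.time()
        labels = pd.read_csv(out / "loads.csv", index_col=0)
        t_minus = pd.read_csv(out / "t_minus.csv")
        sv = prediction._single_visit_features(t_minus, _stage_seed(seed, "imp_visit"))
        common = labels.index.intersection(sv.index)
        imp_fn = loco_importance if importance_method == "loco" else permutation_importance
        imp = imp_fn(
            sv.loc[common], labels.loc[common, "total_level"],
            tiers=frozenset({1}), model_name=importance_model,
            seed=_stage_seed(seed, "importance"),
        )
        imp.to_csv(out / f"importance_{importance_method}.csv", index=False)
        manifest["stages"]["importance"] = {
            "runtime_s": round(time.time() - t0, 2),
            "top_features": imp.head(5)["feature"].tolist(),
        }

    # -- associate ------------------------------------------------------
    if need("associate"):
        t0 = time.time()
        c = get_cohort()
        statuses = binarize_panel(c.neuropathology)
        lesion_screen = associations.correlation_matrix(statuses)
        lesion_screen.r.to_csv(out / "assoc_lesion_r.csv")
        lesion_screen.masked_r.to_csv(out / "assoc_lesion_masked.csv")
        sv = prediction._single_visit_features(
            pd.read_csv(out / "t_minus.csv"), _stage_seed(seed, "assoc_visit")
        )
        common = statuses.index.intersection(sv.index)
        num_cols = [c_ for c_ in sv.columns if sv[c_].dtype != object
                    and c_ not in ("visit_index", "years_before_death")]
        feat_screen = associations.correlation_matrix(
            sv.loc[common, num_cols], statuses.loc[common]
        )
        feat_screen.r.to_csv(out / "assoc_feature_r.csv")
        feat_screen.masked_r.to_csv(out / "assoc_feature_masked.csv")
        order, _ = associations.order_matrix(lesion_screen.r)
        manifest["stages"]["associate"] = {
            "runtime_s": round(time.time() - t0, 2),
            "lesion_order": list(order),
            "n_feature_tests": feat_screen.n_tests,
        }

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
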