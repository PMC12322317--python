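"""Representative clustering and trajectory-group classification.

The clustering pipeline learns the broad clinical landscape from the
generalized (non-autopsy) set: an a-priori feature selection (tier filter
plus optional whitelist), an autoencoder embedding (two encoder layers to
a small bottleneck), and a Gaussian mixture model with K=3 components on
the embedded single-visit profiles.  Components are then ranked from least
(rank 1) to most clinically impaired by the proportion of members whose
clinician diagnosis is cognitively normal.

Autopsy participants are subsequently assigned to the predefined clusters
at every visit (hard argmax-posterior assignment), and each participant's
trajectory is classified from the first and final surviving visits after
discarding visits less than two years before death (volunteer bias close
to death):

* group A — moved to a less impaired cluster (final rank < first rank),
* group B — no net change (equal ranks),
* group C — moved to a more impaired cluster (final rank > first rank).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.neural_network import MLPRegressor

from .cohort import FeaturePreprocessor

__all__ = ["ClusterModel", "fit_cluster_model", "rank_clusters", "assign_trajectory",
           "TrajectoryResult"]


def _encode(ae: MLPRegressor, X: np.ndarray, bottleneck_layer: int) -> np.ndarray:
    """Activations at the autoencoder bottleneck (manual forward pass)."""
    h = X
    for i in range(bottleneck_layer):
        h = h @ ae.coefs_[i] + ae.intercepts_[i]
        h = np.tanh(h)
    return h


@dataclass
class ClusterModel:
    """Fitted embedding + mixture with clinical ranks.

    ``ranks`` maps GMM component index to rank in 1..K with 1 the least
    impaired; it is filled by :func:`rank_clusters`.
    """

    preprocessor: FeaturePreprocessor
    autoencoder: MLPRegressor
    gmm: GaussianMixture
    selected_feature_list: list[str]
    bottleneck_layer: int
    k: int
    seed: int
    ranks: dict[int, int] | None = None
    rank_proportions: dict[int, float] | None = None

    def embed(self, features: pd.DataFrame) -> np.ndarray:
        X = self.preprocessor.transform(features)
        return _encode(self.autoencoder, X, self.bottleneck_layer)

    def assign(self, features: pd.DataFrame) -> np.ndarray:
        """Hard component assignment (argmax posterior)."""
        return self.gmm.predict(self.embed(features))

    def posterior(self, features: pd.DataFrame) -> np.ndarray:
        return self.gmm.predict_proba(self.embed(features))

    def assign_ranks(self, features: pd.DataFrame) -> np.ndarray:
        if self.ranks is None:
            raise RuntimeError("clusters are not ranked yet; call rank_clusters")
        comp = self.assign(features)
        return np.array([self.ranks[c] for c in comp])

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the model bundle as JSON (weights as nested lists)."""
        d = {
            "k": self.k,
            "seed": self.seed,
            "bottleneck_layer": self.bottleneck_layer,
            "selected_feature_list": self.selected_feature_list,
            "ranks": self.ranks,
            "rank_proportions": self.rank_proportions,
            "ae_coefs": [c.tolist() for c in self.autoencoder.coefs_],
            "ae_intercepts": [c.tolist() for c in self.autoencoder.intercepts_],
            "gmm_weights": self.gmm.weights_.tolist(),
            "gmm_means": self.gmm.means_.tolist(),
            "gmm_covariances": self.gmm.covariances_.tolist(),
        }
        Path(path).write_text(json.dumps(d))


def fit_cluster_model(
    features: pd.DataFrame,
    tiers: frozenset[int] | set[int] = frozenset({1}),
    k: int = 3,
    seed: int = 0,
    feature_whitelist: list[str] | None = None,
    hidden: int = 32,
    bottleneck: int = 8,
    max_iter: int = 200,
) -> ClusterModel:
    """Fit the autoencoder + GMM pipeline on single-visit features.

    ``features`` is the generalized set (one row per participant).  The
    a-priori reduction keeps the selected tiers (and, if given, only the
    whitelisted features); the autoencoder (hidden -> bottleneck -> hidden)
    is trained by reconstruction loss, and the GMM is fit on the bottleneck
    embedding.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(features) < 10 * k:
        raise ValueError(f"need at least {10 * k} rows to fit {k} clusters")
    pp = FeaturePreprocessor(tiers=frozenset(tiers)).fit(features)
    if feature_whitelist is not None:
        keep = [c for c in pp._numeric if c.split("__")[0] in feature_whitelist]
        keep_cat = [c for c in pp._categorical if c.split("__")[0] in feature_whitelist]
        missing = set(feature_whitelist) - {
            c.split("__")[0] for c in (pp._numeric + pp._categorical)
        }
        if missing:
            warnings.warn(f"whitelisted features not available: {sorted(missing)}")
        pp._numeric, pp._categorical = keep, keep_cat
    X = pp.transform(features)

    # full-batch LBFGS keeps the fit deterministic and invariant to row
    # duplication (the mean reconstruction loss is unchanged)
    ae = MLPRegressor(
        hidden_layer_sizes=(hidden, bottleneck, hidden),
        activation="tanh",
        solver="lbfgs",
        random_state=seed,
        max_iter=max_iter,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        ae.fit(X, X)
    Z = _encode(ae, X, 2)
    gmm = GaussianMixture(
        n_components=k, covariance_type="full", random_state=seed, n_init=3,
        reg_covar=1e-5,
    ).fit(Z)
    return ClusterModel(
        preprocessor=pp,
        autoencoder=ae,
        gmm=gmm,
        selected_feature_list=pp.feature_names_,
        bottleneck_layer=2,
        k=k,
        seed=seed,
    )


def rank_clusters(
    model: ClusterModel,
    features: pd.DataFrame,
    cognitive_status: pd.Series | None = None,
    unimpaired_label: str = "normal",
) -> ClusterModel:
    """Rank components from least to most clinically impaired.

    Rank 1 goes to the component with the highest proportion of members
    whose clinician cognitive status equals ``unimpaired_label``; ties are
    broken by component index (and reported).  A component with no members
    in ``features`` is an error.
    """
    status = (
        cognitive_status
        if cognitive_status is not None
        else features["cognitive_status"]
    )
    comp = model.assign(features)
    status = np.asarray(status)
    props = {}
    for c in range(model.k):
        members = comp == c
        if not members.any():
            raise ValueError(f"cluster component {c} has no members; cannot rank")
        props[c] = float((status[members] == unimpaired_label).mean())
    if len(set(props.values())) < model.k:
        warnings.warn("tied unimpaired proportions; ranking ties broken by component index")
    # highest unimpaired proportion -> rank 1; ties keep component order
    order = sorted(range(model.k), key=lambda c: (-props[c], c))
    model.ranks = {c: r + 1 for r, c in enumerate(order)}
    model.rank_proportions = props
    return model


class TrajectoryResult(NamedTuple):
    assignments: pd.DataFrame  # participant_id, group, first_rank, final_rank, n_used
    visit_ranks: pd.DataFrame  # participant_id, visit_index, years_before_death, rank, used
    n_excluded: int


def assign_trajectory(
    model: ClusterModel,
    visits: pd.DataFrame,
    exclusion_window_years: float = 2.0,
    rule: str = "endpoint",
) -> TrajectoryResult:
    """Classify autopsy participants into trajectory groups A/B/C.

    Visits strictly less than ``exclusion_window_years`` before death are
    discarded; participants with no surviving visit are excluded and
    counted.  With the default endpoint rule the group compares the first
    and final surviving ranks; ``rule='mean'`` instead uses the sign of the
    least-squares slope of rank against time toward death.
    """
    if rule not in ("endpoint", "mean"):
        raise ValueError("rule must be 'endpoint' or 'mean'")
    if model.ranks is None:
        raise RuntimeError("rank_clusters must run before trajectory assignment")
    v = visits.copy()
    ranks = model.assign_ranks(v)
    v["rank"] = ranks
    v["used"] = v["years_before_death"] >= exclusion_window_years
    assignments = []
    n_excluded = 0
    for pid, g in v.groupby("participant_id", sort=True):
        used = g[g["used"]].sort_values("years_before_death", ascending=False)
        if used.empty:
            n_excluded += 1
            continue
        first, final = int(used["rank"].iloc[0]), int(used["rank"].iloc[-1])
        if rule == "endpoint":
            delta = final - first
        else:
            t = -used["years_before_death"].to_numpy(dtype=float)
            r = used["rank"].to_numpy(dtype=float)
            tc = t - t.mean()
            delta = float((tc * r).sum()) if (tc**2).sum() > 0 else 0.0
        group = "C" if delta > 0 else ("A" if delta < 0 else "B")
        assignments.append(
            {
                "participant_id": pid,
                "group": group,
                "first_rank": first,
                "final_rank": final,
                "n_used": int(len(used)),
            }
        )
    cols = ["participant_id", "visit_index", "years_before_death", "rank", "used"]
    return TrajectoryResult(pd.DataFrame(assignments), v[cols], n_excluded)
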