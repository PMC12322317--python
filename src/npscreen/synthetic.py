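"""Synthetic cohort generator.

Emulates the statistical structure of a longitudinal aging cohort with a
small autopsy (labeled) subset and a large non-autopsy (unlabeled) pool:

* three participant-level standard-normal latent factors — amyloid,
  cerebrovascular, and "other" pathology propensity — drive both the
  14-lesion autopsy panel (logistic links) and, weakly, the clinical
  features;
* amyloid-domain lesions load on the amyloid factor, cerebrovascular-domain
  lesions on the cerebrovascular factor, and Lewy body disease, sclerosis
  and TDP-43 on mixtures, reproducing a two-block lesion correlation
  structure whose strength is set by ``within_domain_correlation`` (a
  liability-scale correlation);
* lesion prevalence is age-dependent, with intercepts solved numerically so
  marginal prevalence matches the configured values exactly (quadrature over
  the latent and age distributions);
* clinical visits are spaced about a year apart with jitter; autopsy
  participants carry 3-7 visits indexed by years before death, and a
  per-visit clinician cognitive status (normal → dementia) that is monotone
  non-decreasing over time by construction;
* tiered clinical features are noisy functions of the latent factors, age
  and severity (schema in :mod:`npscreen.features`), with completely-at-
  random missingness.

``generate_null_cohort`` keeps every marginal but forces all feature-side
effect sizes to zero, making features statistically independent of the
lesion labels — the negative control for every downstream stage.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import CohortConfig
from .features import FEATURES, FeatureDef
from .lesions import LESION_CODES, LESION_PANEL

__all__ = ["Cohort", "generate_cohort", "generate_null_cohort", "write_cohort", "read_cohort"]

COGNITIVE_STATES = ("normal", "impaired-not-mci", "mci", "dementia")
_SEVERITY_CUTS = (0.4, 0.9, 1.5)

# Unit-norm factor loadings per lesion.  Lewy body disease sits at the edge
# of the amyloid block; sclerosis and TDP-43 are mixtures at the periphery.
_LESION_WEIGHTS: dict[str, dict[str, float]] = {
    **{c: {"amyloid": 1.0} for c in ("ADNC", "BRAAK", "DIFF", "NEUR", "CAA")},
    **{c: {"cerebrovascular": 1.0} for c in ("INF", "MICR", "HEM", "ARTE", "AVAS", "WMR")},
    "LEWY": {"amyloid": 0.8, "other": 0.6},
    "SCL": {"cerebrovascular": 0.55, "other": 0.835},
    "TDP": {"amyloid": 0.45, "cerebrovascular": 0.35, "other": 0.822},
}

# Per-lesion age slope on the logit scale per standardized-age unit.
# Cerebrovascular structural lesions rise fastest with age; Lewy body
# disease prevalence declines across years lived.
_AGE_SLOPES: dict[str, float] = {
    **{c: 0.4 for c in LESION_CODES},
    "ARTE": 0.6,
    "AVAS": 0.6,
    "WMR": 0.6,
    "LEWY": -0.3,
}


class Cohort(NamedTuple):
    """The three-table cohort layout."""

    participants: pd.DataFrame
    visits: pd.DataFrame
    neuropathology: pd.DataFrame


def _age_zscale(config: CohortConfig) -> tuple[float, float]:
    lo, hi = config.age_range
    return (lo + hi) / 2.0, (hi - lo) / 4.0


def _domain_loading(within_domain_correlation: float) -> float:
    """Factor loading (logit scale) giving the requested liability correlation.

    Two lesions sharing a factor with loading lam each have latent-liability
    correlation lam^2 / (lam^2 + pi^2/3) under the logistic link.
    """
    rho = within_domain_correlation
    if rho <= 0.0:
        return 0.0
    s2_logistic = np.pi**2 / 3.0
    return float(np.sqrt(rho / (1.0 - rho) * s2_logistic))


def _solve_intercept(prevalence: float, gauss_sd: float, age_slope: float,
                     age_z_bounds: tuple[float, float]) -> float:
    """Intercept b with E[sigmoid(b + gauss_sd*G + age_slope*U)] = prevalence.

    G is standard normal, U uniform over ``age_z_bounds``; the expectation is
    evaluated by Gauss-Hermite x Gauss-Legendre quadrature so the marginal
    prevalence matches the target to numerical precision.
    """
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(31)
    gh_w = gh_w / gh_w.sum()
    gl_x, gl_w = np.polynomial.legendre.leggauss(21)
    lo, hi = age_z_bounds
    u = 0.5 * (hi - lo) * gl_x + 0.5 * (hi + lo)
    gl_w = gl_w / gl_w.sum()
    grid = gauss_sd * gh_x[:, None] + age_slope * u[None, :]
    w = gh_w[:, None] * gl_w[None, :]

    def mean_prev(b: float) -> float:
        return float(np.sum(w * expit(b + grid))) - prevalence

    return brentq(mean_prev, -20.0, 20.0, xtol=1e-12)


def _sample_grades(rng: np.random.Generator, code: str, high: np.ndarray) -> np.ndarray:
    """Raw ordinal grades consistent with the sampled high/low status."""
    lesion = LESION_PANEL[code]
    low_grades = [g for g in lesion.scale if g in lesion.low_values]
    high_grades = [g for g in lesion.scale if g in lesion.high_values]
    out = np.empty(high.shape[0], dtype=object)
    n_low = int((~high).sum())
    out[~high] = rng.choice(low_grades, size=n_low)
    out[high] = rng.choice(high_grades, size=int(high.sum()))
    return out


def _saturate(x: np.ndarray) -> np.ndarray:
    return 1.5 * np.tanh(x / 1.2)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort (participants, visits, neuropathology) from the model.

    The seed in ``config`` fully determines all three tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_lab, n_unl = config.n_labeled, config.n_unlabeled
    n = n_lab + n_unl
    age_mid, age_scale = _age_zscale(config)
    age_lo, age_hi = config.age_range

    labeled = np.zeros(n, dtype=bool)
    labeled[:n_lab] = True
    pid = np.array([f"P{i + 1:06d}" for i in range(n)])

    # -- participant-level draws ---------------------------------------
    factors = {
        "amyloid": rng.standard_normal(n),
        "cerebrovascular": rng.standard_normal(n),
        "other": rng.standard_normal(n),
    }
    # autopsy participants: age at death; others: age at first visit
    age_death = rng.uniform(age_lo + 3.0, age_hi, size=n)
    age_baseline_unl = rng.uniform(age_lo - 5.0, age_hi - 2.0, size=n)

    # clinical severity tracks the dominant pathology (max blend) with a
    # smaller additive component, so cognitive decline is not a purely
    # linear readout of the latent factors
    sev_base = (
        0.35 * (factors["amyloid"] + 0.5 * factors["cerebrovascular"] + 0.45 * factors["other"])
        + 0.55 * np.maximum.reduce(
            [factors["amyloid"], 0.9 * factors["cerebrovascular"], 0.8 * factors["other"]]
        )
        + rng.normal(0.0, 0.6, size=n)
    )
    sev_drift = np.abs(rng.normal(0.0, 0.25, size=n)) + 0.1 * np.maximum(
        factors["amyloid"], 0.0
    )

    # -- visit skeleton ------------------------------------------------
    vmin, vmax = config.visit_count_range
    umin, umax = config.unlabeled_visit_count_range
    n_visits = np.where(
        labeled,
        rng.integers(vmin, vmax + 1, size=n),
        rng.integers(umin, umax + 1, size=n),
    )
    row_pid, row_owner = [], []
    visit_index = []
    for i in range(n):
        k = int(n_visits[i])
        row_owner.extend([i] * k)
        visit_index.extend(range(1, k + 1))
    row_owner = np.asarray(row_owner)
    visit_index = np.asarray(visit_index)
    row_pid = pid[row_owner]
    n_rows = row_owner.shape[0]
    jitter = rng.uniform(-0.25, 0.25, size=n_rows)

    k_of_owner = n_visits[row_owner]
    row_labeled = labeled[row_owner]
    # visit j of an autopsy participant with K visits sits ~(K - j + 1)
    # years before death; the newest visit is ~1 year out
    years_before_death = np.where(
        row_labeled, k_of_owner - visit_index + 1 + jitter, np.nan
    )
    age_at_visit = np.where(
        row_labeled,
        age_death[row_owner] - years_before_death,
        age_baseline_unl[row_owner] + (visit_index - 1) + jitter,
    )
    t_elapsed = (visit_index - 1).astype(float)
    severity = sev_base[row_owner] + sev_drift[row_owner] * t_elapsed
    cognitive_status = np.asarray(COGNITIVE_STATES, dtype=object)[
        np.searchsorted(_SEVERITY_CUTS, severity, side="right")
    ]
    age_z = (age_at_visit - age_mid) / age_scale

    # -- clinical features ----------------------------------------------
    es = config.latent_effect_sizes
    drivers_row = {
        "amyloid": factors["amyloid"][row_owner],
        "cerebrovascular": factors["cerebrovascular"][row_owner],
        "other": factors["other"][row_owner],
        "age": age_z,
        "severity": severity,
    }
    first_visit = visit_index == 1
    feat_cols: dict[str, np.ndarray] = {}

    # interaction channels: the factor signal is carried with a sign that
    # flips with a context indicator, so its marginal correlation is ~0
    _IX = {
        "ix_cvd": ("on_antihypertensive", "cerebrovascular"),
        "ix_amy": ("informant_available", "amyloid"),
    }

    def linear_part(f: FeatureDef) -> np.ndarray:
        lin = np.zeros(n_rows)
        for key, w in f.pattern.items():
            if key in _IX:
                carrier, factor = _IX[key]
                sign = np.where(feat_cols[carrier] > 0.5, 1.0, -1.0)
                scale = es.get((factor, f.modality), 0.0)
                lin = lin + w * scale * sign * drivers_row[factor]
            else:
                scale = es.get((key, f.modality), 0.0)
                lin = lin + w * scale * drivers_row[key]
        return lin

    for f in FEATURES:
        if f.name == "age_at_visit":
            feat_cols[f.name] = age_at_visit.copy()
            continue
        if f.kind == "categorical":
            if f.name == "sex":
                probs = [0.55, 0.45]
            elif f.name == "race":
                probs = [0.60, 0.15, 0.12, 0.08, 0.05]
            else:
                probs = [1.0 / len(f.categories)] * len(f.categories)
            per_part = rng.choice(np.asarray(f.categories, dtype=object), size=n, p=probs)
            feat_cols[f.name] = per_part[row_owner]
            continue
        if not f.per_visit:
            # stable participant-level value from first-visit drivers
            lin_rows = linear_part(f)
            lin_part = np.zeros(n)
            lin_part[row_owner[first_visit]] = lin_rows[first_visit]
            if f.kind == "binary":
                p = expit(1.6 * lin_part - 0.8)
                val_part = (rng.uniform(size=n) < p).astype(float)
            else:
                base = _saturate(lin_part) if f.transform == "saturate" else lin_part
                val_part = base + f.noise_sd * rng.standard_normal(n)
                if f.name == "education_years":
                    val_part = np.clip(np.round(14.0 + 2.5 * val_part), 6, 20)
                elif f.name == "bmi":
                    val_part = 27.0 + 4.0 * val_part
            feat_cols[f.name] = val_part[row_owner]
        else:
            lin = linear_part(f)
            if f.kind == "binary":
                p = expit(1.6 * lin - 0.8)
                feat_cols[f.name] = (rng.uniform(size=n_rows) < p).astype(float)
            else:
                base = _saturate(lin) if f.transform == "saturate" else lin
                feat_cols[f.name] = base + f.noise_sd * rng.standard_normal(n_rows)

    # completely-at-random missingness (age is always observed)
    for f in FEATURES:
        if f.name == "age_at_visit" or config.missingness_rate == 0.0:
            continue
        mask = rng.uniform(size=n_rows) < config.missingness_rate
        col = feat_cols[f.name]
        if f.kind == "categorical":
            col = col.astype(object)
            col[mask] = np.nan
        else:
            col = col.astype(float)
            col[mask] = np.nan
        feat_cols[f.name] = col

    visits = pd.DataFrame(
        {
            "participant_id": row_pid,
            "visit_index": visit_index,
            "years_before_death": years_before_death,
            "age_at_visit": age_at_visit,
            "cognitive_status": cognitive_status,
            **feat_cols,
        }
    )

    # -- neuropathology panel (labeled participants only) ----------------
    lam = _domain_loading(config.within_domain_correlation)
    zb = ((age_lo + 3.0 - age_mid) / age_scale, (age_hi - age_mid) / age_scale)
    age_z_death = (age_death[:n_lab] - age_mid) / age_scale
    np_cols: dict[str, np.ndarray] = {}
    for code in LESION_CODES:
        w = _LESION_WEIGHTS[code]
        shared = sum(w[k] * factors[k][:n_lab] for k in w)
        beta = _AGE_SLOPES[code] * config.lesion_age_slope_scale
        b = _solve_intercept(config.lesion_prevalence[code], lam, beta, zb)
        eta = b + lam * shared + beta * age_z_death
        high = rng.uniform(size=n_lab) < expit(eta)
        grades = _sample_grades(rng, code, high)
        if config.lesion_missingness_rate > 0.0:
            miss = rng.uniform(size=n_lab) < config.lesion_missingness_rate
            grades = grades.copy()
            grades[miss] = np.nan
        np_cols[code] = grades
    neuropathology = pd.DataFrame({"participant_id": pid[:n_lab], **np_cols})

    last_state = (
        visits.groupby("participant_id", sort=False)["cognitive_status"].last()
    )
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "autopsy": labeled,
            "age_at_death": np.where(labeled, age_death, np.nan),
            "n_visits": n_visits,
            "cognitive_status_final": last_state.reindex(pid).to_numpy(),
        }
    )
    return Cohort(participants, visits, neuropathology)


def generate_null_cohort(config: CohortConfig) -> Cohort:
    """A cohort with identical marginals but zero feature-lesion signal.

    All latent effect sizes on the feature side are forced to zero, so every
    clinical feature is statistically independent of the neuropathology
    labels; lesion prevalence and the lesion correlation block structure are
    unchanged.
    """
    null_es = {k: 0.0 for k in config.latent_effect_sizes}
    # also cover any (factor, modality) pair missing from the user's map
    from .config import DEFAULT_EFFECT_SIZES

    for k in DEFAULT_EFFECT_SIZES:
        null_es.setdefault(k, 0.0)
    # the age feature is always observed, so the age->lesion pathway must
    # also be cut for labels to be independent of every feature
    return generate_cohort(
        config.replace(latent_effect_sizes=null_es, lesion_age_slope_scale=0.0)
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write participants.csv, visits.csv and neuropathology.csv."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.csv", index=False)
    cohort.visits.to_csv(out / "visits.csv", index=False)
    cohort.neuropathology.to_csv(out / "neuropathology.csv", index=False)


def read_cohort(indir) -> Cohort:
    from pathlib import Path

    d = Path(indir)
    return Cohort(
        pd.read_csv(d / "participants.csv"),
        pd.read_csv(d / "visits.csv"),
        pd.read_csv(d / "neuropathology.csv"),
    )
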