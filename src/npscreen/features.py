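"""Clinical feature schema: tiers, modalities, and generative patterns.

Features are stratified by acquisition burden:

* tier 1 — obtainable in primary care: demographics, patient history,
  behavioral surveys (functional assessment, neuropsychiatric inventory,
  depression scale), and a brief mental-state exam;
* tier 2 — specialty neuropsychological battery (delayed logical memory,
  trail making, naming, fluency, digit span);
* tier 3 — research-grade: ApoE e4 carriership and Clinical Dementia Rating
  scores.

Each :class:`FeatureDef` also carries the loading pattern used by the
synthetic generator: how strongly the feature reflects the amyloid,
cerebrovascular and other latent pathology factors, standardized age, and
the per-visit clinical severity index.  Patterns are multiplied by the
config's ``latent_effect_sizes[(factor, modality)]`` so that zeroing that
map yields features statistically independent of pathology.  A few history
features carry their cerebrovascular signal only through an interaction
with a medication indicator — the sign of the association flips with
medication status, so the marginal correlation is near zero and the signal
is only recoverable by models that capture interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["FeatureDef", "FEATURES", "feature_names", "tier_features", "MODALITIES"]

MODALITIES = (
    "demographics",
    "history",
    "behavioral",
    "mmse",
    "neuropsych",
    "genetic",
    "cdr",
)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    tier: int  # 1, 2 or 3
    modality: str
    kind: str = "numeric"  # numeric | binary | categorical
    # loading pattern over drivers: amyloid / cerebrovascular / other /
    # age / severity, plus "ix_cvd" / "ix_amy" for the interaction channels
    # (signal sign flips with a context indicator)
    pattern: dict = field(default_factory=dict)
    transform: str = "linear"  # linear | saturate
    noise_sd: float = 1.0
    per_visit: bool = True  # False: drawn once per participant
    categories: tuple = ()

    def __post_init__(self):
        if self.tier not in (1, 2, 3):
            raise ValueError(f"{self.name}: tier must be 1, 2 or 3")
        if self.modality not in MODALITIES:
            raise ValueError(f"{self.name}: unknown modality {self.modality!r}")


FEATURES: tuple[FeatureDef, ...] = (
    # ---- tier 1: demographics -------------------------------------------
    FeatureDef("age_at_visit", 1, "demographics", pattern={"age": 1.0}, noise_sd=0.0),
    FeatureDef("sex", 1, "demographics", kind="categorical",
               categories=("female", "male"), per_visit=False),
    FeatureDef("education_years", 1, "demographics", noise_sd=1.0, per_visit=False),
    FeatureDef("race", 1, "demographics", kind="categorical",
               categories=("white", "black", "hispanic", "asian", "other"),
               per_visit=False),
    FeatureDef("living_alone", 1, "demographics", kind="binary",
               pattern={"severity": -0.3}, per_visit=False),
    FeatureDef("informant_available", 1, "demographics", kind="binary",
               pattern={}, per_visit=False),
    FeatureDef("independence_level", 1, "demographics",
               pattern={"severity": 0.8, "amyloid": 0.3}, transform="saturate",
               noise_sd=0.8),
    # ---- tier 1: patient history ----------------------------------------
    FeatureDef("bmi", 1, "history", pattern={"cerebrovascular": -0.3}, per_visit=False),
    FeatureDef("heart_disease", 1, "history", kind="binary",
               pattern={"cerebrovascular": 0.9}, per_visit=False),
    FeatureDef("diabetes", 1, "history", kind="binary",
               pattern={"cerebrovascular": 0.7}, per_visit=False),
    FeatureDef("stroke_history", 1, "history", kind="binary",
               pattern={"cerebrovascular": 1.0}, per_visit=False),
    FeatureDef("family_history_dementia", 1, "history", kind="binary",
               pattern={"amyloid": 0.5}, per_visit=False),
    # antihypertensive use is a pure indicator; bp_control_score reflects
    # vascular burden with a sign that depends on treatment status
    FeatureDef("on_antihypertensive", 1, "history", kind="binary",
               pattern={}, per_visit=False),
    FeatureDef("bp_control_score", 1, "history",
               pattern={"ix_cvd": 1.3, "cerebrovascular": 0.15}, noise_sd=0.6),
    FeatureDef("hearing_impairment", 1, "history", kind="binary",
               pattern={"amyloid": 0.4, "age": 0.4}, per_visit=False),
    # ---- tier 1: behavioral surveys --------------------------------------
    FeatureDef("faq_score", 1, "behavioral",
               pattern={"severity": 0.7, "amyloid": 0.3, "other": 0.3},
               transform="saturate", noise_sd=1.0),
    FeatureDef("npiq_severity", 1, "behavioral",
               pattern={"amyloid": 0.3, "other": 0.45, "severity": 0.3},
               transform="saturate", noise_sd=1.0),
    FeatureDef("gds_total", 1, "behavioral",
               pattern={"other": 0.5, "cerebrovascular": 0.35, "severity": 0.3},
               noise_sd=0.9),
    FeatureDef("memory_complaint", 1, "behavioral", kind="binary",
               pattern={"amyloid": 0.5, "other": 0.5}),
    # subjective-decline report whose sign flips with informant availability
    # (self-report under anosognosia vs informant report)
    FeatureDef("decline_report_score", 1, "behavioral",
               pattern={"ix_amy": 1.3, "amyloid": 0.1}, noise_sd=0.6),
    # activity-drop item: informant-dependent like the decline report
    FeatureDef("activity_drop_score", 1, "behavioral",
               pattern={"ix_amy": 1.0, "other": 0.2}, noise_sd=0.7),
    # ---- tier 1: brief cognitive testing ---------------------------------
    FeatureDef("mmse_total", 1, "mmse",
               pattern={"severity": -0.8, "amyloid": -0.35}, transform="saturate",
               noise_sd=0.9),
    # ---- tier 2: neuropsychological battery ------------------------------
    FeatureDef("logical_memory_delayed", 2, "neuropsych",
               pattern={"amyloid": -0.8, "severity": -0.5}, noise_sd=0.9),
    FeatureDef("trails_a_seconds", 2, "neuropsych",
               pattern={"severity": 0.5, "cerebrovascular": 0.45}, noise_sd=0.9),
    FeatureDef("trails_b_seconds", 2, "neuropsych",
               pattern={"amyloid": 0.55, "cerebrovascular": 0.5, "severity": 0.5},
               noise_sd=0.9),
    FeatureDef("boston_naming", 2, "neuropsych",
               pattern={"amyloid": -0.5, "other": -0.45}, noise_sd=0.9),
    FeatureDef("animal_fluency", 2, "neuropsych",
               pattern={"amyloid": -0.6, "severity": -0.4}, noise_sd=0.9),
    FeatureDef("digit_span", 2, "neuropsych",
               pattern={"amyloid": -0.4, "severity": -0.3}, noise_sd=1.0),
    # ---- tier 3: genetics + CDR ------------------------------------------
    FeatureDef("apoe_e4_carrier", 3, "genetic", kind="binary",
               pattern={"amyloid": 0.9}, per_visit=False),
    FeatureDef("cdr_global", 3, "cdr",
               pattern={"severity": 0.9, "amyloid": 0.5}, transform="saturate",
               noise_sd=0.6),
    FeatureDef("cdr_sum_boxes", 3, "cdr",
               pattern={"severity": 1.0, "amyloid": 0.55, "other": 0.3},
               noise_sd=0.7),
)

_BY_NAME = {f.name: f for f in FEATURES}


def feature_names(tiers: set[int] | None = None) -> list[str]:
    """Feature column names, optionally restricted to a set of tiers."""
    return [f.name for f in FEATURES if tiers is None or f.tier in tiers]


def tier_features(tiers: set[int]) -> list[FeatureDef]:
    bad = set(tiers) - {1, 2, 3}
    if bad:
        raise ValueError(f"unknown tiers {sorted(bad)}")
    if not tiers:
        raise ValueError("tier selection must be nonempty")
    return [f for f in FEATURES if f.tier in tiers]


def get_feature(name: str) -> FeatureDef:
    return _BY_NAME[name]
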