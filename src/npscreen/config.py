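"""Cohort-generator configuration.

:class:`CohortConfig` collects every knob of the synthetic cohort: cohort
sizes, visit-count ranges, age range, per-lesion baseline prevalence, the
latent-factor effect sizes that couple clinical features to pathology, the
within-domain lesion correlation, missingness, and the seed that fully
determines the output.  Configs round-trip through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lesions import LESION_CODES

__all__ = ["CohortConfig", "ConfigError", "DEFAULT_LESION_PREVALENCE", "DEFAULT_EFFECT_SIZES"]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


# Baseline marginal prevalence of a high-grade lesion among autopsy
# participants.  Amyloid-associated lesions are common, cerebrovascular
# lesions vary widely (atherosclerosis common, hemorrhages rare).
DEFAULT_LESION_PREVALENCE: dict[str, float] = {
    "ADNC": 0.60,
    "BRAAK": 0.55,
    "DIFF": 0.55,
    "NEUR": 0.45,
    "CAA": 0.30,
    "INF": 0.25,
    "MICR": 0.25,
    "HEM": 0.08,
    "ARTE": 0.40,
    "AVAS": 0.45,
    "WMR": 0.30,
    "LEWY": 0.25,
    "SCL": 0.12,
    "TDP": 0.20,
}

# Multipliers applied to each feature's loading pattern, keyed by
# (latent factor, feature modality).  "severity" and "age" are treated as
# additional drivers alongside the three pathology factors, so zeroing this
# map severs every feature-label pathway (the null cohort).  The scale is
# calibrated once so that informative features show a standardized mean
# shift of about 0.8 between the none/low and high total-load classes.
DEFAULT_EFFECT_SIZES: dict[tuple[str, str], float] = {
    (factor, modality): 1.0
    for factor in ("amyloid", "cerebrovascular", "other", "severity", "age")
    for modality in (
        "demographics",
        "history",
        "behavioral",
        "mmse",
        "neuropsych",
        "genetic",
        "cdr",
    )
}


def _as_pair(value, name: str) -> tuple[int, int]:
    try:
        lo, hi = int(value[0]), int(value[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"{name} must be an integer pair, got {value!r}") from exc
    if lo > hi:
        raise ConfigError(f"{name} must be ordered, got {value!r}")
    return lo, hi


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort draw.

    ``seed`` fully determines the generated tables: the same config generates
    byte-identical cohorts on every call.
    """

    n_unlabeled: int = 5000
    n_labeled: int = 800
    visit_count_range: tuple[int, int] = (3, 7)
    unlabeled_visit_count_range: tuple[int, int] = (1, 5)
    age_range: tuple[float, float] = (60.0, 95.0)
    lesion_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_PREVALENCE)
    )
    latent_effect_sizes: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    within_domain_correlation: float = 0.45
    #: scales the age-dependence of lesion prevalence; 0 severs the
    #: age-lesion pathway (used by the null cohort so that the age feature
    #: carries no label information)
    lesion_age_slope_scale: float = 1.0
    missingness_rate: float = 0.05
    lesion_missingness_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_labeled < 0 or self.n_unlabeled < 0:
            raise ConfigError("cohort sizes must be nonnegative")
        if self.n_labeled + self.n_unlabeled == 0:
            raise ConfigError("empty cohort: n_labeled + n_unlabeled must be positive")
        self.visit_count_range = _as_pair(self.visit_count_range, "visit_count_range")
        self.unlabeled_visit_count_range = _as_pair(
            self.unlabeled_visit_count_range, "unlabeled_visit_count_range"
        )
        if self.visit_count_range[0] < 1:
            raise ConfigError("labeled participants need at least one visit")
        lo, hi = float(self.age_range[0]), float(self.age_range[1])
        if not lo < hi:
            raise ConfigError(f"age_range must be increasing, got {self.age_range}")
        self.age_range = (lo, hi)
        unknown = set(self.lesion_prevalence) - set(LESION_CODES)
        if unknown:
            raise ConfigError(f"unknown lesion codes in prevalence map: {sorted(unknown)}")
        missing = set(LESION_CODES) - set(self.lesion_prevalence)
        if missing:
            raise ConfigError(f"lesion_prevalence lacks codes: {sorted(missing)}")
        for code, p in self.lesion_prevalence.items():
            if not 0.0 < float(p) < 1.0:
                raise ConfigError(f"prevalence for {code} must be in (0,1), got {p}")
        if not 0.0 <= self.within_domain_correlation < 1.0:
            raise ConfigError("within_domain_correlation must be in [0,1)")
        for rate_name in ("missingness_rate", "lesion_missingness_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{rate_name} must be in [0,1), got {rate}")
        self.seed = int(self.seed)

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latent_effect_sizes"] = {
            f"{factor}:{modality}": v
            for (factor, modality), v in self.latent_effect_sizes.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "latent_effect_sizes" in d and d["latent_effect_sizes"] is not None:
            es = {}
            for key, v in d["latent_effect_sizes"].items():
                if isinstance(key, str):
                    factor, modality = key.split(":")
                else:
                    factor, modality = key
                es[(factor, modality)] = float(v)
            d["latent_effect_sizes"] = es
        for pair_key in ("visit_count_range", "unlabeled_visit_count_range", "age_range"):
            if pair_key in d and d[pair_key] is not None:
                d[pair_key] = tuple(d[pair_key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
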