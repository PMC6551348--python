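"""Configuration objects for the synthetic cohort generator and pipeline runs.

The defaults describe the study design the package emulates: a cross-sectional
cohort of 206 typically developing (TD) and 321 autistic (ASD) participants,
6-31 years of age, recruited into four schedules (A adults, B adolescents,
C children, D adolescents/adults with IQ < 70), with cortical thickness
measured at a set of surface vertices grouped into parcels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


#: Symptom instruments: name -> (target mean, target SD) among ASD subjects.
#: Means/SDs follow the clinical descriptives of the emulated cohort.
SYMPTOM_MOMENTS: dict[str, tuple[float, float]] = {
    "adi_social": (16.20, 6.71),
    "adi_communication": (13.11, 5.69),
    "adi_repetitive": (4.32, 2.69),
    "ados_total": (5.12, 2.77),
    "ados_social": (5.78, 2.62),
    "ados_repetitive": (4.78, 2.76),
}

#: Instrument membership, used for per-instrument (listwise) missingness.
SYMPTOM_INSTRUMENT: dict[str, str] = {
    "adi_social": "adi",
    "adi_communication": "adi",
    "adi_repetitive": "adi",
    "ados_total": "ados",
    "ados_social": "ados",
    "ados_repetitive": "ados",
}


@dataclass(frozen=True)
class ScheduleRule:
    """One recruitment stratum: an age window, an IQ band, and group sizes."""

    label: str
    age_min: float
    age_max: float
    iq_min: float
    iq_max: float
    n_td: int
    n_asd: int

    def validate(self) -> None:
        if self.age_min >= self.age_max:
            raise ConfigurationError(
                f"schedule {self.label}: age_min must be < age_max"
            )
        if self.iq_min >= self.iq_max:
            raise ConfigurationError(f"schedule {self.label}: empty IQ band")
        if self.n_td < 0 or self.n_asd < 0:
            raise ConfigurationError(f"schedule {self.label}: negative count")


def default_schedule_rules() -> tuple[ScheduleRule, ...]:
    """Four strata with the emulated study's group sizes per schedule."""
    return (
        ScheduleRule("A", 18.0, 31.0, 70.0, 160.0, n_td=84, n_asd=125),
        ScheduleRule("B", 12.0, 18.0, 70.0, 160.0, n_td=70, n_asd=112),
        ScheduleRule("C", 6.0, 12.0, 70.0, 160.0, n_td=52, n_asd=64),
        ScheduleRule("D", 12.0, 31.0, 50.0, 70.0, n_td=0, n_asd=20),
    )


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator.

    Geometry defaults (1,000 vertices in 34 parcels) stand in for one
    hemisphere of a Desikan-Killiany-style parcellation. Deviation
    parameters are expressed in per-vertex noise-SD units so planted
    effect sizes are interpretable as Z shifts.
    """

    n_td: int = 206
    n_asd: int = 321
    #: male fraction per group (127/206 TD, 232/321 ASD)
    male_fraction_td: float = 127 / 206
    male_fraction_asd: float = 232 / 321
    #: overall admissible age range per group, years
    age_range_td: tuple[float, float] = (7.0, 31.0)
    age_range_asd: tuple[float, float] = (6.0, 31.0)
    schedule_rules: tuple[ScheduleRule, ...] = field(
        default_factory=default_schedule_rules
    )
    n_sites: int = 3
    #: probability an ASD subject is missing IQ (emulates 316/321 observed)
    iq_missing_rate_asd: float = 5 / 321

    n_vertices: int = 1000
    n_regions: int = 34
    #: optional explicit per-vertex (intercept mm, linear mm/yr, quad mm/yr^2);
    #: drawn from the seeded meta-model when None
    trajectory_coeffs: Any = None
    #: fraction of vertices given an inverted-U (negative quadratic) trajectory
    inverted_u_fraction: float = 0.2
    #: per-vertex male-female offset range, mm (drawn uniformly, random sign)
    sex_offset_range: tuple[float, float] = (0.0, 0.06)
    #: per-vertex residual SD range, mm
    noise_sd_range: tuple[float, float] = (0.10, 0.25)

    #: proportion of ASD subjects carrying planted deviations (exact count)
    deviation_prevalence: float = 0.4
    #: number of whole parcels affected per deviating subject
    deviation_extent: int = 2
    #: deviation magnitude in noise-SD units: (mean, sd), truncated at > 0
    deviation_magnitude: tuple[float, float] = (4.0, 0.5)
    #: planted sign per schedule: children negative, older schedules positive
    deviation_sign_by_schedule: dict[str, int] = field(
        default_factory=lambda: {"A": +1, "B": +1, "C": -1, "D": +1}
    )

    #: target Spearman rank correlation between a subject's planted deviation
    #: magnitude and each symptom score (Gaussian-copula link)
    symptom_link: dict[str, float] = field(
        default_factory=lambda: {
            "adi_social": -0.10,
            "adi_communication": -0.10,
            "adi_repetitive": -0.10,
            "ados_total": -0.10,
            "ados_social": -0.10,
            "ados_repetitive": -0.21,
        }
    )
    #: per-instrument missingness among ASD (listwise per instrument);
    #: defaults emulate ADI-R observed for 308/321, ADOS-2 for 258/321
    instrument_missing_rate: dict[str, float] = field(
        default_factory=lambda: {"adi": 13 / 321, "ados": 63 / 321}
    )

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_td < 0 or self.n_asd < 0 or self.n_td + self.n_asd == 0:
            raise ConfigurationError("group sizes must be non-negative, total > 0")
        for frac in (self.male_fraction_td, self.male_fraction_asd):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("male fractions must lie in [0, 1]")
        for lo, hi in (self.age_range_td, self.age_range_asd):
            if lo >= hi:
                raise ConfigurationError("age_range min must be < max")
        if not self.schedule_rules:
            raise ConfigurationError("at least one schedule rule required")
        for rule in self.schedule_rules:
            rule.validate()
        if sum(r.n_td for r in self.schedule_rules) != self.n_td:
            raise ConfigurationError("schedule TD counts do not sum to n_td")
        if sum(r.n_asd for r in self.schedule_rules) != self.n_asd:
            raise ConfigurationError("schedule ASD counts do not sum to n_asd")
        if self.n_vertices <= 0 or self.n_regions <= 0:
            raise ConfigurationError("n_vertices and n_regions must be positive")
        if self.n_regions > self.n_vertices:
            raise ConfigurationError("n_regions cannot exceed n_vertices")
        if not 0.0 <= self.deviation_prevalence <= 1.0:
            raise ConfigurationError("deviation_prevalence must lie in [0, 1]")
        if not 1 <= self.deviation_extent <= self.n_regions:
            raise ConfigurationError(
                "deviation_extent must lie in [1, n_regions]"
            )
        if self.noise_sd_range[0] <= 0:
            raise ConfigurationError("noise SD must be positive")
        if self.deviation_magnitude[1] < 0:
            raise ConfigurationError("deviation magnitude SD must be >= 0")
        for name, rho in self.symptom_link.items():
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(
                    f"symptom link for {name} outside [-1, 1]"
                )
            if name not in SYMPTOM_MOMENTS:
                raise ConfigurationError(f"unknown symptom score {name!r}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["schedule_rules"] = [dataclasses.asdict(r) for r in self.schedule_rules]
        if d["trajectory_coeffs"] is not None:
            d["trajectory_coeffs"] = [list(map(float, row))
                                      for row in d["trajectory_coeffs"]]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "schedule_rules" in d:
            d["schedule_rules"] = tuple(
                ScheduleRule(**r) for r in d["schedule_rules"]
            )
        for key in ("age_range_td", "age_range_asd", "sex_offset_range",
                    "noise_sd_range", "deviation_magnitude"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _largest_remainder(total: int, weights) -> list[int]:
    weights = [max(w, 0.0) for w in weights]
    s = sum(weights) or 1.0
    raw = [total * w / s for w in weights]
    counts = [int(c) for c in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i],
                  reverse=True)
    for i in rema[: total - sum(counts)]:
        counts[i] += 1
    return counts


def scaled_simulation_config(n_td: int, n_asd: int, n_vertices: int,
                             n_regions: int, seed: int = 0,
                             **overrides) -> SimulationConfig:
    """A SimulationConfig at reduced size, preserving the default design's
    per-schedule proportions (largest-remainder apportionment)."""
    base = default_schedule_rules()
    td_counts = _largest_remainder(n_td, [r.n_td for r in base])
    asd_counts = _largest_remainder(n_asd, [r.n_asd for r in base])
    rules = tuple(
        dataclasses.replace(r, n_td=td, n_asd=asd)
        for r, td, asd in zip(base, td_counts, asd_counts)
    )
    cfg = SimulationConfig(
        n_td=n_td, n_asd=n_asd, schedule_rules=rules,
        n_vertices=n_vertices, n_regions=n_regions, seed=seed, **overrides)
    cfg.validate()
    return cfg


@dataclass
class RunConfig:
    """End-to-end run settings; defaults mirror the analysis protocol
    (10-fold CV, q = 0.05 at every FDR stage, top-1% trimmed extreme
    scores, top-15 cohort-membership test)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    covariates: tuple[str, ...] = ("age", "sex")
    folds: int = 10
    q_npm: float = 0.05
    q_fit: float = 0.05
    q_glm: float = 0.05
    q_assoc: float = 0.05
    extreme_fraction: float = 0.01
    top_k: int = 15
    topk_null: str = "hypergeometric"
    glm_age_powers: tuple[int, ...] = (1,)
    n_restarts: int = 5
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        for q in (self.q_npm, self.q_fit, self.q_glm, self.q_assoc):
            if not 0.0 <= q < 1.0:
                raise ConfigurationError("FDR levels must lie in [0, 1)")
        if not 0.0 < self.extreme_fraction <= 1.0:
            raise ConfigurationError("extreme_fraction must lie in (0, 1]")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.topk_null not in ("hypergeometric", "binomial-cohort",
                                  "binomial-half"):
            raise ConfigurationError(f"unknown topk null {self.topk_null!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for key in ("covariates", "glm_age_powers"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
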