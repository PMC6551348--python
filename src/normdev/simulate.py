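"""Seeded synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* TD cortical thickness declines approximately linearly with age at most
  vertices, with inverted-U (negative quadratic) trajectories at a subset;
  a small sex offset and independent per-vertex Gaussian noise.
* ASD subjects follow the same typical law, except that an exact-count
  subset of them carries sparse, subject-specific deviations planted in
  whole parcels; the deviation sign depends on the recruitment schedule
  (negative in children, positive in adolescents/adults by default).
* Symptom scores among ASD subjects are linked to the planted deviation
  magnitude through a rank-preserving Gaussian copula so the target
  Spearman correlation is directly controllable; TD scores are missing.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` substreams, so each stage is individually
reproducible and the whole generator is bit-for-bit deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    SYMPTOM_INSTRUMENT,
    SYMPTOM_MOMENTS,
    ConfigurationError,
    SimulationConfig,
)

COHORT_COLUMNS = [
    "subject_id", "group", "sex", "age", "schedule", "iq", "site",
    "quality_surrogate",
    "adi_social", "adi_communication", "adi_repetitive",
    "ados_total", "ados_social", "ados_repetitive",
]

_STAGE = {"demographics": 1, "trajectories": 2, "measurements": 3,
          "symptoms": 4}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(_STAGE[stage],))
    )


@dataclass
class MeasureMatrix:
    """Subjects x vertices morphometry values (mm for thickness)."""

    values: np.ndarray
    vertex_ids: np.ndarray
    measure: str = "thickness"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x vertices)")
        if self.values.shape[1] != self.vertex_ids.size:
            raise ValueError("vertex_ids length must match column count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    """Planted effects, kept for parameter-recovery and power tests."""

    deviation_mask: np.ndarray        # subjects x vertices, signed {-1,0,+1}
    deviation_magnitudes: np.ndarray  # subjects x vertices, mm (signed)
    #: per-subject mean planted |magnitude| in noise-SD units (0 if none)
    subject_magnitude: np.ndarray
    trajectory_coeffs: np.ndarray     # vertices x 3 (intercept, lin, quad)
    sex_offset: np.ndarray            # vertices, mm (added for males)
    noise_sd: np.ndarray              # vertices, mm
    seed: int


def _draw_trajectories(config: SimulationConfig):
    """Per-vertex trajectory coefficients, sex offsets and noise SDs.

    Most vertices decline linearly (slope about -0.005 to -0.035 mm/yr from
    a 2.2-3.4 mm intercept at age 0 reference); a configured fraction get an
    inverted-U with its peak inside childhood/adolescence.
    """
    rng = _rng(config, "trajectories")
    m = config.n_vertices
    if config.trajectory_coeffs is not None:
        coeffs = np.asarray(config.trajectory_coeffs, dtype=float)
        if coeffs.shape != (m, 3):
            raise ConfigurationError(
                f"trajectory_coeffs must have shape ({m}, 3)"
            )
    else:
        intercept = rng.uniform(2.6, 3.6, size=m)
        linear = rng.uniform(-0.035, -0.005, size=m)
        quad = np.zeros(m)
        n_u = int(round(config.inverted_u_fraction * m))
        if n_u:
            idx = rng.choice(m, size=n_u, replace=False)
            peak_age = rng.uniform(8.0, 14.0, size=n_u)
            curvature = rng.uniform(-0.004, -0.001, size=n_u)
            quad[idx] = curvature
            # choose linear so the parabola peaks at peak_age
            linear[idx] = -2.0 * curvature * peak_age
            intercept[idx] = rng.uniform(2.2, 3.0, size=n_u)
        coeffs = np.column_stack([intercept, linear, quad])
    lo, hi = config.sex_offset_range
    sex_offset = rng.uniform(lo, hi, size=m) * rng.choice([-1.0, 1.0], size=m)
    noise_sd = rng.uniform(*config.noise_sd_range, size=m)
    return coeffs, sex_offset, noise_sd


def simulate_demographics(config: SimulationConfig) -> pd.DataFrame:
    """Generate the cohort table: ids, group, sex, age, schedule, IQ, site,
    quality surrogate; symptom columns initialized to missing.

    Group sizes, per-schedule counts and male counts are exact (not
    sampled), matching the emulated study design.
    """
    config.validate()
    rng = _rng(config, "demographics")

    rows: list[dict] = []
    for group, n_group, age_rng in (
        ("TD", config.n_td, config.age_range_td),
        ("ASD", config.n_asd, config.age_range_asd),
    ):
        for rule in config.schedule_rules:
            n = rule.n_td if group == "TD" else rule.n_asd
            if n == 0:
                continue
            lo = max(rule.age_min, age_rng[0])
            hi = min(rule.age_max, age_rng[1])
            if lo >= hi:
                raise ConfigurationError(
                    f"schedule {rule.label} window empty for group {group}"
                )
            ages = rng.uniform(lo, hi, size=n)
            if rule.iq_max <= 70.0:
                iqs = rng.uniform(rule.iq_min, rule.iq_max, size=n)
            else:
                mean = 108.2 if group == "TD" else 103.6
                iqs = stats.truncnorm.rvs(
                    (rule.iq_min - mean) / 15.0, (rule.iq_max - mean) / 15.0,
                    loc=mean, scale=15.0, size=n, random_state=rng)
            for age, iq in zip(ages, iqs):
                rows.append({"group": group, "schedule": rule.label,
                             "age": float(age), "iq": float(iq)})

    demo = pd.DataFrame(rows)
    # exact male counts per group, positions shuffled
    sexes = np.empty(len(demo), dtype=object)
    for group, frac in (("TD", config.male_fraction_td),
                        ("ASD", config.male_fraction_asd)):
        idx = np.flatnonzero((demo["group"] == group).to_numpy())
        n_male = int(round(frac * idx.size))
        males = rng.choice(idx, size=n_male, replace=False)
        sexes[idx] = "female"
        sexes[males] = "male"
    demo["sex"] = sexes

    demo["site"] = rng.integers(0, config.n_sites, size=len(demo))
    demo["site"] = "site" + demo["site"].astype(str)
    # Euler-number-like image-quality surrogate, independent of deviations
    demo["quality_surrogate"] = rng.normal(-70.0, 25.0, size=len(demo))

    n_iq_missing = int(round(config.iq_missing_rate_asd * config.n_asd))
    if n_iq_missing:
        asd_idx = np.flatnonzero((demo["group"] == "ASD").to_numpy())
        eligible = asd_idx[demo.loc[asd_idx, "schedule"].to_numpy() != "D"]
        drop = rng.choice(eligible, size=n_iq_missing, replace=False)
        demo.loc[drop, "iq"] = np.nan

    demo["subject_id"] = [f"sub-{i:04d}" for i in range(len(demo))]
    for col in SYMPTOM_MOMENTS:
        demo[col] = np.nan
    demo = demo[COHORT_COLUMNS].reset_index(drop=True)
    return demo


def make_parcellation(config: SimulationConfig) -> np.ndarray:
    """Contiguous equal-size-as-possible parcels: vertex -> region id."""
    edges = np.linspace(0, config.n_vertices, config.n_regions + 1)
    region_of_vertex = np.searchsorted(edges[1:], np.arange(config.n_vertices),
                                       side="right")
    return region_of_vertex.astype(int)


def simulate_measurements(
    demo: pd.DataFrame, config: SimulationConfig
) -> tuple[MeasureMatrix, np.ndarray, GroundTruth]:
    """Generate the subjects x vertices thickness matrix plus ground truth.

    TD law at vertex v: intercept + lin*age + quad*age^2 + sex_offset*male
    + N(0, noise_sd^2). ASD rows additionally carry whole-parcel deviations
    for an exact-count prevalence subset, signed per schedule.
    """
    config.validate()
    if len(demo) != config.n_td + config.n_asd:
        raise ConfigurationError("cohort table size inconsistent with config")
    coeffs, sex_offset, noise_sd = _draw_trajectories(config)
    parcellation = make_parcellation(config)
    rng = _rng(config, "measurements")

    age = demo["age"].to_numpy(float)
    male = (demo["sex"] == "male").to_numpy(float)
    mean = (coeffs[:, 0][None, :]
            + coeffs[:, 1][None, :] * age[:, None]
            + coeffs[:, 2][None, :] * age[:, None] ** 2
            + sex_offset[None, :] * male[:, None])
    values = mean + rng.normal(0.0, 1.0, size=mean.shape) * noise_sd[None, :]

    n_sub = len(demo)
    mask = np.zeros((n_sub, config.n_vertices), dtype=np.int8)
    magnitudes = np.zeros((n_sub, config.n_vertices))
    subject_magnitude = np.zeros(n_sub)

    asd_idx = np.flatnonzero((demo["group"] == "ASD").to_numpy())
    n_affected = int(round(config.deviation_prevalence * asd_idx.size))
    if n_affected:
        affected = np.sort(rng.choice(asd_idx, size=n_affected, replace=False))
        mag_mean, mag_sd = config.deviation_magnitude
        sign_map = config.deviation_sign_by_schedule
        for i in affected:
            regions = rng.choice(config.n_regions, size=config.deviation_extent,
                                 replace=False)
            sign = sign_map.get(str(demo.at[i, "schedule"]), +1)
            mags = np.abs(rng.normal(mag_mean, mag_sd,
                                     size=config.deviation_extent))
            subject_magnitude[i] = float(np.mean(mags))
            for r, mag_units in zip(regions, mags):
                verts = np.flatnonzero(parcellation == r)
                mask[i, verts] = sign
                magnitudes[i, verts] = sign * mag_units * noise_sd[verts]
        values = values + magnitudes

    truth = GroundTruth(
        deviation_mask=mask,
        deviation_magnitudes=magnitudes,
        subject_magnitude=subject_magnitude,
        trajectory_coeffs=coeffs,
        sex_offset=sex_offset,
        noise_sd=noise_sd,
        seed=config.seed,
    )
    matrix = MeasureMatrix(values=values,
                           vertex_ids=np.arange(config.n_vertices))
    return matrix, parcellation, truth


def simulate_symptoms(
    demo: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Fill in ASD symptom scores linked to planted deviation magnitude.

    The link is a Gaussian copula on the mid-ranks of the per-subject planted
    magnitude: the latent Pearson correlation is 2*sin(pi*rho_S/6), the
    bivariate-normal inversion of the target Spearman rho_S. Scores are then
    rescaled to the configured instrument mean/SD; missingness is applied
    listwise per instrument at exact counts; TD scores stay missing.
    """
    config.validate()
    rng = _rng(config, "symptoms")
    demo = demo.copy()

    asd_idx = np.flatnonzero((demo["group"] == "ASD").to_numpy())
    n = asd_idx.size
    if n == 0:
        return demo
    mags = truth.subject_magnitude[asd_idx]
    # normal scores of mid-ranks (Blom); ties (unaffected subjects) share one
    ranks = stats.rankdata(mags, method="average")
    z_mag = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    sd = z_mag.std()
    z_mag = z_mag / sd if sd > 0 else np.zeros(n)

    for score, rho_s in config.symptom_link.items():
        mu, sigma = SYMPTOM_MOMENTS[score]
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        latent = r * z_mag + np.sqrt(1.0 - r ** 2) * rng.normal(size=n)
        demo.loc[asd_idx, score] = mu + sigma * latent

    for instrument, rate in config.instrument_missing_rate.items():
        cols = [s for s, inst in SYMPTOM_INSTRUMENT.items() if inst == instrument]
        n_missing = int(round(rate * n))
        if n_missing:
            drop = rng.choice(asd_idx, size=n_missing, replace=False)
            demo.loc[drop, cols] = np.nan
    return demo


def simulate_cohort(config: SimulationConfig):
    """Run all three generator stages; returns (cohort, matrix, parcellation,
    truth)."""
    demo = simulate_demographics(config)
    matrix, parcellation, truth = simulate_measurements(demo, config)
    cohort = simulate_symptoms(demo, truth, config)
    return cohort, matrix, parcellation, truth
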