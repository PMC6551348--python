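"""Synthetic cohort generator: design fidelity, determinism, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from normdev import (ConfigurationError, SimulationConfig,
                     scaled_simulation_config, simulate_cohort,
                     simulate_demographics, simulate_measurements,
                     simulate_symptoms)
from normdev.config import SYMPTOM_MOMENTS


class TestDemographics:
    def test_default_design_counts(self):
        """Default cohort reproduces the study composition: 206 TD
        (127 male) and 321 ASD (232 male), with the per-schedule sizes."""
        demo = simulate_demographics(SimulationConfig(seed=0))
        td = demo[demo["group"] == "TD"]
        asd = demo[demo["group"] == "ASD"]
        assert len(td) == 206 and (td["sex"] == "male").sum() == 127
        assert len(asd) == 321 and (asd["sex"] == "male").sum() == 232
        sched = demo.groupby(["group", "schedule"]).size()
        assert sched.get(("ASD", "A")) == 125
        assert sched.get(("ASD", "B")) == 112
        assert sched.get(("ASD", "C")) == 64
        assert sched.get(("ASD", "D")) == 20
        assert sched.get(("TD", "A")) == 84
        assert ("TD", "D") not in sched.index

    def test_invariants(self):
        demo = simulate_demographics(SimulationConfig(seed=1))
        assert demo["subject_id"].is_unique
        td = demo["group"] == "TD"
        assert demo.loc[td, "age"].between(7, 31).all()
        assert demo.loc[~td, "age"].between(6, 31).all()
        d_rows = demo["schedule"] == "D"
        assert (demo.loc[d_rows, "iq"] < 70).all()
        assert (demo.loc[~d_rows, "iq"].dropna() >= 70).all()
        # symptom columns start null everywhere
        assert demo[list(SYMPTOM_MOMENTS)].isna().all().all()

    def test_determinism_bitwise(self):
        cfg = SimulationConfig(seed=11)
        a = simulate_demographics(cfg)
        b = simulate_demographics(cfg)
        assert a.to_csv() == b.to_csv()

    def test_no_td_gives_asd_only_table(self):
        rules = tuple(
            dataclasses.replace(r, n_td=0)
            for r in SimulationConfig().schedule_rules)
        cfg = SimulationConfig(n_td=0, schedule_rules=rules, seed=0)
        demo = simulate_demographics(cfg)
        assert (demo["group"] == "ASD").all()

    def test_inconsistent_schedule_counts_rejected(self):
        cfg = SimulationConfig(n_td=100)  # rules still sum to 206
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestMeasurements:
    def test_noise_free_limit(self):
        """With vanishing noise and no planted deviations, every row sits
        exactly on its trajectory polynomial."""
        cfg = scaled_simulation_config(30, 30, 40, 8, seed=2,
                                       noise_sd_range=(1e-12, 2e-12),
                                       deviation_prevalence=0.0)
        demo = simulate_demographics(cfg)
        matrix, _, truth = simulate_measurements(demo, cfg)
        age = demo["age"].to_numpy()
        male = (demo["sex"] == "male").to_numpy(float)
        c = truth.trajectory_coeffs
        expected = (c[:, 0] + np.outer(age, c[:, 1]) +
                    np.outer(age ** 2, c[:, 2]) +
                    np.outer(male, truth.sex_offset))
        np.testing.assert_allclose(matrix.values, expected, atol=1e-9)

    def test_age_slope_recovery_ols_oracle(self):
        """Per-vertex OLS on the TD rows recovers the configured linear
        coefficient within 2 standard errors at the default TD size."""
        cfg = SimulationConfig(seed=5, n_vertices=300,
                               deviation_prevalence=0.0)
        demo = simulate_demographics(cfg)
        matrix, _, truth = simulate_measurements(demo, cfg)
        td = (demo["group"] == "TD").to_numpy()
        age = demo.loc[td, "age"].to_numpy()
        male = (demo["sex"] == "male").to_numpy(float)[td]
        X = np.column_stack([np.ones(td.sum()), age, male])
        linear_vertices = np.flatnonzero(truth.trajectory_coeffs[:, 2] == 0)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ matrix.values[td][:, linear_vertices]
        resid = matrix.values[td][:, linear_vertices] - X @ beta
        se = np.sqrt(resid.var(axis=0, ddof=3) * XtX_inv[1, 1])
        err = np.abs(beta[1] - truth.trajectory_coeffs[linear_vertices, 1])
        assert np.mean(err <= 2 * se) >= 0.90

    def test_inverted_u_mid_age_exceeds_endpoints(self):
        cfg = SimulationConfig(seed=6, n_vertices=200)
        demo = simulate_demographics(cfg)
        _, _, truth = simulate_measurements(demo, cfg)
        c = truth.trajectory_coeffs
        u_vertices = c[:, 2] < 0
        assert u_vertices.sum() == 40  # 20% of vertices
        ages = np.array([6.0, 18.5, 31.0])
        for v in np.flatnonzero(u_vertices):
            vals = c[v, 0] + c[v, 1] * ages + c[v, 2] * ages ** 2
            assert vals[1] > (vals[0] + vals[2]) / 2

    def test_exact_prevalence_count_and_sign_law(self, small_config,
                                                 small_cohort):
        cohort, _, _, truth = small_cohort
        n_affected = (truth.subject_magnitude > 0).sum()
        assert n_affected == round(
            small_config.deviation_prevalence * small_config.n_asd)
        # planted rows are ASD only
        td = (cohort["group"] == "TD").to_numpy()
        assert not truth.deviation_mask[td].any()
        # sign law: C negative, A/B/D positive under the default sign map
        for i in np.flatnonzero((truth.deviation_mask != 0).any(axis=1)):
            signs = np.unique(truth.deviation_mask[i])
            signs = signs[signs != 0]
            expected = -1 if cohort.at[i, "schedule"] == "C" else +1
            assert list(signs) == [expected]

    def test_deviations_fill_whole_parcels(self, small_cohort):
        _, _, parcellation, truth = small_cohort
        for i in np.flatnonzero((truth.deviation_mask != 0).any(axis=1)):
            hit_regions = np.unique(parcellation[truth.deviation_mask[i] != 0])
            planted = np.isin(parcellation, hit_regions)
            assert (truth.deviation_mask[i] != 0).sum() == planted.sum()

    def test_null_embedding_identical_laws(self):
        """With prevalence 0 the ASD and TD generative laws coincide."""
        cfg = scaled_simulation_config(40, 40, 30, 6, seed=9,
                                       deviation_prevalence=0.0)
        demo = simulate_demographics(cfg)
        matrix, _, truth = simulate_measurements(demo, cfg)
        assert not truth.deviation_mask.any()
        assert truth.deviation_magnitudes.sum() == 0


class TestSymptoms:
    def test_null_link_uncorrelated(self):
        cfg = SimulationConfig(
            seed=3, n_vertices=50, n_regions=10,
            symptom_link={k: 0.0 for k in SYMPTOM_MOMENTS})
        cohort, _, _, truth = simulate_cohort(cfg)
        asd = (cohort["group"] == "ASD").to_numpy()
        from scipy.stats import spearmanr
        s = cohort.loc[asd, "ados_repetitive"].to_numpy()
        keep = np.isfinite(s)
        rho = spearmanr(truth.subject_magnitude[asd][keep], s[keep]).statistic
        assert abs(rho) < 0.1

    def test_moderate_link_recovered(self):
        """A -0.5 link yields empirical Spearman rho in [-0.65, -0.35]
        (mean over seeds, rank-correlation oracle)."""
        from scipy.stats import spearmanr
        rhos = []
        for seed in range(8):
            cfg = SimulationConfig(
                seed=seed, n_vertices=50, n_regions=10,
                symptom_link={"ados_repetitive": -0.5})
            cohort, _, _, truth = simulate_cohort(cfg)
            asd = (cohort["group"] == "ASD").to_numpy()
            s = cohort.loc[asd, "ados_repetitive"].to_numpy()
            keep = np.isfinite(s)
            rhos.append(spearmanr(truth.subject_magnitude[asd][keep],
                                  s[keep]).statistic)
        assert -0.65 <= np.mean(rhos) <= -0.35

    def test_target_moments_reproduced(self):
        """ADI-R repetitive-behavior moments (4.32 +/- 2.69) within 10%."""
        means, sds = [], []
        for seed in range(3):
            cohort, *_ = simulate_cohort(
                SimulationConfig(seed=seed, n_vertices=50, n_regions=10))
            means.append(cohort["adi_repetitive"].mean())
            sds.append(cohort["adi_repetitive"].std())
        assert abs(np.mean(means) - 4.32) / 4.32 < 0.10
        assert abs(np.mean(sds) - 2.69) / 2.69 < 0.10

    def test_instrument_missingness_listwise(self):
        cohort, *_ = simulate_cohort(
            SimulationConfig(seed=0, n_vertices=50, n_regions=10))
        asd = cohort["group"] == "ASD"
        adi = cohort.loc[asd, ["adi_social", "adi_communication",
                               "adi_repetitive"]]
        # missing whole-instrument: rows are all-NaN or all-observed
        assert ((adi.isna().sum(axis=1) == 0)
                | (adi.isna().sum(axis=1) == 3)).all()
        assert adi.dropna().shape[0] == 308
        ados = cohort.loc[asd, ["ados_total", "ados_social",
                                "ados_repetitive"]]
        assert ados.dropna().shape[0] == 258
        assert cohort.loc[~asd, list(SYMPTOM_MOMENTS)].isna().all().all()

    def test_link_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(symptom_link={"ados_total": -1.5}).validate()


def test_full_generator_determinism(small_config):
    a = simulate_cohort(small_config)
    b = simulate_cohort(small_config)
    pd.testing.assert_frame_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1].values, b[1].values)
    np.testing.assert_array_equal(a[3].deviation_mask, b[3].deviation_mask)
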