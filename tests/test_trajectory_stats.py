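"""Mixed-model estimation: GLS oracles, calibration, power, BH behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from fastproteo import synthetic_data as sd
from fastproteo import trajectory_stats as ts


def _simulate_y(design, curve, sigma_u, sigma_e, rng, sex_offset=None):
    """Raw trajectories: mean curve + participant intercept + noise."""
    n_p = design.n_participants
    n_t = len(design.timepoints)
    u = rng.normal(0, sigma_u, n_p)
    y = curve[None, :] + u[:, None] + rng.normal(0, sigma_e, (n_p, n_t))
    if sex_offset is not None:
        female = np.array([s == "F" for s in design.sex])
        y[female] += sex_offset[None, :]
    return y


def _day_curve(design, day, amplitude):
    curve = np.zeros(len(design.timepoints))
    curve[list(design.timepoints).index(day)] = amplitude
    return curve


class TestStandardize:
    def test_prefast_pool_mean0_sd1_and_unit_mapping(self, design):
        rng = np.random.default_rng(0)
        values = rng.normal(5.0, 2.0, (12, 9, 3))
        m = sd.ProteinMatrix(design=design, assay_ids=["a", "b", "c"], values=values)
        out, excluded = ts.standardize(m)
        assert excluded == []
        base = out.values[:, 0, :]  # day −2 only
        np.testing.assert_allclose(base.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(base.std(axis=0, ddof=1), 1.0, atol=1e-12)
        # a raw value equal to mean maps to 0; mean + 2·sd maps to 2
        mu, sdev = values[:, 0, 0].mean(), values[:, 0, 0].std(ddof=1)
        m.values[0, 1, 0] = mu
        m.values[1, 1, 0] = mu + 2 * sdev
        out, _ = ts.standardize(m)
        assert out.values[0, 1, 0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[1, 1, 0] == pytest.approx(2.0, abs=1e-12)

    def test_constant_assay_excluded_not_nan(self, design):
        values = np.random.default_rng(1).normal(size=(12, 9, 2))
        values[:, :, 1] = 3.0
        m = sd.ProteinMatrix(design=design, assay_ids=["ok", "const"], values=values)
        out, excluded = ts.standardize(m)
        assert excluded == ["const"]
        assert out.assay_ids == ["ok"]
        assert np.isfinite(out.values).all()


class TestFitTrajectory:
    def test_balanced_contrasts_equal_timepoint_mean_differences(self, design):
        rng = np.random.default_rng(2)
        y = _simulate_y(design, np.zeros(9), 0.5, 0.5, rng)
        res = ts.fit_trajectory(y, design)
        expected = y.mean(axis=0)[1:] - y[:, 0].mean()
        np.testing.assert_allclose(res.beta, expected, atol=1e-10)

    def test_gls_oracle_on_random_unbalanced_instances(self, design):
        """Fixed effects match a dense GLS solve with the estimated covariance."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = _simulate_y(design, rng.normal(0, 1, 9), 0.6, 0.4, rng)
            y[rng.random(y.shape) < 0.1] = np.nan  # unbalanced
            res = ts.fit_trajectory(y, design)
            vals, days, parts = ts._long_arrays(y, design)
            X, _ = ts._design_matrix(days, design)
            Z = (parts[:, None] == np.unique(parts)[None, :]).astype(float)
            V = res.sigma_e2 * np.eye(len(vals)) + res.sigma_u2 * (Z @ Z.T)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ vals)
            np.testing.assert_allclose(res.beta, beta[1:], atol=1e-8)

    def test_statsmodels_mixedlm_cross_check(self, design):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        y = _simulate_y(design, sd.archetype_curve(1, np.asarray(design.timepoints, float)), 0.5, 0.5, rng)
        res = ts.fit_trajectory(y, design)
        df = pd.DataFrame({
            "y": y.reshape(-1),
            "day": pd.Categorical(np.tile(design.timepoints, 12)),
            "pid": np.repeat(np.arange(12), 9),
        })
        fit = smf.mixedlm("y ~ C(day)", df, groups=df["pid"]).fit(reml=True)
        sm_beta = fit.fe_params.to_numpy()[1:]
        np.testing.assert_allclose(res.beta, sm_beta, atol=1e-6)
        np.testing.assert_allclose(res.sigma_u2, float(fit.cov_re.iloc[0, 0]), atol=1e-4)
        np.testing.assert_allclose(res.sigma_e2, fit.scale, atol=1e-4)

    def test_constant_data_flat_and_insignificant(self, design):
        y = np.full((12, 9), 1.7)
        res = ts.fit_trajectory(y, design)
        np.testing.assert_allclose(res.beta, 0.0, atol=1e-10)
        assert res.p_global > 0.999

    def test_coverage_of_planted_day5_effect(self, design):
        rng = np.random.default_rng(5)
        curve = _day_curve(design, 5, 2.0)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            y = _simulate_y(design, curve, 0.5, 0.5, rng)
            res = ts.fit_trajectory(y, design)
            i = res.timepoints.index(5)
            lo = res.beta[i] - 1.96 * res.se[i]
            hi = res.beta[i] + 1.96 * res.se[i]
            hits += lo <= 2.0 <= hi
        assert hits / n_rep >= 0.90

    def test_global_p_monotone_in_amplitude(self, design):
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 0.5, (12, 9))
        u = rng.normal(0, 0.5, 12)
        pvals = []
        for amp in (0.0, 0.4, 0.8, 1.6):
            y = amp * _day_curve(design, 5, 1.0)[None, :] + u[:, None] + noise
            pvals.append(ts.fit_trajectory(y, design).p_global)
        assert pvals == sorted(pvals, reverse=True)

    def test_lrt_statistic_nonnegative_and_less_powerful_calibration(self, design):
        rng = np.random.default_rng(7)
        y = _simulate_y(design, np.zeros(9), 0.5, 0.5, rng)
        res = ts.fit_trajectory(y, design, global_test="lrt")
        assert 0.0 <= res.p_global <= 1.0

    def test_sigma_u_recovered_as_zero(self, design):
        rng = np.random.default_rng(8)
        est = [ts.fit_trajectory(_simulate_y(design, np.zeros(9), 0.0, 1.0, rng), design).sigma_u2
               for _ in range(50)]
        assert np.median(est) < 0.05

    def test_too_few_participants_flagged(self, design):
        y = np.full((12, 9), np.nan)
        y[0] = 1.0
        res = ts.fit_trajectory(y, design)
        assert res.excluded and not res.converged


class TestSexInteraction:
    def test_null_calibration(self, design):
        rng = np.random.default_rng(9)
        curve = sd.archetype_curve(4, np.asarray(design.timepoints, float))
        ps = [ts.test_sex_interaction(_simulate_y(design, curve, 0.5, 0.5, rng), design)
              for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 1e-3
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200) + 0.02

    def test_power_for_sexed_offset(self, design):
        rng = np.random.default_rng(10)
        offset = np.array([1.0 if t in design.fasting_days else 0.0 for t in design.timepoints])
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = _simulate_y(design, np.zeros(9), 0.5, 0.3, rng, sex_offset=offset)
            hits += ts.test_sex_interaction(y, design) < 0.01
        assert hits / n_rep >= 0.95

    def test_single_sex_design_rejected(self):
        design = sd.StudyDesign(participant_ids=tuple("abcdef"), sex=("M",) * 6)
        y = np.random.default_rng(0).normal(size=(6, 9))
        with pytest.raises(ValueError):
            ts.test_sex_interaction(y, design)


class TestExposureAssociation:
    def test_identity_recovers_unit_slope(self, design):
        expo = sd.generate_exposures(design, seed=11)
        y = expo.pivot(index="participant", columns="day", values="weight")
        y = y.loc[list(design.participant_ids), list(design.timepoints)].to_numpy()
        r = ts.associate_exposure(y, expo, design, exposure_name="weight")
        assert r.beta == pytest.approx(1.0, abs=1e-6)

    def test_permutation_null_type_one_error(self, design):
        rng = np.random.default_rng(12)
        expo = sd.generate_exposures(design, seed=12)
        bhb = expo.pivot(index="participant", columns="day", values="bhb")
        bhb = bhb.loc[list(design.participant_ids), list(design.timepoints)].to_numpy()
        n_rep, alpha_hits = 300, 0
        for _ in range(n_rep):
            # null protein: participant intercept + noise, no link to x
            y = rng.normal(0, 0.5, (12, 1)) + rng.normal(0, 0.5, (12, 9))
            # exposure shuffled across participants independently at each day
            x_perm = np.column_stack([bhb[rng.permutation(12), j] for j in range(9)])
            expo_perm = pd.DataFrame({
                "participant": np.repeat(design.participant_ids, 9),
                "day": np.tile(design.timepoints, 12),
                "bhb": x_perm.reshape(-1),
            })
            r = ts.associate_exposure(y, expo_perm, design, exposure_name="bhb")
            alpha_hits += r.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(alpha_hits / n_rep - 0.05) < 3 * se + 0.01

    def test_negative_slope_sign_recovered(self, design):
        rng = np.random.default_rng(13)
        expo = sd.generate_exposures(design, seed=13)
        w = expo.pivot(index="participant", columns="day", values="weight")
        w = w.loc[list(design.participant_ids), list(design.timepoints)].to_numpy()
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = -0.2 * w + rng.normal(0, 0.5, (12, 1)) + rng.normal(0, 0.5, (12, 9))
            r = ts.associate_exposure(y, expo, design, exposure_name="weight")
            hits += r.beta < 0
        assert hits / n_rep >= 0.90

    def test_constant_exposure_rejected(self, design):
        expo = pd.DataFrame({
            "participant": np.repeat(design.participant_ids, 9),
            "day": np.tile(design.timepoints, 12),
            "weight": 70.0,
        })
        y = np.random.default_rng(0).normal(size=(12, 9))
        with pytest.raises(ValueError):
            ts.associate_exposure(y, expo, design, exposure_name="weight")


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.03], [0.03]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(ts.adjust_bh(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ts.adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            ts.adjust_bh([np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_dominance(self, p, rnd):
        p = np.array(p)
        q = ts.adjust_bh(p)
        assert np.all(q >= p - 1e-15)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        np.testing.assert_allclose(ts.adjust_bh(p[perm]), q[perm], atol=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        p = rng.random(200)
        np.testing.assert_allclose(
            ts.adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_discoveries_monotone_in_amplitude(self, design):
        rng = np.random.default_rng(14)
        noise = rng.normal(0, 0.5, (40, 12, 9))
        u = rng.normal(0, 0.5, (40, 12))
        counts = []
        for amp in (0.0, 1.0, 2.0):
            ps = []
            for a in range(40):
                y = amp * _day_curve(design, 5, 1.0)[None, :] + u[a][:, None] + noise[a]
                ps.append(ts.fit_trajectory(y, design).p_global)
            counts.append(int((ts.adjust_bh(np.array(ps)) < 0.05).sum()))
        assert counts == sorted(counts)
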