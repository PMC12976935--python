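import numpy as np
import pytest

from funclust import crm
from funclust.crm import (
    CRMFitConfig,
    CRMObservation,
    CRMParameters,
    analytic_crm,
    build_observations,
    carbon_for_depletion_time,
    crm_rhs,
    fit_crm,
    randomize_group,
    simulate_crm,
    simulate_species_dataset,
)


class TestRHS:
    def test_hand_evaluated_derivatives(self):
        p = CRMParameters(gamma1=1, gamma2=1, r1=1, r2=1, rC=1, KA=1e-3, KC=1e-3)
        d = crm_rhs((1.0, 1.0, 2.0, 1.0), p)
        mA = 2.0 / (2.0 + 1e-3)
        mC = 1.0 / (1.0 + 1e-3)
        np.testing.assert_allclose(d, [mA * mC, mA * mC, -2 * mA, -2 * mC])

    def test_exhausted_nitrate_stops_everything_but_carbon(self):
        p = CRMParameters(gamma1=1, gamma2=2, r1=1, r2=0.5)
        d = crm_rhs((1.0, 1.0, 0.0, 1.0), p)
        assert d[0] == d[1] == d[2] == 0.0
        assert d[3] < 0
        np.testing.assert_array_equal(crm_rhs((1.0, 1.0, 0.0, 0.0), p), 0.0)

    def test_single_biomass_reduction(self):
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.0)
        d = crm_rhs((1.0, 0.0, 2.0, 1.0), p)
        assert d[1] == 0.0  # x2 stays zero: the single-biomass model
        assert d[0] > 0 and d[2] < 0

    def test_negative_state_rejected(self):
        p = CRMParameters(gamma1=1, gamma2=1, r1=1, r2=1)
        with pytest.raises(ValueError):
            crm_rhs((-0.1, 0.0, 1.0, 1.0), p)


class TestSimulate:
    def test_zero_biomass_leaves_resources_constant(self):
        p = CRMParameters(gamma1=1, gamma2=1, r1=1, r2=1)
        traj = simulate_crm(p, (0.0, 0.0, 2.0, 1.0), np.linspace(0, 4, 9))
        np.testing.assert_allclose(traj.nitrate, 2.0, atol=1e-8)
        np.testing.assert_allclose(traj.carbon, 1.0, atol=1e-8)

    def test_nitrate_non_increasing_and_biomass_non_decreasing(self):
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5)
        traj = simulate_crm(p, (0.3, 0.2, 2.0, 1.5), np.linspace(0, 4, 41))
        assert (np.diff(traj.nitrate) <= 1e-9).all()
        assert (np.diff(traj.biomass1) >= -1e-9).all()
        assert (np.diff(traj.biomass2) >= -1e-9).all()

    def test_yield_bookkeeping_in_small_K_limit(self):
        """Nitrate consumed equals sum_i (x_i(T) - x_i(0)) / gamma_i while
        both Monod factors are ~1 (K -> 0, resources not yet depleted)."""
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5, KA=1e-6, KC=1e-6)
        traj = simulate_crm(p, (0.3, 0.2, 5.0, 50.0), np.linspace(0, 1.5, 10))
        consumed = traj.nitrate[0] - traj.nitrate[-1]
        by_yields = (traj.biomass1[-1] - traj.biomass1[0]) / p.gamma1 + (
            traj.biomass2[-1] - traj.biomass2[0]
        ) / p.gamma2
        np.testing.assert_allclose(consumed, by_yields, rtol=1e-4)

    def test_tolerance_convergence(self):
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5)
        times = np.linspace(0, 4, 5)
        a = simulate_crm(p, (0.3, 0.2, 2.0, 1.0), times, rtol=1e-8)
        b = simulate_crm(p, (0.3, 0.2, 2.0, 1.0), times, rtol=1e-10)
        assert np.abs(a.nitrate[-1] - b.nitrate[-1]) / max(a.nitrate[0], 1) < 1e-6


class TestAnalytic:
    def test_growth_inhibited_regime_is_linear(self):
        """t* = 0: biomasses frozen, nitrate declines linearly from t = 0
        (the chloramphenicol-treated limit)."""
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5)
        times = np.linspace(0, 2, 9)
        traj = analytic_crm(p, (0.4, 0.2, 5.0), 0.0, times)
        np.testing.assert_allclose(traj.biomass1, 0.4)
        np.testing.assert_allclose(traj.biomass2, 0.2)
        rate = p.r1 * 0.4 + p.r2 * 0.2
        np.testing.assert_allclose(traj.nitrate, 5.0 - rate * times)

    def test_vanishing_growth_rate_limit(self):
        # gamma1*r1 -> 0: x1 constant, its nitrate term -> r1 x1(0) t
        p = CRMParameters(gamma1=1e-15, gamma2=1.0, r1=1.0, r2=0.0)
        times = np.linspace(0, 2, 5)
        traj = analytic_crm(p, (0.5, 0.0, 3.0), 2.0, times)
        np.testing.assert_allclose(traj.biomass1, 0.5, rtol=1e-9)
        np.testing.assert_allclose(traj.nitrate, 3.0 - 0.5 * times, rtol=1e-9)

    def test_yield_identity_exact(self):
        """x_i(t*) - x_i(0) = gamma_i * (nitrate consumed by consumer i on
        [0, t*]) holds exactly in the analytic solution."""
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.3, r2=0.6)
        x10, x20, A0, t_star = 0.3, 0.2, 8.0, 1.7
        traj = analytic_crm(p, (x10, x20, A0), t_star, np.array([0.0, t_star]))
        for x0, gamma, r, xT in [
            (x10, p.gamma1, p.r1, traj.biomass1[-1]),
            (x20, p.gamma2, p.r2, traj.biomass2[-1]),
        ]:
            k = gamma * r
            consumed_i = r * x0 * (np.exp(k * t_star) - 1) / k
            assert xT - x0 == pytest.approx(gamma * consumed_i, rel=1e-12)

    def test_nitrate_floored_at_zero_and_monotone(self):
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=5.0, r2=3.0)
        traj = analytic_crm(p, (0.5, 0.5, 1.0), 1.0, np.linspace(0, 6, 61))
        assert (traj.nitrate >= 0).all()
        assert (np.diff(traj.nitrate) <= 1e-12).all()
        assert traj.nitrate[-1] == 0.0

    def test_matches_numeric_solution_at_small_affinities(self):
        p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5)
        init = (0.3, 0.4, 2.0)
        t_star = 2.0
        times = np.linspace(0, 4, 41)
        C0 = carbon_for_depletion_time(p, init, t_star)
        num = simulate_crm(p, (*init, C0), times)
        ana = analytic_crm(p, init, t_star, times)
        assert np.abs(num.nitrate - ana.nitrate).max() / init[2] < 0.02

    def test_agreement_improves_as_affinities_shrink(self):
        init = (0.3, 0.4, 2.0)
        t_star = 2.0
        times = np.linspace(0, 4, 41)
        errs = []
        for K in (1e-2, 1e-3, 1e-4):
            p = CRMParameters(gamma1=0.5, gamma2=2.0, r1=1.0, r2=0.5, KA=K, KC=K)
            C0 = carbon_for_depletion_time(p, init, t_star)
            num = simulate_crm(p, (*init, C0), times)
            ana = analytic_crm(p, init, t_star, times)
            errs.append(np.abs(num.nitrate - ana.nitrate).max())
        assert errs[0] > errs[1] > errs[2]


class TestFit:
    def test_noiseless_recovery_small(self):
        """Self-consistency at reduced size: rates and depletion times from
        noiseless analytic-model data come back within 5%. The generating
        yields must sit on the search grid for the check to be well-posed."""
        grid = np.geomspace(0.05, 5.0, 8)
        ds = simulate_species_dataset(n_samples=2, seed=4, gamma1=grid[4], gamma2=grid[5])
        fit = fit_crm(build_observations(ds, ds.grouping), CRMFitConfig(gamma_grid_size=8))
        for i, p in enumerate(ds.params):
            assert fit.r1[i] == pytest.approx(p["r1"], rel=0.05)
            assert fit.t_star[i] == pytest.approx(p["t_star"], rel=0.05)

    def test_single_biomass_r2_unidentifiable(self):
        p = CRMParameters(gamma1=float(np.geomspace(0.05, 5.0, 8)[4]), gamma2=2.0, r1=1.0, r2=0.0)
        times = np.linspace(0, 4, 10)
        obs = []
        for i, (x10, ts) in enumerate([(0.2, 1.5), (0.3, 2.0)]):
            traj = analytic_crm(p, (x10, 0.0, 2.0), ts, times)
            obs.append(CRMObservation(
                sample_id=f"s{i}", x1_0=x10, x2_0=0.0,
                x1_T=traj.biomass1[-1], x2_T=0.0, times=times, nitrate=traj.nitrate,
            ))
        fit = fit_crm(obs, CRMFitConfig(gamma_grid_size=8))
        assert fit.unidentifiable_r2 == ["s0", "s1"]
        assert np.isnan(fit.r2).all()
        for i, (x10, ts) in enumerate([(0.2, 1.5), (0.3, 2.0)]):
            assert fit.r1[i] == pytest.approx(1.0, rel=0.05)

    def test_all_zero_observations_rejected(self):
        times = np.linspace(0, 4, 10)
        obs = [CRMObservation("s0", 0, 0, 0, 0, times, np.zeros(10))]
        with pytest.raises(ValueError):
            fit_crm(obs)


class TestRandomizeGroup:
    def test_tolerance_enforced(self, rng):
        ds = simulate_species_dataset(n_samples=3, seed=1)
        x0 = ds.species_initial.mean(axis=0)
        for seed in range(10):
            null = randomize_group(ds.grouping, ds.species_initial, "group1", seed)
            target = x0[ds.grouping[1]].sum()
            assert abs(x0[null[1]].sum() - target) / target <= 0.05
            assert not set(null[1]) & set(ds.grouping[1].tolist())

    def test_both_mode_gives_disjoint_groups(self):
        ds = simulate_species_dataset(n_samples=3, seed=2)
        for seed in range(5):
            null = randomize_group(ds.grouping, ds.species_initial, "both", seed)
            assert not set(null[1]) & set(null[2])

    def test_null_sums_center_on_target(self):
        ds = simulate_species_dataset(n_samples=3, seed=3)
        x0 = ds.species_initial.mean(axis=0)
        target = x0[ds.grouping[1]].sum()
        rng = np.random.default_rng(0)
        sums = [
            x0[randomize_group(ds.grouping, ds.species_initial, "group1", rng)[1]].sum()
            for _ in range(100)
        ]
        assert np.mean(sums) == pytest.approx(target, rel=0.02)

    def test_unknown_mode_rejected(self):
        ds = simulate_species_dataset(n_samples=2, seed=0)
        with pytest.raises(ValueError):
            randomize_group(ds.grouping, ds.species_initial, "everything", 0)


class TestNullComparison:
    def test_true_grouping_beats_nulls_at_small_n(self):
        """Scaled-down smoke version of the null comparison: the generating
        grouping's nitrate error should sit in the low tail."""
        grid = np.geomspace(0.05, 5.0, 6)
        ds = simulate_species_dataset(n_samples=2, seed=5, gamma1=grid[2], gamma2=grid[3])
        res = crm.null_model_comparison(
            ds, ds.grouping, n_null=20, seed=0,
            fit_config=CRMFitConfig(gamma_grid_size=6), modes=("both",),
        )
        assert res["modes"]["both"]["p_values"]["nitrate_mse"] < 0.3
        assert len(res["modes"]["both"]["errors"]["nitrate_mse"]) == 20

    def test_rejects_tiny_null_count(self):
        ds = simulate_species_dataset(n_samples=2, seed=5)
        with pytest.raises(ValueError):
            crm.null_model_comparison(ds, ds.grouping, n_null=5)
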