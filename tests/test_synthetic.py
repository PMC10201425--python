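"""Generators: stationary distribution, ground truth and determinism."""

import numpy as np
import pytest
from scipy import integrate, stats

import ribomech as rm
from ribomech.afe import ti_integrate
from ribomech.constants import R_KCAL
from ribomech.geometry import reaction_coordinates
from ribomech.synthetic import (
    AnalyticPotential,
    SamplerConfig,
    dense_grid_extrema,
    gen_active_site_traj,
    gen_lambda_series,
    gen_toy_structure,
    gen_umbrella_samples,
    sample_distribution,
    window_grid,
)
from ribomech.trajectory import AtomMap

RT = R_KCAL * 298.15


class TestUmbrellaSampler:
    def test_flat_potential_single_window_centered(self):
        pot = AnalyticPotential.make("flat", ndim=2)
        ws = gen_umbrella_samples(
            pot,
            [(0.0, 0.0)],
            (100.0, 100.0),
            SamplerConfig(n_samples_per_window=4000, seed=1),
        )
        s = ws.windows[0].samples
        # bias minimum is the only structure: mean within 3 standard errors
        sd_theory = np.sqrt(RT / 100.0)
        for d in range(2):
            se = sd_theory / np.sqrt(4000 / 10)  # generous ESS allowance
            assert abs(s[:, d].mean()) < 3 * se + 3e-3

    def test_harmonic_zero_bias_variance_matches_closed_form(self):
        pot = AnalyticPotential.make("harmonic", kappa=2.0)
        ws = gen_umbrella_samples(
            pot, [[0.0]], 1e-12, SamplerConfig(n_samples_per_window=40_000, seed=5)
        )
        var = ws.windows[0].samples[:, 0].var()
        assert var == pytest.approx(RT / 2.0, rel=0.05)

    def test_symmetric_double_well_equal_occupancy(self):
        # ensemble of independent unbiased chains started at the barrier top:
        # each relaxes into a random well, occupancy ratio ~ 1:1
        pot = AnalyticPotential.make("double_well_1d", a=5.0)
        ws = gen_umbrella_samples(
            pot,
            [[0.0]] * 64,
            1e-12,
            SamplerConfig(n_samples_per_window=2000, burn_in=800, seed=17),
        )
        means = np.array([w.samples[:, 0].mean() for w in ws.windows])
        n_right = int((means > 0).sum())
        # binomial 99% interval for p=0.5, n=64
        lo, hi = stats.binom.ppf([0.005, 0.995], 64, 0.5)
        assert lo <= n_right <= hi

    def test_detailed_balance_boltzmann_histogram(self):
        # long unbiased runs on a low-barrier double well; chi-square GOF of
        # the (thinned) histogram against the Boltzmann weights at alpha=0.01
        pot = AnalyticPotential.make("double_well_1d", a=1.0)
        ws = gen_umbrella_samples(
            pot,
            [[0.0]] * 8,
            1e-12,
            SamplerConfig(n_samples_per_window=6000, burn_in=1000, seed=23, thin=10),
        )
        x = np.concatenate([w.samples[:, 0] for w in ws.windows])
        edges = np.linspace(-1.8, 1.8, 13)
        x = x[(x >= edges[0]) & (x <= edges[-1])]
        obs, _ = np.histogram(x, edges)
        probs = np.array(
            [
                integrate.quad(
                    lambda t: float(np.exp(-pot.energy(np.array([[t]]))[0] / RT)), a, b
                )[0]
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
        probs /= probs.sum()
        stat, p = stats.chisquare(obs, probs * obs.sum())
        assert p > 0.01

    def test_zero_windows_rejected(self):
        pot = AnalyticPotential.make("flat", ndim=1)
        with pytest.raises(ValueError):
            gen_umbrella_samples(pot, [], 10.0, SamplerConfig(n_samples_per_window=10))

    def test_seed_determinism_bit_identical(self):
        pot = AnalyticPotential.make("double_well_1d", a=5.0)
        cfg = SamplerConfig(n_samples_per_window=200, seed=3)
        a = gen_umbrella_samples(pot, [[-1.0], [1.0]], 50.0, cfg)
        b = gen_umbrella_samples(pot, [[-1.0], [1.0]], 50.0, cfg)
        for wa, wb in zip(a.windows, b.windows):
            np.testing.assert_array_equal(wa.samples, wb.samples)

    def test_window_grid_exposes_ranges_and_step(self):
        centers = window_grid((-1.5, 1.5), (-2.5, 2.5), 0.2)
        assert len(centers) == 16 * 26
        assert centers[0] == (-1.5, -2.5) and centers[-1] == (1.5, 2.5)


class TestLambdaSeries:
    def test_zero_target_zero_noise_integrates_to_zero(self):
        s = gen_lambda_series(0.0, "linear", 0.0, 8, 10, seed=0)
        assert ti_integrate(s).value == pytest.approx(0.0, abs=1e-12)

    def test_linear_noiseless_trapezoid_exact(self):
        s = gen_lambda_series(2.810, "linear", 0.0, 12, 10, seed=0)
        assert ti_integrate(s).value == pytest.approx(2.810, abs=1e-12)

    def test_cubic_shape_integral_matches_target(self):
        s = gen_lambda_series(-3.5, "cubic", 0.0, 101, 10, seed=0)
        # dense grid: trapezoid discretization error is negligible
        assert ti_integrate(s).value == pytest.approx(-3.5, abs=1e-3)

    def test_noisy_series_recovered_within_two_se(self):
        s = gen_lambda_series(2.810, "linear", 0.5, 12, 500, seed=7)
        est = ti_integrate(s)
        assert abs(est.value - 2.810) <= 2 * est.se

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_lambda_series(1.0, "linear", 0.5, 1, 100)
        with pytest.raises(ValueError):
            gen_lambda_series(1.0, "linear", -0.1, 5, 100)


class TestActiveSiteTrajectory:
    def test_point_mass_geometry_reproduced_exactly(self):
        traj = gen_active_site_traj(
            50, {"kind": "point", "value": 3.0}, {"kind": "point", "value": 160.0}, seed=1
        )
        amap = AtomMap.default_synthetic()
        res = rm.inline_fitness(traj, amap)
        np.testing.assert_allclose(res.distances, 3.0, atol=1e-9)
        np.testing.assert_allclose(res.angles, 160.0, atol=1e-9)
        assert res.fraction == 1.0

    def test_proton_transfer_asymmetry_exact(self):
        traj = gen_active_site_traj(
            3,
            {"kind": "point", "value": 3.0},
            {"kind": "point", "value": 160.0},
            seed=1,
            pt_asymmetry=-0.7,
        )
        rc = reaction_coordinates(traj.frame(0), AtomMap.default_synthetic())
        assert rc.xi_pt == pytest.approx(-0.7, abs=1e-9)

    def test_mixture_in_box_fraction_within_binomial_ci(self):
        dist = {
            "kind": "mixture",
            "components": [
                {"weight": 0.8, "dist": {"kind": "point", "value": 3.0}},
                {"weight": 0.2, "dist": {"kind": "point", "value": 4.0}},
            ],
        }
        traj = gen_active_site_traj(10_000, dist, {"kind": "point", "value": 160.0}, seed=1)
        frac = rm.inline_fitness(traj, AtomMap.default_synthetic()).fraction
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.8) / 10_000
        assert lo <= frac <= hi

    def test_same_seed_identical_coordinates(self):
        spec_d = {"kind": "truncnorm", "mean": 3.2, "sd": 0.3, "low": 2.0, "high": 5.0}
        spec_a = {"kind": "uniform", "low": 120.0, "high": 180.0}
        t1 = gen_active_site_traj(100, spec_d, spec_a, seed=11)
        t2 = gen_active_site_traj(100, spec_d, spec_a, seed=11)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError):
            sample_distribution({"kind": "cauchy"}, 5, np.random.default_rng(0))


class TestToyStructure:
    def test_zero_sigma_all_models_identical(self):
        traj, ref = gen_toy_structure(4, 2, 0.0, n_models=5, seed=0)
        prof = rm.atomic_fluctuations(traj, reference=ref, presuperpose=False)
        np.testing.assert_allclose(prof.sigma, 0.0, atol=1e-12)

    def test_isotropic_sigma_gives_rmsf_sigma_sqrt3(self, isotropic_toy_structure):
        traj, ref = isotropic_toy_structure
        prof = rm.atomic_fluctuations(traj, reference=ref, presuperpose=False)
        assert prof.sigma.mean() == pytest.approx(0.5 * np.sqrt(3.0), rel=0.02)

    def test_fluctuation_ranking_preserved(self):
        traj, ref = gen_toy_structure(3, 4, [0.2, 0.4, 0.8], n_models=400, seed=2)
        prof = rm.atomic_fluctuations(traj, reference=ref, presuperpose=False)
        assert prof.sigma[0] < prof.sigma[1] < prof.sigma[2]

    def test_reference_bfactors_follow_declared_convention(self):
        traj, _ = gen_toy_structure(3, 2, [0.2, 0.4, 0.8], n_models=2, seed=0)
        sigma3d = rm.bvalue_to_sigma(traj.bfactors)
        np.testing.assert_allclose(
            sigma3d[::2], np.array([0.2, 0.4, 0.8]) * np.sqrt(3.0), rtol=1e-12
        )

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            gen_toy_structure(3, 2, 0.5, n_models=1)


class TestTwoChannelOracle:
    def test_grid_search_finds_corner_basins_and_tilted_saddle(self):
        pot = AnalyticPotential.make("two_channel_2d", a=2.0, c=0.6)
        res = dense_grid_extrema(pot)
        (m1, m2) = (np.array(m["xy"]) for m in res["minima"])
        np.testing.assert_allclose(m1, [-1.0, -1.0], atol=0.06)
        np.testing.assert_allclose(m2, [1.0, 1.0], atol=0.06)
        # bottleneck saddle sits on the low (PT-first) channel: a - c relative
        # to the corner term, located near (0, -1) or (1, 0)
        sx, sy = res["saddle"]["xy"]
        on_low_channel = (abs(sy + 1.0) < 0.1) or (abs(sx - 1.0) < 0.1)
        assert on_low_channel
        assert res["saddle"]["energy"] == pytest.approx(2.0 - 0.6, abs=0.05)
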