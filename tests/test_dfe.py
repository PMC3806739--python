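import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import expon as expon_dist, gamma as gamma_dist

from popsel.demography import SelectionGrid, build_equilibrium_cache
from popsel.dfe import (
    DFEModel,
    bootstrap_ci,
    class_masses,
    dfe_weights,
    expected_sfs_under_dfe,
    fit_dfe,
    poisson_loglik,
)
from popsel.sfs import Spectrum

from conftest import random_spectrum


class TestDFEModel:
    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            DFEModel("weird", {})

    def test_rejects_bad_proportion(self):
        with pytest.raises(ValueError, match="p_point"):
            DFEModel("point_lethal", {"p_point": 1.4, "gamma_point": -1.0})

    def test_rejects_positive_point(self):
        with pytest.raises(ValueError, match="negative"):
            DFEModel("point_lethal", {"p_point": 0.5, "gamma_point": 2.0})


class TestWeights:
    def test_point_mass_on_grid_value(self, reduced_grid):
        g = reduced_grid.gamma_values
        target = g[g < 0][10]
        dfe = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": target})
        w = dfe_weights(dfe, reduced_grid)
        assert w.grid_weights[10] == pytest.approx(0.36)
        assert w.lethal_mass == pytest.approx(0.64)
        assert w.total() == pytest.approx(1.0)

    def test_point_mass_interpolates_between_grid_points(self, reduced_grid):
        g = reduced_grid.gamma_values
        mid = -np.sqrt(g[g < 0][10] * g[g < 0][11])  # log-midpoint
        dfe = DFEModel("point_lethal", {"p_point": 1.0, "gamma_point": mid})
        w = dfe_weights(dfe, reduced_grid)
        assert w.grid_weights[10] == pytest.approx(0.5)
        assert w.grid_weights[11] == pytest.approx(0.5)

    def test_gamma_family_normalizes(self, reduced_grid):
        dfe = DFEModel("gamma", {"shape": 0.2, "scale": 1000.0})
        w = dfe_weights(dfe, reduced_grid)
        assert w.total() == pytest.approx(1.0, abs=1e-9)

    def test_expon_matches_fine_quadrature_oracle(self, reduced_grid):
        mean, p_lethal = 40.0, 0.2
        dfe = DFEModel("expon_lethal", {"mean": mean, "p_lethal": p_lethal})
        w = dfe_weights(dfe, reduced_grid)
        # 1e6-point midpoint quadrature of the |gamma| density over each
        # Voronoi cell in log-magnitude space
        g = reduced_grid.gamma_values
        neg = g[g < 0]
        lg = np.log(-neg)
        edges_mag = np.concatenate([[-neg[0]], np.exp((lg[:-1] + lg[1:]) / 2.0), [0.0]])
        z = np.linspace(1e-9, 5000.0, 1_000_000)
        dz = z[1] - z[0]
        pdf = expon_dist.pdf(z, scale=mean)
        oracle = np.zeros_like(w.grid_weights)
        for k in range(len(neg)):
            hi_mag, lo_mag = edges_mag[k], edges_mag[k + 1]
            sel = (z > lo_mag) & (z <= hi_mag)
            oracle[k] = (1 - p_lethal) * pdf[sel].sum() * dz
        assert np.max(np.abs(w.grid_weights - oracle)) < 1e-4

    def test_mass_beyond_grid_minimum_is_lethal(self, reduced_grid):
        dfe = DFEModel("expon_lethal", {"mean": 5000.0, "p_lethal": 0.0})
        w = dfe_weights(dfe, reduced_grid)
        beyond = expon_dist.sf(2000.0, scale=5000.0)
        assert w.lethal_mass == pytest.approx(beyond, rel=1e-6)

    def test_norm_family_reaches_positive_branch(self, reduced_grid):
        dfe = DFEModel("norm_lethal", {"mean": 0.0, "sd": 10.0, "p_lethal": 0.0})
        w = dfe_weights(dfe, reduced_grid)
        g = reduced_grid.gamma_values
        assert w.grid_weights[g > 0].sum() == pytest.approx(0.5, abs=0.01)
        assert w.total() == pytest.approx(1.0, abs=1e-9)


class TestExpectedUnderDfe:
    def test_neutral_point_delegates(self, eq_cache, reduced_grid):
        g = reduced_grid.gamma_values
        tiny = g[g < 0][-1]  # -1e-6, indistinguishable from neutral
        dfe = DFEModel("point_lethal", {"p_point": 1.0, "gamma_point": tiny})
        out = expected_sfs_under_dfe(eq_cache, dfe, theta_non=3.0)
        neutral = eq_cache.spectra[int(np.flatnonzero(g == 0)[0])]
        np.testing.assert_allclose(out.counts[1:8], 3.0 * neutral.counts[1:8],
                                   rtol=1e-4)

    def test_full_lethality_zero_spectrum(self, eq_cache):
        dfe = DFEModel("expon_lethal", {"mean": 1.0, "p_lethal": 1.0})
        out = expected_sfs_under_dfe(eq_cache, dfe, theta_non=5.0)
        assert out.segregating_total() == 0.0

    def test_two_point_mixture_hand_sum(self, eq_cache, reduced_grid):
        g = reduced_grid.gamma_values
        i1, i2 = 5, 20
        a = DFEModel("point_lethal", {"p_point": 1.0, "gamma_point": g[i1]})
        b = DFEModel("point_lethal", {"p_point": 1.0, "gamma_point": g[i2]})
        mix_counts = (
            0.3 * expected_sfs_under_dfe(eq_cache, a, 2.0).counts
            + 0.7 * expected_sfs_under_dfe(eq_cache, b, 2.0).counts
        )
        hand = 2.0 * (0.3 * eq_cache.spectra[i1].counts + 0.7 * eq_cache.spectra[i2].counts)
        np.testing.assert_allclose(mix_counts, hand, rtol=1e-12)

    def test_linear_in_theta(self, eq_cache):
        dfe = DFEModel("gamma", {"shape": 0.2, "scale": 100.0})
        a = expected_sfs_under_dfe(eq_cache, dfe, 1.0)
        b = expected_sfs_under_dfe(eq_cache, dfe, 4.0)
        np.testing.assert_allclose(b.counts, 4.0 * a.counts)


class TestPoissonLoglik:
    def test_closed_form_entry(self):
        m = Spectrum(np.array([0.0, 1.0, 0.0]))
        d = Spectrum(np.array([0.0, 2.0, 0.0]))
        assert poisson_loglik(m, d) == pytest.approx(-1.0 + 2 * np.log(1.0) - np.log(2.0))

    def test_model_zero_data_positive(self):
        m = Spectrum(np.array([0.0, 0.0, 1.0, 0.0]))
        d = Spectrum(np.array([0.0, 2.0, 1.0, 0.0]))
        assert poisson_loglik(m, d) == -np.inf

    def test_scaling_mle_property(self, rng):
        d = random_spectrum(rng, (9,))
        base = poisson_loglik(d, d)
        for c in (0.8, 1.2):
            scaled = Spectrum(d.counts * c, mask=d.mask.copy())
            assert poisson_loglik(scaled, d) <= base

    def test_matches_bruteforce_sum(self, rng):
        m = random_spectrum(rng, (7, 7))
        m.counts[~m.mask] += 0.5
        d = random_spectrum(rng, (7, 7))
        expected = 0.0
        for idx in np.ndindex(m.counts.shape):
            if m.mask[idx]:
                continue
            mm, dd = m.counts[idx], d.counts[idx]
            expected += -mm + dd * np.log(mm) - gammaln(dd + 1)
        assert poisson_loglik(m, d) == pytest.approx(expected)

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            poisson_loglik(random_spectrum(rng, (7,)), random_spectrum(rng, (9,)))


class TestFitDfe:
    def test_noiseless_point_lethal_recovery(self, eq_cache):
        truth = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": -0.85})
        theta = 800.0
        data = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
        fit = fit_dfe(data, eq_cache, "point_lethal", theta_non=theta, seed=7)
        assert fit.params["p_point"] == pytest.approx(0.36, abs=0.01)
        assert fit.params["gamma_point"] == pytest.approx(-0.85, rel=0.10)
        # fitted likelihood at least as good as at the generating parameters
        truth_model = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
        assert fit.loglik >= poisson_loglik(truth_model, data) - 1e-6

    def test_noisy_recovery_majority_of_seeds(self, eq_cache):
        truth = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": -0.85})
        theta = 6000.0  # ~4.9k segregating sites, the study's scale
        exp = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            noisy = Spectrum(
                np.where(exp.mask, 0.0, rng.poisson(exp.counts)).astype(float),
                folded=True, mask=exp.mask.copy(),
            )
            fit = fit_dfe(noisy, eq_cache, "point_lethal", theta_non=theta, seed=rep)
            hits += abs(fit.params["p_point"] - 0.36) <= 0.05
        assert hits >= 0.9 * n_rep

    def test_gamma_family_beats_own_truth(self, eq_cache):
        truth = DFEModel("gamma", {"shape": 0.25, "scale": 400.0})
        theta = 500.0
        data = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
        fit = fit_dfe(data, eq_cache, "gamma", theta_non=theta, seed=3)
        truth_ll = poisson_loglik(
            expected_sfs_under_dfe(eq_cache, truth, theta).fold(), data
        )
        assert fit.loglik >= truth_ll - 1e-6

    def test_reduced_vs_dense_grid_agreement(self):
        # 60-point vs full 2501-point grid, noiseless point_lethal data
        truth = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": -0.85})
        theta = 800.0
        small = build_equilibrium_cache(SelectionGrid.reduced(), 8)
        dense = build_equilibrium_cache(SelectionGrid.default(), 8)
        p_hats = []
        for cache in (small, dense):
            data = expected_sfs_under_dfe(cache, truth, theta).fold()
            fit = fit_dfe(data, cache, "point_lethal", theta_non=theta, seed=11)
            p_hats.append(fit.params["p_point"])
        assert abs(p_hats[0] - p_hats[1]) < 0.02

    def test_fitted_total_near_data_total(self, eq_cache):
        truth = DFEModel("expon_lethal", {"mean": 30.0, "p_lethal": 0.3})
        theta = 600.0
        rng = np.random.default_rng(5)
        exp = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
        data = Spectrum(np.where(exp.mask, 0.0, rng.poisson(exp.counts)).astype(float),
                        folded=True, mask=exp.mask.copy())
        fit = fit_dfe(data, eq_cache, "expon_lethal", theta_non=theta, seed=5)
        model = expected_sfs_under_dfe(eq_cache, fit.dfe(), theta).fold()
        tot = data.segregating_total()
        assert abs(model.segregating_total() - tot) < 3.0 * np.sqrt(tot)


class TestClassMasses:
    def test_paper_style_point_lethal_bins(self):
        dfe = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": -0.85})
        masses = class_masses(dfe, N_anc=17000.0)  # |s| = 2.5e-5 < 1e-4
        np.testing.assert_allclose(masses, [64.0, 0.0, 0.0, 36.0])

    def test_full_lethality(self):
        dfe = DFEModel("expon_lethal", {"mean": 1.0, "p_lethal": 1.0})
        np.testing.assert_allclose(class_masses(dfe, 1000.0), [100.0, 0, 0, 0])

    def test_gamma_masses_match_cdf_oracle(self):
        shape, scale, N = 0.3, 500.0, 10000.0
        dfe = DFEModel("gamma", {"shape": shape, "scale": scale})
        masses = class_masses(dfe, N)
        edges = [2 * N * s for s in (-1e-2, -1e-3, -1e-4)]
        cdf = lambda x: gamma_dist.sf(-x, a=shape, scale=scale)
        oracle = 100.0 * np.array([
            cdf(edges[0]),
            cdf(edges[1]) - cdf(edges[0]),
            cdf(edges[2]) - cdf(edges[1]),
            1.0 - cdf(edges[2]),
        ])
        np.testing.assert_allclose(masses, oracle, atol=1e-6)

    def test_masses_sum_to_100(self):
        dfe = DFEModel("norm_lethal", {"mean": -5.0, "sd": 50.0, "p_lethal": 0.25})
        assert class_masses(dfe, 5000.0).sum() == pytest.approx(100.0)


class TestBootstrap:
    def test_single_entry_zero_width(self, eq_cache):
        counts = np.zeros(9)
        counts[1] = 50.0
        data = Spectrum(counts).fold()
        ci = bootstrap_ci(data, eq_cache, "point_lethal", n_boot=5, seed=0,
                          theta_non=100.0, n_restarts=2)
        for lo, hi in ci.values():
            assert hi - lo < 1e-6

    def test_interval_shrinks_with_data(self, eq_cache):
        truth = DFEModel("point_lethal", {"p_point": 0.36, "gamma_point": -0.85})
        widths = []
        for theta in (60.0, 6000.0):
            exp = expected_sfs_under_dfe(eq_cache, truth, theta).fold()
            rng = np.random.default_rng(2)
            data = Spectrum(np.where(exp.mask, 0.0, rng.poisson(exp.counts)).astype(float),
                            folded=True, mask=exp.mask.copy())
            ci = bootstrap_ci(data, eq_cache, "point_lethal", n_boot=25, seed=9,
                              theta_non=theta, n_restarts=2)
            lo, hi = ci["p_point"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]
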