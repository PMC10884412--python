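"""Poisson-random-field expected SFS against quadrature oracles, gamma
DFE parameter recovery, adaptive-divergence estimation, MK statistics,
bootstrap, and class contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import comb

from polyrekit import selectionrx as sx
from polyrekit import simgenome as sg


class TestExpectedSfs:
    def test_neutral_folded_proportions_n4(self):
        e = sx.expected_folded_sfs(0.0, 1.0, 4)
        props = e / e.sum()
        assert props[0] == pytest.approx(8 / 11)
        assert props[1] == pytest.approx(3 / 11)

    def test_matches_numerical_integration_oracle(self):
        def unfolded_class(s, n, i):
            def f(q):
                dens = (1 - np.exp(-s * (1 - q))) \
                    / ((1 - np.exp(-s)) * q * (1 - q))
                return dens * comb(n, i) * q**i * (1 - q)**(n - i)
            return integrate.quad(f, 0, 1, limit=200)[0]

        for s in (-5.0, -0.5, 2.0):
            n = 10
            unf = [unfolded_class(s, n, i) for i in range(1, n)]
            oracle = sx.fold_sfs(np.array(unf), n)
            mine = sx.expected_folded_sfs(s, 1.0, n)
            assert np.abs(mine - oracle).max() < 1e-8

    def test_lethal_limit_vanishes(self):
        e = sx.expected_folded_sfs(-1e4, 1.0, 10)
        assert e.max() < 1e-3

    def test_continuous_at_zero(self):
        lo = sx.expected_folded_sfs(-1e-6, 1.0, 8)
        hi = sx.expected_folded_sfs(1e-6, 1.0, 8)
        at = sx.expected_folded_sfs(0.0, 1.0, 8)
        assert np.abs(lo - at).max() < 1e-5
        assert np.abs(hi - at).max() < 1e-5

    def test_monotone_decreasing_in_deleterious_strength(self):
        strengths = [0.0, -1.0, -5.0, -20.0, -100.0]
        prev = None
        for s in strengths:
            e = sx.expected_folded_sfs(s, 1.0, 12)
            if prev is not None:
                assert (e <= prev + 1e-12).all()
            prev = e

    def test_folding_equals_complementary_sums(self, rng):
        n = 12
        unfolded = rng.uniform(0, 5, size=n - 1)
        folded = sx.fold_sfs(unfolded, n)
        for i in range(1, n // 2 + 1):
            want = unfolded[i - 1] if i == n - i \
                else unfolded[i - 1] + unfolded[n - i - 1]
            assert folded[i - 1] == pytest.approx(want)


class TestFixationFactor:
    def test_matches_quadrature_oracle(self):
        for shape, mean in [(0.4, 2000.0), (0.5, 100.0), (0.2, 50.0)]:
            scale = mean / shape

            def f(g):
                h = g / np.expm1(g) if 1e-8 < g < 500 else \
                    (1.0 if g <= 1e-8 else 0.0)
                return stats.gamma.pdf(g, shape, scale=scale) * h

            oracle, _ = integrate.quad(f, 0, np.inf, limit=400)
            assert sx.dfe_fixation_factor(shape, mean) \
                == pytest.approx(oracle, rel=1e-6)

    def test_neutral_point_mass_is_one(self):
        assert sx.dfe_fixation_factor(0.4, 0.0) == 1.0


class TestDfeFit:
    def test_parameter_recovery(self):
        cfg = sg.SimConfig(seed=51, dfe_shape=0.4, dfe_mean_nes=2000.0,
                           theta_site=0.01, n_chrom_sampled=24)
        sel = sg.simulate_selection_data(cfg, n_genes_per_class=200)
        fit = sx.fit_gamma_dfe(sel[2])
        assert abs(fit.shape - 0.4) < 0.1
        true_bins = sx.gamma_bin_props(0.4, 2000.0)
        for got, want in zip(fit.bin_props, true_bins):
            assert abs(got - want) < 0.05
        assert sum(fit.bin_props) == pytest.approx(1.0)

    def test_neutral_data_concentrates_in_weakest_bin(self):
        cfg = sg.SimConfig(seed=52, dfe_mean_nes=0.0, alpha_true=0.0,
                           theta_site=0.02)
        sel = sg.simulate_selection_data(cfg, n_genes_per_class=150)
        fit = sx.fit_gamma_dfe(sel[1])
        assert fit.bin_props[0] > 0.8

    def test_likelihood_peaks_at_truth_on_noise_free_data(self):
        # expected (noise-free) counts: the Poisson log-likelihood at the
        # generating parameters beats nearby perturbations
        shape, mean, n, theta = 0.5, 100.0, 12, 500.0
        lam0 = sx.dfe_expected_folded_sfs(shape, mean, theta, n)

        def ll(sh, mn):
            lam = sx.dfe_expected_folded_sfs(sh, mn, theta, n)
            return float(stats.poisson.logpmf(np.round(lam0), lam).sum())

        base = ll(shape, mean)
        for sh, mn in [(0.3, 100.0), (0.8, 100.0), (0.5, 30.0),
                       (0.5, 400.0)]:
            assert base >= ll(sh, mn)

    def test_empty_synonymous_rejected(self):
        genes = pd.DataFrame({"gene": ["g"], "L0": [600], "L4": [200],
                              "Pn": [0], "Ps": [0], "Dn": [1], "Ds": [1]})
        sel = sx.SelectionInput(1, 8, genes, np.zeros((1, 4)),
                                np.zeros((1, 4)))
        with pytest.raises(ValueError, match="synonymous"):
            sx.fit_gamma_dfe(sel)


class TestAlpha:
    def _sel(self, cfg, n_genes=150, **kw):
        return sg.simulate_selection_data(cfg, n_genes_per_class=n_genes,
                                          **kw)

    def test_neutral_identity_alpha_zero(self):
        # DFE at S=0 and Dn = Ds * L0/L4 gives alpha exactly 0
        genes = pd.DataFrame({"gene": ["g"], "L0": [600.0], "L4": [200.0],
                              "Pn": [10], "Ps": [10], "Dn": [300.0],
                              "Ds": [100.0]})
        sel = sx.SelectionInput(1, 8, genes, np.ones((1, 4)),
                                np.ones((1, 4)))
        fit = sx.DFEFit(shape=0.5, mean_nes=0.0, theta_ns=1.0,
                        bin_props=(1, 0, 0, 0), loglik=0.0,
                        converged=True, n_chrom=8)
        est = sx.estimate_alpha_omega_a(fit, sel, n_boot=0)
        assert est.alpha == pytest.approx(0.0)

    def test_lethal_dfe_alpha_one(self):
        genes = pd.DataFrame({"gene": ["g"], "L0": [600.0], "L4": [200.0],
                              "Pn": [1], "Ps": [10], "Dn": [50.0],
                              "Ds": [100.0]})
        sel = sx.SelectionInput(1, 8, genes, np.ones((1, 4)),
                                np.ones((1, 4)))
        fit = sx.DFEFit(shape=10.0, mean_nes=1e6, theta_ns=1.0,
                        bin_props=(0, 0, 0, 1), loglik=0.0,
                        converged=True, n_chrom=8)
        est = sx.estimate_alpha_omega_a(fit, sel, n_boot=0)
        assert est.alpha == pytest.approx(1.0, abs=1e-3)

    def test_omega_a_identity(self):
        cfg = sg.SimConfig(seed=53, alpha_true=0.3)
        sel = self._sel(cfg)[2]
        fit = sx.fit_gamma_dfe(sel)
        est = sx.estimate_alpha_omega_a(fit, sel, n_boot=0)
        t = sel.totals()
        assert est.omega_a == pytest.approx(
            est.alpha * (t["Dn"] / t["L0"]) / (t["Ds"] / t["L4"]))

    def test_zero_ds_rejected(self):
        genes = pd.DataFrame({"gene": ["g"], "L0": [600.0], "L4": [200.0],
                              "Pn": [1], "Ps": [1], "Dn": [5.0],
                              "Ds": [0.0]})
        sel = sx.SelectionInput(1, 8, genes, np.ones((1, 4)),
                                np.ones((1, 4)))
        fit = sx.DFEFit(0.5, 10.0, 1.0, (0.5, 0.3, 0.1, 0.1), 0.0, True, 8)
        with pytest.raises(ValueError, match="divergence"):
            sx.estimate_alpha_omega_a(fit, sel, n_boot=0)

    def test_bootstrap_deterministic_under_seed(self):
        cfg = sg.SimConfig(seed=54, alpha_true=0.3)
        sel = self._sel(cfg, n_genes=60)[1]
        fit = sx.fit_gamma_dfe(sel, n_starts=2)
        e1 = sx.estimate_alpha_omega_a(
            fit, sel, n_boot=5, rng=np.random.default_rng(9),
            boot_starts=1)
        e2 = sx.estimate_alpha_omega_a(
            fit, sel, n_boot=5, rng=np.random.default_rng(9),
            boot_starts=1)
        np.testing.assert_array_equal(e1.bootstrap_alpha,
                                      e2.bootstrap_alpha)


class TestMkStats:
    def test_fi_symmetric_counts(self):
        fi, corrected = sx.fixation_index(10, 10, 10, 10)
        assert fi == pytest.approx(1.0)
        assert not corrected

    def test_fi_arithmetic(self):
        fi, _ = sx.fixation_index(10, 10, 5, 10)
        assert fi == pytest.approx(2.0)

    def test_fi_zero_cell_corrected(self):
        fi, corrected = sx.fixation_index(10, 10, 5, 0)
        assert corrected
        assert fi == pytest.approx((10.5 / 10.5) / (5.5 / 0.5))

    def test_fi_all_zero_undefined(self):
        fi, corrected = sx.fixation_index(0, 0, 0, 0)
        assert fi is None

    def test_constraint_zero_when_ratios_match(self):
        # Pn+.5 / Ps+.5 == L0/L4 -> constraint 0
        c, s = sx.snipre_like_effects(dn=2, ds=2, pn=5.5, ps=1.5,
                                      l0=600, l4=200)
        assert c == pytest.approx(0.0)
        assert s == pytest.approx(math.log(2.5 / 2.5) - math.log(3.0))

    def test_selection_zero_when_ratios_match(self):
        c, s = sx.snipre_like_effects(dn=9.5, ds=4.5, pn=9.5, ps=4.5,
                                      l0=600, l4=200)
        assert s == pytest.approx(0.0)

    def test_hand_built_table(self):
        c, s = sx.snipre_like_effects(dn=10, ds=5, pn=4, ps=8,
                                      l0=500, l4=250)
        assert c == pytest.approx(math.log(4.5 / 8.5) - math.log(2.0))
        assert s == pytest.approx(math.log(10.5 / 5.5)
                                  - math.log(4.5 / 8.5))


class TestBootstrap:
    def _sel(self, n_genes=10):
        genes = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n_genes)],
            "L0": 600.0, "L4": 200.0, "Pn": 5, "Ps": 10,
            "Dn": 8.0, "Ds": 12.0})
        sfs = np.ones((n_genes, 4))
        return sx.SelectionInput(1, 8, genes, sfs, sfs.copy())

    def test_identical_genes_zero_width(self):
        sel = self._sel()
        boots = sx.bootstrap_by_gene(
            sel, lambda s: s.totals()["Dn"] / s.totals()["Ds"], n_reps=20,
            rng=np.random.default_rng(1))
        assert np.ptp(boots) == 0.0

    def test_fixed_seed_reproducible(self):
        sel = self._sel()
        stat = lambda s: float(s.pooled_zero.sum())
        b1 = sx.bootstrap_by_gene(sel, stat, 10, np.random.default_rng(7))
        b2 = sx.bootstrap_by_gene(sel, stat, 10, np.random.default_rng(7))
        np.testing.assert_array_equal(b1, b2)

    def test_bootstrap_se_close_to_analytic_for_mean(self, rng):
        values = rng.normal(10, 2, size=200)
        genes = pd.DataFrame({
            "gene": [f"g{i}" for i in range(200)],
            "L0": 1.0, "L4": 1.0, "Pn": values, "Ps": 1.0,
            "Dn": 1.0, "Ds": 1.0})
        sel = sx.SelectionInput(1, 8, genes, np.ones((200, 4)),
                                np.ones((200, 4)))
        boots = sx.bootstrap_by_gene(
            sel, lambda s: float(s.genes["Pn"].mean()), n_reps=400,
            rng=rng)
        analytic = values.std(ddof=1) / math.sqrt(200)
        assert abs(boots.std(ddof=1) - analytic) / analytic < 0.2


class TestContrasts:
    def test_identical_samples(self):
        out = sx.compare_retention_classes(
            {1: [1.0, 1.0, 1.0], 2: [1.0, 1.0, 1.0]})
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0
        assert out.loc[0, "degenerate"]

    def test_known_shift_matches_reference(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        out = sx.compare_retention_classes({1: a, 3: b})
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert out.loc[0, "t"] == pytest.approx(t_ref, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_star_annotations(self, rng):
        out = sx.compare_retention_classes({
            1: rng.normal(0, 1, 500), 2: rng.normal(0.15, 1, 500),
            3: rng.normal(5, 1, 500)})
        by = out.set_index(["class_a", "class_b"])
        assert by.loc[(1, 3), "stars"] == "***"
        assert by.loc[(1, 3), "p"] < 0.001

    def test_fig4_style_ordering_with_graded_selection(self):
        # stronger purifying + adaptive selection from one- to
        # three-copy classes: alpha and FI increase with class,
        # constraint effect decreases
        cfg = sg.SimConfig(seed=55, theta_site=0.01)
        class_params = {
            1: {"mean_nes": 50.0, "alpha": 0.0},
            2: {"mean_nes": 500.0, "alpha": 0.2},
            3: {"mean_nes": 5000.0, "alpha": 0.5},
        }
        sel = sg.simulate_selection_data(cfg, n_genes_per_class=200,
                                         class_params=class_params)
        alphas, fis, constraints = [], [], []
        for klass in (1, 2, 3):
            fit = sx.fit_gamma_dfe(sel[klass], n_starts=3)
            est = sx.estimate_alpha_omega_a(fit, sel[klass], n_boot=0)
            t = sel[klass].totals()
            fi, _ = sx.fixation_index(t["Dn"], t["Ds"], t["Pn"], t["Ps"])
            c, _ = sx.snipre_like_effects(t["Dn"], t["Ds"], t["Pn"],
                                          t["Ps"], t["L0"], t["L4"])
            alphas.append(est.alpha)
            fis.append(fi)
            constraints.append(c)
        assert alphas[0] < alphas[1] < alphas[2]
        assert fis[0] < fis[1] < fis[2]
        assert constraints[0] > constraints[1] > constraints[2]
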