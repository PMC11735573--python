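"""Simulators: reproducibility, distributional convergence, study tables."""

import numpy as np
import pytest

from tetraseg.simulate import (
    ReadModel,
    SimScenario,
    alternative_q_menu,
    default_null_grid,
    gl_to_posteriors,
    posterior_mode_counts,
    roc_summary,
    run_alt_study,
    run_null_study,
    sample_simplex_q,
    sim_genotype_likelihoods,
    sim_offspring_genotypes,
)


class TestGenotypeSimulation:
    def test_nullplex_cross_all_zero(self, rng):
        counts, dosages = sim_offspring_genotypes(
            SimScenario(n=50, ells=(0, 0)), rng)
        assert counts[0] == 50 and np.all(dosages == 0)

    def test_simplex_13_10_1_convergence(self, rng):
        counts, _ = sim_offspring_genotypes(
            SimScenario(n=100_000, ells=(1, 0), alpha=1 / 6), rng)
        freq = counts / counts.sum()
        np.testing.assert_allclose(freq[:3], np.array([13, 10, 1]) / 24,
                                   atol=0.01)

    def test_alternative_q_convergence(self, rng):
        counts, _ = sim_offspring_genotypes(
            SimScenario(n=100_000, q=(0.2, 0.2, 0.2, 0.2, 0.2)), rng)
        np.testing.assert_allclose(counts / counts.sum(), 0.2, atol=0.01)

    def test_seed_reproducibility(self):
        a = sim_offspring_genotypes(SimScenario(n=100, ells=(1, 2)),
                                    np.random.default_rng(9))[0]
        b = sim_offspring_genotypes(SimScenario(n=100, ells=(1, 2)),
                                    np.random.default_rng(9))[0]
        assert np.array_equal(a, b)

    def test_invalid_xi_rejected(self):
        with pytest.raises(ValueError):
            sim_offspring_genotypes(
                SimScenario(n=10, ells=(2, 2), alpha=1 / 6, xi1=0.9),
                np.random.default_rng(0))


class TestReadSimulation:
    def test_high_depth_no_error_converges_to_indicators(self, rng):
        dosages = np.array([0, 1, 2, 3, 4])
        model = ReadModel(depth=5000, seq_error=0.0, overdispersion=0.0)
        log_g = sim_genotype_likelihoods(dosages, model, rng)
        assert np.array_equal(np.argmax(log_g, axis=1), dosages)
        post = gl_to_posteriors(log_g)
        assert np.all(post[np.arange(5), dosages] > 0.999)

    def test_zero_count_favors_nullplex(self, rng):
        # a dosage-0 individual with zero alt reads at depth 10
        model = ReadModel(depth=10)
        for _ in range(20):
            log_g = sim_genotype_likelihoods(np.zeros(3, dtype=int), model,
                                             rng)
            assert np.all(np.argmax(log_g, axis=1) == 0)
            break

    def test_bit_identical_under_seed(self):
        model = ReadModel()
        d = np.array([0, 1, 2, 2, 3])
        g1 = sim_genotype_likelihoods(d, model, np.random.default_rng(4))
        g2 = sim_genotype_likelihoods(d, model, np.random.default_rng(4))
        assert np.array_equal(g1, g2)

    def test_zero_depth_warns_uniform(self, rng):
        with pytest.warns(UserWarning):
            g = sim_genotype_likelihoods(np.array([1, 2]), ReadModel(depth=0),
                                         rng)
        assert np.allclose(g, 0.0)

    def test_posterior_mode_counts(self):
        log_g = np.log(np.array([[0.9, 0.1, 1e-6, 1e-6, 1e-6],
                                 [0.1, 0.8, 0.1, 1e-6, 1e-6]]))
        np.testing.assert_array_equal(posterior_mode_counts(log_g),
                                      [1, 1, 0, 0, 0])


class TestMenus:
    def test_alternative_menu(self):
        menu = alternative_q_menu()
        assert len(menu) == 14
        np.testing.assert_allclose(menu[0], np.full(5, 0.2))
        np.testing.assert_allclose(menu[10], [0.75, 0.25, 0, 0, 0])
        for q in menu:
            assert q.sum() == pytest.approx(1.0)
            assert np.all(q >= 0)

    def test_simplex_sampler(self, rng):
        q = sample_simplex_q(rng)
        assert q.shape == (5,) and q.sum() == pytest.approx(1.0)

    def test_null_grid_xi_menu_collapses_at_max_dr(self):
        grid = default_null_grid(n_list=(20,), alpha_list=(1 / 6,),
                                 depth_list=(None,))
        duplex = [s for s in grid if 2 in s.ells]
        assert duplex  # grid exercises duplex parents
        for s in duplex:
            assert s.xi1 == pytest.approx(1 / 3)
            assert s.xi2 == pytest.approx(1 / 3)


class TestStudies:
    def test_null_smoke_run_shape(self):
        table = run_null_study(
            grid=[SimScenario(n=30, ells=(1, 0), alpha=0.0)],
            reps=2, methods=("lrt", "chisq"), seed=0)
        assert len(table) == 4
        assert set(table["method"]) == {"lrt", "chisq"}
        assert table["truth"].eq("null").all()

    def test_alt_smoke_run_shape(self):
        table = run_alt_study(q_list=[np.full(5, 0.2)], n_list=(25,),
                              depth_list=(None,), reps=1,
                              methods=("lrt", "polymapr_like"), seed=0)
        assert len(table) == 2

    def test_alt_power_three_to_one(self):
        """Strong 3:1 distortion at n=200 with estimated parents: LRT power
        well above one half."""
        table = run_alt_study(q_list=[np.array([0.75, 0.25, 0, 0, 0])],
                              n_list=(200,), depth_list=(None,), reps=40,
                              methods=("lrt",), seed=1)
        assert (table["p_value"] <= 0.05).mean() > 0.5

    def test_alt_low_power_three_thirds(self):
        """Three genotype classes at 1/3 each, n=20: a near-null-looking
        alternative where power is known to be weak."""
        table = run_alt_study(q_list=[np.array([0, 1 / 3, 1 / 3, 1 / 3, 0])],
                              n_list=(20,), depth_list=(None,), reps=40,
                              methods=("lrt",), seed=2)
        assert (table["p_value"] <= 0.05).mean() < 0.5

    def test_study_deterministic_under_seed(self):
        kw = dict(grid=[SimScenario(n=30, ells=(1, 1), alpha=0.0)], reps=3,
                  methods=("lrt",), seed=5)
        t1, t2 = run_null_study(**kw), run_null_study(**kw)
        assert t1.equals(t2)


class TestRoc:
    def _table(self, method, pvals, truth):
        import pandas as pd

        return pd.DataFrame({"method": method, "p_value": pvals,
                             "truth": truth})

    def test_identical_distributions_on_diagonal(self, rng):
        p = rng.uniform(size=400)
        roc = roc_summary(self._table("lrt", p, "null"),
                          self._table("lrt", p, "alt"))
        np.testing.assert_allclose(roc["fpr"], roc["tpr"], atol=1e-12)

    def test_perfect_separation(self):
        roc = roc_summary(self._table("lrt", np.full(50, 0.8), "null"),
                          self._table("lrt", np.full(50, 1e-8), "alt"),
                          fpr_grid=[0.0, 0.05])
        assert roc.loc[roc["fpr"] == 0.0, "tpr"].iloc[0] == 1.0

    def test_lrt_dominates_chisq_under_double_reduction(self):
        """Pooled reduced-rep study: at low false-positive rates the LRT
        ROC sits above the plain chi-squared ROC when double reduction is
        active under the null."""
        null = run_null_study(
            grid=[SimScenario(n=200, ells=(1, 0), alpha=1 / 6)],
            reps=40, methods=("lrt", "chisq"), seed=3)
        alt = run_alt_study(q_list=[np.array([0.75, 0.25, 0, 0, 0])],
                            n_list=(200,), depth_list=(None,), reps=40,
                            methods=("lrt", "chisq"), seed=3)
        roc = roc_summary(null, alt, fpr_grid=[0.05, 0.1])
        piv = roc.pivot(index="fpr", columns="method", values="tpr")
        assert (piv["lrt"] >= piv["chisq"]).all()
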