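import numpy as np
import pytest

from sitdemog._diagnostics import ess, split_rhat
from sitdemog.bayes_binomial import (
    PosteriorMatrix,
    RankWarning,
    TreatmentPosterior,
    aggregate_by_treatment,
    detect_separation,
    fit_binomial_mixed,
    population_posterior,
    summarize,
)

pytestmark = pytest.mark.usefixtures("ignore_convergence")


def constant_matrix(values_by_row, n_draws=100):
    labels = [(f"c{i}", "r1", t) for i, (t, _) in enumerate(values_by_row)]
    draws = np.tile(np.array([v for _, v in values_by_row])[:, None], (1, n_draws))
    levels = list(dict.fromkeys(t for t, _ in values_by_row))
    return PosteriorMatrix(row_labels=labels, draws=draws, treatment_levels=levels)


class TestFit:
    def test_symmetric_treatments_agree(self):
        fit = fit_binomial_mixed([30, 30, 30, 30], [100, 100, 100, 100],
                                 ["A", "A", "B", "B"], n_draws=2000, seed=0)
        agg = aggregate_by_treatment(fit)
        a, b = agg.row("A"), agg.row("B")
        se = np.sqrt(a.var() + b.var())
        assert abs(a.mean() - b.mean()) < 2 * se

    def test_single_treatment_posterior_mean(self):
        with pytest.warns(RankWarning):
            fit = fit_binomial_mixed([250], [1000], ["A"], n_draws=2000, seed=1,
                                     random_effect=False)
        assert abs(fit.draws.mean() - 0.25) < 0.02

    def test_zero_success_treatment_finite_with_flag(self):
        successes = [0, 0, 0, 0, 90, 88, 92, 91]
        trials = [50, 60, 55, 57, 100, 100, 100, 100]
        treatment = ["SIT5"] * 4 + ["control"] * 4
        fit = fit_binomial_mixed(successes, trials, treatment, n_draws=2000, seed=2)
        assert np.all(np.isfinite(fit.draws))
        assert np.all(fit.beta_draws is not None)
        flags = detect_separation(successes, trials, treatment, fit=fit)
        assert any(f.kind == "row" for f in flags)
        assert any(f.kind == "treatment" and f.target == "SIT5" for f in flags)
        # separated group keeps a wider interval than the well-identified one
        agg = aggregate_by_treatment(fit)
        s = {x.treatment: x for x in summarize(agg)}
        assert (s["SIT5"].ul - s["SIT5"].ll) > 0

    def test_draws_strictly_inside_unit_interval(self, trial):
        cohorts, _, _ = trial
        fit = fit_binomial_mixed(
            [c.eggs_hatched for c in cohorts], [c.eggs_total for c in cohorts],
            [c.treatment for c in cohorts], n_draws=1000, seed=3)
        assert np.all(fit.draws > 0) and np.all(fit.draws < 1)
        assert fit.draws.shape == (20, 1000)

    def test_deterministic_given_seed(self):
        kw = dict(n_draws=500, seed=9)
        a = fit_binomial_mixed([5, 9], [20, 20], ["A", "B"], **kw)
        b = fit_binomial_mixed([5, 9], [20, 20], ["A", "B"], **kw)
        assert np.array_equal(a.draws, b.draws)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_binomial_mixed([5], [3], ["A"], n_draws=100)

    def test_marginal_fitted_values(self):
        fit = fit_binomial_mixed([10, 50], [60, 60], ["A", "B"], n_draws=1000,
                                 seed=4, fitted="marginal")
        assert np.all((fit.draws > 0) & (fit.draws < 1))


class TestAggregate:
    def test_identical_rows_equal_single_row(self):
        m = constant_matrix([("A", 0.3)] * 4)
        agg = aggregate_by_treatment(m)
        assert np.allclose(agg.row("A"), 0.3)

    def test_mean_of_two_constant_rows(self):
        m = constant_matrix([("A", 0.2), ("A", 0.4)])
        assert np.allclose(aggregate_by_treatment(m).row("A"), 0.3)

    def test_row_order_invariance(self):
        rows = [("A", 0.2), ("B", 0.7), ("A", 0.4), ("B", 0.5)]
        m1 = constant_matrix(rows)
        m2 = constant_matrix(rows[::-1])
        a1 = aggregate_by_treatment(m1)
        a2 = aggregate_by_treatment(m2)
        for t in ("A", "B"):
            assert np.allclose(a1.row(t), a2.row(t))

    def test_unknown_treatment_errors(self):
        m = constant_matrix([("A", 0.2)])
        m.row_labels = [("c0", "r1", "Z")]
        with pytest.raises(ValueError, match="Z"):
            aggregate_by_treatment(m)

    def test_trials_weighting(self):
        m = constant_matrix([("A", 0.2), ("A", 0.4)])
        agg = aggregate_by_treatment(m, weights="trials", trials=[3, 1])
        assert np.allclose(agg.row("A"), 0.25)


class TestSummarize:
    def test_constant_draws(self):
        t = TreatmentPosterior(["A"], np.full((1, 500), 0.936))
        (s,) = summarize(t)
        assert s.mean == s.ll == s.ul == pytest.approx(0.936)

    def test_uniform_quantiles(self):
        rng = np.random.default_rng(0)
        t = TreatmentPosterior(["A"], rng.uniform(size=(1, 10_000)))
        (s,) = summarize(t)
        assert s.ll == pytest.approx(0.025, abs=0.01)
        assert s.ul == pytest.approx(0.975, abs=0.01)

    def test_alpha_one_degenerates_to_median(self):
        draws = np.arange(1, 100, dtype=float)[None, :] / 100
        t = TreatmentPosterior(["A"], draws)
        (s,) = summarize(t, alpha=1.0)
        assert s.ll == s.ul == pytest.approx(np.median(draws))


class TestDetectSeparation:
    def test_zero_row_flagged(self):
        flags = detect_separation([0, 30], [57, 60], ["SIT5", "control"])
        assert any(f.kind == "row" and "SIT5" in f.target for f in flags)

    def test_nearly_separated_control_no_row_flag(self):
        # 215/228 is not an exact boundary: no row flag, and 0.943 is inside
        # the treatment-level (eps, 1-eps) band
        flags = detect_separation([215], [228], ["control"])
        assert flags == []

    def test_all_half_no_flags(self):
        flags = detect_separation([50, 50, 50], [100, 100, 100], ["A", "B", "C"])
        assert flags == []

    def test_treatment_level_near_boundary(self):
        flags = detect_separation([199, 200], [200, 200], ["A", "A"])
        assert any(f.kind == "treatment" for f in flags)


class TestPopulationPosterior:
    def test_matches_beta_draws(self):
        fit = fit_binomial_mixed([10, 40], [50, 50], ["A", "B"], n_draws=500, seed=5)
        pop = population_posterior(fit)
        assert pop.treatment_labels == ["A", "B"]
        expected = 1 / (1 + np.exp(-fit.beta_draws))
        assert np.allclose(pop.draws, expected)


class TestDiagnostics:
    def test_rhat_near_one_for_iid(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 2000))
        assert abs(split_rhat(chains) - 1.0) < 0.01
        assert ess(chains) > 4000

    def test_rhat_detects_disagreement(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 500))
        chains[0] += 5.0
        assert split_rhat(chains) > 1.5

    def test_ess_detects_autocorrelation(self):
        rng = np.random.default_rng(3)
        x = np.empty((4, 2000))
        for c in range(4):
            e = rng.standard_normal(2000)
            for i in range(1, 2000):
                e[i] = 0.95 * e[i - 1] + np.sqrt(1 - 0.95**2) * e[i]
            x[c] = e
        assert ess(x) < 1000
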