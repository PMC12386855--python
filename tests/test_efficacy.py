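import numpy as np
import pytest

from sitdemog.bayes_binomial import PosteriorMatrix, TreatmentPosterior
from sitdemog.efficacy import (
    competitiveness_plugin,
    competitiveness_posterior,
    delta_test,
    emergence_product,
    relative_risk,
)


def constant_tp(values: dict[str, float], n_draws: int = 200) -> TreatmentPosterior:
    labels = list(values)
    draws = np.tile(np.array([values[t] for t in labels])[:, None], (1, n_draws))
    return TreatmentPosterior(labels, draws)


def random_matrix(rng, treatments, n_draws=50):
    labels = [(f"c{i}", "r1", t) for i, t in enumerate(treatments)]
    draws = rng.uniform(0.05, 0.95, size=(len(treatments), n_draws))
    return PosteriorMatrix(row_labels=labels, draws=draws,
                           treatment_levels=list(dict.fromkeys(treatments)))


class TestCompetitivenessPlugin:
    def test_observed_bsit5(self):
        assert competitiveness_plugin(0.936, 0.576, 5) == pytest.approx(0.125, abs=1e-12)

    def test_fitted_bsit1(self):
        assert competitiveness_plugin(0.936, 0.773, 1) == pytest.approx(0.211, abs=5e-4)

    def test_no_suppression_is_zero(self):
        assert competitiveness_plugin(0.5, 0.5, 3) == 0.0

    def test_zero_hatch_undefined(self):
        with pytest.raises(ZeroDivisionError, match="separation"):
            competitiveness_plugin(0.9, 0.0, 5)

    def test_control_undefined(self):
        with pytest.raises(ValueError):
            competitiveness_plugin(0.9, 0.5, 0)


class TestCompetitivenessPosterior:
    def test_degenerate_posterior_equals_plugin(self):
        tp = constant_tp({"control": 0.936, "bSIT5": 0.576})
        s = competitiveness_posterior(tp, "bSIT5", 5)
        assert s.cp_mean == pytest.approx(s.cp_plugin) == pytest.approx(0.125)
        assert s.ll == s.ul == pytest.approx(0.125)

    def test_sign_when_treatment_below_control(self):
        rng = np.random.default_rng(0)
        draws = np.vstack([np.full(500, 0.9), rng.uniform(0.2, 0.5, 500)])
        tp = TreatmentPosterior(["control", "SIT1"], draws)
        assert competitiveness_posterior(tp, "SIT1", 1).cp_mean > 0

    def test_two_point_posterior_hand_enumeration(self):
        # draws {0.2, 0.4} vs constant control 0.8 at s2f=1:
        # Cp draws are (0.8-0.2)/0.2 = 3 and (0.8-0.4)/0.4 = 1 -> mean 2
        draws = np.array([[0.8, 0.8], [0.2, 0.4]])
        tp = TreatmentPosterior(["control", "X"], draws)
        assert competitiveness_posterior(tp, "X", 1).cp_mean == pytest.approx(2.0)

    def test_control_rejected(self):
        tp = constant_tp({"control": 0.9})
        with pytest.raises(ValueError):
            competitiveness_posterior(tp, "control", 1)


class TestEmergenceProduct:
    def test_identity_when_emergence_is_one(self):
        rng = np.random.default_rng(1)
        mh = random_matrix(rng, ["control", "SIT1"])
        ma = PosteriorMatrix(mh.row_labels, np.ones_like(mh.draws),
                             treatment_levels=mh.treatment_levels)
        assert np.array_equal(emergence_product(mh, ma).draws, mh.draws)

    def test_constant_product(self):
        mh = PosteriorMatrix([("c", "r", "A")], np.full((1, 10), 0.5))
        ma = PosteriorMatrix([("c", "r", "A")], np.full((1, 10), 0.4))
        assert np.allclose(emergence_product(mh, ma).draws, 0.2)

    def test_product_bound(self):
        rng = np.random.default_rng(2)
        mh = random_matrix(rng, ["A", "B"])
        ma = PosteriorMatrix(mh.row_labels,
                             rng.uniform(size=mh.draws.shape),
                             treatment_levels=mh.treatment_levels)
        me = emergence_product(mh, ma)
        assert np.all(me.draws <= np.minimum(mh.draws, ma.draws) + 1e-15)

    def test_label_mismatch_is_error(self):
        mh = PosteriorMatrix([("c1", "r", "A")], np.full((1, 10), 0.5))
        ma = PosteriorMatrix([("c2", "r", "A")], np.full((1, 10), 0.5))
        with pytest.raises(ValueError, match="row labels"):
            emergence_product(mh, ma)


class TestRelativeRisk:
    def test_printed_ratio_bsit5(self):
        tp = constant_tp({"control": 0.636, "bSIT5": 0.335})
        rr = {r.treatment: r for r in relative_risk(tp)}
        assert round(rr["bSIT5"].rr_mean, 3) == 0.527

    def test_reference_against_itself_is_one(self):
        tp = constant_tp({"control": 0.636, "SIT1": 0.509})
        rr = {r.treatment: r for r in relative_risk(tp)}
        assert rr["control"].rr_mean == rr["control"].ll == rr["control"].ul == 1.0

    def test_posterior_mean_vs_printed_sit5(self):
        tp = constant_tp({"control": 0.636, "SIT5": 0.132})
        rr = {r.treatment: r for r in relative_risk(tp)}
        assert rr["SIT5"].rr_mean == pytest.approx(0.2075, abs=1e-4)
        assert abs(rr["SIT5"].rr_mean - 0.207) < 0.001

    def test_rr_control_identically_one_per_draw(self):
        rng = np.random.default_rng(3)
        draws = rng.uniform(0.1, 0.9, size=(2, 300))
        tp = TreatmentPosterior(["control", "X"], draws)
        rr = {r.treatment: r for r in relative_risk(tp)}
        assert rr["control"].rr_mean == 1.0

    def test_zero_reference_draws_excluded(self):
        draws = np.array([[0.0, 0.5, 0.5], [0.2, 0.2, 0.3]])
        tp = TreatmentPosterior(["control", "X"], draws)
        rr = {r.treatment: r for r in relative_risk(tp)}
        assert rr["X"].excluded_draws == 1
        assert rr["X"].rr_mean == pytest.approx(0.5)


class TestRRDecomposition:
    def test_rr_from_product_equals_product_of_rrs(self):
        # per draw: Me_i/Me_ref == (Mh_i/Mh_ref) * (Ma_i/Ma_ref)
        rng = np.random.default_rng(4)
        treatments = ["control", "SIT1", "SIT5"]
        mh = random_matrix(rng, treatments, n_draws=100)
        ma = PosteriorMatrix(mh.row_labels,
                             rng.uniform(0.05, 0.95, size=mh.draws.shape),
                             treatment_levels=mh.treatment_levels)
        me = emergence_product(mh, ma)
        ref = 0  # control row index
        lhs = me.draws / me.draws[ref]
        rhs = (mh.draws / mh.draws[ref]) * (ma.draws / ma.draws[ref])
        assert np.allclose(lhs, rhs)


class TestDeltaTest:
    def test_printed_point_estimate(self):
        tp = constant_tp({"bSIT1": 0.773, "SIT1": 0.764})
        res = delta_test(tp, "bSIT1", "SIT1", B=200)
        assert res.delta_mean == pytest.approx(0.009, abs=1e-12)

    def test_identical_groups_p_one_with_ties(self):
        draws = np.tile(np.linspace(0.2, 0.8, 100), (2, 1))
        tp = TreatmentPosterior(["A", "B"], draws)
        res = delta_test(tp, "A", "B", B=100, direction="less")
        assert res.delta_mean == 0.0 and res.p_value == 1.0

    def test_strictly_above_empty_tail(self):
        # group_a always above group_b: no posterior mass on delta < 0
        draws = np.vstack([np.full(50, 0.8), np.full(50, 0.3)])
        tp = TreatmentPosterior(["A", "B"], draws)
        res = delta_test(tp, "A", "B", B=50, direction="less")
        assert res.p_value == 0.0

    def test_b_exceeding_draws_errors(self):
        tp = constant_tp({"A": 0.5, "B": 0.4}, n_draws=10)
        with pytest.raises(ValueError, match="exceeds"):
            delta_test(tp, "A", "B", B=100)

    def test_direction_recorded(self):
        tp = constant_tp({"A": 0.5, "B": 0.4}, n_draws=10)
        res = delta_test(tp, "A", "B", B=10, direction="less")
        assert res.direction == "less" and res.B == 10
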