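"""Graded response model primitives: probabilities, information, EAP, T metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probank.grm import (ItemBank, ItemParameters, boundary_probability,
                         category_probabilities, default_grid, eap_score,
                         from_t_metric, item_information, to_t_metric)
from probank.grm import test_information as total_information
from probank.bankio import read_bank, write_bank


def item(slope, thresholds, iid="x"):
    return ItemParameters(iid, slope, tuple(thresholds))


@st.composite
def random_items(draw):
    m = draw(st.integers(2, 6))
    slope = draw(st.floats(0.2, 4.0))
    start = draw(st.floats(-3.0, 0.0))
    gaps = [draw(st.floats(0.1, 1.5)) for _ in range(m - 2)]
    thresholds = np.concatenate([[start], start + np.cumsum(gaps)]) if m > 2 \
        else np.array([start])
    return item(slope, thresholds)


class TestBoundaryProbability:
    def test_logistic_at_location_is_half(self):
        assert boundary_probability(0.0, item(1.0, [0.0]), 1) == pytest.approx(0.5)

    def test_logistic_limits(self):
        it = item(1.0, [0.0])
        assert boundary_probability(50.0, it, 1) == pytest.approx(1.0)
        assert boundary_probability(-50.0, it, 1) == pytest.approx(0.0)

    def test_direct_logistic_evaluation(self):
        # oracle: 1 / (1 + exp(-1.5 * (0 - (-0.5)))) = 0.679179
        expected = 1.0 / (1.0 + np.exp(-1.5 * 0.5))
        assert boundary_probability(0.0, item(1.5, [-0.5]), 1) == \
            pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.6792, abs=5e-5)

    def test_out_of_range_boundary_raises(self):
        with pytest.raises(IndexError):
            boundary_probability(0.0, item(1.0, [-1.0, 1.0]), 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(random_items(), st.floats(-5, 5))
    def test_boundary_curves_strictly_ordered(self, it, theta):
        ps = [boundary_probability(theta, it, k)
              for k in range(1, it.n_categories)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCategoryProbabilities:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(random_items(), st.floats(-5, 5))
    def test_simplex(self, it, theta):
        p = category_probabilities(theta, it)
        assert p.shape == (it.n_categories,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dichotomous_degenerates_to_2pl(self):
        it = item(1.3, [0.4])
        p = category_probabilities(0.7, it)
        pstar = boundary_probability(0.7, it, 1)
        assert p == pytest.approx([1 - pstar, pstar])

    def test_symmetric_thresholds_symmetric_extremes(self):
        p = category_probabilities(0.0, item(1.0, [-1.0, 1.0]))
        assert p[0] == pytest.approx(p[-1])


class TestItemInformation:
    def test_flat_item_uninformative(self):
        it = item(0.01, [-1.0, 0.0, 1.0])
        theta = np.linspace(-4, 4, 30)
        assert np.all(item_information(theta, it) < 1e-3)

    def test_information_vanishes_in_tails_and_integrates(self):
        it = item(2.0, [-1.0, 0.0, 1.0])
        assert item_information(15.0, it) < 1e-6
        grid = np.linspace(-10, 10, 2001)
        area = np.trapezoid(item_information(grid, it), grid)
        assert np.isfinite(area) and area > 0

    def test_matches_finite_difference_of_expected_loglik(self):
        # I(theta) = -E[d2/dtheta2 log P(X|theta)] evaluated at the true theta
        it = item(2.0, [-1.0, 0.0, 1.0])
        h = 1e-4
        for theta in np.linspace(-4, 4, 17):
            p0 = category_probabilities(theta, it)
            lp = np.log(category_probabilities(theta + h, it))
            lm = np.log(category_probabilities(theta - h, it))
            l0 = np.log(p0)
            d2 = (lp - 2 * l0 + lm) / h**2
            expected = -float(p0 @ d2)
            assert item_information(theta, it) == pytest.approx(expected, rel=1e-4)

    def test_test_information_is_sum(self, small_bank):
        theta = np.linspace(-3, 3, 7)
        total = sum(item_information(theta, it) for it in small_bank)
        assert total_information(theta, small_bank) == pytest.approx(total)


class TestEapScore:
    def test_empty_pattern_returns_prior(self, small_bank):
        est = eap_score({}, small_bank)
        assert est.theta == pytest.approx(0.0, abs=1e-9)
        assert est.se == pytest.approx(1.0, abs=0.01)

    def test_all_missing_pattern_returns_prior(self, small_bank):
        est = eap_score({"a1": None, "a2": None}, small_bank)
        assert est.theta == pytest.approx(0.0, abs=1e-9)

    def test_extreme_patterns_move_theta(self, small_bank):
        high = eap_score({it.item_id: it.n_categories for it in small_bank},
                         small_bank)
        low = eap_score({it.item_id: 1 for it in small_bank}, small_bank)
        assert high.theta > 0.5
        assert low.theta < -0.5

    def test_matches_dense_grid_oracle(self, small_bank):
        """49-point EAP agrees with brute-force 10,001-point integration."""
        pattern = {"a1": 4, "a2": 2, "a3": 3, "a4": 5, "a5": 1}
        est = eap_score(pattern, small_bank)

        dense = np.linspace(-6, 6, 10001)
        prior = np.exp(-0.5 * dense**2)
        like = np.ones_like(dense)
        for iid, resp in pattern.items():
            like *= category_probabilities(dense, small_bank.item(iid))[resp - 1]
        post = prior * like
        post /= post.sum()
        mean = post @ dense
        sd = np.sqrt(post @ (dense - mean) ** 2)
        assert est.theta == pytest.approx(mean, abs=1e-4)
        assert est.se == pytest.approx(sd, abs=1e-4)

    def test_invalid_category_raises(self, small_bank):
        with pytest.raises(ValueError, match="invalid"):
            eap_score({"a1": 9}, small_bank)

    def test_mean_se_non_increasing_with_bank_size(self, rng):
        """More informative items shrink the posterior SD on average."""
        from probank.simulate import make_bank, SimulationDesign, simulate_responses
        bank = make_bank(n_items=12, seed=6)
        design = SimulationDesign(bank=bank, n_persons=200, seed=1)
        data = simulate_responses(design)
        mean_ses = []
        for size in (3, 6, 12):
            ids = bank.item_ids[:size]
            sub = bank.subset(ids)
            ses = [eap_score({i: data.pattern(p)[i] for i in ids
                              if i in data.pattern(p)}, sub).se
                   for p in range(200)]
            mean_ses.append(np.mean(ses))
        assert mean_ses[0] >= mean_ses[1] >= mean_ses[2]


class TestTMetric:
    def test_reference_mean_maps_to_50(self):
        assert to_t_metric(0.0) == 50.0

    def test_one_sd_maps_to_10_points(self):
        assert to_t_metric(1.0) == 60.0

    def test_linearity(self):
        assert to_t_metric(-2.5) == 25.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-5, 5))
    def test_round_trip(self, theta):
        assert from_t_metric(to_t_metric(theta)) == pytest.approx(theta)


class TestBankIO:
    def test_round_trip_lossless_to_6_decimals(self, default_bank, tmp_path):
        path = tmp_path / "bank.tsv"
        write_bank(default_bank, path)
        loaded = read_bank(path)
        assert loaded.item_ids == default_bank.item_ids
        assert loaded.metric_name == default_bank.metric_name
        for orig, got in zip(default_bank, loaded):
            assert got.slope == pytest.approx(orig.slope, abs=1e-6)
            assert np.allclose(got.thresholds, orig.thresholds, atol=1e-6)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="slope"):
            ItemParameters("bad", -1.0, (0.0,))
        with pytest.raises(ValueError, match="increasing"):
            ItemParameters("bad", 1.0, (1.0, 0.0))
        with pytest.raises(ValueError, match="duplicate"):
            ItemBank((item(1, [0], "a"), item(1, [0], "a")))
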