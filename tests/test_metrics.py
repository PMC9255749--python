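"""Discrimination and calibration metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.special import expit, logit

import gosepred as g
from gosepred.metrics import UndefinedMetricError, mann_whitney_auc
from tests.conftest import brute_dxy, brute_orc


class TestRiskScore:
    def test_point_masses(self):
        assert g.risk_score(np.eye(7)[0]) == pytest.approx(0.0)
        assert g.risk_score(np.eye(7)[6]) == pytest.approx(6.0)

    def test_uniform_class_probs(self):
        assert g.risk_score(np.full(7, 1 / 7)) == pytest.approx(3.0)

    def test_threshold_input_accepted(self):
        t = np.array([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
        assert g.risk_score(t) == pytest.approx(t.sum())

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            g.risk_score(np.full(7, 0.5))


class TestOrc:
    def test_perfect_separation(self):
        y = np.repeat(np.arange(1, 8), 3)
        s = y + np.linspace(0, 0.4, len(y))
        assert g.orc(s, y) == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        y = np.repeat(np.arange(1, 8), 5)
        assert g.orc(np.zeros(len(y)), y) == pytest.approx(0.5)

    def test_worked_example_against_enumeration(self):
        y = np.array([1, 1, 2, 3])
        s = np.array([0.1, 0.4, 0.3, 0.9])
        assert g.orc(s, y) == pytest.approx((0.5 + 1 + 1) / 3)
        assert g.orc(s, y) == pytest.approx(brute_orc(s, y))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = rng.integers(1, 8, size=30)
            if len(np.unique(y)) < 2:
                continue
            s = rng.normal(size=30)
            assert g.orc(s, y) == pytest.approx(brute_orc(s, y))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(1, 8, size=60)
        s = rng.normal(size=60)
        assert g.orc(np.exp(3 * s), y) == pytest.approx(g.orc(s, y))

    def test_invariant_to_category_duplication(self):
        rng = np.random.default_rng(2)
        y = rng.integers(1, 8, size=40)
        s = rng.normal(size=40)
        dup = y == 3
        y2 = np.concatenate([y, y[dup]])
        s2 = np.concatenate([s, s[dup]])
        assert g.orc(s2, y2) == pytest.approx(g.orc(s, y))
        # Somers' Dxy is prevalence-dependent and generally changes
        assert g.somers_dxy(s2, y2) != pytest.approx(g.somers_dxy(s, y), abs=1e-6)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedMetricError):
            g.orc([1.0, 2.0], [3, 3])

    def test_set_ranking_interpretation(self):
        """Average pairwise-correct fraction over one-per-category draws
        converges to the ORC."""
        rng = np.random.default_rng(7)
        y = np.repeat(np.arange(1, 8), 12)
        s = y + rng.normal(0, 2.0, size=len(y))
        orc_val = g.orc(s, y)
        idx_by_cat = [np.flatnonzero(y == c) for c in range(1, 8)]
        total = 0.0
        draws = 4000
        for _ in range(draws):
            picks = [s[rng.choice(ix)] for ix in idx_by_cat]
            correct = 0.0
            for i in range(7):
                for j in range(i + 1, 7):
                    if picks[j] > picks[i]:
                        correct += 1
                    elif picks[j] == picks[i]:
                        correct += 0.5
            total += correct / 21
        assert total / draws == pytest.approx(orc_val, abs=0.01)


class TestSomersDxy:
    def test_perfect_ranking_is_one(self):
        y = np.repeat(np.arange(1, 8), 4)
        s = y + np.linspace(0, 0.4, len(y))
        assert g.somers_dxy(s, y) == pytest.approx(1.0)

    def test_worked_example(self):
        y = np.array([1, 1, 2, 3])
        s = np.array([0.1, 0.4, 0.3, 0.9])
        assert g.somers_dxy(s, y) == pytest.approx((4 - 1) / 5)
        assert g.somers_dxy(s, y) == pytest.approx(brute_dxy(s, y))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = rng.integers(1, 5, size=25)
            s = rng.normal(size=25)
            if len(np.unique(y)) < 2:
                continue
            assert g.somers_dxy(s, y) == pytest.approx(brute_dxy(s, y))

    def test_binary_reduction_two_auc_minus_one(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=80)
        s = y + rng.normal(0, 1, size=80)
        auc = mann_whitney_auc(s[y == 0], s[y == 1])
        assert g.somers_dxy(s, y) == pytest.approx(2 * auc - 1)

    def test_no_cross_pairs_undefined(self):
        with pytest.raises(UndefinedMetricError):
            g.somers_dxy([1.0, 2.0], [4, 4])


class TestDichotomousCIndex:
    def test_perfect_and_constant(self):
        y = np.array([0] * 10 + [1] * 10)
        p = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        assert g.dichotomous_c_index(p, y) == pytest.approx(1.0)
        assert g.dichotomous_c_index(np.full(20, 0.3), y) == pytest.approx(0.5)

    def test_matches_pair_enumeration_on_toy(self):
        p = np.array([0.2, 0.6, 0.5, 0.9])
        y = np.array([0, 0, 1, 1])
        # pairs: (0.2,0.5)+ (0.2,0.9)+ (0.6,0.5)- (0.6,0.9)+ -> 3/4
        assert g.dichotomous_c_index(p, y) == pytest.approx(0.75)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            g.dichotomous_c_index([0.2, 0.4], [1, 1])

    def test_binary_orc_equals_c_index(self):
        rng = np.random.default_rng(10)
        y = rng.integers(1, 3, size=60)
        s = rng.normal(size=60)
        assert g.orc(s, y) == pytest.approx(
            g.dichotomous_c_index(s, (y == 2).astype(int)))


class TestCalibration:
    def test_calibrated_simulation_slope_near_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.05, 0.95, size=10000)
        y = rng.uniform(size=10000) < p
        slope = g.calibration_slope(p, y)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_sharpened_logits_halve_the_slope(self):
        """Outcomes from p, predictions with doubled logits -> slope 0.5."""
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.9, size=10000)
        y = rng.uniform(size=10000) < p
        sharpened = expit(2 * logit(p))
        assert g.calibration_slope(sharpened, y) == pytest.approx(0.5, abs=0.06)

    def test_constant_predictions_rejected(self):
        with pytest.raises(UndefinedMetricError):
            g.calibration_slope(np.full(50, 0.4),
                                np.r_[np.zeros(25), np.ones(25)])

    def test_ici_near_zero_when_calibrated(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.05, 0.95, size=5000)
        y = rng.uniform(size=5000) < p
        assert g.integrated_calibration_index(p, y) < 0.03

    def test_ici_constant_predictor_closed_form(self):
        """Flat predictor at q with prevalence r: ICI -> |q - r|."""
        rng = np.random.default_rng(14)
        q, r = 0.7, 0.3
        y = rng.uniform(size=4000) < r
        p = np.full(4000, q)
        assert g.integrated_calibration_index(p, y) == pytest.approx(
            abs(q - r), abs=0.02)

    def test_curve_bounded_in_unit_interval(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(0.01, 0.99, size=500)
        y = rng.uniform(size=500) < p
        _, smoothed, _ = g.smoothed_calibration_curve(p, y)
        assert smoothed.min() >= 0.0 and smoothed.max() <= 1.0
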