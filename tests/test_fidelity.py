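"""Fidelity metrics, verbal labels and the URA aggregate."""

import itertools

import numpy as np
import pytest

import statsynth as ss


class TestWelch:
    def test_identical_vectors(self):
        t, p = ss.welch_t_pvalue([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        t, p = ss.welch_t_pvalue([1, 2, 3], [2, 3, 4])
        # (2-3)/sqrt(1/3 + 1/3), df = 4
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.288, abs=5e-3)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        t1, p1 = ss.welch_t_pvalue(a, b)
        t2, p2 = ss.welch_t_pvalue(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_convention_and_errors(self):
        _, p = ss.welch_t_pvalue([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        with pytest.raises(ss.ValidationError):
            ss.welch_t_pvalue([1], [1, 2])


class TestChiSquare:
    def test_identical_counts(self):
        chi2, p = ss.chi_square_pvalue([10, 20], [10, 20])
        assert chi2 == 0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        chi2, _ = ss.chi_square_pvalue([400, 366], [380, 386])
        assert chi2 == pytest.approx(400 / 400 + 400 / 366)
        assert chi2 == pytest.approx(2.093, abs=1e-3)

    def test_doubling_scale(self):
        chi2, _ = ss.chi_square_pvalue([400, 366], [380, 386])
        chi2x2, _ = ss.chi_square_pvalue([800, 732], [760, 772])
        assert chi2x2 == pytest.approx(2 * chi2)

    def test_zero_real_count_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.chi_square_pvalue([0, 10], [5, 5])


class TestWasserstein:
    def test_identical_samples(self):
        x = np.random.default_rng(0).uniform(size=30)
        assert ss.wasserstein_distance(x, x.copy(), normalize=False) == 0

    def test_unit_translation(self):
        assert ss.wasserstein_distance([0.0], [1.0], normalize=False) == 1.0

    def test_sorted_difference_oracle(self):
        # equal-size samples: mean |sorted differences|
        assert ss.wasserstein_distance([0, 1], [0.5, 1], normalize=False) == \
            pytest.approx(0.25)

    def test_translation_detecting(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.2, 0.5, 50)
        d0 = ss.wasserstein_distance(x, x, normalize=False)
        d1 = ss.wasserstein_distance(x, x + 0.3, normalize=False)
        assert d1 - d0 == pytest.approx(0.3)

    def test_degenerate_real_range_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.wasserstein_distance([5, 5, 5], [1, 2, 3], normalize=True)


@pytest.mark.parametrize("n_pass,n_total,label", [
    (7, 8, "Excellent"),
    (5, 8, "Excellent"),
    (2, 8, "Good"),
    (4, 8, "Good"),      # exactly 50% is conservatively Good
    (0, 8, "Poor"),
    (1, 1, "Excellent"),
])
def test_label_from_counts(n_pass, n_total, label):
    assert ss.label_from_counts(n_pass, n_total) == label


def ura_brute_force(labels):
    score = {"Excellent": 3, "Good": 2, "Poor": 1}
    total = sum(score[l] for l in labels) / len(labels)
    rounded = int(np.floor(total + 0.5))
    return {3: "Excellent", 2: "Good", 1: "Poor"}[min(max(rounded, 1), 3)]


def test_ura_total_known_combinations():
    assert ss.ura_total(["Good", "Excellent", "Good"]) == "Good"
    assert ss.ura_total(["Excellent"] * 3) == "Excellent"
    assert ss.ura_total(["Good", "Excellent", "Excellent"]) == "Excellent"
    assert ss.ura_total(["Poor"] * 3) == "Poor"


def test_ura_total_matches_enumeration():
    """All 27 three-label combinations agree with a brute-force scorer."""
    for combo in itertools.product(["Excellent", "Good", "Poor"], repeat=3):
        assert ss.ura_total(combo) == ura_brute_force(combo)


def test_ura_total_rejects_unknown_label():
    with pytest.raises(ss.ValidationError):
        ss.ura_total(["Great"])


class TestFidelityReport:
    def test_self_comparison_is_excellent(self, reference_table):
        rep = ss.fidelity_report(reference_table, reference_table)
        for results in rep.results.values():
            assert all(r.passes for r in results)
        assert set(rep.metric_labels.values()) == {"Excellent"}
        assert rep.ura_label == "Excellent"

    def test_coefficient_renders_to_two_decimals(self, reference_table):
        rep = ss.fidelity_report(reference_table, reference_table)
        assert f"{rep.proportionality_coefficient:.2f}" == "0.33"

    def test_noise_corrupted_matches_independent_recomputation(self, reference_table):
        rng = np.random.default_rng(5)
        noisy_vals = reference_table.values.copy()
        schema = reference_table.schema
        for j, c in enumerate(schema.columns):
            if not c.is_outcome:
                noisy_vals[:, j] += rng.normal(0, 0.05 * c.value_range, 766)
                noisy_vals[:, j] = np.clip(noisy_vals[:, j], c.min_value, c.max_value)
        noisy = ss.Table(noisy_vals, schema)
        rep = ss.fidelity_report(reference_table, noisy)
        # independent per-column recomputation
        from scipy import stats as sps
        for r in rep.results["t_test"]:
            t, p = sps.ttest_ind(reference_table.column(r.column),
                                 noisy.column(r.column), equal_var=False)
            assert r.statistic == pytest.approx(float(t))
            assert r.p_value == pytest.approx(float(p))
            assert r.passes == (p > 0.05)
        for r in rep.results["wasserstein"]:
            a = reference_table.column(r.column)
            b = noisy.column(r.column)
            lo, hi = a.min(), a.max()
            d = sps.wasserstein_distance((a - lo) / (hi - lo), (b - lo) / (hi - lo))
            assert r.statistic == pytest.approx(float(d))
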