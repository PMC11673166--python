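"""Schema, statistics extraction and perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsynth as ss
from statsynth.schema import (
    STAT_MAX,
    STAT_MEAN,
    STAT_MIN,
    STAT_OR,
    STAT_RISKY,
)


def test_schema_invariants_enforced():
    c = ss.ColumnSpec
    with pytest.raises(ss.SchemaError):
        c("x", "continuous", 5, 1)                       # min > max
    with pytest.raises(ss.SchemaError):
        c("x", "continuous", 0, 1, risky_threshold=2, risky_direction="above")
    with pytest.raises(ss.SchemaError):
        c("x", "continuous", 0, 1, is_outcome=True)      # outcome must be binary
    with pytest.raises(ss.SchemaError):                  # no outcome at all
        ss.TableSchema((c("x", "continuous", 0, 1),))
    with pytest.raises(ss.SchemaError):                  # duplicate names
        ss.TableSchema((c("x", "continuous", 0, 1),
                        c("x", "binary", 0, 1, is_outcome=True)))


@pytest.mark.parametrize("values,threshold,direction,expected", [
    ((80, 120, 150), 100, "above", 2 / 3),
    ((80, 120, 150), 1000, "above", 0.0),     # threshold above the maximum
    ((80, 120, 150), 10, "above", 1.0),       # everything exceeds
    ((80, 120, 150), 100, "below", 1 / 3),
    ((5, 5, 5, 5), 5, "above", 0.0),          # strict inequality
])
def test_risky_fraction(values, threshold, direction, expected):
    assert ss.risky_fraction(np.array(values), threshold, direction) == pytest.approx(expected)


def test_risky_fraction_rejects_empty():
    with pytest.raises(ss.ValidationError):
        ss.risky_fraction(np.array([]), 1.0, "above")


@pytest.mark.parametrize("a,b,c,d,expected", [
    (10, 10, 10, 10, 1.0),
    (10, 5, 2, 4, 4.0),
    (10, 0, 2, 4, (10.5 * 4.5) / (0.5 * 2.5)),   # Haldane-Anscombe correction
])
def test_compute_odds_ratio(a, b, c, d, expected):
    risky = np.repeat([1, 1, 0, 0], [a, b, c, d])
    outcome = np.repeat([1, 0, 1, 0], [a, b, c, d])
    assert ss.compute_odds_ratio(risky, outcome) == pytest.approx(expected)


def test_compute_odds_ratio_validates_input():
    with pytest.raises(ss.ValidationError):
        ss.compute_odds_ratio(np.array([1, 0]), np.array([1]))
    with pytest.raises(ss.ValidationError):
        ss.compute_odds_ratio(np.array([1, 2]), np.array([1, 0]))


def test_extract_constant_column():
    c = ss.ColumnSpec
    schema = ss.TableSchema((
        c("const", "continuous", 0, 10, 7, "above"),
        c("Y", "binary", 0, 1, is_outcome=True),
    ), n_rows_default=4)
    vals = np.column_stack([np.full(4, 5.0), [0, 1, 0, 1]])
    sv = ss.extract_statistics(ss.Table(vals, schema))
    assert sv.get("const", STAT_MIN) == 5
    assert sv.get("const", STAT_MAX) == 5
    assert sv.get("const", STAT_MEAN) == 5
    assert sv.get("const", STAT_RISKY) == 0


def test_extract_risky_fraction_brute_force():
    """4-row toy table, 2 cells above threshold -> fraction 0.5 (counted)."""
    c = ss.ColumnSpec
    schema = ss.TableSchema((
        c("x", "continuous", 0, 10, 5, "above"),
        c("Y", "binary", 0, 1, is_outcome=True),
    ))
    col = np.array([1.0, 6.0, 7.0, 2.0])
    vals = np.column_stack([col, [0, 1, 0, 1]])
    sv = ss.extract_statistics(ss.Table(vals, schema))
    brute = sum(1 for v in col if v > 5) / len(col)
    assert brute == 0.5
    assert sv.get("x", STAT_RISKY) == brute


def test_default_menu_covers_published_statistic_kinds():
    menu = ss.pima_schema().statistic_menu()
    kinds = {k for _, k in menu}
    assert {"min", "max", "mean", "risky_fraction", "odds_ratio"} <= kinds


def test_extract_row_permutation_invariant(tiny_table):
    sv = ss.extract_statistics(tiny_table)
    perm = np.random.default_rng(3).permutation(tiny_table.n_rows)
    shuffled = ss.Table(tiny_table.values[perm], tiny_table.schema)
    sv2 = ss.extract_statistics(shuffled)
    assert np.array_equal(sv.values, sv2.values)


def test_extract_rejects_mismatch_and_nonfinite(tiny_schema, tiny_table):
    c = ss.ColumnSpec
    other = ss.TableSchema((c("Z", "continuous", 0, 1),
                            c("Y", "binary", 0, 1, is_outcome=True)))
    with pytest.raises(ss.SchemaError):
        ss.extract_statistics(tiny_table, other)
    bad = tiny_table.values.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ss.ValidationError):
        ss.extract_statistics(ss.Table(bad, tiny_schema))


class TestPerturb:
    def test_zero_amplitude_is_identity(self, tiny_stats):
        out = ss.perturb_statistics(tiny_stats, 0.0, seed=1)
        assert np.array_equal(out.values, tiny_stats.values)

    def test_deterministic_given_seed(self, tiny_stats):
        a = ss.perturb_statistics(tiny_stats, 0.01, seed=7)
        b = ss.perturb_statistics(tiny_stats, 0.01, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_one_percent_envelope(self, tiny_stats):
        """Pre-repair values stay within +/-1% of their input."""
        for seed in range(10):
            out = ss.perturb_statistics(tiny_stats, 0.01, seed=seed)
            # repair can only move values toward validity, never further
            # than the envelope on entries that were already interior
            rel = np.abs(out.values - tiny_stats.values) / np.maximum(
                np.abs(tiny_stats.values), 1e-12)
            mean_idx = [i for i, (_, k) in enumerate(tiny_stats.entries)
                        if k == STAT_MEAN]
            assert np.all(rel[mean_idx] <= 0.01 + 1e-12)

    def test_output_is_valid(self, tiny_stats, tiny_schema):
        for seed in range(10):
            out = ss.perturb_statistics(tiny_stats, 0.05, seed=seed)
            assert ss.validate_statistics(out, tiny_schema) == []


class TestValidate:
    def test_roundtrip_is_valid(self, tiny_stats, tiny_schema):
        assert ss.validate_statistics(tiny_stats, tiny_schema) == []

    def test_mean_above_max_flagged(self, tiny_stats, tiny_schema):
        bad = tiny_stats.copy()
        bad.set("A", STAT_MEAN, bad.get("A", STAT_MAX) + 1)
        violations = ss.validate_statistics(bad, tiny_schema)
        assert len(violations) == 1 and "A" in violations[0]

    def test_fraction_out_of_range_flagged(self, tiny_stats, tiny_schema):
        bad = tiny_stats.copy()
        bad.set("A", STAT_RISKY, 1.2)
        violations = ss.validate_statistics(bad, tiny_schema)
        assert len(violations) == 1 and "[0, 1]" in violations[0]


def test_statistics_csv_roundtrip(tmp_path, tiny_stats, tiny_schema):
    """CSV round trip is lossless at 10 significant digits."""
    path = tmp_path / "stats.csv"
    ss.write_statistics_csv(path, [tiny_stats])
    back = ss.read_statistics_csv(path, tiny_schema)[0]
    np.testing.assert_allclose(back.values, tiny_stats.values, rtol=1e-9)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
       st.floats(-1e6, 1e6))
def test_risky_fraction_always_in_unit_interval(values, threshold):
    f = ss.risky_fraction(np.array(values), threshold, "above")
    assert 0.0 <= f <= 1.0
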