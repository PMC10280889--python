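"""Frequency tables, per-100k normalization, ranking, prediction intervals, stability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emergepi import (
    AdmissionRecord,
    ConfigurationError,
    UndefinedIntervalError,
    expected_counts,
    generate_admissions,
    normalize_per_100k,
    prediction_interval,
    rank_by_mean,
    rank_stability,
    tabulate,
)
from emergepi.synthetic_data import _rounded_counts, synthetic_category_labels


def records_from_counts(counts_by_cat_year):
    records = []
    i = 0
    for (cat, year), n in counts_by_cat_year.items():
        for _ in range(n):
            records.append(AdmissionRecord(f"p{i}", cat, year))
            i += 1
    return records


class TestTabulate:
    def test_direct_count(self):
        records = records_from_counts({("I21", 2015): 2, ("I63", 2015): 1})
        table = tabulate(records, {2015: 1000.0})
        assert table.counts.loc["I21", 2015] == 2
        assert table.counts.loc["I63", 2015] == 1
        assert table.total == 3

    def test_empty_stream(self):
        table = tabulate([], {2015: 1000.0})
        assert table.total == 0

    def test_missing_population_year_is_config_error(self):
        records = [AdmissionRecord("p", "I21", 2099)]
        with pytest.raises(ConfigurationError, match="population"):
            tabulate(records, {2015: 1000.0})

    def test_chapter_scope_filters_by_group(self):
        records = records_from_counts({("A09", 2015): 2, ("B15", 2015): 1, ("I21", 2015): 4})
        table = tabulate(records, {2015: 1000.0}, scope="chapter:A/B")
        assert table.total == 3 and set(table.counts.index) == {"A09", "B15"}

    def test_roster_scope_uses_record_labels(self):
        records = [
            AdmissionRecord("p1", "S72", 2015, roster="surgical"),
            AdmissionRecord("p2", "I21", 2015, roster="medical"),
        ]
        table = tabulate(records, {2015: 1000.0}, scope="roster:surgical")
        assert table.total == 1 and list(table.counts.index) == ["S72"]

    def test_noiseless_stream_reproduces_expected_matrix(self, six_year_exponential_config):
        # cross-module identity: tabulated counts equal the generator's
        # rounded expected-count matrix exactly when noise is off
        cfg = six_year_exponential_config
        cfg = type(cfg)(
            law=cfg.law,
            years=cfg.years,
            population_per_year=cfg.population_per_year,
            z_fraction=0.0,
            noise="none",
            seed=cfg.seed,
        )
        records = generate_admissions(cfg)
        table = tabulate(records, cfg.population_per_year)
        expected = _rounded_counts(expected_counts(cfg.law))
        labels = synthetic_category_labels(cfg.law.n_categories)
        for year in cfg.years:
            got = table.counts[year].reindex(labels).to_numpy()
            assert np.array_equal(got, expected)


class TestNormalize:
    def test_proportionality(self):
        assert normalize_per_100k(315, 315_000) == pytest.approx(100.0)
        assert normalize_per_100k(0, 315_000) == 0.0

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ConfigurationError, match="population"):
            normalize_per_100k(10, 0)

    @given(st.integers(1, 10_000), st.floats(1e3, 1e7), st.floats(1.1, 10.0))
    def test_scale_equivariance(self, count, pop, c):
        assert normalize_per_100k(count, pop * c) == pytest.approx(
            normalize_per_100k(count, pop) / c, rel=1e-12
        )


class TestPredictionInterval:
    def test_zero_variance_collapses_to_mean(self):
        assert prediction_interval([10, 10, 10]) == (10.0, 10.0)

    def test_hand_computed_three_year_case(self):
        # mean 10, s = 2, t(0.975, 2) = 4.302653, width factor sqrt(1 + 1/3)
        lo, hi = prediction_interval([8, 10, 12])
        assert lo == pytest.approx(0.0634491530, abs=1e-9)
        assert hi == pytest.approx(19.9365508470, abs=1e-9)

    def test_clipping_at_zero(self):
        lo, _ = prediction_interval([1, 2, 9])
        assert lo == 0.0
        lo_raw, _ = prediction_interval([1, 2, 9], clip_at_zero=False)
        assert lo_raw < 0

    def test_single_value_is_undefined(self):
        with pytest.raises(UndefinedIntervalError):
            prediction_interval([10])

    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=12))
    def test_interval_contains_the_mean(self, values):
        lo, hi = prediction_interval(values)
        assert lo <= float(np.mean(values)) <= hi


class TestRankByMean:
    def make_table(self, counts_per_cat, years=(2015, 2016)):
        counts = {}
        for cat, per_year in counts_per_cat.items():
            for y, n in zip(years, per_year):
                counts[(cat, y)] = n
        return tabulate(records_from_counts(counts), {y: 100_000.0 for y in years})

    def test_sorted_non_increasing_with_lexicographic_ties(self):
        table = self.make_table({"I21": (5, 5), "G40": (5, 5), "S72": (9, 9)})
        profile = rank_by_mean(table)
        assert [e.category for e in profile.entries] == ["S72", "G40", "I21"]
        freqs = profile.frequencies
        assert np.all(np.diff(freqs) <= 0)

    def test_pi_brackets_mean(self):
        table = self.make_table({"I21": (8, 12), "G40": (1, 3)})
        for e in rank_by_mean(table).entries:
            assert e.pi_lower <= e.mean <= e.pi_upper

    def test_coverage_truncation_keeps_minimal_prefix(self):
        table = self.make_table({"A00": (10, 10), "C00": (5, 5), "D00": (3, 3), "E00": (2, 2)})
        profile = rank_by_mean(table, coverage_truncation=0.8)
        assert len(profile) == 3  # cumulative shares 50%, 75%, 90%
        assert len(rank_by_mean(table, coverage_truncation=1.0)) == 4

    def test_truncation_by_category_count(self):
        table = self.make_table({f"C{i:02d}": (10 - i, 10 - i) for i in range(10)})
        profile = rank_by_mean(table, coverage_truncation=0.8, truncation_basis="categories")
        assert len(profile) == 8

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=15))
    def test_truncated_prefix_is_minimal(self, counts):
        table = self.make_table({f"C{i:02d}": (n, n) for i, n in enumerate(counts)})
        profile = rank_by_mean(table, coverage_truncation=0.8)
        shares = np.cumsum(sorted(counts, reverse=True)) / sum(counts)
        brute = int(np.argmax(shares >= 0.8 - 1e-12)) + 1
        assert len(profile) == brute

    def test_count_scale_profile(self):
        table = self.make_table({"I21": (10, 20)})
        profile = rank_by_mean(table, scale="count")
        assert profile.entries[0].mean == pytest.approx(15.0)


class TestRankStability:
    def test_identical_years_correlate_perfectly(self):
        records = records_from_counts(
            {("I21", 2015): 5, ("G40", 2015): 2, ("I21", 2016): 5, ("G40", 2016): 2}
        )
        stab = rank_stability(tabulate(records, {2015: 1.0, 2016: 1.0}))
        assert stab.mean == pytest.approx(1.0)

    def test_reversed_year_correlates_minus_one(self):
        records = records_from_counts(
            {("I21", 2015): 5, ("G40", 2015): 2, ("I21", 2016): 2, ("G40", 2016): 5}
        )
        stab = rank_stability(tabulate(records, {2015: 1.0, 2016: 1.0}))
        assert stab.minimum == pytest.approx(-1.0)

    def test_poisson_exponential_stream_is_stable(self, six_year_exponential_config):
        records = generate_admissions(six_year_exponential_config)
        records = [r for r in records if r.icd10_code[0] != "Z"]
        stab = rank_stability(tabulate(records, six_year_exponential_config.population_per_year))
        assert stab.mean > 0.9
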