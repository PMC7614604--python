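"""Age standardization, Dobson intervals, exposure windows, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonoprev.epi import (
    ExposureWindowSpec,
    RegionRecord,
    Stratum,
    age_standardized_rate,
    dobson_ci,
    egfr_mutation_rate,
    egfrm_incidence,
    exposure_groups,
    load_standard_population,
    pm25_exposure_window,
    weighted_pearson,
)
from clonoprev.exceptions import MissingYearError


class TestStandardPopulations:
    def test_esp2013_weights_sum_to_100000(self):
        esp = load_standard_population("esp2013")
        assert esp["std_weight"].sum() == 100_000
        assert len(esp) == 20

    def test_who2000_loads(self):
        who = load_standard_population("who2000")
        assert len(who) == 18
        assert who["std_weight"].iloc[0] == 8860


class TestAgeStandardizedRate:
    def test_single_stratum_weight_cancels(self):
        for w in (1.0, 7000.0):
            s = Stratum("50-54", cases=10, population=100_000, std_weight=w)
            assert age_standardized_rate([s]) == pytest.approx(10.0)

    def test_two_stratum_arithmetic_oracle(self):
        strata = [
            Stratum("a", cases=5, population=50_000, std_weight=1.0),
            Stratum("b", cases=30, population=100_000, std_weight=2.0),
        ]
        expected = (1 * 0.0001 + 2 * 0.0003) / 3 * 100_000
        assert age_standardized_rate(strata) == pytest.approx(expected)
        assert expected == pytest.approx(23.33, abs=0.01)

    def test_zero_cases_zero_rate(self):
        strata = [Stratum("a", cases=0, population=1000, std_weight=2.0)]
        assert age_standardized_rate(strata) == 0.0

    def test_invariant_to_joint_scaling(self):
        base = pd.DataFrame(
            {
                "cases": [3, 8, 20],
                "population": [10_000, 20_000, 30_000],
                "std_weight": [5500, 7000, 4000],
            }
        )
        scaled = base.assign(cases=base.cases * 7, population=base.population * 7)
        assert age_standardized_rate(scaled) == pytest.approx(
            age_standardized_rate(base)
        )


class TestDobsonCI:
    def test_single_stratum_exact_poisson_oracle(self):
        # chi-square identity oracle evaluated independently
        x = 10
        lo_cases = stats.chi2.ppf(0.025, 2 * x) / 2
        hi_cases = stats.chi2.ppf(0.975, 2 * x + 2) / 2
        assert lo_cases == pytest.approx(4.795, abs=1e-3)
        assert hi_cases == pytest.approx(18.39, abs=1e-2)
        s = [Stratum("a", cases=x, population=100_000, std_weight=3.0)]
        lo, hi = dobson_ci(s)
        # one stratum: rate scale is cases per 100,000 directly
        assert lo == pytest.approx(lo_cases, rel=1e-6)
        assert hi == pytest.approx(hi_cases, rel=1e-6)

    def test_zero_cases_lower_bound_zero(self):
        s = [Stratum("a", cases=0, population=50_000, std_weight=2.0)]
        lo, hi = dobson_ci(s)
        assert lo == 0.0
        assert hi > 0.0

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            strata = pd.DataFrame(
                {
                    "cases": rng.integers(0, 50, 4),
                    "population": rng.integers(10_000, 90_000, 4),
                    "std_weight": rng.integers(1000, 8000, 4),
                }
            )
            if strata["cases"].sum() == 0:
                continue
            rate = age_standardized_rate(strata)
            lo, hi = dobson_ci(strata)
            assert lo <= rate <= hi

    def test_converges_to_normal_approximation(self):
        # at 10,000 cases the exact-Poisson anchoring is within 2% of the
        # plain normal-theory interval
        rng = np.random.default_rng(17)
        strata = pd.DataFrame(
            {
                "cases": rng.multinomial(10_000, [0.2, 0.3, 0.3, 0.2]),
                "population": [3e6, 4e6, 5e6, 6e6],
                "std_weight": [5500, 7000, 6000, 4000],
            }
        )
        rate = age_standardized_rate(strata)
        x, d, w = (
            strata["cases"].to_numpy(float),
            strata["population"].to_numpy(float),
            strata["std_weight"].to_numpy(float),
        )
        v = np.sum(w**2 * x / d**2) / np.sum(w) ** 2 * 100_000.0**2
        norm_lo, norm_hi = rate - 1.96 * np.sqrt(v), rate + 1.96 * np.sqrt(v)
        lo, hi = dobson_ci(strata)
        assert lo == pytest.approx(norm_lo, rel=0.02)
        assert hi == pytest.approx(norm_hi, rel=0.02)

    def test_width_shrinks_with_case_load(self):
        def width(scale):
            s = pd.DataFrame(
                {
                    "cases": [10 * scale, 20 * scale],
                    "population": [100_000 * scale, 200_000 * scale],
                    "std_weight": [6000, 5000],
                }
            )
            lo, hi = dobson_ci(s)
            return hi - lo

        assert width(100) < width(10) < width(1)


class TestEGFRMutationRate:
    @pytest.mark.parametrize(
        "abnormal,normal,expected", [(25, 75, 0.25), (0, 40, 0.0), (40, 0, 1.0)]
    )
    def test_proportion(self, abnormal, normal, expected):
        assert egfr_mutation_rate(abnormal, normal) == expected

    def test_no_tests_raises(self):
        with pytest.raises(ValueError):
            egfr_mutation_rate(0, 0)

    def test_egfrm_incidence_product(self):
        assert egfrm_incidence(50.0, 0.2) == 10.0
        assert egfrm_incidence(7.5, 0.0) == 0.0
        assert egfrm_incidence(39.2, 0.147) == pytest.approx(5.76, abs=0.01)


class TestExposureWindow:
    @staticmethod
    def _series(years, value=None):
        return {y: (value if value is not None else float(y)) for y in years}

    def test_england_convention_ten_years_no_washout(self):
        series = self._series(range(2000, 2019))
        spec = ExposureWindowSpec(window_years=10, washout_years=0)
        got = pm25_exposure_window(series, spec, diagnosis_year=2018)
        assert got == pytest.approx(np.mean(range(2008, 2018)))

    def test_taiwan_convention_two_year_washout(self):
        # diagnosis 2017 with 2-year washout averages 2006-2015
        series = self._series(range(2006, 2018))
        spec = ExposureWindowSpec(window_years=10, washout_years=2)
        got = pm25_exposure_window(series, spec, diagnosis_year=2017, min_year=2006)
        assert got == pytest.approx(np.mean(range(2006, 2016)))
        # diagnosis 2011: only 2006-2009 available inside the window
        got11 = pm25_exposure_window(series, spec, diagnosis_year=2011, min_year=2006)
        assert got11 == pytest.approx(np.mean(range(2006, 2010)))

    def test_constant_series_returns_constant(self):
        series = self._series(range(2000, 2019), value=7.7)
        record = RegionRecord("r1", series, diagnosis_year=2018)
        assert pm25_exposure_window(record) == 7.7

    def test_missing_year_raises(self):
        series = self._series(range(2008, 2018))
        del series[2012]
        with pytest.raises(MissingYearError):
            pm25_exposure_window(series, diagnosis_year=2018)


class TestWeightedPearson:
    def test_equal_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r_plain = stats.pearsonr(x, y).statistic
        assert weighted_pearson(x, y, np.full(40, 3.0)) == pytest.approx(
            r_plain, abs=1e-12
        )

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        w = np.arange(1.0, 11.0)
        assert weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)
        assert weighted_pearson(x, -x + 4, w) == pytest.approx(-1.0)

    def test_five_point_direct_summation_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
        y = np.array([2.0, 1.5, 4.5, 6.0, 9.5])
        w = np.array([1.0, 5.0, 2.0, 0.5, 3.0])
        mx = (w * x).sum() / w.sum()
        my = (w * y).sum() / w.sum()
        expected = ((w * (x - mx) * (y - my)).sum()
                    / np.sqrt((w * (x - mx) ** 2).sum() * (w * (y - my) ** 2).sum()))
        assert weighted_pearson(x, y, w) == pytest.approx(expected, rel=1e-12)

    @given(
        a=st.floats(min_value=0.1, max_value=5),
        b=st.floats(min_value=-10, max_value=10),
        c=st.floats(min_value=0.1, max_value=5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_affine_and_weight_rescaling_invariance(self, a, b, c):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        w = rng.uniform(0.5, 2.0, size=20)
        base = weighted_pearson(x, y, w)
        assert weighted_pearson(a * x + b, y, w) == pytest.approx(base, abs=1e-9)
        assert weighted_pearson(x, y, c * w) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])


class TestExposureGroups:
    def test_linear_interpolation_quantile_cutoffs(self):
        values = np.arange(1.0, 11.0)
        labels, thresholds = exposure_groups(values)
        assert thresholds.low_cut == pytest.approx(np.quantile(values, 0.2))
        assert thresholds.high_cut == pytest.approx(np.quantile(values, 0.8))
        assert labels[0] == "low" and labels[-1] == "high"
        # strict inequalities: values at the cutoffs are intermediate
        for v, lab in zip(values, labels):
            if v < thresholds.low_cut:
                assert lab == "low"
            elif v > thresholds.high_cut:
                assert lab == "high"
            else:
                assert lab == "intermediate"

    def test_all_equal_everything_intermediate(self):
        labels, _ = exposure_groups([7.0] * 8)
        assert set(labels) == {"intermediate"}

    def test_single_low_value(self):
        values = [1.0, 10.0, 10.0, 10.0, 10.0, 10.0]
        labels, thresholds = exposure_groups(values)
        assert labels.count("low") == 1 and labels[0] == "low"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            exposure_groups([1.0, 2.0, 3.0])
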