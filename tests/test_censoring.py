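import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm, spearmanr

from metalscreen import (
    PUBLISHED_LIMITS,
    CensoredSeries,
    ConfigurationError,
    DataError,
    DeficiencyThresholds,
    DetectionLimits,
    censored_percentiles,
    classify,
    compute_limits,
    flag_deficiencies,
    prevalence_table,
    substitute,
)

AS = PUBLISHED_LIMITS["As"]
PB = PUBLISHED_LIMITS["Pb"]


class TestComputeLimits:
    def test_lod_loq_are_3sd_and_10sd(self):
        # blanks with sample SD exactly 0.1
        blanks = [0.0, 0.2]  # mean 0.1, sd (n-1) = sqrt(2*0.01) ... construct directly
        sd = np.std(blanks, ddof=1)
        lim = compute_limits(blanks, toxic_threshold=20.0, analyte="As")
        assert lim.lod == pytest.approx(3 * sd)
        assert lim.loq == pytest.approx(10 * sd)

    def test_matches_two_pass_sd_formula(self):
        rng = np.random.default_rng(1)
        blanks = rng.normal(0.05, 0.02, size=10)
        m = sum(blanks) / 10
        sd = (sum((b - m) ** 2 for b in blanks) / 9) ** 0.5
        lim = compute_limits(blanks, 20.0, "As")
        assert lim.lod == pytest.approx(3 * sd, rel=1e-12)

    def test_constant_blanks_rejected(self):
        with pytest.raises(DataError):
            compute_limits([0.0] * 10, 20.0)

    def test_needs_two_measurements(self):
        with pytest.raises(DataError):
            compute_limits([0.1], 20.0)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (25.0, "toxic"),  # above the 20 ug/L acute threshold for As
            (1.88, "quantified"),
            (0.2, "lod_loq"),  # exactly LoD -> detected-not-quantified (half-open)
            (0.19, "below_lod"),
            (0.55, "quantified"),  # exactly LoQ -> quantified
        ],
    )
    def test_arsenic_categories(self, value, expected):
        s = classify([value], AS)
        assert s.category[0] == expected

    def test_lead_between_limits(self):
        assert classify([1.0], PB).category[0] == "lod_loq"

    def test_values_withheld_when_censored(self):
        s = classify([0.1, 0.3, 1.88], AS)
        assert np.isnan(s.values[0]) and np.isnan(s.values[1])
        assert s.values[2] == 1.88

    def test_negative_value_rejected_with_record_index(self):
        with pytest.raises(DataError, match=r"\[2\]"):
            classify([0.1, 0.2, -0.5], AS)

    def test_invalid_limit_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectionLimits("X", lod=1.0, loq=0.5, toxic=20.0)


def series_from_counts(limits, below, mid, quant, toxic=0):
    """Category vector with the given composition (quantified values spread
    over [loq, toxic))."""
    cats = (
        ["below_lod"] * below + ["lod_loq"] * mid + ["quantified"] * quant + ["toxic"] * toxic
    )
    vals = np.full(len(cats), np.nan)
    q = np.linspace(limits.loq, limits.toxic * 0.9, max(quant, 1))
    vals[below + mid : below + mid + quant] = q[:quant]
    if toxic:
        vals[-toxic:] = limits.toxic * 1.1
    return CensoredSeries(limits.analyte, np.array(cats, dtype=object), vals, limits)


class TestPrevalence:
    def test_counts_and_percentages_sum(self):
        s = series_from_counts(AS, 18, 148, 246)
        row = prevalence_table(s)
        assert sum(row.counts.values()) == 412
        assert row.percentages["quantified"] == 59.7
        assert row.detected_pct == 95.6

    def test_all_quantified_boundary(self):
        s = series_from_counts(AS, 0, 0, 50)
        row = prevalence_table(s)
        assert row.detected_pct == 100.0
        assert row.percentages["below_lod"] == 0.0

    def test_half_up_rounding(self):
        # 1/16 = 6.25% rounds half-up to 6.3
        s = series_from_counts(AS, 1, 0, 15)
        assert prevalence_table(s).percentages["below_lod"] == 6.3

    def test_toxic_counts_as_detected_and_quantified(self):
        s = series_from_counts(AS, 2, 2, 4, toxic=2)
        row = prevalence_table(s)
        assert row.detected_count == 8
        assert row.quantified_total_count == 6


class TestCensoredPercentiles:
    def test_censored_mass_dominates(self):
        s = series_from_counts(AS, 8, 0, 2)
        out = censored_percentiles(s, probs=(5, 25, 50, 75))
        assert all(v == "below_lod" for v in out.percentiles.values())

    def test_uncensored_matches_numpy_quantiles(self):
        rng = np.random.default_rng(3)
        vals = np.sort(rng.uniform(0.6, 15.0, 41))
        s = classify(vals, AS)
        assert (s.category == "quantified").all()
        out = censored_percentiles(s)
        for p, v in out.percentiles.items():
            assert v == pytest.approx(np.percentile(vals, p), rel=1e-12)

    def test_label_pattern_across_probabilities(self):
        # 6% below LoD, 34% detected-not-quantified: P5 censored at the
        # detection limit, P25 in the LoD-LoQ band, P50 numeric
        s = series_from_counts(AS, 6, 34, 60)
        out = censored_percentiles(s)
        assert out.percentiles[5.0] == "below_lod"
        assert out.percentiles[25.0] == "lod_loq"
        assert isinstance(out.percentiles[50.0], float)

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(9)
        s = series_from_counts(PB, 12, 9, 17)
        perm = rng.permutation(len(s.category))
        s2 = CensoredSeries(s.analyte, s.category[perm], s.values[perm], s.limits)
        probs = (5, 25, 50, 75, 95, 99)
        a = censored_percentiles(s, probs).percentiles
        b = censored_percentiles(s2, probs).percentiles
        assert a == b
        rank = {"below_lod": -2.0, "lod_loq": -1.0}
        keys = [rank.get(a[p], a[p]) for p in map(float, probs)]
        assert all(k2 >= k1 for k1, k2 in zip(keys, keys[1:]))


class TestSubstitute:
    def test_half_lod_mid_values(self):
        s = series_from_counts(AS, 1, 0, 0)
        assert substitute(s).values[0] == pytest.approx(0.1)
        s = series_from_counts(PB, 0, 1, 0)
        assert substitute(s).values[0] == pytest.approx(1.35)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            substitute(series_from_counts(AS, 1, 1, 1), scheme="zeros")

    def test_scheme_recorded(self):
        sub = substitute(series_from_counts(AS, 1, 1, 1), scheme="lod_sqrt2")
        assert sub.scheme == "lod_sqrt2"
        assert sub.values[0] == pytest.approx(0.2 / np.sqrt(2))

    def test_category_rank_order_matches_any_monotone_scheme(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([[0.05, 0.1], [0.3, 0.4], rng.uniform(0.6, 18, 30)])
        s = classify(vals, AS)
        r = substitute(s, "category_rank").values
        h = substitute(s, "half_lod_mid").values
        rho, _ = spearmanr(r, h)
        assert rho == pytest.approx(1.0)


class TestCensoringFractionCalibration:
    def test_below_lod_fraction_matches_lognormal_cdf(self):
        # mu, sigma chosen so P(X < LoD) = 0.3 exactly
        sigma = 0.7
        mu = np.log(AS.lod) - sigma * norm.ppf(0.3)
        rng = np.random.default_rng(12)
        draws = np.exp(mu + sigma * rng.standard_normal(1000))
        s = classify(draws, AS)
        frac = np.mean(s.category == "below_lod")
        assert frac == pytest.approx(0.30, abs=0.04)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(min_value=0.0, max_value=30.0), min_size=5, max_size=60),
    st.floats(min_value=0.05, max_value=5.0),
)
def test_censoring_is_monotone_in_lod(values, lod):
    """Raising the LoD never decreases the below-LoD count, and the three
    category counts always conserve n."""
    lim_lo = DetectionLimits("X", lod, lod * 4, 100.0)
    lim_hi = DetectionLimits("X", lod * 1.5, lod * 4, 100.0)
    s_lo, s_hi = classify(values, lim_lo), classify(values, lim_hi)
    assert np.sum(s_hi.category == "below_lod") >= np.sum(s_lo.category == "below_lod")
    for s in (s_lo, s_hi):
        assert sum(s.counts().values()) == len(values)


class TestDeficiencyFlags:
    def test_thresholds_and_boundaries(self):
        cov = pd.DataFrame(
            {
                "hb": [10.4, 11.0, np.nan],
                "zn": [65.0, 64.9, 70.0],
                "haz": [-2.1, -2.0, -1.0],
                "se": [50.0, 80.0, np.nan],
            }
        )
        flags = flag_deficiencies(cov, DeficiencyThresholds())
        assert flags.loc[0, "anemia"] == True  # noqa: E712
        assert flags.loc[1, "anemia"] == False  # 11.0 not < 11 (strict)  # noqa: E712
        assert flags.loc[2, "anemia"] is pd.NA
        assert flags.loc[0, "zinc_deficiency"] == False  # 65.0 exactly  # noqa: E712
        assert flags.loc[1, "zinc_deficiency"] == True  # noqa: E712
        assert flags.loc[0, "stunting"] == True  # noqa: E712
        assert flags.loc[1, "stunting"] == False  # noqa: E712
        assert flags.loc[2, "selenium_deficiency"] is pd.NA

    def test_absent_column_skipped(self):
        flags = flag_deficiencies(pd.DataFrame({"hb": [9.0]}))
        assert "copper_deficiency" not in flags.columns
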