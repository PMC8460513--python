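"""Normality check, Kruskal-Wallis, quantiles, correlation bins, reports."""

import numpy as np
import pandas as pd
import pytest

import fetalmorph as fm
from fetalmorph.errors import SampleSizeError


def test_anderson_darling_requires_valid_sample():
    with pytest.raises(SampleSizeError):
        fm.anderson_darling_normality([1.0, 2.0])
    with pytest.raises(SampleSizeError):
        fm.anderson_darling_normality([3.0] * 10)


def test_anderson_darling_calibration():
    """Non-reject for normal draws in >=90% of replicates; reject for
    exponential draws in >=95%."""
    normal_rejects = exp_rejects = 0
    for i in range(60):
        rng = np.random.default_rng(i)
        _, reject = fm.anderson_darling_normality(rng.standard_normal(500))
        normal_rejects += reject
        _, reject = fm.anderson_darling_normality(rng.exponential(size=500))
        exp_rejects += reject
    assert normal_rejects / 60 <= 0.10
    assert exp_rejects / 60 >= 0.95


def test_kruskal_identical_groups_h_zero():
    res = fm.kruskal_wallis([[1.0, 2, 3], [1.0, 2, 3]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=0.05)


def test_kruskal_all_values_identical():
    res = fm.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_matches_scipy():
    from scipy import stats as sps
    rng = np.random.default_rng(0)
    a, b, c = rng.normal(size=8), rng.normal(0.5, size=6), rng.normal(1, size=7)
    ours = fm.kruskal_wallis([a, b, c])
    ref = sps.kruskal(a, b, c)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_kruskal_two_group_maximum_by_rank_formula():
    """Fully separated n=3,3 gives H = 12/(n(n+1)) * (R1^2/3 + R2^2/3) - 3(n+1)
    with rank sums 6 and 15."""
    expected = 12.0 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
    res = fm.kruskal_wallis([[1.0, 2, 3], [101.0, 102, 103]])
    assert res.statistic == pytest.approx(expected)


def test_kruskal_exact_permutation_two_groups_n4():
    """Chi-squared approximation within 0.02 of the exact permutation p
    (all 70 assignments) for fully separated groups of 4."""
    a = [1.0, 2.0, 3.0, 4.0]
    b = [101.0, 102.0, 103.0, 104.0]
    chi2 = fm.kruskal_wallis([a, b], method="chi2")
    exact = fm.kruskal_wallis([a, b], method="exact")
    # both extremal assignments (a|b and b|a) reach the maximal H
    assert exact.p_value == pytest.approx(2.0 / 70.0)
    assert abs(chi2.p_value - exact.p_value) < 0.02


def test_kruskal_exact_matches_brute_force_enumeration():
    """Independent oracle: enumerate all 70 labelings with itertools and
    count H >= H_obs using scipy's statistic."""
    import itertools
    from scipy import stats as sps
    rng = np.random.default_rng(5)
    pooled = rng.normal(size=8)
    a, b = pooled[:4], pooled[4:]
    h_obs = sps.kruskal(a, b).statistic
    count = 0
    for combo in itertools.combinations(range(8), 4):
        mask = np.zeros(8, bool)
        mask[list(combo)] = True
        count += sps.kruskal(pooled[mask], pooled[~mask]).statistic >= h_obs - 1e-12
    ours = fm.kruskal_wallis([a, b], method="exact")
    assert ours.p_value == pytest.approx(count / 70.0)


def test_kruskal_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=6), rng.normal(1, size=5)
    h1 = fm.kruskal_wallis([a, b]).statistic
    h2 = fm.kruskal_wallis([np.exp(a), np.exp(b)]).statistic
    assert h1 == pytest.approx(h2)


def test_kruskal_sample_size_errors():
    with pytest.raises(SampleSizeError):
        fm.kruskal_wallis([[1.0]])
    with pytest.raises(SampleSizeError):
        fm.kruskal_wallis([[1.0], [2.0]])


def test_median_iqr_type7():
    assert fm.median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)
    assert fm.median_iqr([5.0]) == (5.0, 5.0, 5.0)
    assert fm.median_iqr([1, 2, 3, 4]) == (2.5, 1.75, 3.25)
    with pytest.raises(SampleSizeError):
        fm.median_iqr([])


def _data_with_exact_r(r, n=12, seed=0):
    """y = r*x + sqrt(1-r^2)*z with z orthogonal to x and both standardized:
    sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    return x, r * x + np.sqrt(1 - r * r) * z


def test_pearson_perfect_line_is_strong():
    x = np.arange(10.0)
    r, label = fm.pearson_with_strength(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert label == "strong"


@pytest.mark.parametrize("r,expected", [
    (0.56, "moderate"), (0.64, "moderate"),
    (0.2, "none or very weak"), (0.4, "weak"), (0.9, "strong"),
    (-0.6, "moderate"),
])
def test_pearson_strength_bins(r, expected):
    x, y = _data_with_exact_r(r)
    got_r, label = fm.pearson_with_strength(x, y)
    assert got_r == pytest.approx(r, abs=1e-9)
    assert label == expected


@pytest.mark.parametrize("r,expected", [(0.3, "weak"), (0.5, "moderate"),
                                        (0.7, "strong"), (0.29, "none or very weak"),
                                        (-0.7, "strong")])
def test_strength_boundaries_go_to_higher_bin(r, expected):
    from fetalmorph.stats import strength_label
    assert strength_label(r) == expected


def test_pearson_negation_keeps_strength():
    x, y = _data_with_exact_r(0.6)
    r1, l1 = fm.pearson_with_strength(x, y)
    r2, l2 = fm.pearson_with_strength(x, -y)
    assert r2 == pytest.approx(-r1) and l1 == l2


def test_pearson_constant_input_raises():
    with pytest.raises(SampleSizeError):
        fm.pearson_with_strength([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

def test_cohort_counts_and_determinism():
    c1 = fm.generate_cohort(12, 12, 12, seed=7)
    c2 = fm.generate_cohort(12, 12, 12, seed=7)
    assert len(c1.demographics) == 36
    assert len(c1.table) == 48  # 12 paired MMC + 24 single controls
    pd.testing.assert_frame_equal(c1.table, c2.table)


def test_report_row_bookkeeping():
    cohort = fm.generate_cohort(6, 6, 6, seed=3)
    metrics = ["ventricles_volume", "unmyelinated_wm_volume"]
    report = fm.run_group_analysis(cohort.table, metrics=metrics)
    assert len(report.absolute_tests) == len(metrics) * 2  # pre+post contrasts
    assert len(report.rate_tests) == len(metrics)
    assert set(report.rate_tests.metric) == set(metrics)
    assert np.all((report.absolute_tests.p_value >= 0)
                  & (report.absolute_tests.p_value <= 1))
    assert np.all(report.absolute_tests.significant
                  == (report.absolute_tests.p_value < 0.05))


def test_unpaired_mmc_subject_excluded():
    cohort = fm.generate_cohort(4, 4, 4, seed=1)
    table = cohort.table
    drop = (table.subject_id == "mmc00") & (table.timepoint == "post")
    report = fm.run_group_analysis(table[~drop], metrics=["ventricles_volume"])
    mmc_rates = report.rates[(report.rates.group == "mmc")
                             & (report.rates.metric == "ventricles_volume")]
    assert len(mmc_rates) == 3  # mmc00 excluded for missing pairing


def test_default_effect_flags_ventricular_rate():
    cohort = fm.generate_cohort(12, 12, 12, seed=0)
    report = fm.run_group_analysis(cohort.table, metrics=["ventricles_volume"])
    row = report.rate_tests.iloc[0]
    assert row.significant
    assert row.median_mmc > row.median_control


def test_report_writes_outputs(tmp_path):
    cohort = fm.generate_cohort(4, 4, 4, seed=2)
    report = fm.run_group_analysis(cohort.table)
    report.write(tmp_path)
    for name in ("absolute_tests.csv", "rate_tests.csv", "correlations.csv",
                 "paired_rates.csv", "normality.csv", "run_log.json"):
        assert (tmp_path / name).exists()
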