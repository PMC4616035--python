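"""Reading, stratified summaries, rank tests and log-linear CH4 fits."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import fluvialghg as fg
from fluvialghg.measurements import class_comparison_report


def _write_csv(tmp_path, rows, name="data.csv"):
    cols = ["river", "date", "longitude", "latitude", "channel_class",
            "pco2_ppm", "ch4_nmol_l"]
    path = tmp_path / name
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


GOOD_ROWS = [
    ["Amazon", "2008-05-11", -60.5, -3.2, "MS", 4500.0, 900.0],
    ["Amazon", "2008-05-12", -60.4, -3.1, "T>100m", 6000.0, 1500.0],
    ["Congo", "2013-12-05", 20.1, -1.0, "T<100m", 9000.0, 8000.0],
]


class TestReadMeasurements:
    def test_well_formed_file(self, tmp_path):
        df = fg.read_measurements(_write_csv(tmp_path, GOOD_ROWS))
        assert len(df) == 3
        assert df.attrs["n_rejected"] == 0

    def test_invalid_rows_rejected_and_counted(self, tmp_path):
        rows = GOOD_ROWS + [
            ["Congo", "2013-12-06", 20.0, -1.1, "T<100m", 9000.0, 0.0],   # ch4 = 0
            ["Congo", "2013-12-07", 20.0, -1.1, "lake", 9000.0, 10.0],    # bad class
            ["Congo", "2013-12-08", 20.0, -1.1, "MS", "n/a", 10.0],       # bad numeric
        ]
        df = fg.read_measurements(_write_csv(tmp_path, rows))
        assert len(df) == 3
        assert df.attrs["n_rejected"] == 3

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"river": ["Amazon"], "pco2_ppm": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="ch4_nmol_l") as err:
            fg.read_measurements(path)
        assert "channel_class" in str(err.value)


class TestClassifyChannel:
    @pytest.mark.parametrize(
        "width, mainstem, expected",
        [
            (150.0, False, "T>100m"),
            (100.0, False, "T>100m"),  # tie goes to the large class
            (99.9, False, "T<100m"),
            (5.0, True, "MS"),
            (None, True, "MS"),
        ],
    )
    def test_classification(self, width, mainstem, expected):
        assert fg.classify_channel(width, mainstem) == expected

    def test_nonpositive_width_raises(self):
        with pytest.raises(ValueError):
            fg.classify_channel(0.0, False)


class TestSummarize:
    def test_single_record_collapses(self, tmp_path):
        df = fg.read_measurements(_write_csv(tmp_path, GOOD_ROWS[:1]))
        s = fg.summarize(df, "Amazon", "MS")
        assert s.n == 1
        assert s.pco2_median == s.pco2_mean == s.pco2_min == s.pco2_max == 4500.0

    def test_order_statistics_ordered_and_permutation_invariant(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(8, 1, size=200)
        ch4 = rng.lognormal(6, 1, size=200)
        df = pd.DataFrame(
            {"river": "R", "channel_class": "MS", "pco2_ppm": vals,
             "ch4_nmol_l": ch4}
        )
        s = fg.summarize(df, "R", "MS")
        assert (s.pco2_min <= s.pco2_p5 <= s.pco2_q25 <= s.pco2_median
                <= s.pco2_q75 <= s.pco2_p95 <= s.pco2_max)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s2 = fg.summarize(shuffled, "R", "MS")
        for field in ("pco2_median", "pco2_mean", "pco2_q25", "pco2_p95",
                      "ch4_median", "ch4_mean", "ch4_min", "ch4_max"):
            assert getattr(s2, field) == pytest.approx(getattr(s, field), rel=1e-12)

    def test_large_stratum_recovers_configured_median(self):
        cfg = fg.MeasurementSimConfig(
            strata=(fg.StratumConfig("R", "MS", 1001, 5000.0, 1.6, 0.0, 3.0, 0.2),),
            seed=5,
        )
        df = fg.generate_measurements(cfg)
        s = fg.summarize(df, "R", "MS")
        assert s.pco2_median == pytest.approx(5000.0, rel=0.05)

    def test_empty_stratum_raises(self, tmp_path):
        df = fg.read_measurements(_write_csv(tmp_path, GOOD_ROWS))
        with pytest.raises(ValueError, match="empty stratum"):
            fg.summarize(df, "Amazon", "T<100m")

    def test_pooled_range_spans_all_classes(self, study_df):
        lo, hi = fg.pooled_range(study_df, "Amazon", "pco2")
        assert lo == study_df.loc[study_df.river == "Amazon", "pco2_ppm"].min()
        assert hi == study_df.loc[study_df.river == "Amazon", "pco2_ppm"].max()


def _manual_kruskal(groups):
    """Textbook tie-corrected H computed from first principles."""
    all_vals = np.concatenate(groups)
    n_total = len(all_vals)
    order = np.argsort(all_vals, kind="stable")
    ranks = np.empty(n_total)
    i = 0
    sorted_vals = all_vals[order]
    while i < n_total:
        j = i
        while j < n_total and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        h, p = fg.kruskal_wallis([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_ranked_computation(self):
        groups = ([3.0, 1.0, 4.0, 1.0], [5.0, 9.0, 2.0, 6.0], [5.0, 3.0, 5.0, 8.0])
        h, _ = fg.kruskal_wallis(*groups)
        assert h == pytest.approx(_manual_kruskal(groups), rel=1e-12)

    def test_heavy_ties_remain_finite(self):
        h, p = fg.kruskal_wallis([1, 1, 2], [1, 2, 2], [2, 2, 1])
        assert math.isfinite(h) and math.isfinite(p)

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(ValueError):
            fg.kruskal_wallis([1.0, 2.0])

    def test_two_group_h_monotone_in_mw_deviation(self):
        # with two groups, H and the Mann-Whitney deviation |U - n1 n2 / 2|
        # order data-sets identically
        rng = np.random.default_rng(3)
        hs, devs = [], []
        for shift in (0.0, 0.5, 1.5, 3.0):
            a = rng.normal(0, 1, 12)
            b = rng.normal(shift, 1, 12)
            h, _ = fg.kruskal_wallis(a, b)
            u, _ = fg.mann_whitney(a, b)
            hs.append(h)
            devs.append(abs(u - len(a) * len(b) / 2))
        assert np.argsort(hs).tolist() == np.argsort(devs).tolist()


def _mw_exact_p(a, b):
    """Two-sided p by exhaustive enumeration of all rank splits (no ties)."""
    combined = np.concatenate([a, b])
    n1, n2 = len(a), len(b)

    def u_of(idx_a):
        idx_a = set(idx_a)
        aa = [combined[i] for i in idx_a]
        bb = [combined[i] for i in range(n1 + n2) if i not in idx_a]
        return sum(x > y for x in aa for y in bb)

    u_obs = u_of(range(n1))
    mu = n1 * n2 / 2.0
    splits = list(itertools.combinations(range(n1 + n2), n1))
    count = sum(abs(u_of(s) - mu) >= abs(u_obs - mu) - 1e-12 for s in splits)
    return count / len(splits)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        _, p = fg.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_matches_exhaustive_enumeration(self):
        a = [1.2, 3.4, 0.5, 2.2]
        b = [2.9, 4.1, 1.8, 5.0]
        _, p = fg.mann_whitney(a, b)
        assert p == pytest.approx(_mw_exact_p(a, b), abs=1e-12)

    def test_complete_separation_extreme_u(self):
        u, p = fg.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0])
        assert u in (0.0, 12.0)
        assert p == pytest.approx(_mw_exact_p([1.0, 2.0, 3.0],
                                              [10.0, 11.0, 12.0, 13.0]), abs=1e-12)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            fg.mann_whitney([], [1.0])


class TestLogLinearFit:
    def test_exact_line_recovered(self):
        pco2 = np.array([1000.0, 3000.0, 5000.0, 8000.0])
        log_ch4 = 2.0 + 1e-4 * pco2
        df = pd.DataFrame(
            {"river": "R", "channel_class": "MS", "pco2_ppm": pco2,
             "ch4_nmol_l": 10.0**log_ch4}
        )
        fit = fg.fit_log_ch4_vs_pco2(df, "R", "MS")
        assert fit.slope == pytest.approx(1e-4, rel=1e-9)
        assert fit.intercept == pytest.approx(2.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_slope_within_two_se(self):
        rng = np.random.default_rng(8)
        pco2 = rng.uniform(500, 10000, 400)
        noise_sd = 0.2
        log_ch4 = 2.5 + 8e-5 * pco2 + rng.normal(0, noise_sd, 400)
        df = pd.DataFrame(
            {"river": "R", "channel_class": "T<100m", "pco2_ppm": pco2,
             "ch4_nmol_l": 10.0**log_ch4}
        )
        fit = fg.fit_log_ch4_vs_pco2(df, "R", "T<100m")
        se_slope = noise_sd / math.sqrt(np.sum((pco2 - pco2.mean()) ** 2))
        assert abs(fit.slope - 8e-5) < 2 * se_slope

    def test_negative_coupling_sign_recovered(self):
        # a mainstem-like stratum generated with weak negative coupling: at
        # large n the fitted slope sign is reliably negative
        cfg = fg.MeasurementSimConfig(
            strata=(fg.StratumConfig("R", "MS", 3000, 4500.0, 1.5,
                                     -2e-5, 2.74, 0.35),),
            seed=2,
        )
        df = fg.generate_measurements(cfg)
        fit = fg.fit_log_ch4_vs_pco2(df, "R", "MS")
        assert fit.slope < 0

    def test_degenerate_pco2_raises(self):
        df = pd.DataFrame(
            {"river": "R", "channel_class": "MS",
             "pco2_ppm": [5000.0] * 4, "ch4_nmol_l": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="singular"):
            fg.fit_log_ch4_vs_pco2(df, "R", "MS")

    def test_too_few_records_raises(self, study_df):
        with pytest.raises(ValueError, match=">=3"):
            fg.fit_log_ch4_vs_pco2(study_df.head(2), "Amazon", "MS")


class TestComparisonReport:
    def test_reports_all_tests(self, study_df):
        report = class_comparison_report(study_df)
        assert set(report["test"]) == {"kruskal-wallis", "mann-whitney"}
        # 2 rivers x 2 gases KW + 3 classes x 2 gases pairwise MW
        assert (report["test"] == "kruskal-wallis").sum() == 4
        assert (report["test"] == "mann-whitney").sum() == 6
        assert report["p_value"].between(0, 1).all()
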