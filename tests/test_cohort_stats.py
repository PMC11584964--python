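"""Descriptive tables, cluster-robust mean, exact McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from periomesh import (
    bleeding_transitions,
    clustered_mean,
    describe,
    mcnemar_exact_p,
    summarize_cohort,
)
from periomesh.cohort_stats import naive_mean_ci
from periomesh.synthetic_scan import chart_to_frame, generate_cohort_chart


class TestDescribe:
    def test_basic_values(self):
        row = describe([1, 2, 3], "x")
        assert (row.n, row.mean, row.sd, row.median) == (3, 2.0, 1.0, 2.0)

    def test_quartiles_inclusive_interpolation(self):
        # brute-force oracle: sorted x, rank r = (n-1)q, linear interpolation
        x = np.arange(1.0, 9.0)

        def quartile(q):
            r = (len(x) - 1) * q
            lo = int(np.floor(r))
            return x[lo] + (r - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        row = describe(x, "x", decimals=3)
        assert row.p25 == pytest.approx(quartile(0.25)) == 2.75
        assert row.p75 == pytest.approx(quartile(0.75)) == 6.25

    def test_mean_linearity_of_difference(self):
        chart = chart_to_frame(generate_cohort_chart(12, 11, seed=4))
        d = describe((chart.pst1 - chart.pst0).to_numpy(), "d", decimals=9)
        m0 = np.mean(chart.pst0)
        m1 = np.mean(chart.pst1)
        assert d.mean == pytest.approx(m1 - m0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            describe([], "x")

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        perm = list(values)
        rnd.shuffle(perm)
        a = describe(values, "x", decimals=6)
        b = describe(perm, "x", decimals=6)
        assert a == b


class TestClusteredMean:
    def test_one_value_per_cluster_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        est = clustered_mean(x, np.arange(25))
        # brute-force formula: sqrt(sum((x - mean)^2)) / n
        se = np.sqrt(np.sum((x - x.mean()) ** 2)) / len(x)
        assert est.robust_se == pytest.approx(se, rel=1e-12)
        assert est.estimate == pytest.approx(x.mean())
        assert est.wald_chi2 == pytest.approx((est.estimate / est.robust_se) ** 2)
        lo, hi = est.ci95
        assert lo < est.estimate < hi

    def test_constant_data_flagged_degenerate(self):
        est = clustered_mean([2.0] * 10, [0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        assert est.degenerate
        assert est.ci95 == (2.0, 2.0)
        assert np.isnan(est.p_value)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            clustered_mean([1.0, 2.0], [0, 0])

    def test_matches_statsmodels_gee(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(12), 11)
        x = rng.normal(-0.34, 0.4, 132) + np.repeat(rng.normal(0, 0.3, 12), 11)
        mine = clustered_mean(x, groups)
        fit = sm.GEE(x, np.ones((len(x), 1)), groups=groups).fit()
        assert mine.estimate == pytest.approx(fit.params[0], rel=1e-10)
        assert mine.robust_se == pytest.approx(fit.bse[0], rel=1e-10)

    def test_clustering_inflates_se(self):
        """With patient effects the cluster-robust SE exceeds the naive SE in
        the clear majority of replicates; without them the two agree."""
        wins, ratio_nocluster = 0, []
        for rep in range(200):
            chart = chart_to_frame(generate_cohort_chart(
                12, 11, sd_between=0.3, seed=rep))
            d = (chart.pst1 - chart.pst0).to_numpy()
            est = clustered_mean(d, chart.patient_id.to_numpy())
            naive_se = np.std(d, ddof=1) / np.sqrt(len(d))
            wins += est.robust_se > naive_se

            chart0 = chart_to_frame(generate_cohort_chart(
                12, 11, sd_between=0.0, seed=10_000 + rep))
            d0 = (chart0.pst1 - chart0.pst0).to_numpy()
            est0 = clustered_mean(d0, chart0.patient_id.to_numpy())
            naive0 = np.std(d0, ddof=1) / np.sqrt(len(d0))
            ratio_nocluster.append(est0.robust_se / naive0)
        assert wins > 150  # one-sided sign test at p << 0.001
        assert abs(np.mean(ratio_nocluster) - 1.0) < 0.1


class TestMcNemar:
    def test_balanced_discordance_gives_one(self):
        assert mcnemar_exact_p(5, 5) == pytest.approx(1.0)
        assert mcnemar_exact_p(0, 0) == 1.0

    def test_brute_force_enumeration(self):
        from math import comb

        for n in range(1, 21):
            for b in range(n + 1):
                c = n - b
                k = min(b, c)
                tail = sum(comb(n, i) for i in range(k + 1)) / 2.0**n
                expected = min(1.0, 2.0 * tail)
                assert mcnemar_exact_p(b, c) == pytest.approx(expected, rel=1e-12)

    def test_matches_statsmodels_exact(self):
        mcnemar = pytest.importorskip(
            "statsmodels.stats.contingency_tables").mcnemar
        for b, c in [(52, 1), (5, 3), (0, 7), (10, 10)]:
            table = [[11, b], [c, 13]]
            assert mcnemar_exact_p(b, c) == pytest.approx(
                mcnemar(table, exact=True).pvalue, rel=1e-12)


class TestBleedingTransitions:
    def test_cohort_counts_and_prevalences(self):
        b0 = [True] * 97 + [False] * 34
        b1 = [True] * 45 + [False] * 52 + [True] * 1 + [False] * 33
        res = bleeding_transitions((b0, b1))
        assert (res.stayed, res.resolved, res.appeared, res.never) == (45, 52, 1, 33)
        assert res.prevalence0_pct == 74.0
        assert res.prevalence1_pct == 35.1
        assert res.resolved_pct == 39.7
        assert res.appeared_pct == 0.8
        assert res.mcnemar_p < 0.001

    def test_no_discordance(self):
        res = bleeding_transitions(([True, False], [True, False]))
        assert res.mcnemar_p == 1.0

    def test_record_interface(self):
        records = generate_cohort_chart(3, 5, seed=0)
        res = bleeding_transitions(records)
        assert res.n == 15
        assert res.stayed + res.resolved + res.appeared + res.never == res.n


class TestSummarizeCohort:
    def test_summary_table_shape(self):
        chart = chart_to_frame(generate_cohort_chart(12, 11, seed=1))
        import pandas as pd

        meas = pd.DataFrame({
            "patient_id": chart.patient_id,
            "tooth_id": chart.tooth_id,
            "height_loss": np.abs(np.random.default_rng(0).normal(0.2, 0.1, 132)),
            "width_loss": np.abs(np.random.default_rng(1).normal(0.34, 0.2, 132)),
            "status": "ok",
        })
        s = summarize_cohort(chart, meas)
        assert set(s.rows) == {"pst0", "pst1", "diff", "height_loss", "width_loss"}
        for label, row in s.rows.items():
            assert row.min <= row.p25 <= row.median <= row.p75 <= row.max
            est = s.estimates[label]
            assert est.ci95[0] <= row.mean + 0.01
            assert est.ci95[1] >= row.mean - 0.01
        assert s.bleeding is not None
        assert s.bleeding.n == 132
        frame = s.to_frame()
        assert len(frame) == 5
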