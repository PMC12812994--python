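"""Disproportionality statistics against independent formula oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from faersig.signals import (
    ContingencyTable,
    DegenerateTableError,
    GPSHyperparams,
    SignalCriteria,
    SignalStats,
    bcpnn_ic,
    build_contingency,
    ebgm_stat,
    evaluate_signal,
    gps_fit,
    naive_ic,
    prr_chi2,
    rank_tables,
    ror_stat,
    signal_table,
)
from tests.conftest import random_tables

cells = st.integers(min_value=1, max_value=500)
pos_table = st.tuples(cells, cells, cells, cells).map(lambda t: ContingencyTable(*t))


class TestROR:
    def test_direct_formula_example(self):
        # independent oracle: ror = ad/bc; CI = exp(ln ror +/- 1.96 sqrt(sum 1/cell))
        ror, low, high = ror_stat(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert low == pytest.approx(math.exp(math.log(11.0) - 1.959963984540054 * se))
        assert (low, high) == (pytest.approx(5.56, abs=0.01), pytest.approx(21.76, abs=0.01))

    def test_balanced_table_is_symmetric_about_one(self):
        ror, low, high = ror_stat(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert low * high == pytest.approx(1.0)  # symmetric on the log scale

    def test_doubling_cells_preserves_ror_and_narrows_ci(self):
        r1 = ror_stat(ContingencyTable(10, 90, 100, 9900))
        r2 = ror_stat(ContingencyTable(20, 180, 200, 19800))
        assert r2[0] == pytest.approx(r1[0])
        assert r2[2] - r2[1] < r1[2] - r1[1]

    def test_zero_cell_continuity_policy(self):
        # Haldane-Anscombe: all four cells get +0.5
        ror, low, high = ror_stat(ContingencyTable(1, 0, 1, 0))
        assert ror == pytest.approx((1.5 * 0.5) / (0.5 * 1.5))
        with pytest.raises(DegenerateTableError):
            ror_stat(ContingencyTable(1, 0, 1, 0), zero_correction=False)

    @settings(max_examples=100, deadline=None)
    @given(pos_table)
    def test_ror_prr_algebraic_identity(self, t):
        ror = ror_stat(t)[0]
        prr = prr_chi2(t)[0]
        expected_ratio = (t.d / (t.c + t.d)) / (t.b / (t.a + t.b))
        assert ror / prr == pytest.approx(expected_ratio, rel=1e-10)


class TestPRRChi2:
    def test_direct_formula_example(self):
        prr, _ = prr_chi2(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)

    def test_equal_proportions_give_null(self):
        prr, chi2 = prr_chi2(ContingencyTable(10, 90, 20, 180))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_chi2_matches_scipy_on_random_tables(self):
        for a, b, c, d in random_tables(seed=2, n=200):
            _, chi2 = prr_chi2(ContingencyTable(a, b, c, d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=True)[0]
            assert chi2 == pytest.approx(ref, rel=1e-10, abs=1e-12)


class TestBCPNN:
    def test_bate_closed_form_regression_value(self):
        # hand-evaluated from the published closed-form expressions
        ic, ic025 = bcpnn_ic(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(2.382489, abs=1e-5)
        assert ic025 < ic

    def test_prior_pseudocounts_to_zero_recovers_naive_ic(self):
        for a, b, c, d in random_tables(seed=3, n=50):
            t = ContingencyTable(a, b, c, d)
            ic, _ = bcpnn_ic(t, prior_scale=1e-9)
            assert ic == pytest.approx(naive_ic(t), abs=1e-5)

    def test_independence_table_gives_zero_ic_negative_ic025(self):
        ic, ic025 = bcpnn_ic(ContingencyTable(50, 50, 50, 50))
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 < 0

    @settings(max_examples=200, deadline=None)
    @given(pos_table)
    def test_ic025_below_ic(self, t):
        ic, ic025 = bcpnn_ic(t)
        assert ic025 < ic


@pytest.fixture(scope="module")
def fitted_gps():
    """Hyperparameters fitted on a synthetic cell universe with signals."""
    rng = np.random.default_rng(42)
    e = rng.uniform(0.5, 50, size=400)
    lam = np.where(rng.random(400) < 0.1, rng.gamma(2.0, 2.0, 400), 1.0)
    a = rng.poisson(lam * e)
    return a, e, gps_fit(a, e)


class TestGPS:
    def test_single_gamma_recovery(self):
        # lambda ~ Gamma(shape 2, rate 4); the dominant fitted component
        # should recover (2, 4) within 20% at 5,000 cells
        rng = np.random.default_rng(1)
        e = rng.uniform(1, 40, size=5000)
        lam = rng.gamma(2.0, 1.0 / 4.0, size=5000)
        a = rng.poisson(lam * e)
        h = gps_fit(a, e)
        comps = [(h.alpha1, h.beta1, h.mix_weight), (h.alpha2, h.beta2, 1 - h.mix_weight)]
        alpha, beta, w = max(comps, key=lambda c: c[2])
        assert w > 0.8
        assert alpha == pytest.approx(2.0, rel=0.2)
        assert beta == pytest.approx(4.0, rel=0.2)

    def test_no_signal_data_concentrates_near_unit_lambda(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(1, 40, size=2000)
        a = np.round(e)  # observed equals expected everywhere
        h = gps_fit(a, e)
        ebgm, _ = ebgm_stat(ContingencyTable(20, 180, 200, 19800), h)  # E = 2.0, a = 20? no: use a=E cell
        # prior mean of the fitted mixture should be close to 1
        prior_mean = h.mix_weight * h.alpha1 / h.beta1 + (1 - h.mix_weight) * h.alpha2 / h.beta2
        assert prior_mean == pytest.approx(1.0, abs=0.15)

    def test_cell_order_does_not_change_fit(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(1, 20, size=300)
        a = rng.poisson(e)
        h1 = gps_fit(a, e)
        perm = rng.permutation(300)
        h2 = gps_fit(a[perm], e[perm])
        assert h1.loglik == pytest.approx(h2.loglik, rel=1e-6)
        assert h1.alpha1 == pytest.approx(h2.alpha1, rel=1e-3)

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            gps_fit([1, 2], [1.0])


class TestEBGM:
    def test_observed_equals_expected_with_diffuse_prior_is_null(self):
        h = GPSHyperparams(2.0, 2.0, 2.0, 2.0, 0.5)  # prior mean 1
        t = ContingencyTable(50, 450, 450, 4050)  # E = 500*500/5000 = 50 = a
        assert t.expected == pytest.approx(t.a)
        ebgm, eb05 = ebgm_stat(t, h)
        assert ebgm == pytest.approx(1.0, abs=0.1)
        assert eb05 < ebgm

    def test_eb05_below_ebgm_on_random_tables(self, fitted_gps):
        _, _, h = fitted_gps
        for a, b, c, d in random_tables(seed=4, n=500):
            ebgm, eb05 = ebgm_stat(ContingencyTable(a, b, c, d), h)
            assert eb05 < ebgm

    def test_quantile_matches_quadrature_oracle(self, fitted_gps):
        # independent oracle: integrate the posterior mixture density and
        # root-find the 5th percentile
        _, _, h = fitted_gps
        for a, b, c, d in random_tables(seed=5, n=10):
            t = ContingencyTable(a, b, c, d)
            e = t.expected
            _, eb05 = ebgm_stat(t, h)
            lp1 = math.log(h.mix_weight) + stats.nbinom.logpmf(t.a, h.alpha1, h.beta1 / (h.beta1 + e))
            lp2 = math.log1p(-h.mix_weight) + stats.nbinom.logpmf(t.a, h.alpha2, h.beta2 / (h.beta2 + e))
            q1 = math.exp(lp1 - np.logaddexp(lp1, lp2))

            def pdf(x):
                return q1 * stats.gamma.pdf(x, h.alpha1 + t.a, scale=1 / (h.beta1 + e)) + (
                    1 - q1
                ) * stats.gamma.pdf(x, h.alpha2 + t.a, scale=1 / (h.beta2 + e))

            def cdf(x):
                return integrate.quad(pdf, 0, x, limit=200)[0]

            oracle = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-9, eb05 * 10, xtol=1e-10)
            assert eb05 == pytest.approx(oracle, abs=1e-6)

    def test_rare_cell_spike_is_shrunk_toward_one(self, fitted_gps):
        # a single report against a tiny expectation: the raw ratio a/E is
        # huge, the empirical-Bayes estimate pulls it strongly toward 1
        _, _, h = fitted_gps
        t = ContingencyTable(1, 9, 40, 39950)  # E ~ 0.01, a/E ~ 100
        ebgm, _ = ebgm_stat(t, h)
        assert 1 < ebgm < t.a / t.expected / 10

    @settings(max_examples=100, deadline=None)
    @given(pos_table)
    def test_log_ebgm_bounded_by_log_observed_ratio_plus_prior_offset(self, t):
        # |ln EBGM| <= |ln(a/E)| + |ln(prior mean)| + slack: shrinkage never
        # overshoots past the prior
        h = GPSHyperparams(0.5, 0.25, 4.0, 4.0, 0.3)
        ebgm, _ = ebgm_stat(t, h)
        prior_mean = h.mix_weight * h.alpha1 / h.beta1 + (1 - h.mix_weight) * h.alpha2 / h.beta2
        offset = abs(math.log(prior_mean)) + 1.0
        assert abs(math.log(ebgm)) <= abs(math.log(t.a / t.expected)) + offset


class TestMonotonicityAndInvariance:
    def test_increasing_a_with_fixed_margins_increases_all_statistics(self, fitted_gps):
        _, _, h = fitted_gps
        prev = None
        for a in (10, 20, 30, 40):
            delta = a - 10
            t = ContingencyTable(a, 100 - a, 300 - delta, 10000 + delta)
            cur = (
                ror_stat(t)[0],
                prr_chi2(t)[0],
                bcpnn_ic(t)[0],
                ebgm_stat(t, h)[0],
            )
            if prev is not None:
                assert all(c > p for c, p in zip(cur, prev))
            prev = cur

    def test_relabeling_background_drugs_leaves_target_stats_unchanged(self, small_events):
        events, _ = small_events
        renamed = events.copy()
        renamed["drug"] = renamed["drug"].replace(
            {f"backgrounddrug{i:02d}": f"otherdrug{i}" for i in range(1, 21)}
        )
        targets = ["bortezomib", "carfilzomib", "ixazomib"]
        t1 = signal_table(events, drugs=targets).reset_index(drop=True)
        t2 = signal_table(renamed, drugs=targets).reset_index(drop=True)
        for col in ("a", "ror", "prr", "chi2", "ic", "ic025"):
            assert np.allclose(t1[col], t2[col])


class TestSignalCriterion:
    def _stats(self, **kw):
        base = dict(
            drug="d", pt="p", n_reports=10, ror=3.0, ror_ci=(1.5, 6.0), prr=3.0, chi2=10.0,
            ic=1.0, ic025=0.5, ebgm=3.0, eb05=2.5, is_signal=False,
        )
        base.update(kw)
        return SignalStats(**base)

    def test_null_statistics_are_not_a_signal(self):
        s = self._stats(ror=1.0, ror_ci=(0.5, 2.0), prr=1.0, chi2=0.1, ic025=-0.5, eb05=0.8)
        assert not evaluate_signal(s)

    def test_count_floor_blocks_huge_ror(self):
        s = self._stats(n_reports=2, ror=100.0, ror_ci=(20.0, 500.0))
        assert not evaluate_signal(s)

    def test_all_criteria_met_is_a_signal(self):
        assert evaluate_signal(self._stats())

    def test_thresholds_configurable(self):
        s = self._stats(eb05=1.5)
        assert not evaluate_signal(s)
        assert evaluate_signal(s, SignalCriteria(eb05_min=1.0))

    def test_concordant_set_is_subset_of_each_single_criterion(self, small_events):
        events, _ = small_events
        table = signal_table(events)
        for col in ("sig_ror", "sig_prr", "sig_ic", "sig_ebgm"):
            assert (table.loc[table["is_signal"], col]).all()


@pytest.fixture(scope="module")
def table(small_events):
    events, _ = small_events
    return signal_table(events, drugs=["bortezomib", "carfilzomib", "ixazomib"])


class TestRanking:

    def test_k_larger_than_list_returns_all(self, table):
        n_sig = int(table["is_signal"].sum())
        assert len(rank_tables(table, "frequency", k=10_000)) == n_sig

    def test_frequency_ranking_sorted_by_count(self, table):
        ranked = rank_tables(table, "frequency", k=5)
        assert list(ranked["a"]) == sorted(ranked["a"], reverse=True)

    def test_ror_ranking_sorted_by_ror(self, table):
        ranked = rank_tables(table, "ror", k=5)
        assert list(ranked["ror"]) == sorted(ranked["ror"], reverse=True)

    def test_frequency_ranking_ignores_statistic_values(self, table):
        jittered = table.copy()
        jittered["ror"] = 1.0  # frequency order must not depend on ror values
        a = rank_tables(table, "frequency", k=3)[["drug", "pt"]]
        b = rank_tables(jittered, "frequency", k=3)[["drug", "pt"]]
        assert a.equals(b)

    def test_nonpositive_k_rejected(self, table):
        with pytest.raises(ValueError):
            rank_tables(table, "frequency", k=0)


class TestBuildContingency:
    def test_two_report_universe_boundary(self, small_events):
        import pandas as pd

        events = pd.DataFrame(
            {
                "case_id": ["C1", "C2"],
                "drug": ["bortezomib", "other"],
                "pt": ["Nausea", "Nausea"],
                "soc": [None, None],
                "sex": ["female", "male"],
            }
        )
        t = build_contingency(events, "bortezomib", "Nausea")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 1, 0)
        ror, low, high = ror_stat(t)  # degenerate cells handled by continuity
        assert np.isfinite([ror, low, high]).all()

    def test_a_plus_b_equals_drug_pair_total(self, small_events):
        events, truth = small_events
        t = build_contingency(events, "bortezomib", "Neuropathy peripheral")
        assert t.a + t.b == sum(truth.pair_case_counts["bortezomib"].values())
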