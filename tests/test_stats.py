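"""Edgewise mixed-effects model, BY-FDR, effect sizes and power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sleepconn import stats, synth


def brute_force_by(p):
    """Independent step-up oracle for Benjamini-Yekutieli q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        val = min(prev, m * c_m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(val, 1.0)
        prev = val
    q = np.empty(m)
    q[order] = q_sorted
    return q


def mixed_dataset(seed=3, n_part=12, runs_per=4, sigma_u=0.08, sigma_e=0.1,
                  beta_state=0.05):
    rng = np.random.default_rng(seed)
    rows, ys = [], []
    for i in range(n_part):
        u = rng.normal(0, sigma_u)
        for k in range(runs_per):
            state = k % 2
            rows.append({"participant": f"p{i:02d}", "state": state,
                         "pma_weeks": 45 + rng.normal(), "sex": i % 2,
                         "mean_fd": 0.03 + 0.01 * rng.random()})
            ys.append(0.3 + beta_state * state + u + rng.normal(0, sigma_e))
    return np.array(ys), pd.DataFrame(rows)


class TestEdgeLme:
    def test_one_run_per_participant_equals_two_sample_t(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 24) + 0.3 * (np.arange(24) % 2)
        design = pd.DataFrame({"participant": [f"p{i}" for i in range(24)],
                               "state": np.arange(24) % 2})
        beta, se, t, df, p = stats.fit_edge_lme(y, design)
        ref = sps.ttest_ind(y[design.state == 1], y[design.state == 0])
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)
        assert df == 22

    def test_matches_statsmodels_reml(self):
        import statsmodels.api as sm

        y, design = mixed_dataset()
        beta, se, t, df, p = stats.fit_edge_lme(y, design)
        X = np.column_stack([np.ones(len(y)), design["state"]])
        ref = sm.MixedLM(y, X, groups=design["participant"]).fit(reml=True)
        assert beta == pytest.approx(ref.params[1], abs=1e-4)
        assert se == pytest.approx(ref.bse[1], rel=1e-3)
        # between-within df: n_obs - n_participants - 1
        assert df == 48 - 12 - 1

    def test_adjusted_model_matches_statsmodels(self):
        import statsmodels.api as sm

        y, design = mixed_dataset(seed=9)
        beta, se, t, df, p = stats.fit_edge_lme(y, design, adjust=True)
        X = np.column_stack([np.ones(len(y)), design["state"], design["pma_weeks"],
                             design["sex"], design["mean_fd"]])
        ref = sm.MixedLM(y, X, groups=design["participant"]).fit(reml=True)
        assert beta == pytest.approx(ref.params[1], abs=1e-3)
        assert se == pytest.approx(ref.bse[1], rel=5e-3)
        assert df == 48 - 12 - 4

    def test_null_type_one_error_rate(self):
        """Seeded null simulation: rejection rate at alpha=0.05 stays within
        the binomial band."""
        rng = np.random.default_rng(17)
        n_part, runs_per, reps = 10, 4, 600
        rows = []
        for i in range(n_part):
            for k in range(runs_per):
                rows.append({"participant": f"p{i}", "state": k % 2})
        design = pd.DataFrame(rows)
        n = len(design)
        u = rng.normal(0, 0.08, (n_part, reps))
        Y = np.repeat(u, runs_per, axis=0) + rng.normal(0, 0.1, (n, reps))
        res = stats._fit_many(Y, design, adjust=False)
        rate = np.mean(res["p"] < 0.05)
        ci = 2.58 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < ci + 0.005

    def test_all_one_state_rejected(self):
        y = np.zeros(6)
        design = pd.DataFrame({"participant": list("aabbcc"), "state": [1] * 6})
        with pytest.raises(ValueError, match="one sleep state"):
            stats.fit_edge_lme(y, design)

    def test_single_participant_rejected(self):
        design = pd.DataFrame({"participant": ["a"] * 6, "state": [0, 1] * 3})
        with pytest.raises(ValueError, match="participants"):
            stats.fit_edge_lme(np.zeros(6), design)


class TestEdgewiseAnalysis:
    def test_edge_count_and_columns(self, study_edges):
        Z, design = study_edges
        es = stats.edgewise_analysis(Z, design)
        assert es.n_edges == 45  # 10 nodes
        for col in ("beta", "se", "t", "df", "p", "q_by", "cohens_d"):
            assert col in es.table.columns
        assert np.all(es.table.q_by >= es.table.p - 1e-12)

    def test_duplicated_edges_identical_rows(self, study_edges):
        Z, design = study_edges
        Zdup = np.tile(Z[:, :1], (1, 5))
        es = stats.edgewise_analysis(Zdup, design)
        for col in ("beta", "se", "t", "df", "p"):
            assert es.table[col].nunique() == 1

    def test_design_alignment_checked(self, study_edges):
        Z, design = study_edges
        with pytest.raises(ValueError):
            stats.edgewise_analysis(Z[:-1], design)


class TestByFdr:
    def test_worked_triplet(self):
        q = stats.by_fdr(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.055, 0.055, 0.055])

    def test_single_p_unchanged(self):
        assert stats.by_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
           st.integers(0, 10 ** 6))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle_and_dominates_bh(self, ps, _seed):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(ps)
        q = stats.by_fdr(p)
        np.testing.assert_allclose(q, brute_force_by(p), atol=1e-12)
        q_bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(q >= q_bh - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.by_fdr(np.array([0.5, 1.2]))


class TestCohensD:
    def test_spot_values(self):
        assert stats.t_to_cohens_d(0.0, 10.0) == 0.0
        assert stats.t_to_cohens_d(2.0, 16.0) == pytest.approx(1.0)

    def test_sign_follows_t(self):
        t = np.array([-2.0, -0.1, 0.0, 0.1, 2.0])
        d = stats.t_to_cohens_d(t, 16.0)
        assert np.array_equal(np.sign(d), np.sign(t))

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            stats.t_to_cohens_d(1.0, 0.0)


class TestEffectSizeSummary:
    def test_bin_boundaries(self):
        s = stats.effect_size_summary(np.array([0.6]))
        assert s.frac_medium == 1.0
        s = stats.effect_size_summary(np.array([0.8]))
        assert s.frac_large == 1.0  # boundary inclusive
        s = stats.effect_size_summary(np.array([0.2, -0.49999]))
        assert s.frac_small == 1.0

    def test_fractions_sum_to_one(self):
        d = np.random.default_rng(0).normal(0, 0.5, 500)
        s = stats.effect_size_summary(d)
        total = s.frac_negligible + s.frac_small + s.frac_medium + s.frac_large
        assert total == pytest.approx(1.0)

    def test_symmetric_input_balanced_means(self):
        d = np.array([0.3, -0.3, 0.9, -0.9])
        s = stats.effect_size_summary(d)
        assert s.mean_abs_d_as_greater == pytest.approx(s.mean_abs_d_qs_greater)


class TestPower:
    def test_single_test_benchmark(self):
        assert stats.power_analysis(d=0.8, m_tests=1) == 50
        assert stats.power_analysis(d=0.8, m_tests=1, method="t") == 52

    def test_monotone_in_test_count(self):
        ns = [stats.power_analysis(d=0.8, m_tests=m) for m in (1, 10, 137, 1000)]
        assert ns == sorted(ns)
        assert ns[0] < ns[-1]

    def test_bonferroni_denominator_cross_check(self):
        from statsmodels.stats.power import NormalIndPower

        total = stats.power_analysis(d=0.8, m_tests=137)
        n_per = NormalIndPower().solve_power(effect_size=0.8, alpha=0.05 / 137,
                                             power=0.8, ratio=1.0,
                                             alternative="two-sided")
        assert total == 2 * int(np.ceil(n_per - 1e-9))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stats.power_analysis(power=1.2)
        with pytest.raises(ValueError):
            stats.power_analysis(m_tests=0)
        with pytest.raises(ValueError):
            stats.power_analysis(d=-0.5)


class TestCalibration:
    def test_calibrated_effect_recovered(self):
        edges = (0, 7, 20)
        delta = stats.calibrate_delta_z(0.8, 40, 40, 20, ols_df=False)
        eff = synth.EffectMap(edges, delta, target_cohens_d=0.8)
        dhats = []
        for seed in range(6):
            Z, design = synth.simulate_study_connectomes(
                n_infants=20, n_runs=80, n_qs_runs=40, n_qs_infants=20,
                n_nodes=10, effect=eff, seed=500 + seed)
            es = stats.edgewise_analysis(Z, design)
            dhats.append(es.table.cohens_d.to_numpy()[list(edges)].mean())
        assert np.mean(dhats) == pytest.approx(0.8, abs=0.2)
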