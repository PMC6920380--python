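"""Group statistics: paired t, ANOVA, Holm–Sidak, reporting conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurorestore import stats, synth
from neurorestore.stats import ZeroVarianceError


def paired_t_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * sps.t.sf(abs(t), n - 1)


def anova_oracle(groups):
    """Explicit sum-of-squares decomposition."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, sps.f.sf(f, df_b, df_w)


def holm_sidak_oracle(pvals, alpha=0.05):
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, 1 - (1 - p[idx]) ** (m - rank))
        adj[idx] = min(running, 1.0)
    return adj


class TestPairedT:
    def test_worked_example(self):
        res = stats.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])  # diffs 1,2,3
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-4)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            stats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self):
        a, b = [2.0, 4.0, 7.0], [1.0, 5.0, 3.0]
        r1, r2 = stats.paired_t(a, b), stats.paired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova:
    def test_identical_means_give_f_zero(self):
        res = stats.one_way_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_worked_example_against_ss_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]
        res = stats.one_way_anova(groups)
        f, p = anova_oracle(groups)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_group_order_exchangeable(self):
        groups = [[1.0, 2.0], [4.0, 5.0], [2.0, 8.0]]
        r1 = stats.one_way_anova(groups)
        r2 = stats.one_way_anova(groups[::-1])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_all_identical_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            stats.one_way_anova([[2.0, 2.0], [2.0, 2.0]])


class TestHolmSidak:
    def test_single_p_unchanged(self):
        res = stats.holm_sidak([0.03])
        assert res.adjusted == (0.03,)

    def test_worked_example_with_monotonicity(self):
        res = stats.holm_sidak([0.01, 0.04, 0.03])
        assert res.adjusted[0] == pytest.approx(1 - 0.99**3)      # 0.029701
        assert res.adjusted[1] == pytest.approx(1 - 0.97**2)      # 0.0591
        assert res.adjusted[2] == pytest.approx(1 - 0.97**2)      # raised to 0.0591
        assert res.reject == (True, False, False)

    def test_all_zero(self):
        assert stats.holm_sidak([0.0, 0.0, 0.0]).adjusted == (0.0, 0.0, 0.0)

    def test_ordering_invariance_and_dominance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=8)
        res = stats.holm_sidak(p)
        perm = rng.permutation(8)
        res_perm = stats.holm_sidak(p[perm])
        assert np.allclose(np.asarray(res_perm.adjusted), np.asarray(res.adjusted)[perm])
        assert np.all(np.asarray(res.adjusted) >= np.asarray(res.raw))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(2, 9)))
            mine = stats.holm_sidak(p)
            _, adj, _, _ = multipletests(p, alpha=0.05, method="holm-sidak")
            assert np.allclose(mine.adjusted, adj, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_sidak([0.5, 1.5])


class TestReportingConversions:
    def test_percent_injected_truncation(self):
        assert stats.pct_injected_per_gram(29.05, 400.0) == 7.2
        assert stats.pct_injected_per_gram(35.07, 400.0) == 8.7
        # truncation, not rounding: 7.2625 -> 7.2 even though it rounds to 7.3
        assert stats.pct_injected_per_gram(29.05, 400.0, truncate=False) == 7.3

    def test_zero_concentration(self):
        assert stats.pct_injected_per_gram(0.0, 400.0) == 0.0

    def test_nonpositive_injected_rejected(self):
        with pytest.raises(ValueError):
            stats.pct_injected_per_gram(10.0, 0.0)

    def test_bdnf_per_total_protein(self):
        assert stats.bdnf_per_total_protein(50.0, 2.0) == 25.0
        assert stats.bdnf_per_total_protein(49.91, 1.0) == 49.91
        with pytest.raises(ValueError):
            stats.bdnf_per_total_protein(10.0, 0.0)


class TestOracleGrid:
    def test_paired_t_and_anova_match_brute_force(self):
        """100 random small datasets: agreement with explicit-formula oracles."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a, b = rng.normal(size=n), rng.normal(size=n)
            res = stats.paired_t(a, b)
            t, p = paired_t_oracle(a, b)
            assert res.statistic == pytest.approx(t, rel=1e-10, abs=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10, abs=1e-10)

            groups = [rng.normal(size=int(rng.integers(3, 9))) for _ in range(3)]
            ra = stats.one_way_anova(groups)
            f, pf = anova_oracle(groups)
            assert ra.statistic == pytest.approx(f, rel=1e-10)
            assert ra.p == pytest.approx(pf, rel=1e-10, abs=1e-12)

    def test_holm_sidak_matches_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 10)))
            assert np.allclose(
                stats.holm_sidak(p).adjusted, holm_sidak_oracle(p), atol=1e-12
            )


def mouse_table(effect=1.2, seed=7, **kw):
    df = synth.gen_group_study(effect=effect, seed=seed, **kw)
    return stats.summarize_mice(df)


class TestGroupAnalysis:
    def test_null_table_flagged_degenerate(self):
        rows = [
            {"mouse": f"m{i}{g}", "group": g, "region": "striatum",
             "ipsi_mean": 0.2, "contra_mean": 0.2, "ratio": 1.0}
            for g in ("A", "B") for i in range(3)
        ]
        res = stats.group_analysis(pd.DataFrame(rows))["striatum"]
        assert all(t.degenerate for t in res.paired.values())
        assert res.anova.degenerate
        assert all(t.degenerate for t in res.pairwise.values())

    def test_treated_effect_detected_controls_not(self):
        res = stats.group_analysis(mouse_table())["striatum"]
        assert res.paired["IN+FUS"].significant
        assert not res.paired["MPTP"].significant
        assert not res.paired["FUS"].significant
        assert res.anova.significant
        assert res.pairwise[("IN+FUS", "MPTP")].significant
        assert res.pairwise[("FUS", "IN+FUS")].significant
        assert not res.pairwise[("FUS", "MPTP")].significant

    def test_treated_ratio_near_effect(self):
        res = stats.group_analysis(mouse_table())["striatum"]
        assert res.group_means["IN+FUS"] == pytest.approx(1.2, abs=0.03)
        assert res.group_means["MPTP"] == pytest.approx(1.0, abs=0.03)

    def test_grubbs_removal_is_local(self):
        """Removing a flagged outlier changes that group's paired test only."""
        table = mouse_table()
        table = table.copy()
        # plant a gross outlier ratio in the MPTP group
        idx = table.index[table["group"] == "MPTP"][0]
        table.loc[idx, ["ipsi_mean", "ratio"]] = [
            table.loc[idx, "contra_mean"] * 3.0, 3.0,
        ]
        plain = stats.group_analysis(table)["striatum"]
        screened = stats.group_analysis(table, grubbs_alpha=0.05)["striatum"]
        assert screened.removed == {"MPTP": str(table.loc[idx, "mouse"])}
        assert screened.paired["MPTP"].p != plain.paired["MPTP"].p
        for g in ("FUS", "IN+FUS"):
            assert screened.paired[g].p == plain.paired[g].p

    def test_mouse_in_two_groups_rejected(self):
        rows = [
            {"mouse": "m1", "group": g, "region": "striatum",
             "ipsi_mean": 0.2, "contra_mean": 0.2, "ratio": 1.0}
            for g in ("A", "B")
        ] * 2
        with pytest.raises(ValueError, match="exactly one group"):
            stats.group_analysis(pd.DataFrame(rows))

    def test_type_one_error_rate_under_null(self):
        """Paired test on a null group rejects at ~alpha over 200 replicates."""
        alpha = 0.05
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            table = mouse_table(effect=1.0, seed=10_000 + rep)
            res = stats.group_analysis(table, alpha=alpha)["striatum"]
            hits += res.paired["MPTP"].significant
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 2 * se
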