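"""Group summaries, ratio statistics, Welch test, Holm adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import stripequant as sq
from stripequant.stats import GroupSummary

PRINTED_PCT = [74.2, 88.2, 60.8, 27.5, 49.6, 70.0, 40.7]
PRINTED_PCT_SD = [41.1, 43.4, 27.4, 18.5, 27.2, 43.1, 42.2]
PRINTED_P = [0.238, 0.564, 0.0546, 0.00251, 0.024, 0.203, 0.0317]
PRINTED_P_ADJ = [0.609, 0.609, 0.218, 0.0176, 0.144, 0.609, 0.159]


def summaries_by_stripe():
    summ = sq.zebra_deletion_summaries()
    wt = summ[summ.genotype == sq.WILDTYPE].set_index("stripe")
    mut = summ[summ.genotype == sq.MUTANT].set_index("stripe")
    for stripe in range(1, 8):
        w, m = wt.loc[stripe], mut.loc[stripe]
        yield (
            GroupSummary(stripe, sq.WILDTYPE, int(w.n), float(w["mean"]), float(w.sd)),
            GroupSummary(stripe, sq.MUTANT, int(m.n), float(m["mean"]), float(m.sd)),
        )


def exact_sample(mean, sd, n, rng):
    """n values with exactly the requested sample mean and SD."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestSummaries:
    def test_hand_calculation(self):
        table = pd.DataFrame(
            {
                "embryo_id": ["a", "b"],
                "genotype": ["wt", "wt"],
                "stripe": [1, 1],
                "integration": [10.0, 20.0],
            }
        )
        (s,) = sq.summarize_groups(table)
        assert s.mean == 15.0
        assert s.sd == pytest.approx(7.0711, abs=1e-4)

    def test_zero_sd_cohort(self):
        spec = sq.CohortSpec(
            groups=[sq.GroupLevels(genotype="wt", n=5, mean=[3.0], sd=[0.0])]
        )
        (s,) = sq.summarize_groups(sq.generate_cohort(spec))
        assert s.sd == 0.0

    def test_simulation_recovers_group_mean(self):
        spec = sq.CohortSpec(
            groups=[sq.GroupLevels(genotype="wt", n=10_000, mean=[157.0], sd=[55.5])],
            seed=9,
        )
        (s,) = sq.summarize_groups(sq.generate_cohort(spec))
        assert s.mean == pytest.approx(157.0, rel=0.02)

    def test_single_embryo_rejected(self):
        table = pd.DataFrame(
            {"embryo_id": ["a"], "genotype": ["wt"], "stripe": [1], "integration": [1.0]}
        )
        with pytest.raises(sq.StatsError):
            sq.summarize_groups(table)


class TestPercentOfWildtype:
    @pytest.mark.parametrize(
        "wt,mut,pct,pct_sd",
        [
            ((58.6, 20.6), (16.1, 9.22), 27.5, 18.5),  # headline stripe 4
            ((63.9, 23.6), (47.4, 19.6), 74.2, 41.1),  # stripe 1
        ],
    )
    def test_published_rows_reproduced(self, wt, mut, pct, pct_sd):
        w = GroupSummary(1, "wt", 6, *wt)
        m = GroupSummary(1, "mut", 5, *mut)
        got_pct, got_sd = sq.percent_of_wildtype(w, m)
        assert got_pct == pytest.approx(pct, abs=0.05)
        assert got_sd == pytest.approx(pct_sd, abs=0.05)

    def test_identical_groups_give_100(self):
        s = GroupSummary(1, "wt", 6, 50.0, 0.0)
        m = GroupSummary(1, "mut", 6, 50.0, 0.0)
        assert sq.percent_of_wildtype(s, m) == (100.0, 0.0)

    def test_zero_wildtype_mean_rejected(self):
        with pytest.raises(sq.StatsError):
            sq.percent_of_wildtype(
                GroupSummary(1, "wt", 6, 0.0, 1.0), GroupSummary(1, "mut", 5, 1.0, 1.0)
            )

    def test_propagated_sd_matches_monte_carlo(self):
        # the first-order ratio propagation must agree with the SD of
        # Monte-Carlo ratios of resampled group means (CVs of the means
        # are ~0.14 and ~0.22 here, well inside the small-CV regime)
        rng = np.random.default_rng(5)
        sem_wt, sem_mut = 20.6 / np.sqrt(6), 8.0 / np.sqrt(5)
        wt = GroupSummary(1, "wt", 6, 58.6, sem_wt)
        mut = GroupSummary(1, "mut", 5, 16.1, sem_mut)
        _, pct_sd = sq.percent_of_wildtype(wt, mut)
        ratios = 100 * rng.normal(16.1, sem_mut, 200_000) / rng.normal(
            58.6, sem_wt, 200_000
        )
        assert pct_sd == pytest.approx(np.std(ratios), rel=0.05)


class TestWelch:
    @pytest.mark.parametrize("wt,mut", list(summaries_by_stripe()))
    def test_matches_scipy_oracle(self, wt, mut):
        t, df, p = sq.welch_t_test(wt, mut)
        oracle = sps.ttest_ind_from_stats(
            wt.mean, wt.sd, wt.n, mut.mean, mut.sd, mut.n, equal_var=False
        )
        assert t == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-12)

    def test_published_raw_p_reproduced(self):
        got = [sq.welch_t_test(w, m)[2] for w, m in summaries_by_stripe()]
        np.testing.assert_allclose(got, PRINTED_P, rtol=0.01)

    def test_identical_summaries(self):
        s = GroupSummary(1, "wt", 6, 10.0, 2.0)
        m = GroupSummary(1, "mut", 6, 10.0, 2.0)
        t, _, p = sq.welch_t_test(s, m)
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance(self):
        s = GroupSummary(1, "wt", 6, 10.0, 0.0)
        assert sq.welch_t_test(s, GroupSummary(1, "mut", 5, 10.0, 0.0))[2] == 1.0
        with pytest.raises(sq.StatsError, match="degenerate"):
            sq.welch_t_test(s, GroupSummary(1, "mut", 5, 11.0, 0.0))

    def test_agrees_with_permutation_test(self):
        # difference-of-means permutation oracle on one simulated cohort
        rng = np.random.default_rng(17)
        a = rng.normal(58.6, 20.6, 6)
        b = rng.normal(34.1, 13.4, 5)
        wt = GroupSummary(1, "wt", 6, a.mean(), a.std(ddof=1))
        mut = GroupSummary(1, "mut", 5, b.mean(), b.std(ddof=1))
        _, _, p_welch = sq.welch_t_test(wt, mut)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        for _ in range(10_000):
            perm = rng.permutation(pooled)
            count += abs(perm[:6].mean() - perm[6:].mean()) >= observed
        assert p_welch == pytest.approx(count / 10_000, abs=0.02)


class TestHolm:
    def test_published_adjusted_column_reproduced(self):
        adj = sq.holm_adjust(PRINTED_P)
        printed = ["0.609", "0.609", "0.218", "0.0176", "0.144", "0.609", "0.159"]
        for got, text in zip(adj, printed):
            decimals = len(text.split(".")[1])
            # agreement to the printed precision (half a unit in the last digit)
            assert got == pytest.approx(float(text), abs=0.51 * 10.0**-decimals)

    def test_ties_all_equal(self):
        np.testing.assert_allclose(sq.holm_adjust([0.01] * 7), 0.07)

    def test_single_p_unchanged(self):
        assert sq.holm_adjust([0.2])[0] == 0.2

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 9)
        np.testing.assert_allclose(
            sq.holm_adjust(p), multipletests(p, method="holm")[1], rtol=1e-12
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_bounds_and_monotonicity(self, p):
        adj = sq.holm_adjust(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestComparisonTable:
    def cohort_with_exact_summaries(self):
        rng = np.random.default_rng(23)
        summ = sq.zebra_deletion_summaries()
        rows = []
        for r in summ.itertuples():
            vals = exact_sample(r.mean, r.sd, r.n, rng)
            for i, v in enumerate(vals):
                rows.append((f"{r.genotype}_{i}", r.genotype, r.stripe, v))
        return pd.DataFrame(
            rows, columns=["embryo_id", "genotype", "stripe", "integration"]
        )

    def test_published_table_reproduced_from_embryo_level_data(self):
        table = self.cohort_with_exact_summaries()
        comp = sq.build_comparison_table(table, sq.WILDTYPE, sq.MUTANT)
        np.testing.assert_allclose(comp["pct"], PRINTED_PCT, atol=0.15)
        assert comp["significant"].tolist() == [
            False, False, False, True, False, False, False,
        ]
        assert comp.loc[comp.stripe == 4, "p_adj"].iloc[0] == pytest.approx(
            0.0176, abs=5e-4
        )

    def test_self_comparison_is_null(self):
        table = self.cohort_with_exact_summaries()
        wt = table[table.genotype == sq.WILDTYPE]
        other = wt.assign(genotype="copy")
        comp = sq.build_comparison_table(
            pd.concat([wt, other]), sq.WILDTYPE, "copy"
        )
        np.testing.assert_allclose(comp["pct"], 100.0)
        assert not comp["significant"].any()

    def test_missing_genotype_named(self):
        table = self.cohort_with_exact_summaries()
        with pytest.raises(sq.StatsError, match="nope"):
            sq.build_comparison_table(table, sq.WILDTYPE, "nope")

    def test_width_halved_gives_width_pct_near_50(self):
        rng = np.random.default_rng(31)
        rows = []
        for genotype, scale in [("wt", 1.0), ("mut", 0.5)]:
            for stripe in range(1, 8):
                base = 8.0 * (scale if stripe == 4 else 1.0)
                vals = exact_sample(base, 0.4, 6, rng)
                for i, v in enumerate(vals):
                    rows.append((f"{genotype}_{i}", genotype, stripe, v, 50.0))
        table = pd.DataFrame(
            rows,
            columns=["embryo_id", "genotype", "stripe", "width_pct_el", "centroid_pct_el"],
        )
        out = sq.compare_widths_and_centers(table, "wt", "mut")
        width4 = out["width"].loc[out["width"].stripe == 4, "pct"].iloc[0]
        assert width4 == pytest.approx(50.0, abs=1.0)
        # centroids identical across genotypes: nothing significant
        assert not out["centroid"]["significant"].any()
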