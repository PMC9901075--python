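import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octapvd import (AllZeroDifferencesError, CohortConfig, LongitudinalCohort,
                     StatsError, fisher_exact_2x2, format_difference_table,
                     generate_cohort, group_difference_table, mann_whitney_u,
                     rm_anova, wilcoxon_signed_rank)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def hand_rm_anova_f(panel):
    """Sums-of-squares arithmetic written out independently of the module."""
    n, t = panel.shape
    grand = panel.sum() / (n * t)
    ss_time = sum(n * (panel[:, j].sum() / n - grand) ** 2 for j in range(t))
    ss_subj = sum(t * (panel[i, :].sum() / t - grand) ** 2 for i in range(n))
    ss_tot = sum((panel[i, j] - grand) ** 2
                 for i in range(n) for j in range(t))
    ss_err = ss_tot - ss_time - ss_subj
    return (ss_time / (t - 1)) / (ss_err / ((n - 1) * (t - 1)))


def enumerate_mwu_p(a, b):
    """Permutation oracle counting (a>b) pairs directly, no rank formula."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(sample_a, sample_b):
        return sum((x > y) + 0.5 * (x == y)
                   for x in sample_a for y in sample_b)

    mu = na * len(b) / 2.0
    obs = abs(u_stat(a, b) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def enumerate_wilcoxon_p(diffs):
    """Sign-pattern oracle recomputing W+ from scratch per pattern."""
    d = [x for x in diffs if x != 0]
    ranks = sps.rankdata([abs(x) for x in d])
    total = ranks.sum()
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    obs = abs(w_obs - total / 2.0)
    hits = count = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        count += 1
        if abs(w - total / 2.0) >= obs - 1e-9:
            hits += 1
    return hits / count


def enumerate_fisher_p(table):
    """Hypergeometric enumeration with binomial coefficients only."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, r1 - (n - c1)),
                                      min(r1, c1) + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    TOY = np.array([[0.50, 0.48, 0.45],
                    [0.60, 0.58, 0.57],
                    [0.55, 0.50, 0.49],
                    [0.52, 0.51, 0.46]])

    def test_matches_hand_computed_sums_of_squares(self):
        res = rm_anova(self.TOY)
        assert res.f_statistic == pytest.approx(hand_rm_anova_f(self.TOY),
                                                abs=1e-10)
        assert (res.df_num, res.df_den) == (2, 6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, t = self.TOY.shape
        df = pd.DataFrame({"s": np.repeat(range(n), t),
                           "t": list(range(t)) * n,
                           "y": self.TOY.flatten()})
        ref = pg.rm_anova(data=df, dv="y", within="t", subject="s")
        res = rm_anova(self.TOY)
        assert res.f_statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_identical_columns_give_null_result(self):
        panel = np.tile([[0.5], [0.6], [0.7]], (1, 3))
        res = rm_anova(panel)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_error_variance_flagged_not_thrown(self):
        base = np.array([[0.5], [0.6], [0.7], [0.4]])
        panel = base + np.array([[0.0, -0.05, -0.1]])  # exact time effect
        res = rm_anova(panel)
        assert res.degenerate
        assert res.p_value == 0.0

    def test_listwise_deletion_counted(self):
        panel = np.vstack([self.TOY, [0.5, np.nan, 0.4]])
        res = rm_anova(panel)
        assert res.n_dropped == 1
        assert res.n_subjects == 4

    def test_posthoc_bonferroni_bounds(self):
        res = rm_anova(self.TOY)
        assert set(res.posthoc) == {(0, 1), (0, 2), (1, 2)}
        for pair, adj in res.posthoc.items():
            raw = res.posthoc_raw[pair]
            assert raw <= adj <= 1.0
            assert adj == pytest.approx(min(1.0, raw * 3))

    def test_greenhouse_geisser_epsilon_in_range(self):
        res = rm_anova(self.TOY, greenhouse_geisser=True)
        t = self.TOY.shape[1]
        assert 1.0 / (t - 1) <= res.gg_epsilon <= 1.0
        assert res.p_value >= rm_anova(self.TOY).p_value - 1e-12

    def test_too_small_panel_rejected(self):
        with pytest.raises(StatsError):
            rm_anova(np.ones((2, 3)))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5, size=2)
        # half the instances get heavy ties via rounding
        vals = rng.normal(size=na + nb)
        if seed % 2:
            vals = np.round(vals)
        a, b = vals[:na], vals[na:]
        _, p = mann_whitney_u(a, b, method="exact")
        assert p == pytest.approx(enumerate_mwu_p(list(a), list(b)),
                                  abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        u, p = mann_whitney_u(a, b, method="exact")
        ref = sps.mannwhitneyu(a, b, method="exact")
        assert (u, p) == (pytest.approx(ref.statistic),
                          pytest.approx(ref.pvalue))

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approximation_near_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = rng.normal(size=6), rng.normal(size=6)
        _, p_exact = mann_whitney_u(a, b, method="exact")
        _, p_approx = mann_whitney_u(a, b, method="approx")
        assert abs(p_exact - p_approx) <= 0.03

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_n5(self):
        w, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert w == 0.0
        assert p == pytest.approx(2 / 32)

    def test_single_nonzero_difference(self):
        _, p = wilcoxon_signed_rank([0.0, 0.7, 0.0])
        assert p == 1.0

    def test_symmetric_differences(self):
        _, p = wilcoxon_signed_rank([1.5, -1.5])
        assert p == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(AllZeroDifferencesError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=int(rng.integers(3, 8)))
        if seed % 2:
            d = np.round(d * 2) / 2  # force tied magnitudes
            d = d[d != 0]
            if d.size == 0:
                return
        _, p = wilcoxon_signed_rank(d, method="exact")
        assert p == pytest.approx(enumerate_wilcoxon_p(list(d)), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        d = rng.normal(size=9)
        w, p = wilcoxon_signed_rank(d, method="exact")
        ref = sps.wilcoxon(d, mode="exact")
        assert (w, p) == (pytest.approx(ref.statistic),
                          pytest.approx(ref.pvalue))

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approximation_near_exact(self, seed):
        rng = np.random.default_rng(50 + seed)
        d = rng.normal(size=12)
        _, p_exact = wilcoxon_signed_rank(d, method="exact")
        _, p_approx = wilcoxon_signed_rank(d, method="approx")
        assert abs(p_exact - p_approx) <= 0.03


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[2, 0], [0, 2]], 1 / 3),
        ([[1, 1], [1, 1]], 1.0),
        ([[5, 0], [0, 0]], 1.0),
    ])
    def test_printed_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_and_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 2))
        p = fisher_exact_2x2(table)
        assert p == pytest.approx(enumerate_fisher_p(table.tolist()),
                                  abs=1e-12)
        if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
            assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-10)

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(StatsError):
            fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(StatsError):
            fisher_exact_2x2([[0.5, 1], [2, 3]])


# ---------------------------------------------------------------------------
# group-difference table
# ---------------------------------------------------------------------------

def _two_eye_cohort(pvd_dr, pvd_no_dr):
    rows = []
    for eye, group, val in (("E1", "DR", pvd_dr), ("E2", "no-DR", pvd_no_dr)):
        for slab in ("SCP", "DCP"):
            for visit in ("baseline", "6mo", "12mo"):
                for sector in ("superior", "temporal", "inferior", "nasal"):
                    rows.append((eye, group, visit, slab, sector, val))
    df = pd.DataFrame(rows, columns=["eye_id", "group", "visit", "slab",
                                     "sector", "pvd"])
    return LongitudinalCohort(data=df)


class TestGroupDifferenceTable:
    def test_identical_groups_give_zero_differences(self):
        table = group_difference_table(_two_eye_cohort(0.5, 0.5))
        assert np.allclose(table["difference"], 0.0)

    def test_hand_built_two_eye_cohort(self):
        table = group_difference_table(_two_eye_cohort(0.44, 0.52))
        assert np.allclose(table["difference"], 0.52 - 0.44)

    def test_sign_convention_flips_with_labels(self):
        cohort = generate_cohort(CohortConfig(seed=4))
        flipped = LongitudinalCohort(
            data=cohort.data.assign(group=cohort.data["group"].map(
                {"DR": "no-DR", "no-DR": "DR"})),
            visits=cohort.visits)
        t1 = group_difference_table(cohort)
        t2 = group_difference_table(flipped)
        assert np.allclose(t1["difference"], -t2["difference"])

    def test_dcp_deficit_recovered_from_generator(self):
        cfg = CohortConfig(dr_dcp_deficit=-0.06, sigma_between=0.02,
                           sigma_noise=0.01, seed=8)
        table = group_difference_table(generate_cohort(cfg))
        dcp_post = table[(table["slab"] == "DCP")
                         & (table["visit"] != "baseline")
                         & (table["sector"] == "mean")]
        assert np.allclose(dcp_post["difference"], 0.06, atol=0.03)
        baseline = table[(table["visit"] == "baseline")
                         & (table["sector"] == "mean")]
        assert np.allclose(baseline["difference"], 0.0, atol=0.03)

    def test_bonferroni_cells_only_inflates_p(self):
        cohort = generate_cohort(CohortConfig(seed=6))
        plain = group_difference_table(cohort)
        corrected = group_difference_table(cohort, bonferroni_cells=True)
        assert (corrected["p_value"] >= plain["p_value"] - 1e-12).all()
        assert (corrected["p_value"] <= 1.0).all()

    def test_formatted_table_mentions_significance(self):
        cfg = CohortConfig(dr_dcp_deficit=-0.10, sigma_between=0.02,
                           sigma_noise=0.01, seed=2)
        table = group_difference_table(generate_cohort(cfg))
        text = format_difference_table(table)
        assert "SCP" in text and "DCP" in text
        assert "*" in text
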