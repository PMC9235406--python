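import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from artbayes.model import COLLECTED, FORCED_FAIL, SubjectPlay, TrialOutcome
from artbayes.stats import (
    adjusted_score,
    associate,
    bf_anova_oneway,
    bf_interpretation,
    bf_ttest,
    bf_ttest_from_t,
    cohort_table,
    permutation_test,
    tiv_correct,
)


def play_from_casts(spec, subject_id="s1", group="g"):
    """spec: list of (n_casts, collected?) at p=0.1, max_casts generous."""
    trials = []
    for casts, collected in spec:
        if collected:
            trials.append(TrialOutcome(0.1, casts, COLLECTED, 5 * casts, max_casts=99))
        else:
            trials.append(TrialOutcome(0.1, casts, FORCED_FAIL, 0, max_casts=casts))
    return SubjectPlay(subject_id, group, "A", tuple(trials))


class TestAdjustedScore:
    def test_mixed_trials(self):
        play = play_from_casts([(3, True), (5, False), (4, True)])
        assert adjusted_score(play) == pytest.approx(3.5)

    def test_constant_collected(self):
        play = play_from_casts([(6, True)] * 4)
        assert adjusted_score(play) == 6.0

    def test_all_forced_fail_is_missing(self):
        play = play_from_casts([(2, False), (7, False)])
        assert math.isnan(adjusted_score(play))

    def test_invariant_to_trial_order(self):
        spec = [(3, True), (5, False), (4, True), (1, True)]
        a = adjusted_score(play_from_casts(spec))
        b = adjusted_score(play_from_casts(spec[::-1]))
        assert a == b


def jzs_oracle_noncentral_t(t, n1, n2, r=math.sqrt(2) / 2):
    """Independent route: integrate the noncentral-t likelihood over the
    Cauchy effect prior instead of the g-mixture representation."""
    nu = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)

    def num(d):
        return sps.nct.pdf(t, nu, d * np.sqrt(neff)) * sps.cauchy.pdf(d, 0, r)

    num_v, _ = integrate.quad(num, -np.inf, np.inf, limit=400)
    return num_v / sps.t.pdf(t, nu)


class TestBfTtest:
    @pytest.mark.parametrize(
        "t,n1,n2", [(2.1, 11, 24), (0.3, 11, 24), (-1.5, 8, 9), (3.5, 20, 20)]
    )
    def test_matches_quadrature_oracle(self, t, n1, n2):
        got = bf_ttest_from_t(t, n1, n2)
        assert got == pytest.approx(jzs_oracle_noncentral_t(t, n1, n2), rel=1e-4)

    def test_null_data_favors_null(self):
        rng = np.random.default_rng(0)
        bf = bf_ttest(rng.normal(size=100), rng.normal(size=100))
        assert bf < 1.0

    def test_monotone_in_effect_size(self):
        bfs = [bf_ttest_from_t(t, 15, 15) for t in (0.5, 1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(bfs) > 0)

    def test_symmetric_in_samples(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        assert bf_ttest(x, y) == pytest.approx(bf_ttest(y, x), rel=1e-9)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bf_ttest([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            bf_ttest([1.0], [2.0, 3.0])


def anova_oracle_mc(groups, r=0.5, n_mc=60_000, seed=0):
    """Seeded Monte-Carlo over g with an independently coded conditional
    marginal: full N x N covariance route, scipy null-space contrasts."""
    from scipy.linalg import null_space

    y = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    k = len(groups)
    n = y.size
    basis = null_space(np.ones((1, k)))  # k x (k-1), orthonormal
    indicator = np.zeros((n, k))
    indicator[np.arange(n), np.repeat(np.arange(k), [len(g) for g in groups])] = 1.0
    x = indicator @ basis
    yc = y - y.mean()
    xc = x - x.mean(axis=0)
    s0 = yc @ yc
    rng = np.random.default_rng(seed)
    gs = sps.invgamma.rvs(0.5, scale=r**2 / 2.0, size=n_mc, random_state=rng)
    vals = np.empty(n_mc)
    for i, g in enumerate(gs):
        cov = np.eye(n) + g * (xc @ xc.T)
        sign, logdet = np.linalg.slogdet(cov)
        quad = yc @ np.linalg.solve(cov, yc)
        vals[i] = math.exp(-0.5 * logdet - 0.5 * (n - 1) * (math.log(quad) - math.log(s0)))
    return vals.mean(), vals.std(ddof=1) / math.sqrt(n_mc)


class TestBfAnova:
    def test_matches_monte_carlo_oracle_on_fixed_dataset(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.6, 1.2)]
        got = bf_anova_oneway(groups)
        oracle, mc_se = anova_oracle_mc(groups)
        assert abs(got - oracle) / oracle < max(1e-2, 4 * mc_se / oracle)

    def test_null_data_favors_null(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=10) for _ in range(3)]
        assert bf_anova_oneway(groups) < 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8) for _ in range(3)]
        a = bf_anova_oneway(groups)
        b = bf_anova_oneway([groups[2], groups[0], groups[1]])
        assert a == pytest.approx(b, rel=1e-9)

    def test_two_groups_directionally_consistent_with_ttest(self):
        rng = np.random.default_rng(5)
        effect = [rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)]
        null = [rng.normal(0, 1, 50), rng.normal(0, 1, 50)]
        for pair in (effect, null):
            a = bf_anova_oneway(pair)
            t = bf_ttest(pair[0], pair[1])
            assert (a > 1) == (t > 1)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            bf_anova_oneway([[1.0, 1.0], [1.0, 1.0]])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 groups"):
            bf_anova_oneway([[1.0, 2.0]])


class TestPermutationTest:
    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert permutation_test(x, x.copy(), seed=0) == 1.0

    def test_exact_enumeration_disjoint_support(self):
        # only the observed split and its mirror reach the observed |diff|
        x = np.arange(10.0)
        y = np.arange(100.0, 110.0)
        p = permutation_test(x, y, exact=True)
        assert p == pytest.approx(2 / comb(20, 10), abs=1e-12)

    def test_monte_carlo_tracks_exact(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 7)
        y = rng.normal(1.0, 1, 7)
        exact = permutation_test(x, y, exact=True)
        mc = permutation_test(x, y, n_perm=40_000, seed=1)
        se = math.sqrt(exact * (1 - exact) / 40_000)
        assert abs(mc - exact) < 4 * se + 1e-4

    def test_add_one_convention_never_zero(self):
        x = np.arange(10.0)
        y = np.arange(100.0, 110.0)
        p = permutation_test(x, y, n_perm=500, seed=2)
        assert p == pytest.approx(1 / 501)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            pvals.append(permutation_test(x, y, n_perm=199, seed=rng))
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert permutation_test(x, y, seed=5) == permutation_test(x, y, seed=5)

    def test_rejects_unknown_statistic_and_small_n_perm(self):
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], [3.0, 4.0], statistic="median_diff")
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=10)


class TestAssociate:
    @staticmethod
    def table(n=40, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return pd.DataFrame(
            {"x": x, "y2x": 2 * x, "noise": rng.normal(size=n),
             "pos": np.exp(rng.normal(size=n)), "const": 1.0}
        )

    def test_perfect_linear_relation(self):
        res = associate(self.table(), "x", "y2x")
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10
        assert res.n == 40

    def test_matches_synthetic_covariate_construction(self):
        from artbayes.simulate import CovariateSpec, _draw_lognormal, simulate_covariates

        rng = np.random.default_rng(1)
        truth = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(5000)],
             "gamma_plus": _draw_lognormal(rng, 2.0, 0.4, 5000),
             "beta": _draw_lognormal(rng, 0.2, 0.4, 5000)}
        )
        cov = simulate_covariates(truth, [CovariateSpec("v", "gamma_plus", -0.4)], seed=2)
        table = truth.assign(v=cov["v"])
        res = associate(table, "v", "gamma_plus")
        assert res.r == pytest.approx(-0.4, abs=0.04)

    def test_symmetric_in_r(self):
        t = self.table()
        a = associate(t, "x", "noise")
        b = associate(t, "noise", "x")
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_log_transform(self):
        t = self.table()
        res = associate(t, "x", "pos", transform_y="log")
        direct = sps.pearsonr(t["x"], np.log(t["pos"]))
        assert res.r == pytest.approx(direct.statistic)
        assert res.transform == "log"

    def test_log_transform_rejects_nonpositive(self):
        t = self.table()
        t.loc[0, "pos"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            associate(t, "x", "pos", transform_y="log")

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            associate(self.table(), "x", "const")

    def test_bonferroni_only_when_family_declared(self):
        t = self.table()
        nominal = associate(t, "x", "noise")
        assert nominal.p_bonferroni is None
        family = associate(t, "x", "noise", family=6)
        assert family.p_bonferroni == pytest.approx(min(1.0, family.p * 6))

    def test_missing_pairs_dropped(self):
        t = self.table()
        t.loc[:2, "noise"] = np.nan
        res = associate(t, "x", "noise")
        assert res.n == 37

    def test_too_few_pairs_rejected(self):
        t = self.table(n=2)
        with pytest.raises(ValueError, match="pairs"):
            associate(t, "x", "noise")


class TestTivCorrect:
    def test_example_ratio(self):
        assert tiv_correct(4000.0, 1_600_000.0) == pytest.approx(0.0025)

    def test_zero_volume(self):
        assert tiv_correct(0.0, 1e6) == 0.0

    def test_scale_invariance(self):
        assert tiv_correct(4000.0, 1.6e6) == pytest.approx(tiv_correct(8000.0, 3.2e6))

    def test_rejects_nonpositive_tiv(self):
        with pytest.raises(ValueError):
            tiv_correct(100.0, 0.0)


class TestCohortTable:
    def test_missing_scores_propagate(self):
        plays = [
            play_from_casts([(3, True), (4, True)], "s1"),
            play_from_casts([(2, False)], "s2"),
        ]
        table = cohort_table(plays)
        assert table.loc[table.subject_id == "s1", "adjusted_score"].iloc[0] == 3.5
        assert math.isnan(table.loc[table.subject_id == "s2", "adjusted_score"].iloc[0])

    def test_duplicate_ids_rejected(self):
        plays = [play_from_casts([(3, True)], "s1"), play_from_casts([(2, True)], "s1")]
        with pytest.raises(ValueError, match="duplicate"):
            cohort_table(plays)


class TestInterpretationBands:
    @pytest.mark.parametrize(
        "bf,phrase",
        [(20.0, "strong evidence for the alternative"),
         (5.0, "moderate evidence for the alternative"),
         (2.0, "anecdotal evidence for the alternative"),
         (0.5, "anecdotal evidence for the null"),
         (0.2, "moderate evidence for the null"),
         (0.05, "strong evidence for the null")],
    )
    def test_bands(self, bf, phrase):
        assert bf_interpretation(bf) == phrase
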