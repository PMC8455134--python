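"""Shift sets, branch-set enrichment, permutation null, interaction model."""

import numpy as np
import pandas as pd
import pytest

from famevol import read_newick
from famevol.errors import BranchSetError, FitError
from famevol.giants import (branch_set_enrichment, interaction_model,
                            permutation_null, permutation_pvalue, rate_ratio,
                            shifted_sets, sister_control)
from famevol.io import BranchSet, GeneSet


def pv_table(rows, branches):
    return pd.DataFrame(rows, columns=branches)


class TestShiftedSets:
    def setup_method(self):
        # branches 0..3; families f1..f3 with hand-placed significant shifts
        self.pv = pd.DataFrame(
            [[0.01, 0.50, 0.90, 0.80],     # f1: shift on 0 only
             [0.20, 0.02, 0.03, 0.90],     # f2: shifts on 1 and 2
             [0.70, 0.60, 0.80, 0.95]],    # f3: none
            index=["f1", "f2", "f3"], columns=[0, 1, 2, 3])
        self.giant = BranchSet("giant", frozenset({0, 1}))

    def test_hand_enumerated_memberships(self):
        ss = shifted_sets(self.pv, [self.giant])
        assert ss.all_shifted == frozenset({"f1", "f2"})
        assert ss.per_set["giant"] == frozenset({"f1", "f2"})
        assert ss.exclusive["giant"] == frozenset({"f1"})  # f2 also shifts on 2
        assert ss.mean_shift_branches == pytest.approx(1.5)

    def test_set_inclusions(self):
        ss = shifted_sets(self.pv, [self.giant])
        assert ss.per_set["giant"] <= ss.all_shifted
        assert ss.exclusive["giant"] <= ss.per_set["giant"]

    def test_no_flags_all_empty(self):
        pv = self.pv.copy() * 0 + 0.5
        ss = shifted_sets(pv, [self.giant])
        assert not ss.all_shifted
        assert not ss.per_set["giant"]

    def test_unknown_branch_in_set_is_error(self):
        with pytest.raises(BranchSetError, match="missing"):
            shifted_sets(self.pv, [BranchSet("bad", frozenset({99}))])


def synthetic_shift_data(seed, n_fam=600, n_branch=12, n_giant=3,
                         cancer_frac=0.1, effect=0.0):
    """Direct synthetic shift flags: giant-branch flags tilted for cancer families."""
    rng = np.random.default_rng(seed)
    branches = list(range(n_branch))
    giant = BranchSet("giant", frozenset(branches[:n_giant]))
    sister = BranchSet("sister", frozenset(branches[n_giant:2 * n_giant]))
    fams = [f"f{i}" for i in range(n_fam)]
    cancer_mask = rng.random(n_fam) < cancer_frac
    base = 0.08
    p = np.full((n_fam, n_branch), np.nan)
    for j in range(n_branch):
        rate = base
        flag = rng.random(n_fam) < rate
        if j < n_giant and effect > 0:
            extra = rng.random(n_fam) < (effect * base)
            flag = flag | (extra & cancer_mask)
        p[:, j] = np.where(flag, 0.01, 0.5)
    pv = pd.DataFrame(p, index=fams, columns=branches)
    cancer = GeneSet("cancer", frozenset(np.array(fams)[cancer_mask]))
    return pv, giant, sister, cancer


class TestBranchSetEnrichment:
    def test_two_by_two_construction(self):
        pv, giant, sister, cancer = synthetic_shift_data(0, effect=3.0)
        ss = shifted_sets(pv, [giant, sister])
        res = branch_set_enrichment(ss, giant, cancer, "all_shifted")
        t = res.table
        uni = ss.all_shifted
        focal = ss.per_set["giant"]
        assert t.a == len(focal & cancer.families)
        assert t.a + t.b == len(focal)
        assert t.a + t.c == len(uni & cancer.families)
        assert t.n == len(uni)

    def test_effect_detected(self):
        pv, giant, sister, cancer = synthetic_shift_data(1, n_fam=2000, effect=4.0)
        ss = shifted_sets(pv, [giant, sister])
        res = branch_set_enrichment(ss, giant, cancer, "all_shifted")
        assert res.odds_ratio > 1.0
        assert res.p < 0.05

    def test_sister_unaffected_by_giant_only_effect(self):
        """Specificity: a giant-only effect leaves the sister OR near 1.

        Measured over the all-families universe, where sister-shift status is
        exactly independent of the cancer label.  (Restricting the universe
        to shifted families induces a collider: cancer families enter the
        universe preferentially through giant flags, which *depresses* the
        sister OR below 1 rather than inflating it.)
        """
        log_ors = []
        for seed in range(60):
            pv, giant, sister, cancer = synthetic_shift_data(seed, n_fam=1500,
                                                             effect=4.0)
            ss = shifted_sets(pv, [giant, sister])
            res = sister_control(ss, sister, cancer, "all_families",
                                 list(pv.index))
            if np.isfinite(res.odds_ratio) and res.odds_ratio > 0:
                log_ors.append(np.log(res.odds_ratio))
        mean_or = np.exp(np.mean(log_ors))
        assert mean_or == pytest.approx(1.0, abs=0.15)

    def test_focal_covering_everything_degenerates(self):
        pv, giant, sister, cancer = synthetic_shift_data(2)
        every = BranchSet("all", frozenset(pv.columns))
        ss = shifted_sets(pv, [every])
        assert ss.per_set["all"] == ss.all_shifted
        res = branch_set_enrichment(ss, every, cancer, "all_shifted")
        assert res.table.degenerate()
        assert res.p == 1.0

    def test_universe_all_families(self):
        pv, giant, sister, cancer = synthetic_shift_data(3, effect=3.0)
        ss = shifted_sets(pv, [giant])
        res = branch_set_enrichment(ss, giant, cancer, "all_families",
                                    list(pv.index))
        assert res.table.n == len(pv.index)

    def test_empty_sister_set_is_error(self):
        pv, giant, _, cancer = synthetic_shift_data(4)
        ss = shifted_sets(pv, [giant])
        with pytest.raises(BranchSetError, match="empty"):
            sister_control(ss, BranchSet("s", frozenset()), cancer)


class TestPermutationNull:
    def test_p_is_fraction_of_null_at_least_observed(self):
        null = np.array([0.5] * 98 + [3.0, 4.0])
        assert permutation_pvalue(2.66, null) == pytest.approx(0.02)
        assert permutation_pvalue(0.1, null) == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        null = rng.lognormal(size=100)
        obs = 1.7
        p1 = permutation_pvalue(obs, null)
        p2 = permutation_pvalue(np.log(obs), np.log(null))
        assert p1 == p2

    def test_deterministic_and_sized(self):
        tree = read_newick("((A:5,B:5):5,((C:3,D:3):4,E:7):3);")
        pv, giant, sister, cancer = synthetic_shift_data(5, n_branch=8,
                                                         n_giant=2, effect=2.0)
        pv.columns = tree.branches()
        giant = BranchSet("giant", frozenset(list(pv.columns)[:2]))
        r1 = permutation_null(pv, tree, cancer, k=3, n_perm=50, seed=42,
                              focal=giant)
        r2 = permutation_null(pv, tree, cancer, k=3, n_perm=50, seed=42,
                              focal=giant)
        assert np.array_equal(r1.null_or, r2.null_or)
        assert r1.n_permutations == 50
        assert 0 <= r1.p <= 1

    def test_k_too_large(self):
        tree = read_newick("(A:5,B:5);")
        pv = pd.DataFrame(np.full((3, 2), 0.5), index=list("abc"),
                          columns=tree.branches())
        cancer = GeneSet("c", frozenset({"a"}))
        with pytest.raises(BranchSetError, match="exceeds"):
            permutation_null(pv, tree, cancer, k=5, n_perm=10, seed=0,
                             focal=BranchSet("g", frozenset({pv.columns[0]})))


def simulate_rates(seed, n_fam=80, n_branch=10, n_giant=3, sd_family=0.05,
                   sd_resid=0.02, b0=0.05, b_giant=0.02, b_cancer=-0.0025,
                   b_int=0.01, cancer_frac=0.3):
    rng = np.random.default_rng(seed)
    fams = [f"f{i}" for i in range(n_fam)]
    cancer_mask = rng.random(n_fam) < cancer_frac
    if not cancer_mask.any():
        cancer_mask[0] = True
    if cancer_mask.all():
        cancer_mask[-1] = False
    giant = BranchSet("giant", frozenset(range(n_giant)))
    u = rng.normal(0, sd_family, n_fam)
    rates = np.empty((n_fam, n_branch))
    for j in range(n_branch):
        g = 1.0 if j < n_giant else 0.0
        mu = b0 + b_giant * g + b_cancer * cancer_mask + b_int * g * cancer_mask
        rates[:, j] = mu + u + rng.normal(0, sd_resid, n_fam)
    df = pd.DataFrame(rates, index=fams, columns=range(n_branch))
    cancer = GeneSet("cancer", frozenset(np.array(fams)[cancer_mask]))
    return df, giant, cancer, dict(intercept=b0, giant=b_giant,
                                   cancer=b_cancer, **{"giant:cancer": b_int})


class TestInteractionModel:
    def test_zero_variance_reduces_to_ols(self):
        df, giant, cancer, _ = simulate_rates(0, sd_family=0.0)
        fit = interaction_model(df, giant, cancer)
        long = df.stack().rename("rate").reset_index()
        long.columns = ["family", "branch", "rate"]
        g = long["branch"].astype(int) < 3
        c = long["family"].isin(cancer.families)
        X = np.column_stack([np.ones(len(long)), g, c, g & c]).astype(float)
        beta = np.linalg.lstsq(X, long["rate"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_recovers_known_coefficients(self):
        df, giant, cancer, truth = simulate_rates(1, n_fam=400)
        fit = interaction_model(df, giant, cancer)
        for name, val in truth.items():
            assert fit.params[name] == pytest.approx(val, abs=4 * fit.bse[name])
        assert fit.pvalues["giant"] < 1e-6
        assert fit.re_variance > 0

    def test_matches_statsmodels_mixedlm(self):
        """Dual-route check against the standard mixed-model implementation."""
        import statsmodels.api as sm

        df, giant, cancer, _ = simulate_rates(2, n_fam=60, sd_family=0.05)
        fit = interaction_model(df, giant, cancer)
        long = df.stack().rename("rate").reset_index()
        long.columns = ["family", "branch", "rate"]
        g = (long["branch"].astype(int) < 3).astype(float)
        c = long["family"].isin(cancer.families).astype(float)
        X = np.column_stack([np.ones(len(long)), g, c, g * c])
        ref = sm.MixedLM(long["rate"].to_numpy(), X,
                         groups=long["family"].to_numpy()).fit(reml=False)
        assert np.allclose(fit.params.to_numpy(), ref.fe_params, atol=1e-5)
        assert fit.re_variance == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                                rel=0.05)

    def test_rank_deficiency_names_term(self):
        df, giant, _, _ = simulate_rates(3)
        nobody = GeneSet("cancer", frozenset())
        with pytest.raises(FitError, match="cancer"):
            interaction_model(df, giant, nobody)

    def test_too_few_families(self):
        df, giant, cancer, _ = simulate_rates(4)
        with pytest.raises(FitError, match=">= 2"):
            interaction_model(df.iloc[:1], giant, cancer)


class TestRateRatio:
    def test_identical_rates_give_unit_ratios(self):
        df = pd.DataFrame(np.full((4, 6), 0.3), index=list("abcd"),
                          columns=range(6))
        giant = BranchSet("g", frozenset({0, 1}))
        cancer = GeneSet("c", frozenset({"a", "b"}))
        rep = rate_ratio(df, giant, cancer)
        assert rep.ratio_cancer == pytest.approx(1.0)
        assert rep.ratio_noncancer == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        df = pd.DataFrame([[0.4, 0.2, 0.1, 0.1],
                           [0.6, 0.4, 0.2, 0.2]],
                          index=["ca", "bg"], columns=range(4))
        giant = BranchSet("g", frozenset({0, 1}))
        cancer = GeneSet("c", frozenset({"ca"}))
        rep = rate_ratio(df, giant, cancer)
        assert rep.ratio_cancer == pytest.approx(0.3 / 0.1)
        assert rep.ratio_noncancer == pytest.approx(0.5 / 0.2)

    def test_interaction_raises_cancer_stratum_ratio(self):
        df, giant, cancer, _ = simulate_rates(5, n_fam=800, b_int=0.02)
        rep = rate_ratio(df, giant, cancer)
        assert rep.ratio_cancer > rep.ratio_noncancer

    def test_zero_background_flagged_infinite(self):
        df = pd.DataFrame([[0.4, 0.0], [0.6, 0.0]], index=["ca", "bg"],
                          columns=[0, 1])
        giant = BranchSet("g", frozenset({0}))
        cancer = GeneSet("c", frozenset({"ca"}))
        rep = rate_ratio(df, giant, cancer)
        assert np.isinf(rep.ratio_cancer)
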