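"""Birth-death kernel, pruning likelihood, fitting, ancestral states, shifts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import counts_table
from famevol import read_newick
from famevol.birthdeath import (AncestralSizes, BDModel, ancestral_states,
                                branch_rates, branch_shift_pvalues, family_loglik,
                                fit_lambda, table_loglik, transition_matrix,
                                transition_prob)
from famevol.errors import FitError
from famevol.simulate import SimConfig, simulate_counts, simulate_tree


def alpha(lam, t):
    return lam * t / (1 + lam * t)


class TestKernel:
    def test_identity_limit(self):
        P, deficit = transition_matrix(0.0, 10.0, 20)
        assert np.allclose(P, np.eye(21))
        assert deficit == 0.0
        assert transition_prob(3, 3, 0.0, 10.0) == 1.0

    def test_extinction_is_absorbing(self):
        P, _ = transition_matrix(0.01, 30.0, 50)
        assert P[0, 0] == 1.0
        assert P[0, 1:].sum() == 0.0

    def test_single_gene_loss_probability_is_alpha(self):
        lam, t = 0.003, 30.0
        assert transition_prob(1, 0, lam, t) == pytest.approx(alpha(lam, t),
                                                              rel=1e-12)

    def test_rows_sum_to_one_after_renormalization(self):
        P, _ = transition_matrix(0.002, 80.0, 100)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("s", [1, 2, 5])
    def test_martingale_mean_under_truncation(self, s):
        """E[child | parent] = parent to 1e-8 when the truncation bound is ample."""
        lam, t, s_max = 0.004, 50.0, 220
        row = np.array([transition_prob(s, c, lam, t) for c in range(s_max + 1)])
        assert 1.0 - row.sum() < 1e-8  # truncation deficit
        assert (np.arange(s_max + 1) * row).sum() == pytest.approx(s, abs=1e-8)

    def test_matches_event_level_simulation(self):
        """The closed form agrees with Gillespie simulation of the process."""
        rng = np.random.default_rng(0)
        lam, t, s0 = 0.01, 40.0, 2

        def gillespie():
            s, clock = s0, 0.0
            while s > 0:
                clock += rng.exponential(1.0 / (2 * lam * s))
                if clock > t:
                    break
                s += 1 if rng.random() < 0.5 else -1
            return s

        n = 20000
        sims = np.array([gillespie() for _ in range(n)])
        P, _ = transition_matrix(lam, t, 100, renormalize=False)
        for c in range(5):
            assert (sims == c).mean() == pytest.approx(P[s0, c], abs=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(-1, 0, 0.01, 1.0)
        with pytest.raises(ValueError):
            transition_matrix(-0.01, 1.0, 10)


def bruteforce_loglik(table_row, tree, model):
    """Enumerate all internal-node size assignments (tiny trees only)."""
    S = model.s_max + 1
    kernels = {v: transition_matrix(model.lam_of(v), tree.duration(v),
                                    model.s_max)[0]
               for v in tree.branches()}
    pi = model.prior()
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tips = tree.tips
    obs = {t: table_row[tree.tip_label[t]] for t in tips}

    def config_prob(sizes):
        p = pi[sizes[tree.root]]
        for v in tree.branches():
            parent_s = sizes[tree.parent[v]]
            if tree.is_tip(v):
                p *= kernels[v][parent_s, obs[v]]
            else:
                p *= kernels[v][parent_s, sizes[v]]
        return p

    num = 0.0
    for combo in itertools.product(range(S), repeat=len(internals)):
        sizes = dict(zip(internals, combo))
        num += config_prob(sizes)

    # survival conditioning: P(>= min_surviving tips non-extinct)
    cond = 0.0
    for combo in itertools.product(range(S), repeat=len(internals)):
        sizes = dict(zip(internals, combo))
        base = pi[sizes[tree.root]]
        for v in tree.branches():
            if not tree.is_tip(v):
                base *= kernels[v][sizes[tree.parent[v]], sizes[v]]
        p_ext = [kernels[t][sizes[tree.parent[t]], 0] for t in tips]
        p_ge = 0.0
        for pattern in itertools.product([0, 1], repeat=len(tips)):
            if sum(pattern) < model.min_surviving:
                continue
            q = 1.0
            for alive, pe in zip(pattern, p_ext):
                q *= (1 - pe) if alive else pe
            p_ge += q
        cond += base * p_ge
    return np.log(num) - np.log(cond)


class TestLikelihood:
    def test_point_prior_frozen_process_is_certain(self):
        tree = read_newick("(A:10,B:20);")
        model = BDModel(lam={"background": 0.0}, s_max=10,
                        root_prior=("point", 3))
        assert family_loglik({"A": 3, "B": 3}, tree, model) == pytest.approx(0.0)

    def test_two_tip_direct_sum(self, two_tip_tree):
        model = BDModel(lam={"background": 0.01}, s_max=25)
        ll = family_loglik({"A": 3, "B": 2}, two_tip_tree, model)
        PA, _ = transition_matrix(0.01, 10, 25)
        PB, _ = transition_matrix(0.01, 20, 25)
        pi = model.prior()
        num = (pi * PA[:, 3] * PB[:, 2]).sum()
        den = (pi * (1 - PA[:, 0]) * (1 - PB[:, 0])).sum()
        assert ll == pytest.approx(np.log(num / den), abs=1e-9)

    @pytest.mark.parametrize("nwk,counts", [
        ("((A:5,B:8):4,C:9);", {"A": 2, "B": 0, "C": 4}),
        ("((A:5,B:8):4,(C:3,D:6):5);", {"A": 1, "B": 2, "C": 0, "D": 3}),
        ("(((A:2,B:3):2,C:4):3,D:7);", {"A": 3, "B": 1, "C": 1, "D": 0}),
    ])
    def test_pruning_equals_enumeration_small_trees(self, nwk, counts):
        tree = read_newick(nwk)
        model = BDModel(lam={"background": 0.02}, s_max=8)
        ll = family_loglik(counts, tree, model)
        assert ll == pytest.approx(bruteforce_loglik(counts, tree, model),
                                   abs=1e-9)

    def test_per_class_rates_respected_in_enumeration(self):
        tree = read_newick("((A:5,B:8):4,C:9);")
        classes = {tree.node_by_label("C"): "giant"}
        model = BDModel(lam={"background": 0.01, "giant": 0.05}, classes=classes,
                        s_max=8)
        ll = family_loglik({"A": 2, "B": 1, "C": 4}, tree, model)
        assert ll == pytest.approx(
            bruteforce_loglik({"A": 2, "B": 1, "C": 4}, tree, model), abs=1e-9)

    def test_truncation_stability_for_small_counts(self, two_tip_tree):
        lls = []
        for s_max in (60, 120):
            model = BDModel(lam={"background": 0.002}, s_max=s_max)
            lls.append(family_loglik({"A": 3, "B": 2}, two_tip_tree, model))
        assert abs(lls[0] - lls[1]) < 1e-6

    def test_all_zero_family_rejected(self, two_tip_tree):
        model = BDModel(lam={"background": 0.01}, s_max=10)
        with pytest.raises(FitError):
            family_loglik({"A": 0, "B": 0}, two_tip_tree, model)


class TestFit:
    def test_recovers_simulated_rate(self):
        tree = simulate_tree(10, seed=3)
        cfg = SimConfig(seed=1, n_families=800, lambda_background=0.002,
                        giant_multiplier=1.0)
        table, _ = simulate_counts(tree, cfg)
        fit = fit_lambda(table, tree, n_starts=1)
        assert fit.lam["background"] == pytest.approx(0.002, rel=0.25)

    def test_two_class_fit_on_single_class_data(self):
        tree = simulate_tree(8, seed=9)
        cfg = SimConfig(seed=4, n_families=400, lambda_background=0.002,
                        giant_multiplier=1.0)
        table, _ = simulate_counts(tree, cfg)
        classes = {v: "giant" for v in list(tree.branches())[:4]}
        fit1 = fit_lambda(table, tree, n_starts=1)
        fit2 = fit_lambda(table, tree, classes, n_starts=1, x0=fit1.lam)
        # both classes near the common truth; improvement in fit is marginal
        assert fit2.lam["giant"] == pytest.approx(fit2.lam["background"], rel=0.8)
        assert 0 <= fit2.loglik - fit1.loglik < 4.0

    def test_frozen_data_drives_rate_to_lower_bound(self):
        tree = read_newick("((A:10,B:10):10,(C:10,D:10):10);")
        rows = {f"f{i}": [k, k, k, k] for i, k in enumerate([1, 2, 3, 2, 1])}
        table = counts_table(tree, rows)
        fit = fit_lambda(table, tree, n_starts=1, s_max=15)
        assert fit.lam["background"] < 1e-6

    def test_multistart_logliks_agree(self):
        tree = simulate_tree(5, seed=13)
        cfg = SimConfig(seed=8, n_families=80, lambda_background=0.003,
                        giant_multiplier=2.0,
                        giant_branches=frozenset(list(tree.branches())[:2]))
        table, _ = simulate_counts(tree, cfg)
        classes = {v: "giant" for v in list(tree.branches())[:2]}
        fit = fit_lambda(table, tree, classes, n_starts=5, seed=0)
        best = max(fit.start_logliks)
        assert all(best - ll < 1e-4 for ll in fit.start_logliks)


def bruteforce_marginal(table_row, tree, model, node):
    """Exhaustive marginal size distribution at one internal node."""
    S = model.s_max + 1
    kernels = {v: transition_matrix(model.lam_of(v), tree.duration(v),
                                    model.s_max)[0]
               for v in tree.branches()}
    pi = model.prior()
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    obs = {t: table_row[tree.tip_label[t]] for t in tree.tips}
    marg = np.zeros(S)
    for combo in itertools.product(range(S), repeat=len(internals)):
        sizes = dict(zip(internals, combo))
        p = pi[sizes[tree.root]]
        for v in tree.branches():
            ps = sizes[tree.parent[v]]
            p *= kernels[v][ps, obs[v] if tree.is_tip(v) else sizes[v]]
        marg[sizes[node]] += p
    return marg / marg.sum()


class TestAncestralStates:
    def test_matches_exhaustive_enumeration(self):
        tree = read_newick("((A:4,B:6):3,C:10);")
        model = BDModel(lam={"background": 0.03}, s_max=10)
        table = counts_table(tree, {"f": [2, 2, 5]})
        anc = ancestral_states(table, tree, model)
        for node in range(tree.n_nodes):
            if tree.is_tip(node):
                continue
            expected = bruteforce_marginal({"A": 2, "B": 2, "C": 5}, tree,
                                           model, node)
            assert np.allclose(anc.marginals[0, node], expected, atol=1e-10)

    def test_marginals_normalized_and_tips_observed(self):
        tree = simulate_tree(6, seed=2)
        cfg = SimConfig(seed=3, n_families=50, lambda_background=0.002)
        table, _ = simulate_counts(tree, cfg)
        model = BDModel(lam={"background": 0.002}, s_max=40)
        anc = ancestral_states(table, tree, model)
        assert np.allclose(anc.marginals.sum(axis=2), 1.0, atol=1e-9)
        for i, tip in enumerate(tree.tips):
            col = table.counts[tree.tip_label[tip]].to_numpy()
            assert (anc.modes[:, tip] == col).all()

    def test_frozen_process_propagates_tip_value(self):
        tree = read_newick("((A:4,B:6):3,C:10);")
        model = BDModel(lam={"background": 1e-9}, s_max=10)
        table = counts_table(tree, {"f": [4, 4, 4]})
        anc = ancestral_states(table, tree, model)
        assert (anc.modes[0] == 4).all()


class TestBranchShifts:
    def test_point_mass_row_gives_p_one(self):
        tree = read_newick("(A:10,B:10);")
        model = BDModel(lam={"background": 0.0}, s_max=10,
                        root_prior=("point", 2), min_surviving=0)
        table = counts_table(tree, {"f": [2, 2]})
        anc = ancestral_states(table, tree, model)
        pv = branch_shift_pvalues(anc)
        assert (pv.to_numpy() == 1.0).all()

    def test_improbable_jump_equals_row_tail_sum(self):
        tree = read_newick("(A:10,B:10);")
        lam, s_max = 0.002, 30
        model = BDModel(lam={"background": lam}, s_max=s_max,
                        root_prior=("point", 2), min_surviving=0)
        table = counts_table(tree, {"f": [9, 2]})
        anc = ancestral_states(table, tree, model)
        pv = branch_shift_pvalues(anc)
        a_branch = tree.node_by_label("A")
        s = anc.modes[0, tree.parent[a_branch]]
        P, _ = transition_matrix(lam, 10, s_max)
        row = P[s]
        expected = row[row <= row[9] * (1 + 1e-12)].sum()
        assert pv.loc["f", a_branch] == pytest.approx(expected, rel=1e-12)
        assert pv.loc["f", a_branch] < 1e-4

    def test_burst_branch_accumulates_most_flags(self):
        tree = simulate_tree(8, seed=21)
        burst = list(tree.branches())[3]
        cfg = SimConfig(seed=5, n_families=400, lambda_background=0.001,
                        giant_multiplier=5.0, giant_branches=frozenset({burst}))
        table, _ = simulate_counts(tree, cfg)
        model = BDModel(lam={"background": 0.001}, s_max=60)
        anc = ancestral_states(table, tree, model, store_marginals=False)
        pv = branch_shift_pvalues(anc)
        flags = (pv < 0.05).sum(axis=0)
        assert flags.idxmax() == burst

    def test_rate_arithmetic(self):
        tree = read_newick("(A:10,B:10);")
        anc = AncestralSizes(
            family_ids=["f"], modes=np.array([[7, 4, 4]]), marginals=None,
            tree=tree, model=BDModel(lam={"background": 0.01}, s_max=10))
        rates = branch_rates(anc, tree)
        assert rates.loc["f", tree.node_by_label("A")] == pytest.approx(0.3)
        assert rates.loc["f", tree.node_by_label("B")] == pytest.approx(0.0)
        assert (rates.to_numpy() >= 0).all()
        assert np.isfinite(rates.to_numpy()).all()
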