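"""Cancer-gene × gigantism analyses on shifted gene families.

Given per-(family, branch) shift p-values and branch rates from the
birth-death stage, this module builds the shifted-family sets (any branch,
restricted to a focal branch set, or exclusive to it), tests those sets for
enrichment of an external family set (e.g. cancer-census orthologs) with the
exact 2x2 test, controls the focal test with a sister-branch set and with a
permutation null over random branch draws, fits a random-intercept linear
mixed model of rate on giant × cancer, and reports giant/background mean-rate
ratios stratified by cancer status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import ContingencyTable, EnrichmentResult, fisher_exact
from .errors import BranchSetError, FitError
from .io import BranchSet, GeneSet
from .trees import TimeTree

__all__ = [
    "ShiftSets", "PermutationResult", "InteractionFit", "RateRatioReport",
    "shifted_sets", "branch_set_enrichment", "sister_control",
    "permutation_pvalue", "permutation_null", "interaction_model", "rate_ratio",
]

log = logging.getLogger(__name__)


@dataclass
class ShiftSets:
    """Shifted-family sets derived from a families × branches p-value table."""

    all_shifted: frozenset[str]
    per_set: dict[str, frozenset[str]]         # shift on >= 1 branch of the set
    exclusive: dict[str, frozenset[str]]       # shifts only on set branches
    mean_shift_branches: float                 # mean #shift branches per shifted family


def shifted_sets(pvalues: pd.DataFrame, sets: Sequence[BranchSet],
                 alpha: float = 0.05) -> ShiftSets:
    """Build shifted-family sets at the per-branch significance level ``alpha``."""
    branch_cols = set(pvalues.columns)
    flags = pvalues < alpha
    any_shift = flags.any(axis=1)
    all_shifted = frozenset(pvalues.index[any_shift])
    n_shift = flags.sum(axis=1)
    mean_branches = float(n_shift[any_shift].mean()) if any_shift.any() else 0.0

    per_set: dict[str, frozenset[str]] = {}
    exclusive: dict[str, frozenset[str]] = {}
    for bs in sets:
        unknown = set(bs.branches) - branch_cols
        if unknown:
            raise BranchSetError(f"branch set {bs.name!r}: branches {sorted(unknown)} "
                                 "missing from the shift table")
        inset = sorted(bs.branches)
        outset = sorted(branch_cols - bs.branches)
        on_set = flags[inset].any(axis=1)
        off_set = flags[outset].any(axis=1) if outset else pd.Series(False, index=flags.index)
        per_set[bs.name] = frozenset(pvalues.index[on_set])
        exclusive[bs.name] = frozenset(pvalues.index[on_set & ~off_set])
    return ShiftSets(all_shifted=all_shifted, per_set=per_set,
                     exclusive=exclusive, mean_shift_branches=mean_branches)


def _enrichment_2x2(shifted_on_focal: frozenset[str], universe: set[str],
                    cancer: set[str], name: str) -> EnrichmentResult:
    if not universe:
        raise FitError("empty universe for enrichment")
    focal = shifted_on_focal & universe
    canc = cancer & universe
    a = len(focal & canc)
    b = len(focal) - a
    c = len(canc) - a
    d = len(universe) - len(focal) - c
    tab = ContingencyTable(a, b, c, d)
    oddsr, p = fisher_exact(tab)
    return EnrichmentResult(name, tab, oddsr, p)


def branch_set_enrichment(shift_sets: ShiftSets, focal: BranchSet,
                          cancer: GeneSet, universe: str = "all_shifted",
                          all_families: Iterable[str] | None = None
                          ) -> EnrichmentResult:
    """2x2 enrichment of ``cancer`` among families shifted on the focal branches.

    ``universe="all_families"`` tests focal-shifted vs all families (requires
    ``all_families``); ``universe="all_shifted"`` restricts the universe to
    families shifted anywhere, isolating *where* shifts happen from *whether*
    they happen.
    """
    if focal.name not in shift_sets.per_set:
        raise BranchSetError(f"focal set {focal.name!r} not present in shift sets")
    if universe == "all_shifted":
        uni = set(shift_sets.all_shifted)
    elif universe == "all_families":
        if all_families is None:
            raise ValueError("universe='all_families' requires the family list")
        uni = set(all_families)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    return _enrichment_2x2(shift_sets.per_set[focal.name], uni,
                           set(cancer.families), f"{focal.name}|{universe}")


def sister_control(shift_sets: ShiftSets, sister: BranchSet, cancer: GeneSet,
                   universe: str = "all_shifted",
                   all_families: Iterable[str] | None = None) -> EnrichmentResult:
    """Same contract as :func:`branch_set_enrichment`, with the sister set.

    The sister branches (non-giant lineages sister to each giant) form a
    specificity control: a giant-specific signal should vanish here.
    """
    if len(sister) == 0:
        raise BranchSetError("empty sister branch set")
    return branch_set_enrichment(shift_sets, sister, cancer, universe,
                                 all_families)


def permutation_pvalue(observed_or: float, null_or: np.ndarray,
                       two_sided: bool = False) -> float:
    """Rank-based permutation p: fraction of null ORs >= the observed OR.

    Invariant under monotone transforms of the OR; ``two_sided`` doubles the
    smaller tail (capped at 1).
    """
    null_or = np.asarray(null_or, dtype=float)
    p_hi = float((null_or >= observed_or).mean())
    if not two_sided:
        return p_hi
    p_lo = float((null_or <= observed_or).mean())
    return min(1.0, 2.0 * min(p_hi, p_lo))


@dataclass
class PermutationResult:
    """Observed OR against a null of random branch draws."""

    observed_or: float
    null_or: np.ndarray
    n_permutations: int
    p: float
    n_degenerate: int = 0


def permutation_null(pvalues: pd.DataFrame, tree: TimeTree, cancer: GeneSet,
                     k: int = 6, n_perm: int = 100, seed: int = 0,
                     universe: str = "all_shifted",
                     all_families: Iterable[str] | None = None,
                     observed: EnrichmentResult | None = None,
                     focal: BranchSet | None = None,
                     alpha: float = 0.05, two_sided: bool = False
                     ) -> PermutationResult:
    """Permutation null for a branch-set enrichment odds ratio.

    Each permutation draws ``k`` distinct branches uniformly from all branches
    of the tree, rebuilds the shifted-on-set family set, and recomputes the OR
    on the same universe.  ``p = #(null OR >= observed) / n_perm`` (rank
    based, hence invariant to monotone transforms of the OR); with
    ``two_sided`` the more extreme tail is doubled.  Degenerate permuted
    tables contribute OR = 1 with a logged count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    branches = [b for b in tree.branches() if b in set(pvalues.columns)]
    if k > len(branches):
        raise BranchSetError(f"k={k} exceeds the {len(branches)} usable branches")
    if observed is None:
        if focal is None:
            raise ValueError("provide either `observed` or `focal`")
        ss = shifted_sets(pvalues, [focal], alpha=alpha)
        observed = branch_set_enrichment(ss, focal, cancer, universe, all_families)
    obs_or = observed.odds_ratio

    rng = np.random.default_rng(seed)
    null_or = np.empty(n_perm)
    n_degen = 0
    for i in range(n_perm):
        draw = rng.choice(len(branches), size=k, replace=False)
        bs = BranchSet(f"perm{i}", frozenset(branches[j] for j in draw))
        ss = shifted_sets(pvalues, [bs], alpha=alpha)
        res = branch_set_enrichment(ss, bs, cancer, universe, all_families)
        if res.table.degenerate() or not np.isfinite(res.odds_ratio):
            null_or[i] = 1.0
            n_degen += 1
        else:
            null_or[i] = res.odds_ratio
    if n_degen:
        log.warning("permutation_null: %d degenerate permutations set to OR=1",
                    n_degen)
    p = permutation_pvalue(obs_or, null_or, two_sided=two_sided)
    return PermutationResult(observed_or=float(obs_or), null_or=null_or,
                             n_permutations=n_perm, p=p, n_degenerate=n_degen)


@dataclass
class InteractionFit:
    """Random-intercept model of branch rate on giant × cancer."""

    params: pd.Series          # intercept, giant, cancer, giant:cancer
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    re_variance: float         # random-intercept (family) variance
    resid_variance: float
    n_obs: int
    n_groups: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse,
                             "z": self.zvalues, "p": self.pvalues})


def _rates_long(rates: pd.DataFrame, giant: BranchSet,
                cancer: GeneSet, log1p: bool) -> pd.DataFrame:
    long = rates.stack().rename("rate").reset_index()
    long.columns = ["family", "branch", "rate"]
    if log1p:
        long["rate"] = np.log1p(long["rate"])
    long["giant"] = long["branch"].isin(giant.branches).astype(float)
    long["cancer"] = long["family"].isin(cancer.families).astype(float)
    long["interaction"] = long["giant"] * long["cancer"]
    return long


class _ProfiledLMM:
    """ML random-intercept model via the profiled variance ratio.

    With θ = σ_u²/σ_ε², each group's covariance is σ_ε²(I + θJ); the Woodbury
    identity gives a closed-form GLS inner solve from per-group sufficient
    statistics, σ_ε² is profiled out in closed form, and the likelihood is
    maximized over the single ratio θ by bounded scalar search (the θ = 0
    boundary is evaluated explicitly, where the fit *is* ordinary least
    squares).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        uniq, inv = np.unique(groups, return_inverse=True)
        self.n_groups = len(uniq)
        self.ng = np.bincount(inv).astype(float)
        p = self.p
        self.XtX = np.zeros((self.n_groups, p, p))
        self.Xty = np.zeros((self.n_groups, p))
        self.yty = np.zeros(self.n_groups)
        self.sx = np.zeros((self.n_groups, p))
        self.sy = np.zeros(self.n_groups)
        for g in range(self.n_groups):
            idx = inv == g
            Xg, yg = X[idx], y[idx]
            self.XtX[g] = Xg.T @ Xg
            self.Xty[g] = Xg.T @ yg
            self.yty[g] = yg @ yg
            self.sx[g] = Xg.sum(axis=0)
            self.sy[g] = yg.sum()

    def _gls(self, theta: float):
        c = theta / (1.0 + self.ng * theta)              # per-group shrinkage
        A = (self.XtX - np.einsum("g,gi,gj->gij", c, self.sx, self.sx)).sum(0)
        b = (self.Xty - (c * self.sy)[:, None] * self.sx).sum(0)
        yy = float((self.yty - c * self.sy ** 2).sum())
        beta = np.linalg.solve(A, b)
        rss = yy - 2 * beta @ b + beta @ A @ beta
        return beta, A, max(rss, 1e-300)

    def loglik(self, theta: float) -> float:
        _, _, rss = self._gls(theta)
        sigma2 = rss / self.n
        logdet = float(np.log1p(self.ng * theta).sum())
        return -0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdet + self.n)

    def fit(self):
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda u: -self.loglik(10.0 ** u),
                              bounds=(-8.0, 6.0), method="bounded",
                              options={"xatol": 1e-6})
        cands = [(self.loglik(0.0), 0.0)]
        if np.isfinite(res.fun):
            cands.append((-res.fun, 10.0 ** res.x))
        ll, theta = max(cands)
        beta, A, rss = self._gls(theta)
        sigma2 = rss / self.n
        cov = sigma2 * np.linalg.inv(A)
        return beta, np.sqrt(np.diag(cov)), theta * sigma2, sigma2, ll


def interaction_model(rates: pd.DataFrame, giant: BranchSet, cancer: GeneSet,
                      log1p: bool = False) -> InteractionFit:
    """ML fit of rate ~ giant * cancer with a random intercept per family.

    ``rates`` is a families × branches table (typically restricted to the
    shifted families).  Fixed effects are tested with Wald statistics against
    a normal reference.  A rank-deficient design (e.g. no cancer family, or
    no giant branch among the columns) raises, naming the collinear term.
    When the fitted random-intercept variance is zero the coefficients reduce
    exactly to ordinary least squares.
    """
    if rates.shape[0] < 2:
        raise FitError("need >= 2 families")
    long = _rates_long(rates, giant, cancer, log1p)
    names = ["intercept", "giant", "cancer", "giant:cancer"]
    X = np.column_stack([np.ones(len(long)), long["giant"], long["cancer"],
                         long["interaction"]])
    for col, name in zip(range(1, 4), names[1:]):
        if np.ptp(X[:, col]) == 0:
            raise FitError(f"design is rank deficient: term {name!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design is rank deficient: collinear giant/cancer terms")

    lmm = _ProfiledLMM(long["rate"].to_numpy(float), X,
                       long["family"].to_numpy())
    beta, se, var_u, var_e, _ = lmm.fit()
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    z = params / bse
    pvals = pd.Series(2 * norm.sf(np.abs(z)), index=names)
    return InteractionFit(params=params, bse=bse, zvalues=z, pvalues=pvals,
                          re_variance=float(var_u), resid_variance=float(var_e),
                          n_obs=len(long), n_groups=rates.shape[0],
                          converged=True)


@dataclass
class RateRatioReport:
    """Giant/background mean-rate ratios, by cancer stratum."""

    mean_giant_cancer: float
    mean_other_cancer: float
    ratio_cancer: float
    mean_giant_noncancer: float
    mean_other_noncancer: float
    ratio_noncancer: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": ["cancer", "non_cancer"],
                "mean_giant_rate": [self.mean_giant_cancer, self.mean_giant_noncancer],
                "mean_other_rate": [self.mean_other_cancer, self.mean_other_noncancer],
                "ratio": [self.ratio_cancer, self.ratio_noncancer],
            }
        )


def rate_ratio(rates: pd.DataFrame, giant: BranchSet,
               cancer: GeneSet) -> RateRatioReport:
    """Mean giant-branch rate over mean other-branch rate, per cancer stratum.

    Means pool all (family, branch) observations within the stratum; a zero
    denominator yields an infinite ratio (flagged by the value itself).
    """
    giant_cols = [c for c in rates.columns if c in giant.branches]
    other_cols = [c for c in rates.columns if c not in giant.branches]
    if not giant_cols or not other_cols:
        raise FitError("need both giant and non-giant branches in the rate table")
    is_cancer = rates.index.isin(cancer.families)
    if not is_cancer.any() or is_cancer.all():
        raise FitError("need both cancer and non-cancer families")

    def _pair(mask):
        g = float(rates.loc[mask, giant_cols].to_numpy().mean())
        o = float(rates.loc[mask, other_cols].to_numpy().mean())
        ratio = g / o if o > 0 else float("inf")
        if o == 0:
            log.warning("rate_ratio: zero background mean; infinite ratio")
        return g, o, ratio

    gc, oc, rc = _pair(is_cancer)
    gn, on, rn = _pair(~is_cancer)
    return RateRatioReport(mean_giant_cancer=gc, mean_other_cancer=oc,
                           ratio_cancer=rc, mean_giant_noncancer=gn,
                           mean_other_noncancer=on, ratio_noncancer=rn)
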