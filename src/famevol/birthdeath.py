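"""Birth-death model of gene-family size evolution on a time tree.

The family-size process is the linear birth-death process with equal per-gene
gain and loss rate λ (per gene per My).  Over a branch of duration t the
transition probability from parent size s to child size c has the closed form

    P(c | s) = Σ_{j=0}^{min(s,c)} C(s, j) C(s+c-j-1, s-1)
               α^{s+c-2j} (1-2α)^j,          α = λt / (1 + λt),

with size 0 absorbing (an extinct family cannot re-appear).  Likelihoods are
computed by Felsenstein pruning over sizes 0..s_max (truncated, rows
renormalized; the pre-renormalization deficit is monitored).  The root size
follows a configurable prior (default: geometric, p = 0.5, truncated to
1..s_max) and the likelihood is conditioned on the family being non-extinct
in at least ``min_surviving`` tips, mirroring the present-in-at-least-two-
species filter applied to real orthogroup tables.

Beyond likelihoods the module provides maximum-likelihood fitting of one rate
per branch class, a parametric-bootstrap likelihood-ratio test between nested
class maps, marginal ancestral size reconstruction (posterior mode, ties
toward the smaller size), per-branch exact shift p-values (probability-
ordering tail of the fitted kernel row) and branch-wise size-change rates
|Δsize| / t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .errors import FitError
from .io import FamilyCountTable
from .trees import TimeTree

__all__ = [
    "BDModel", "BDFit", "AncestralSizes", "LRTResult", "transition_prob",
    "transition_matrix", "family_loglik", "table_loglik", "fit_lambda",
    "lrt_bootstrap", "ancestral_states", "branch_shift_pvalues", "branch_rates",
]

log = logging.getLogger(__name__)

_LAMBDA_BOUNDS = (1e-8, 0.3)  # per gene per My; generous around empirical ~1e-3


# ------------------------------------------------------------------- kernel
_coef_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}


def _kernel_coefficients(s_max: int):
    """Cache the α-independent pieces of the kernel for sizes 1..s_max.

    Returns (logC, expA, expJ, parity) with axes (s-1, c, j): log of the two
    binomials (−inf where j > min(s, c)), the exponent of α (= s+c−2j), the
    exponent of |1−2α| (= j), and the sign (−1)^j used when 1−2α < 0.
    """
    if s_max in _coef_cache:
        return _coef_cache[s_max]
    s = np.arange(1, s_max + 1)[:, None, None]
    c = np.arange(0, s_max + 1)[None, :, None]
    j = np.arange(0, s_max + 1)[None, None, :]
    valid = j <= np.minimum(s, c)
    js = np.where(valid, j, 0)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logc = logC(s, js) + logC(s + c - js - 1, s - 1)
    logc = np.where(valid, logc, -np.inf)
    expA = (s + c - 2 * js).astype(float)
    expJ = js.astype(float)
    parity = np.where(js % 2 == 1, -1.0, 1.0)
    _coef_cache[s_max] = (logc, expA, expJ, parity)
    return _coef_cache[s_max]


def _alpha(lam: float, t: float) -> float:
    return lam * t / (1.0 + lam * t)


def transition_matrix(lam: float, t: float, s_max: int,
                      renormalize: bool = True) -> tuple[np.ndarray, float]:
    """(s_max+1)² transition matrix P[s, c] and the maximum truncation deficit.

    Row 0 is the absorbing extinct state.  With ``renormalize`` each row is
    rescaled to sum to one after truncation at ``s_max``; the returned deficit
    is the largest pre-renormalization mass lost to sizes above ``s_max``.
    """
    if lam < 0 or t < 0:
        raise ValueError("negative rate or duration")
    S = s_max + 1
    P = np.zeros((S, S))
    P[0, 0] = 1.0
    a = _alpha(lam, t)
    if a == 0.0:
        np.fill_diagonal(P, 1.0)
        return P, 0.0
    logc, expA, expJ, parity = _kernel_coefficients(s_max)
    one_m2a = 1.0 - 2.0 * a
    with np.errstate(divide="ignore"):
        log_terms = logc + expA * np.log(a) + expJ * np.log(abs(one_m2a))
    body = np.exp(log_terms)  # exp(-inf) -> 0 for invalid j
    if one_m2a < 0:  # λt > 1: the j-terms alternate in sign
        body = body * parity
    P[1:, :] = np.maximum(body.sum(axis=2), 0.0)
    rowsum = P[1:].sum(axis=1)
    deficit = float(np.max(1.0 - rowsum)) if s_max >= 1 else 0.0
    if renormalize:
        P[1:] /= rowsum[:, None]
    return P, deficit


def transition_prob(s: int, c: int, lam: float, t: float,
                    s_max: int | None = None) -> float:
    """Single transition probability P(child = c | parent = s) (untruncated form)."""
    if min(s, c) < 0 or lam < 0 or t < 0:
        raise ValueError("negative input")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    a = _alpha(lam, t)
    if a == 0.0:
        return 1.0 if c == s else 0.0
    j = np.arange(0, min(s, c) + 1)
    logc = (gammaln(s + 1) - gammaln(j + 1) - gammaln(s - j + 1)
            + gammaln(s + c - j) - gammaln(s) - gammaln(c - j + 1))
    terms = np.exp(logc + (s + c - 2 * j) * np.log(a)) * (1.0 - 2.0 * a) ** j
    return float(max(terms.sum(), 0.0))


# -------------------------------------------------------------------- model
@dataclass
class BDModel:
    """Birth-death model: one λ per branch class on a given tree.

    ``classes`` maps branch (child-node) IDs to class names; branches not in
    the map belong to ``"background"``.  ``root_prior`` is ``("geometric", p)``
    (truncated to 1..s_max), ``("uniform",)`` or ``("point", k)``.
    """

    lam: dict[str, float]
    classes: dict[int, str] = field(default_factory=dict)
    s_max: int = 100
    root_prior: tuple = ("geometric", 0.5)
    min_surviving: int = 2

    def class_of(self, branch: int) -> str:
        return self.classes.get(branch, "background")

    def lam_of(self, branch: int) -> float:
        return self.lam[self.class_of(branch)]

    def prior(self) -> np.ndarray:
        S = self.s_max + 1
        pi = np.zeros(S)
        kind = self.root_prior[0]
        if kind == "geometric":
            p = self.root_prior[1]
            s = np.arange(1, S)
            pi[1:] = (1 - p) ** (s - 1) * p
        elif kind == "uniform":
            pi[1:] = 1.0
        elif kind == "point":
            pi[int(self.root_prior[1])] = 1.0
        else:
            raise ValueError(f"unknown root prior {self.root_prior!r}")
        return pi / pi.sum()


def _branch_kernels(model: BDModel, tree: TimeTree) -> dict[int, np.ndarray]:
    kernels: dict[int, np.ndarray] = {}
    cache: dict[tuple[float, float], np.ndarray] = {}
    worst = 0.0
    for v in tree.branches():
        key = (model.lam_of(v), tree.duration(v))
        if key not in cache:
            P, deficit = transition_matrix(*key, model.s_max)
            worst = max(worst, deficit)
            cache[key] = P
        kernels[v] = cache[key]
    if worst > 1e-6:
        log.debug("kernel truncation deficit %.3g at s_max=%d", worst, model.s_max)
    return kernels


def _prune(tipcond: Mapping[int, np.ndarray], tree: TimeTree,
           kernels: Mapping[int, np.ndarray],
           keep_partials: bool = False):
    """Felsenstein pruning with per-row log-scaling.

    ``tipcond[tip]`` is an (n_rows, S) conditional-likelihood block.  Returns
    (root partials, log-scale per row[, partials per node]).
    """
    n_rows, S = next(iter(tipcond.values())).shape
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_rows)
    for v in tree.postorder():
        if tree.is_tip(v):
            partials[v] = tipcond[v]
            continue
        acc = None
        for ch in tree.children[v]:
            msg = partials[ch] @ kernels[ch].T
            acc = msg if acc is None else acc * msg
            if not keep_partials:
                del partials[ch]
        scale = acc.max(axis=1)
        scale[scale == 0] = 1.0
        acc = acc / scale[:, None]
        logscale += np.log(scale)
        partials[v] = acc
    if keep_partials:
        return partials, logscale
    return partials[tree.root], logscale


def _survival_condition(model: BDModel, tree: TimeTree,
                        kernels: Mapping[int, np.ndarray],
                        tipcond: Mapping[int, np.ndarray] | None = None) -> float:
    """P(family survives in >= min_surviving tips | root prior)."""
    m = model.min_surviving
    if m <= 0:
        return 1.0
    tips = tree.tips
    N = len(tips)
    if tipcond is None:
        tipcond = _survival_tipcond(tree, model.s_max, m)
    root_part, logscale = _prune(tipcond, tree, kernels)
    pi = model.prior()
    vals = (root_part * pi[None, :]).sum(axis=1) * np.exp(logscale)
    p_all_extinct = vals[0]
    if m == 1:
        cond = 1.0 - p_all_extinct
    else:
        # P(<=1 survives) = sum_k P(all but k extinct) - (N-1) P(all extinct)
        p_le1 = vals[1:].sum() - (N - 1) * p_all_extinct
        cond = 1.0 - p_le1
    if cond <= 0:
        raise FitError("survival conditioning probability underflowed to <= 0")
    return float(cond)


def _survival_tipcond(tree: TimeTree, s_max: int, m: int) -> dict[int, np.ndarray]:
    S = s_max + 1
    tips = tree.tips
    N = len(tips)
    extinct = np.zeros(S)
    extinct[0] = 1.0
    n_rows = 1 + (N if m >= 2 else 0)
    tipcond = {}
    for i, tip in enumerate(tips):
        block = np.tile(extinct, (n_rows, 1))
        if m >= 2:
            block[1 + i] = np.ones(S)
        tipcond[tip] = block
    return tipcond


def _tip_conditionals(table: FamilyCountTable, tree: TimeTree,
                      s_max: int) -> dict[int, np.ndarray]:
    table.check_against_tree(tree)
    n_fam = table.n_families()
    S = s_max + 1
    out = {}
    for tip in tree.tips:
        counts = table.counts[tree.tip_label[tip]].to_numpy()
        if counts.max(initial=0) > s_max:
            raise FitError(f"observed count {counts.max()} exceeds s_max={s_max}")
        block = np.zeros((n_fam, S))
        block[np.arange(n_fam), counts] = 1.0
        out[tip] = block
    return out


class _Engine:
    """Precomputed pruning state for repeated likelihood evaluation.

    Tip conditionals, survival-pattern conditionals and branch durations are
    built once; only the per-branch kernels change with λ during a fit.
    """

    def __init__(self, table: FamilyCountTable, tree: TimeTree, s_max: int,
                 root_prior: tuple, min_surviving: int):
        if (table.counts.to_numpy().sum(axis=1) == 0).any():
            raise FitError("all-zero family in the table")
        self.tree = tree
        self.s_max = s_max
        self.root_prior = root_prior
        self.min_surviving = min_surviving
        self.tipcond = _tip_conditionals(table, tree, s_max)
        self.surv_tipcond = (_survival_tipcond(tree, s_max, min_surviving)
                             if min_surviving > 0 else None)
        self.durations = {v: tree.duration(v) for v in tree.branches()}
        self._model = BDModel(lam={}, s_max=s_max, root_prior=root_prior,
                              min_surviving=min_surviving)
        self.prior = self._model.prior()
        self._kcache: dict[tuple[float, float], np.ndarray] = {}

    def kernels(self, branch_lam: Mapping[int, float]) -> dict[int, np.ndarray]:
        out = {}
        for v, t in self.durations.items():
            key = (branch_lam[v], t)
            P = self._kcache.get(key)
            if P is None:
                P, _ = transition_matrix(*key, self.s_max)
                if len(self._kcache) > 4096:
                    self._kcache.clear()
                self._kcache[key] = P
            out[v] = P
        return out

    def loglik(self, branch_lam: Mapping[int, float]) -> np.ndarray:
        kernels = self.kernels(branch_lam)
        root_part, logscale = _prune(self.tipcond, self.tree, kernels)
        lik = (root_part * self.prior[None, :]).sum(axis=1)
        if (lik <= 0).any():
            raise FitError("zero likelihood for some family (check s_max / counts)")
        if self.surv_tipcond is None:
            logcond = 0.0
        else:
            cond = _survival_condition(self._model, self.tree, kernels,
                                       self.surv_tipcond)
            logcond = np.log(cond)
        return np.log(lik) + logscale - logcond


def table_loglik(table: FamilyCountTable, tree: TimeTree,
                 model: BDModel) -> np.ndarray:
    """Per-family log-likelihood under the model (survival-conditioned)."""
    eng = _Engine(table, tree, model.s_max, model.root_prior, model.min_surviving)
    return eng.loglik({v: model.lam_of(v) for v in tree.branches()})


def family_loglik(counts_row: Mapping[str, int] | pd.Series, tree: TimeTree,
                  model: BDModel) -> float:
    """Log-likelihood of a single family's count vector."""
    df = pd.DataFrame([dict(counts_row)], index=["fam"])
    return float(table_loglik(FamilyCountTable(df), tree, model)[0])


# ------------------------------------------------------------------ fitting
@dataclass
class BDFit:
    """Result of maximum-likelihood rate fitting."""

    model: BDModel
    loglik: float
    per_family_loglik: np.ndarray
    converged: bool
    n_evals: int
    start_logliks: list[float] = field(default_factory=list)

    @property
    def lam(self) -> dict[str, float]:
        return self.model.lam


def suggest_s_max(table: FamilyCountTable, cap: int = 100,
                  margin: float = 2.0, floor: int = 15) -> int:
    """Truncation bound adequate for a table: ~margin × the largest count."""
    mx = int(table.counts.to_numpy().max(initial=1))
    return int(min(cap, max(floor, np.ceil(margin * mx) + 5)))


def fit_lambda(table: FamilyCountTable, tree: TimeTree,
               classes: Mapping[int, str] | None = None, *,
               s_max: int | None = None, root_prior: tuple = ("geometric", 0.5),
               min_surviving: int = 2, n_starts: int = 5, seed: int = 0,
               x0: Mapping[str, float] | None = None,
               xatol: float = 1e-4, fatol: float = 1e-6,
               max_evals: int = 500) -> BDFit:
    """Maximize the summed family log-likelihood over one λ per branch class.

    Bounded derivative-free optimization on log10 λ: Brent's method for a
    single class, Nelder-Mead (restarted from ``n_starts`` seeded random
    starts) for several classes.  Non-convergence is flagged on the result,
    never silent.
    """
    if table.n_families() < 1:
        raise FitError("no families to fit")
    classes = dict(classes or {})
    class_names = sorted({"background", *classes.values()})
    if s_max is None:
        s_max = suggest_s_max(table)
    lo, hi = np.log10(_LAMBDA_BOUNDS)
    rng = np.random.default_rng(seed)
    n_eval = 0
    engine = _Engine(table, tree, s_max, root_prior, min_surviving)
    branch_class = {v: classes.get(v, "background") for v in tree.branches()}

    def loglik_of(x: np.ndarray) -> float:
        lam = {cn: float(10.0 ** xi) for cn, xi in zip(class_names, x)}
        return float(engine.loglik({v: lam[c] for v, c in branch_class.items()}).sum())

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        x = np.clip(x, lo, hi)
        try:
            return -loglik_of(x)
        except FitError:
            return np.inf

    converged = True
    start_logliks: list[float] = []
    if len(class_names) == 1:
        res = minimize_scalar(lambda x: objective(np.array([x])),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol, "maxiter": max_evals})
        best_x = np.array([np.clip(res.x, lo, hi)])
        best_f = res.fun
        converged = bool(res.success)
        start_logliks.append(-best_f)
    else:
        starts = []
        if x0 is not None:
            starts.append(np.log10([max(x0.get(cn, 1e-4), _LAMBDA_BOUNDS[0])
                                    for cn in class_names]))
        while len(starts) < max(n_starts, 1):
            starts.append(rng.uniform(lo + 1, hi - 1, size=len(class_names)))
        best_x, best_f = None, np.inf
        for st in starts:
            res = minimize(objective, st, method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": fatol,
                                    "maxfev": max_evals})
            start_logliks.append(-res.fun)
            if res.fun < best_f:
                best_f, best_x = res.fun, np.clip(res.x, lo, hi)
                converged = bool(res.success)
    if not np.isfinite(best_f):
        raise FitError("likelihood not finite at any evaluated rate")

    lam = {cn: float(10.0 ** xi) for cn, xi in zip(class_names, best_x)}
    model = BDModel(lam=lam, classes=classes, s_max=s_max,
                    root_prior=root_prior, min_surviving=min_surviving)
    pf = engine.loglik({v: lam[c] for v, c in branch_class.items()})
    if not converged:
        log.warning("fit_lambda did not converge after %d evaluations", n_eval)
    return BDFit(model=model, loglik=float(pf.sum()), per_family_loglik=pf,
                 converged=converged, n_evals=n_eval,
                 start_logliks=start_logliks)


@dataclass
class LRTResult:
    """Parametric-bootstrap likelihood-ratio test between nested class maps."""

    observed: float
    null_stats: np.ndarray
    p: float
    n_reps: int
    n_dropped: int
    null_fit: BDFit
    alt_fit: BDFit

    @property
    def p_label(self) -> str:
        n = len(self.null_stats)
        return f"< {1.0 / n:g}" if self.p == 0 and n else f"{self.p:g}"


def lrt_bootstrap(table: FamilyCountTable, tree: TimeTree,
                  null_classes: Mapping[int, str] | None,
                  alt_classes: Mapping[int, str], *, n_reps: int = 500,
                  seed: int = 0, s_max: int | None = None,
                  n_starts: int = 1, min_surviving: int = 2,
                  rep_xatol: float = 5e-3, rep_fatol: float = 5e-3) -> LRTResult:
    """Simulate the null distribution of 2ΔlnL and locate the observed value.

    Each replicate simulates a dataset of equal family count under the fitted
    null model (same root prior and survival conditioning) and refits both
    models; p is the fraction of convergent replicates with a statistic at
    least as large as observed.  Replicates that fail to converge are dropped
    with a logged count.
    """
    from .simulate import SimConfig, simulate_counts  # local: avoid cycle

    if s_max is None:
        s_max = suggest_s_max(table)
    fit0 = fit_lambda(table, tree, null_classes, s_max=s_max,
                      n_starts=n_starts, seed=seed, min_surviving=min_surviving)
    fit1 = fit_lambda(table, tree, alt_classes, s_max=s_max, n_starts=n_starts,
                      seed=seed, min_surviving=min_surviving,
                      x0={cn: fit0.lam.get(cn, fit0.lam["background"])
                          for cn in {"background", *alt_classes.values()}})
    observed = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))

    rng = np.random.default_rng(seed)
    null_stats, dropped = [], 0
    n_fam = table.n_families()
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        cfg = SimConfig(seed=rep_seed, n_families=n_fam,
                        lambda_background=fit0.lam["background"],
                        giant_multiplier=1.0, s_max=s_max,
                        root_size_prior=fit0.model.root_prior,
                        min_surviving_tips=min_surviving)
        classes_lam = {v: fit0.lam[fit0.model.class_of(v)] for v in tree.branches()}
        sim_table, _ = simulate_counts(tree, cfg, branch_lambda=classes_lam)
        try:
            f0 = fit_lambda(sim_table, tree, null_classes, s_max=s_max,
                            n_starts=1, seed=rep_seed, xatol=rep_xatol,
                            fatol=rep_fatol,
                            min_surviving=min_surviving, x0=fit0.lam)
            f1 = fit_lambda(sim_table, tree, alt_classes, s_max=s_max,
                            n_starts=1, seed=rep_seed, xatol=rep_xatol,
                            fatol=rep_fatol,
                            min_surviving=min_surviving,
                            x0={cn: f0.lam.get(cn, f0.lam["background"])
                                for cn in {"background", *alt_classes.values()}})
        except FitError:
            dropped += 1
            continue
        if not (f0.converged and f1.converged):
            dropped += 1
            continue
        null_stats.append(max(0.0, 2.0 * (f1.loglik - f0.loglik)))
    if dropped:
        log.warning("lrt_bootstrap: dropped %d non-convergent replicates", dropped)
    null_stats = np.asarray(null_stats)
    if null_stats.size == 0:
        raise FitError("all bootstrap replicates failed")
    p = float((null_stats >= observed).mean())
    return LRTResult(observed=observed, null_stats=null_stats, p=p,
                     n_reps=n_reps, n_dropped=dropped, null_fit=fit0,
                     alt_fit=fit1)


# -------------------------------------------------- ancestral reconstruction
@dataclass
class AncestralSizes:
    """Marginal posterior family sizes per node.

    ``modes[f, v]`` is the posterior-mode size of family ``f`` at node ``v``
    (ties broken toward the smaller size); tips carry their observed counts.
    ``marginals`` (optional) holds the full per-node distributions.
    """

    family_ids: list[str]
    modes: np.ndarray                    # (n_fam, n_nodes) int
    marginals: np.ndarray | None         # (n_fam, n_nodes, S) or None
    tree: TimeTree
    model: BDModel

    def modes_frame(self) -> pd.DataFrame:
        cols = [self.tree.label_of(v) for v in range(self.tree.n_nodes)]
        return pd.DataFrame(self.modes, index=self.family_ids, columns=cols)


def ancestral_states(table: FamilyCountTable, tree: TimeTree, model: BDModel,
                     store_marginals: bool = True) -> AncestralSizes:
    """Marginal ancestral sizes by the up-down (outside) algorithm.

    The survival-conditioning factor cancels in per-node marginals (the
    conditioning event is implied by the observed data), so marginals are
    computed under the unconditioned model.
    """
    kernels = _branch_kernels(model, tree)
    tipcond = _tip_conditionals(table, tree, model.s_max)
    below, _ = _prune(tipcond, tree, kernels, keep_partials=True)
    n_fam = table.n_families()
    S = model.s_max + 1

    above: dict[int, np.ndarray] = {tree.root: np.tile(model.prior(), (n_fam, 1))}
    marg = np.zeros((n_fam, tree.n_nodes, S)) if store_marginals else None
    modes = np.zeros((n_fam, tree.n_nodes), dtype=np.int64)

    for u in tree.preorder():
        post = above[u] * below[u]
        Z = post.sum(axis=1, keepdims=True)
        post = post / Z
        if store_marginals:
            marg[:, u, :] = post
        modes[:, u] = np.argmax(post, axis=1)  # argmax → first (smaller) on ties
        if tree.is_tip(u):
            continue
        msgs = {ch: below[ch] @ kernels[ch].T for ch in tree.children[u]}
        for ch in tree.children[u]:
            acc = above[u].copy()
            for sib in tree.children[u]:
                if sib is not ch:
                    acc *= msgs[sib]
            up = acc @ kernels[ch]
            norm = up.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            above[ch] = up / norm
        del above[u]
    return AncestralSizes(family_ids=table.family_ids, modes=modes,
                          marginals=marg, tree=tree, model=model)


def branch_shift_pvalues(anc: AncestralSizes, tree: TimeTree | None = None,
                         model: BDModel | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Exact per-(family, branch) shift p-values on the fitted kernel row.

    For reconstructed parent size s and child size c on a branch, p is the sum
    of the row's transition probabilities not exceeding P(s→c) — the
    probability-ordering exact tail.  Small p flags an improbable size jump
    (a rate shift) on that branch.  Returns a families × branches frame of
    p-values; flags are ``p < alpha``.
    """
    tree = tree or anc.tree
    model = model or anc.model
    kernels = _branch_kernels(model, tree)
    n_fam = len(anc.family_ids)
    cols, data = [], []
    tol = 1.0 + 1e-12
    for v in tree.branches():
        P = kernels[v]
        s = anc.modes[:, tree.parent[v]]
        c = anc.modes[:, v]
        rows = P[s]                                  # (n_fam, S)
        thresh = rows[np.arange(n_fam), c]
        p = (rows * (rows <= thresh[:, None] * tol)).sum(axis=1)
        data.append(np.clip(p, np.finfo(float).tiny, 1.0))
        cols.append(v)
    return pd.DataFrame(np.column_stack(data), index=anc.family_ids,
                        columns=cols)


def branch_rates(anc: AncestralSizes, tree: TimeTree | None = None) -> pd.DataFrame:
    """Branch-wise size-change rates |size(parent) - size(child)| / t (copies/My)."""
    tree = tree or anc.tree
    cols, data = [], []
    for v in tree.branches():
        s = anc.modes[:, tree.parent[v]]
        c = anc.modes[:, v]
        data.append(np.abs(s - c) / tree.duration(v))
        cols.append(v)
    return pd.DataFrame(np.column_stack(data), index=anc.family_ids, columns=cols)
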