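"""Synthetic data with known ground truth.

Every downstream stage of the package has a parameter-recovery or calibration
test against data from this module: a time-calibrated tree, family
presence/absence generated under the single-origin / multiple-loss process the
Dollo reconstruction assumes, family sizes generated by exact inverse-CDF
sampling from the *same* truncated birth-death kernel the likelihood uses
(so parameter recovery is a pure test of the estimator, not of a simulator
mismatch), and cancer/annotation labels with a configurable enrichment effect
linking the cancer label to families that changed size on designated "giant"
branches.

Defaults mirror a desk-scale version of a vertebrate comparative study:
a background gain/loss rate of 6e-4 per gene per My, a two-fold rate
multiplier on giant branches, ~5% of families cancer-labelled, and a
geometric(0.5) root-size distribution conditioned on >= 1 copy.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, asdict
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .birthdeath import transition_matrix
from .errors import SimulationError
from .io import AnnotationMap, FamilyCountTable, GeneSet, PresenceMatrix
from .trees import TimeTree, read_newick

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_presence",
           "simulate_counts", "simulate_labels"]


@dataclass
class SimConfig:
    """Generator configuration; the seed is mandatory.

    ``origin_rate`` is origins per My of branch length; ``loss_probability``
    is per-branch Bernoulli by default (``loss_per_my`` switches to a per-My
    exponential rate), matching the topology-only model class of the Dollo
    reconstruction.  ``enrichment_effect`` is the odds multiplier tilting the
    cancer label toward families that changed size on a giant branch.
    """

    seed: int
    n_families: int = 2000
    origin_rate: float = 1.0                 # origins per My (shape only; count is fixed)
    loss_probability: float = 0.1
    loss_per_my: float | None = None         # alternative: per-My loss rate
    lambda_background: float = 6e-4          # gains/losses per gene per My
    giant_multiplier: float = 2.0
    s_max: int = 100
    root_size_prior: tuple = ("geometric", 0.5)
    giant_branches: frozenset[int] = frozenset()
    min_surviving_tips: int = 2
    fraction_cancer: float = 0.05
    enrichment_effect: float = 3.0
    shift_min_step: int = 2                  # |Δsize| on a giant branch that counts as a shift
    n_terms: int = 40
    term_freq_range: tuple = (0.005, 0.2)
    max_retries: int = 200                   # ×n_families redraw budget

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.origin_rate < 0 or self.lambda_background < 0:
            raise SimulationError("rates must be >= 0")
        if not 0 <= self.loss_probability <= 1:
            raise SimulationError("loss_probability must be in [0, 1]")
        if not 0 <= self.fraction_cancer <= 1:
            raise SimulationError("fraction_cancer must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["giant_branches"] = sorted(self.giant_branches)
        return d


@dataclass
class SimTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    family_ids: list[str]
    origin_branch: np.ndarray | None = None      # node ID per family
    loss_branches: list[frozenset[int]] | None = None
    node_presence: np.ndarray | None = None      # (n_nodes, n_fam) bool
    node_sizes: np.ndarray | None = None         # (n_fam, n_nodes) int
    branch_lambda: dict[int, float] | None = None
    giant_changed: np.ndarray | None = None      # bool per family
    cancer: np.ndarray | None = None             # bool per family

    def to_frame(self) -> pd.DataFrame:
        d: dict = {}
        if self.origin_branch is not None:
            d["origin_branch"] = self.origin_branch
        if self.loss_branches is not None:
            d["loss_branches"] = [",".join(map(str, sorted(s)))
                                  for s in self.loss_branches]
        if self.giant_changed is not None:
            d["giant_changed"] = self.giant_changed.astype(int)
        if self.cancer is not None:
            d["cancer_flag"] = self.cancer.astype(int)
        return pd.DataFrame(d, index=pd.Index(self.family_ids, name="family"))


# ------------------------------------------------------------------- tree
def simulate_tree(n_tips: int = 10, seed: int = 0, depth: float = 450.0,
                  birth_rate: float = 0.02) -> TimeTree:
    """A random time-calibrated tree: a birth (Yule) tree rescaled to ``depth`` My.

    Tip labels are ``sp01..spNN``; the default depth is on the order of the
    vertebrate crown age.
    """
    rng = _random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_tips)])
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng)
    dtree.seed_node.edge.length = None
    height = max(nd.distance_from_root() for nd in dtree.leaf_node_iter())
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= depth / height
    return read_newick(dtree.as_string(schema="newick").strip(),
                       zero_length_epsilon=1e-6)


# --------------------------------------------------------------- presence
def simulate_presence(tree: TimeTree, cfg: SimConfig
                      ) -> tuple[PresenceMatrix, SimTruth]:
    """Single-origin / multiple-loss presence patterns.

    Each family originates on one branch (chosen with probability
    proportional to branch duration, i.e. the Poisson origin process
    conditioned on its total); presence then propagates tipward, and each
    descendant branch independently loses the family (per-branch Bernoulli by
    default, or per-My exponential).  Families extinct at every tip are
    unobservable and redrawn until ``n_families`` survive; a bounded retry
    budget guards the degenerate all-loss regime.
    """
    if cfg.origin_rate <= 0:
        raise SimulationError("origin_rate must be > 0: no families producible")
    rng = np.random.default_rng(cfg.seed)
    branches = tree.branches()
    durations = np.array([tree.duration(v) for v in branches])
    weights = durations / durations.sum()
    if cfg.loss_per_my is not None:
        loss_p = {v: 1.0 - np.exp(-cfg.loss_per_my * tree.duration(v))
                  for v in branches}
    else:
        loss_p = {v: cfg.loss_probability for v in branches}

    n_nodes = tree.n_nodes
    origins: list[int] = []
    losses: list[frozenset[int]] = []
    presence_cols: list[np.ndarray] = []
    node_presence_cols: list[np.ndarray] = []
    tips = tree.tips
    budget = cfg.max_retries * max(cfg.n_families, 1)
    tries = 0
    while len(origins) < cfg.n_families:
        tries += 1
        if tries > budget:
            raise SimulationError(
                "retry budget exhausted: loss probability too high for any "
                "family to survive")
        origin = branches[rng.choice(len(branches), p=weights)]
        state = np.zeros(n_nodes, dtype=bool)
        loss_set = set()
        # the family can be lost again on the remainder of its origin branch
        # (leaving it unobservable), then propagates tipward
        state[origin] = rng.random() >= loss_p[origin]
        for v in tree.preorder():
            p = tree.parent[v]
            if p < 0 or not state[p] or v == origin:
                continue
            if rng.random() < loss_p[v]:
                loss_set.add(v)
            else:
                state[v] = True
        tip_state = np.array([state[t] for t in tips])
        if not tip_state.any():
            continue
        origins.append(origin)
        losses.append(frozenset(loss_set))
        presence_cols.append(tip_state)
        node_presence_cols.append(state)

    fam_ids = [f"FAM{i:05d}" for i in range(cfg.n_families)]
    df = pd.DataFrame(np.array(presence_cols),
                      index=pd.Index(fam_ids, name="family"),
                      columns=[tree.tip_label[t] for t in tips])
    truth = SimTruth(family_ids=fam_ids, origin_branch=np.array(origins),
                     loss_branches=losses,
                     node_presence=np.array(node_presence_cols).T)
    return PresenceMatrix(df), truth


# ------------------------------------------------------------------ counts
def _root_sampler(prior: tuple, s_max: int, rng: np.random.Generator):
    kind = prior[0]
    if kind == "geometric":
        p = prior[1]
        s = np.arange(1, s_max + 1)
        w = (1 - p) ** (s - 1) * p
        w /= w.sum()
        return lambda n: rng.choice(s, p=w, size=n)
    if kind == "point":
        return lambda n: np.full(n, int(prior[1]), dtype=np.int64)
    if kind == "uniform":
        return lambda n: rng.integers(1, s_max + 1, size=n)
    raise SimulationError(f"unknown root prior {prior!r}")


def simulate_counts(tree: TimeTree, cfg: SimConfig,
                    branch_lambda: Mapping[int, float] | None = None
                    ) -> tuple[FamilyCountTable, SimTruth]:
    """Family sizes under the truncated birth-death kernel (exact sampling).

    λ per branch is ``lambda_background`` times ``giant_multiplier`` on
    branches in ``cfg.giant_branches`` (or an explicit ``branch_lambda`` map).
    The root size is drawn from the configured prior; each child size is drawn
    by inverse CDF from the same truncated kernel row the likelihood code
    uses.  Families surviving in fewer than ``min_surviving_tips`` tips are
    redrawn (they would not pass the observation filter), keeping the output
    exactly in the model class of the conditioned likelihood.
    """
    rng = np.random.default_rng(cfg.seed)
    if branch_lambda is None:
        branch_lambda = {
            v: cfg.lambda_background * (cfg.giant_multiplier
                                        if v in cfg.giant_branches else 1.0)
            for v in tree.branches()
        }
    kernels: dict[int, np.ndarray] = {}
    cache: dict[tuple[float, float], np.ndarray] = {}
    for v in tree.branches():
        key = (branch_lambda[v], tree.duration(v))
        if key not in cache:
            cache[key], _ = transition_matrix(*key, cfg.s_max)
        kernels[v] = cache[key]
    cdfs = {v: np.cumsum(P, axis=1) for v, P in kernels.items()}

    draw_root = _root_sampler(cfg.root_size_prior, cfg.s_max, rng)
    tips = tree.tips
    n_nodes = tree.n_nodes
    kept: list[np.ndarray] = []
    n_kept = 0
    budget = cfg.max_retries * max(cfg.n_families, 1)
    drawn = 0
    while n_kept < cfg.n_families:
        batch = min(max(cfg.n_families - n_kept, 64) * 2, 200_000)
        if drawn > budget:
            raise SimulationError("retry budget exhausted in simulate_counts")
        drawn += batch
        sizes = np.zeros((batch, n_nodes), dtype=np.int64)
        sizes[:, tree.root] = draw_root(batch)
        for v in tree.preorder():
            p = tree.parent[v]
            if p < 0:
                continue
            s = sizes[:, p]
            u = rng.random(batch)
            # inverse CDF on the kernel row of each family's parent size
            sizes[:, v] = (cdfs[v][s] < u[:, None]).sum(axis=1)
        surviving = (sizes[:, tips] > 0).sum(axis=1)
        ok = sizes[surviving >= cfg.min_surviving_tips]
        kept.append(ok)
        n_kept += len(ok)

    sizes_arr = np.concatenate(kept, axis=0)[:cfg.n_families]  # (n_fam, n_nodes)
    fam_ids = [f"FAM{i:05d}" for i in range(cfg.n_families)]
    df = pd.DataFrame(sizes_arr[:, tips],
                      index=pd.Index(fam_ids, name="family"),
                      columns=[tree.tip_label[t] for t in tips])
    giant = sorted(cfg.giant_branches)
    if giant:
        # a family "shifted" on a giant branch if the jump there was at least
        # shift_min_step copies — single-copy drift is the expected background
        parent_sizes = sizes_arr[:, [tree.parent[v] for v in giant]]
        child_sizes = sizes_arr[:, giant]
        giant_changed = (np.abs(parent_sizes - child_sizes)
                         >= cfg.shift_min_step).any(axis=1)
    else:
        giant_changed = np.zeros(len(fam_ids), dtype=bool)
    truth = SimTruth(family_ids=fam_ids, node_sizes=sizes_arr,
                     branch_lambda=dict(branch_lambda),
                     giant_changed=giant_changed)
    return FamilyCountTable(df), truth


# ------------------------------------------------------------------ labels
def simulate_labels(family_ids: list[str], truth: SimTruth, cfg: SimConfig
                    ) -> tuple[GeneSet, AnnotationMap]:
    """Cancer labels and a synthetic annotation map.

    The number of cancer families is ``round(fraction_cancer × n)``; they are
    drawn without replacement with odds multiplied by ``enrichment_effect``
    for families whose size changed on a giant branch (effect 1.0 makes the
    label independent of the ground truth; effect → ∞ labels every changed
    family first).  Annotation terms are drawn per family from per-term
    frequencies and inherited by that family's proteins, one protein per
    (family, species with a copy).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(family_ids)
    n_cancer = int(round(cfg.fraction_cancer * n))
    if n_cancer == 0:
        raise SimulationError("fraction_cancer yields an empty cancer set")
    changed = (truth.giant_changed if truth.giant_changed is not None
               else np.zeros(n, dtype=bool))
    w = np.where(changed, cfg.enrichment_effect, 1.0).astype(float)
    if not np.isfinite(w).all():  # effect = inf: changed families first
        changed_idx = np.flatnonzero(changed)
        rest = np.flatnonzero(~changed)
        order = np.concatenate([rng.permutation(changed_idx),
                                rng.permutation(rest)])
        chosen = order[:n_cancer]
    else:
        chosen = rng.choice(n, size=n_cancer, replace=False, p=w / w.sum())
    cancer = np.zeros(n, dtype=bool)
    cancer[chosen] = True
    truth.cancer = cancer
    gene_set = GeneSet("cancer", frozenset(family_ids[i] for i in chosen))

    lo, hi = cfg.term_freq_range
    freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_terms))
    fam_terms = {
        fid: frozenset(f"T{k:03d}" for k in range(cfg.n_terms)
                       if rng.random() < freqs[k])
        for fid in family_ids
    }
    amap = AnnotationMap()
    for fid in family_ids:
        n_prot = int(rng.integers(1, 5))
        for k in range(n_prot):
            pid = f"{fid}_p{k + 1}"
            amap.protein_species[pid] = f"sp{k + 1:02d}"
            amap.protein_family[pid] = fid
            # proteins inherit the family's terms with high fidelity
            kept = frozenset(t for t in fam_terms[fid] if rng.random() < 0.9)
            if kept:
                amap.protein_terms[pid] = kept
    return gene_set, amap


def simulate_ohnolog_reference(family_ids: list[str], split_fraction: float,
                               seed: int, genes_per_family: int = 2
                               ) -> tuple[dict[str, str], dict[str, str]]:
    """Synthetic gene partitions for the ohnolog-splitting audit.

    Returns (gene → inferred family, gene → reference family).  A fraction of
    reference families are built by pooling genes from two inferred families
    (a "split" reference family, as when one ancient duplicate family is
    scattered across orthogroups); the rest coincide 1:1.
    """
    rng = np.random.default_rng(seed)
    ours: dict[str, str] = {}
    for fid in family_ids:
        for k in range(genes_per_family):
            ours[f"{fid}_g{k + 1}"] = fid
    n_pairs = int(round(split_fraction * len(family_ids) / 2.0))
    order = rng.permutation(len(family_ids))
    ref: dict[str, str] = {}
    paired: set[int] = set()
    for i in range(n_pairs):
        a, b = order[2 * i], order[2 * i + 1]
        paired |= {int(a), int(b)}
        name = f"REF_SPLIT{i:04d}"
        for idx in (a, b):
            for k in range(genes_per_family):
                ref[f"{family_ids[idx]}_g{k + 1}"] = name
    for idx, fid in enumerate(family_ids):
        if idx not in paired:
            for k in range(genes_per_family):
                ref[f"{fid}_g{k + 1}"] = f"REF_{fid}"
    return ours, ref
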