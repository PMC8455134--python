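"""Dollo parsimony: single-origin / multiple-loss mapping of gene families.

Each gene family is assumed to originate exactly once and may subsequently be
lost any number of times.  Under that model, with no outgroup evidence, the
unique minimum-loss placement of the origin is the MRCA of the species that
possess the family; losses are then the branches whose parent is present and
whose child subtree contains no possessing tip.

The module also provides the per-node accounting used to summarize a
reconstruction on a figure of the species tree (totals, gains, losses, unique
losses, core and novel-core families, with losses stratified by the origin of
the lost family), the family filter feeding the birth-death stage, and an
audit of how a reference partition of genes (e.g. ohnolog families from
whole-genome duplication) is split across the inferred families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FamevolError, TreeError
from .io import FamilyCountTable, GeneSet, PresenceMatrix
from .trees import TimeTree

__all__ = [
    "DolloReconstruction", "SplitReport", "infer_origin", "reconstruct",
    "node_summaries", "stratified_losses", "filter_for_bd", "split_report",
]


@dataclass
class DolloReconstruction:
    """Per-family origins, per-node presence and per-branch losses.

    ``presence`` and ``losses`` are node × family boolean arrays (rows indexed
    by node ID, columns by family ID order in ``family_ids``); ``origin`` maps
    each family to the node whose branch it originated on.
    """

    tree: TimeTree
    family_ids: list[str]
    origin: np.ndarray        # (n_fam,) node IDs
    presence: np.ndarray      # (n_nodes, n_fam) bool
    losses: np.ndarray        # (n_nodes, n_fam) bool; row = branch (child node)

    def n_losses(self) -> pd.Series:
        return pd.Series(self.losses.sum(axis=0), index=self.family_ids,
                         name="n_losses")

    def origin_series(self) -> pd.Series:
        return pd.Series(self.origin, index=self.family_ids, name="origin_node")

    def to_frame(self) -> pd.DataFrame:
        """Per-family TSV payload: origin node, number and list of loss branches."""
        loss_lists = [
            ",".join(self.tree.label_of(int(b))
                     for b in np.flatnonzero(self.losses[:, j]))
            for j in range(len(self.family_ids))
        ]
        return pd.DataFrame(
            {
                "origin_node": [self.tree.label_of(int(o)) for o in self.origin],
                "n_losses": self.losses.sum(axis=0),
                "loss_branches": loss_lists,
            },
            index=pd.Index(self.family_ids, name="family"),
        )


def _tip_matrix(presence: PresenceMatrix, tree: TimeTree) -> np.ndarray:
    """(n_nodes, n_fam) bool with presence filled in at tip rows."""
    df = presence.presence
    missing = set(df.columns) ^ set(tree.tip_labels)
    if missing:
        raise FamevolError(f"presence/tree label mismatch: {sorted(missing)}")
    M = np.zeros((tree.n_nodes, df.shape[0]), dtype=bool)
    for tip in tree.tips:
        M[tip] = df[tree.tip_label[tip]].to_numpy()
    return M


def reconstruct(presence: PresenceMatrix, tree: TimeTree) -> DolloReconstruction:
    """Map every family onto the tree under single-origin/any-loss parsimony.

    Raises if any family is absent from all species (no origin is inferable).
    """
    fam_ids = presence.family_ids
    tipM = _tip_matrix(presence, tree)
    n_fam = len(fam_ids)

    # subtree counts of possessing tips, by post-order accumulation
    counts = np.zeros((tree.n_nodes, n_fam), dtype=np.int32)
    subtree_size = np.zeros(tree.n_nodes, dtype=np.int32)
    for v in tree.postorder():
        if tree.is_tip(v):
            counts[v] = tipM[v]
            subtree_size[v] = 1
        else:
            for c in tree.children[v]:
                counts[v] += counts[c]
                subtree_size[v] += subtree_size[c]

    total = counts[tree.root]
    if (total == 0).any():
        bad = [fam_ids[j] for j in np.flatnonzero(total == 0)][:5]
        raise FamevolError(f"families absent from every species: {bad}")

    # origin = deepest node whose subtree contains all possessing tips
    depth = np.array([tree.depth(v) for v in range(tree.n_nodes)])
    full = counts == total[None, :]
    origin = np.argmax(np.where(full, depth[:, None], -1), axis=0)

    # node presence: descends from origin and has >= 1 possessing tip below
    A = tree.ancestor_matrix()          # A[v, a]: a is ancestor-or-self of v
    desc_of_origin = A[:, origin]       # (n_nodes, n_fam)
    node_presence = desc_of_origin & (counts > 0)

    # losses: parent present, child absent
    losses = np.zeros_like(node_presence)
    for v in tree.branches():
        losses[v] = node_presence[tree.parent[v]] & ~node_presence[v]

    return DolloReconstruction(tree=tree, family_ids=fam_ids, origin=origin,
                               presence=node_presence, losses=losses)


def infer_origin(presence_row: Mapping[str, bool] | pd.Series, tree: TimeTree) -> int:
    """Origin node of a single family: MRCA of the possessing tips."""
    present_tips = [tree.node_by_label(sp) for sp, flag in dict(presence_row).items()
                    if flag]
    if not present_tips:
        raise FamevolError("family absent from every species: no origin")
    return tree.mrca(present_tips)


def node_summaries(rec: DolloReconstruction, tree: TimeTree) -> pd.DataFrame:
    """Per-node/branch accounting of a reconstruction.

    Columns: ``total_present`` (families present at the node), ``novel``
    (origins on the branch), ``lost`` and ``unique_lost`` (families lost on
    the branch; unique = lost on no other branch tree-wide), ``core``
    (families present in every descendant tip) and ``novel_core``.  The flow
    equation ``total(child) = total(parent) - lost + novel`` holds on every
    branch.
    """
    n_nodes = tree.n_nodes
    n_fam = len(rec.family_ids)

    subtree_size = np.zeros(n_nodes, dtype=np.int64)
    counts = np.zeros((n_nodes, n_fam), dtype=np.int32)
    tipM = rec.presence  # tip rows of presence == tip possession
    for v in tree.postorder():
        if tree.is_tip(v):
            counts[v] = tipM[v]
            subtree_size[v] = 1
        else:
            for c in tree.children[v]:
                counts[v] += counts[c]
                subtree_size[v] += subtree_size[c]

    total_present = rec.presence.sum(axis=1)
    novel = np.bincount(rec.origin, minlength=n_nodes)
    lost = rec.losses.sum(axis=1)
    n_loss_per_family = rec.losses.sum(axis=0)
    unique = rec.losses & (n_loss_per_family == 1)[None, :]
    unique_lost = unique.sum(axis=1)
    core_mask = counts == subtree_size[:, None]
    core = (core_mask & rec.presence).sum(axis=1)
    novel_core_mask = core_mask & (np.arange(n_nodes)[:, None] == rec.origin[None, :])
    novel_core = novel_core_mask.sum(axis=1)

    return pd.DataFrame(
        {
            "node": [tree.label_of(v) for v in range(n_nodes)],
            "total_present": total_present,
            "novel": novel,
            "lost": lost,
            "unique_lost": unique_lost,
            "core": core,
            "novel_core": novel_core,
        }
    ).set_index(pd.Index(range(n_nodes), name="node_id"))


def stratified_losses(rec: DolloReconstruction, tree: TimeTree) -> pd.DataFrame:
    """Losses per branch stratified by the origin node of the lost family.

    One row per (branch, origin) pair with a nonzero count — the
    "color-coded" loss accounting of a tree figure.
    """
    rows = []
    for v in tree.branches():
        lost_fams = np.flatnonzero(rec.losses[v])
        if lost_fams.size == 0:
            continue
        origins, n = np.unique(rec.origin[lost_fams], return_counts=True)
        for o, k in zip(origins, n):
            rows.append((v, tree.label_of(v), int(o), tree.label_of(int(o)), int(k)))
    return pd.DataFrame(rows, columns=["branch_id", "branch", "origin_id",
                                       "origin", "n_lost"])


def filter_for_bd(counts: FamilyCountTable, rec: DolloReconstruction,
                  ancestor: int, max_copies: int = 100,
                  min_species: int = 2) -> FamilyCountTable:
    """Filter families for birth-death rate estimation.

    Keeps families whose origin is ``ancestor`` or one of its ancestors (the
    family was present in that MRCA), present in at least ``min_species``
    species, and with no per-species count above ``max_copies`` (very large
    families have too much size variance for stable rate estimation).
    """
    if not 0 <= ancestor < rec.tree.n_nodes:
        raise TreeError(f"ancestor node {ancestor} not in tree")
    anc_set = set(rec.tree.ancestors(ancestor, include_self=True))
    origin_ok = np.array([o in anc_set for o in rec.origin])
    df = counts.counts.loc[rec.family_ids]
    n_present = (df > 0).sum(axis=1).to_numpy()
    max_count = df.max(axis=1).to_numpy()
    keep = origin_ok & (n_present >= min_species) & (max_count <= max_copies)
    return FamilyCountTable(df.loc[keep].copy())


@dataclass(frozen=True)
class SplitReport:
    """Audit of how reference families split across inferred families."""

    n_reference_families: int
    n_unsplit: int
    n_split: int
    focal_overlap: int            # focal families touching a split reference family
    focal_size: int
    split_percentage: float       # 100 * focal_overlap / focal_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def split_report(our_partition: Mapping[str, str],
                 reference_partition: Mapping[str, str],
                 focal_families: GeneSet | Iterable[str]) -> SplitReport:
    """Compare an inferred gene→family partition against a reference partition.

    A reference family is *split* iff its member genes (restricted to the
    shared gene namespace) land in more than one inferred family.  The focal
    overlap counts focal inferred families containing at least one gene of a
    split reference family; the percentage scales that by the focal-set size.
    """
    shared = set(our_partition) & set(reference_partition)
    if not shared:
        raise FamevolError("gene namespaces of the two partitions do not intersect")
    focal = set(focal_families.families if isinstance(focal_families, GeneSet)
                else focal_families)

    ref_members: dict[str, set[str]] = {}
    for g in shared:
        ref_members.setdefault(reference_partition[g], set()).add(g)

    n_split = 0
    overlap: set[str] = set()
    for genes in ref_members.values():
        ours = {our_partition[g] for g in genes}
        if len(ours) > 1:
            n_split += 1
            overlap |= ours & focal
    n_ref = len(ref_members)
    pct = 100.0 * len(overlap) / len(focal) if focal else float("nan")
    return SplitReport(
        n_reference_families=n_ref,
        n_unsplit=n_ref - n_split,
        n_split=n_split,
        focal_overlap=len(overlap),
        focal_size=len(focal),
        split_percentage=pct,
    )
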