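"""Readers and writers for count tables, annotation maps, gene sets and branch sets.

Formats follow the conventions of the tools practitioners already use:
gene-count tables are tab-separated in the OrthoFinder
``Orthogroups.GeneCount.tsv`` dialect (first column ``Orthogroup``, one column
per species, optional trailing ``Total``), annotation maps are long-format TSV
(protein_id, species, family_id, term), and gene/branch sets are plain text
with one ID per line ('#' starts a comment).  All output TSVs begin with a
comment line recording the tool version and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import BranchSetError, CountTableError, GeneSetError
from .trees import TimeTree

__all__ = [
    "FamilyCountTable", "PresenceMatrix", "AnnotationMap", "GeneSet",
    "BranchSet", "read_gene_counts", "read_annotation_map", "read_gene_set",
    "read_branch_set", "write_tsv",
]


# --------------------------------------------------------------------- tables
@dataclass
class FamilyCountTable:
    """Orthogroup × species non-negative integer gene counts."""

    counts: pd.DataFrame  # index: family IDs, columns: species labels

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise CountTableError("duplicate family IDs")
        if not df.map(lambda x: float(x).is_integer()).all().all():
            raise CountTableError("non-integer gene count")
        df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise CountTableError("negative gene count")
        self.counts = df

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def n_families(self) -> int:
        return len(self.counts)

    def empty_families(self) -> list[str]:
        """Families with zero counts everywhere (retained at load, flagged here)."""
        mask = (self.counts == 0).all(axis=1)
        return list(self.counts.index[mask])

    def presence(self) -> "PresenceMatrix":
        return PresenceMatrix(self.counts > 0)

    def rename_species(self, alias: Mapping[str, str]) -> "FamilyCountTable":
        """Apply a species alias table (the only renaming mechanism).

        Species matching is otherwise exact string equality against the
        tree's tip labels.
        """
        unknown = set(alias) - set(self.counts.columns)
        if unknown:
            raise CountTableError(f"alias for unknown species: {sorted(unknown)}")
        return FamilyCountTable(self.counts.rename(columns=dict(alias)))

    def subset(self, family_ids: Iterable[str]) -> "FamilyCountTable":
        return FamilyCountTable(self.counts.loc[list(family_ids)].copy())

    def check_against_tree(self, tree: TimeTree) -> None:
        missing = set(self.species) - set(tree.tip_labels)
        extra = set(tree.tip_labels) - set(self.species)
        if missing or extra:
            raise CountTableError(
                f"species/tree label mismatch: table-only={sorted(missing)}, "
                f"tree-only={sorted(extra)}"
            )


@dataclass
class PresenceMatrix:
    """Family × species presence (count > 0)."""

    presence: pd.DataFrame  # boolean

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)

    @property
    def family_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def drop_empty(self) -> "PresenceMatrix":
        keep = self.presence.any(axis=1)
        return PresenceMatrix(self.presence.loc[keep])


def read_gene_counts(path: str, dialect: str = "orthofinder") -> FamilyCountTable:
    """Read a TSV gene-count table.

    ``orthofinder`` dialect: first column ``Orthogroup``, species columns, and
    an optional trailing ``Total`` column which is validated against row sums
    and then dropped.  ``plain`` dialect: first column is the family ID
    (any header name), remaining columns are species.
    """
    if dialect not in ("orthofinder", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise CountTableError(f"cannot read count table {path!r}: {exc}") from exc
    if df.shape[1] < 2:
        raise CountTableError("count table needs a family column and >= 1 species")
    if dialect == "orthofinder" and df.columns[0] != "Orthogroup":
        raise CountTableError(
            f"orthofinder dialect requires first column 'Orthogroup', got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    try:
        df = df.astype(np.int64)
    except ValueError as exc:
        raise CountTableError(f"non-integer cell in count table: {exc}") from exc
    if dialect == "orthofinder" and df.columns[-1] == "Total":
        totals = df.pop("Total")
        bad = df.sum(axis=1) != totals
        if bad.any():
            raise CountTableError(
                f"Total column mismatch for families {list(df.index[bad])[:5]}"
            )
    return FamilyCountTable(df)


# ---------------------------------------------------------------- annotations
@dataclass
class AnnotationMap:
    """Protein-level annotations plus protein → (species, family) membership.

    Terms (GO or Pfam IDs) are opaque strings.  A protein belongs to at most
    one family; proteins without a family (``family_id`` empty or '-') are
    retained as unclustered and can be promoted to singleton families by the
    annotation-assignment rule.
    """

    protein_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    protein_species: dict[str, str] = field(default_factory=dict)
    protein_family: dict[str, str] = field(default_factory=dict)  # unclustered absent

    def proteins_of_family(self) -> dict[str, list[str]]:
        fam: dict[str, list[str]] = {}
        for p, f in self.protein_family.items():
            fam.setdefault(f, []).append(p)
        return fam

    def family_of(self, protein: str) -> str | None:
        return self.protein_family.get(protein)

    def unclustered(self) -> list[str]:
        return [p for p in self.protein_species if p not in self.protein_family]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, sp in self.protein_species.items():
            fam = self.protein_family.get(p, "-")
            terms = sorted(self.protein_terms.get(p, ())) or [""]
            for t in terms:
                rows.append((p, sp, fam, t))
        return pd.DataFrame(rows, columns=["protein_id", "species",
                                           "family_id", "term"])


def read_annotation_map(path: str) -> AnnotationMap:
    """Read a long-format annotation TSV: protein_id, species, family_id, term.

    A protein may appear on several rows (one per term); ``term`` may be empty
    for proteins with no annotation; ``family_id`` of '-' or '' marks an
    unclustered protein.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "species", "family_id", "term"}
    if not required.issubset(df.columns):
        raise CountTableError(
            f"annotation map must have columns {sorted(required)}, got {list(df.columns)}"
        )
    amap = AnnotationMap()
    terms: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        p = row.protein_id
        amap.protein_species[p] = row.species
        if row.family_id not in ("", "-"):
            prev = amap.protein_family.get(p)
            if prev is not None and prev != row.family_id:
                raise CountTableError(f"protein {p!r} mapped to two families")
            amap.protein_family[p] = row.family_id
        if row.term:
            terms.setdefault(p, set()).add(row.term)
    amap.protein_terms = {p: frozenset(t) for p, t in terms.items()}
    return amap


# ------------------------------------------------------------------ gene sets
@dataclass(frozen=True)
class GeneSet:
    """A named set of family IDs (gene IDs collapsed through the family map)."""

    name: str
    families: frozenset[str]
    n_unmapped: int = 0

    def __len__(self) -> int:
        return len(self.families)


def read_gene_set(path: str, id_map: AnnotationMap, name: str | None = None) -> GeneSet:
    """Read one gene/protein ID per line and translate to family IDs.

    Unmapped IDs are counted (``n_unmapped``) but not fatal; an empty result
    after mapping is an error.
    """
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    fams, unmapped = set(), 0
    for gid in ids:
        fam = id_map.family_of(gid)
        if fam is None:
            unmapped += 1
        else:
            fams.add(fam)
    if not fams:
        raise GeneSetError(f"gene set {path!r}: no ID mapped to any family")
    return GeneSet(name or str(path), frozenset(fams), n_unmapped=unmapped)


# ---------------------------------------------------------------- branch sets
@dataclass(frozen=True)
class BranchSet:
    """A named set of branches, each identified by its child node ID."""

    name: str
    branches: frozenset[int]

    def __len__(self) -> int:
        return len(self.branches)

    @staticmethod
    def from_nodes(name: str, nodes: Iterable[int], tree: TimeTree) -> "BranchSet":
        nodes = set(int(v) for v in nodes)
        bad = [v for v in nodes if not 0 <= v < tree.n_nodes or v == tree.root]
        if bad:
            raise BranchSetError(f"branch set {name!r}: invalid branch IDs {bad}")
        return BranchSet(name, frozenset(nodes))


def read_branch_set(path: str, tree: TimeTree, name: str | None = None) -> BranchSet:
    """Read a branch set: one branch per line, named by the child node.

    A line is a tip label, an internal-node label ``N<id>``, a bare node ID,
    or ``mrca:<tip1>,<tip2>,...`` naming the branch above an internal clade.
    """
    nodes: set[int] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("mrca:"):
                tips = [t.strip() for t in line[5:].split(",")]
                node = tree.mrca([tree.node_by_label(t) for t in tips])
            else:
                node = tree.node_by_label(line)
            if node == tree.root:
                raise BranchSetError(f"{line!r} names the root, which has no branch")
            nodes.add(node)
    if not nodes:
        raise BranchSetError(f"branch set {path!r} is empty")
    return BranchSet.from_nodes(name or str(path), nodes, tree)


# -------------------------------------------------------------------- writing
def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str, config: Mapping | None = None,
              index: bool = True) -> None:
    """Write a result TSV with a comment header (tool version + config hash)."""
    with open(path, "w") as fh:
        h = config_hash(config or {})
        fh.write(f"# famevol {__version__} config={h}\n")
        df.to_csv(fh, sep="\t", index=index)
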