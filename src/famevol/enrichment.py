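"""Family-level functional annotation and exact enrichment tests.

Representative annotation follows the 75%/75% rule used by orthology
annotation tools: a term labels a family when at least 75% of the family's
proteins carry it and at least 75% of the taxa in the family have a protein
carrying it.  Enrichment of a family set for a term (or for membership in an
external gene set) is tested with the two-sided Fisher exact test under the
probability-ordering rule, with Benjamini-Hochberg correction applied within
each comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import FamevolError
from .io import AnnotationMap, GeneSet

__all__ = [
    "ContingencyTable", "EnrichmentResult", "assign_family_annotations",
    "fisher_exact", "bh_adjust", "term_enrichment",
]

_TIE_REL = 1 + 1e-7  # relative tolerance for pmf ties in the two-sided sum


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows in-set/out-set, columns has-property/lacks-property."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def degenerate(self) -> bool:
        """True when a margin is zero, making the odds ratio undefined."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


def fisher_exact(table: ContingencyTable | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  The p-value sums hypergeometric point
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table (probability-ordering rule).
    The odds ratio is the sample OR ``(a*d)/(b*c)``, with a 0.5 continuity
    correction applied to every cell when any cell is zero; a degenerate
    margin yields ``p = 1`` and ``odds_ratio = nan``.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.degenerate():
        return float("nan"), 1.0

    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)

    N, r, k = table.n, a + b, a + c
    pmf, lo = _hypergeom_row(N, r, k)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _TIE_REL].sum())
    return float(oddsr), min(p, 1.0)


def _hypergeom_row(N: int, r: int, k: int) -> tuple[np.ndarray, int]:
    """Hypergeometric pmf over the full support for margins (N, r, k)."""
    lo, hi = max(0, r + k - N), min(r, k)
    a = np.arange(lo, hi + 1)
    logp = (_logC(r, a) + _logC(N - r, k - a) - _logC(N, k))
    return np.exp(logp), lo


def _logC(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_family_annotations(ann: AnnotationMap, protein_frac: float = 0.75,
                              taxon_frac: float = 0.75,
                              infer_singletons: bool = False
                              ) -> dict[str, frozenset[str]]:
    """Representative term assignment per family (the 75%/75% rule).

    A term is kept for a family iff the fraction of the family's proteins
    carrying it is >= ``protein_frac`` *and* the fraction of the family's taxa
    with at least one carrying protein is >= ``taxon_frac``.  With
    ``infer_singletons``, unclustered proteins become single-protein families
    (named after the protein) inheriting their own terms.
    """
    out: dict[str, frozenset[str]] = {}
    for fam, proteins in ann.proteins_of_family().items():
        n_prot = len(proteins)
        taxa = {ann.protein_species[p] for p in proteins}
        term_prot: dict[str, int] = {}
        term_taxa: dict[str, set[str]] = {}
        for p in proteins:
            for t in ann.protein_terms.get(p, ()):  # unannotated proteins count in n_prot
                term_prot[t] = term_prot.get(t, 0) + 1
                term_taxa.setdefault(t, set()).add(ann.protein_species[p])
        kept = {
            t for t, np_ in term_prot.items()
            if np_ / n_prot >= protein_frac
            and len(term_taxa[t]) / len(taxa) >= taxon_frac
        }
        out[fam] = frozenset(kept)
    if infer_singletons:
        for p in ann.unclustered():
            out[p] = ann.protein_terms.get(p, frozenset())
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One 2x2 enrichment test: term or set name, table, OR, p, BH q, flag."""

    name: str
    table: ContingencyTable
    odds_ratio: float
    p: float
    q: float = float("nan")
    significant: bool = False


def term_enrichment(target: GeneSet | Iterable[str], background: Iterable[str],
                    fam_ann: dict[str, frozenset[str]], alpha: float = 0.05,
                    annotated_only: bool = False) -> list[EnrichmentResult]:
    """Test every term for enrichment in ``target`` relative to ``background``.

    The universe is the background family set (optionally restricted to
    families carrying at least one representative term).  One 2x2 table per
    term (in-target × has-term); BH correction is applied across the terms of
    this comparison, and results with ``q <= alpha`` are flagged.
    """
    tset = set(target.families if isinstance(target, GeneSet) else target)
    universe = set(background)
    if annotated_only:
        universe = {f for f in universe if fam_ann.get(f)}
        tset &= universe
    if not tset:
        raise FamevolError("empty target set")
    if not tset <= universe:
        raise FamevolError("target is not a subset of the background universe")

    terms = sorted({t for f in universe for t in fam_ann.get(f, ())})
    results = []
    n_t = len(tset)
    n_u = len(universe)
    for term in terms:
        with_term = {f for f in universe if term in fam_ann.get(f, ())}
        a = len(tset & with_term)
        b = n_t - a
        c = len(with_term) - a
        d = n_u - n_t - c
        tab = ContingencyTable(a, b, c, d)
        oddsr, p = fisher_exact(tab)
        results.append(EnrichmentResult(term, tab, oddsr, p))
    if results:
        q = bh_adjust([r.p for r in results])
        results = [
            EnrichmentResult(r.name, r.table, r.odds_ratio, r.p, float(qi),
                             bool(qi <= alpha and not r.table.degenerate()))
            for r, qi in zip(results, q)
        ]
    return results
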