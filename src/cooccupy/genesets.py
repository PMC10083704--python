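"""Gene-set overlap statistics and offline term enrichment.

Peak-derived gene sets are tested for overlap against differential-
expression gene lists with the one-sided (enrichment) hypergeometric tail
— Fisher's exact test for a 2x2 table — over a declared gene universe, and
against GMT term collections with Benjamini-Hochberg FDR control and
top-k reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import PeakGeneAssignment

__all__ = [
    "GeneSet",
    "ContingencyTable",
    "EnrichmentResult",
    "read_gene_list",
    "read_gmt",
    "genes_from_assignments",
    "hypergeom_enrichment_p",
    "fisher_overlap",
    "overlap_matrix",
    "term_enrichment",
    "bh_fdr",
]

#: cap applied to -log10(FDR) when FDR underflows to 0
NEG_LOG10_CAP = 300.0


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset[str]

    def __init__(self, label: str, members: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table over a stated universe: a = overlap, b = A-only,
    c = B-only, d = neither; a + b + c + d = universe size."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    p_value: float
    fdr: float
    neg_log10_fdr: float


def read_gene_list(path: str | Path, label: str | None = None) -> GeneSet:
    """One gene id per line; blank lines and # comments skipped."""
    path = Path(path)
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return GeneSet(label or path.stem, genes)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT collection: ``term<TAB>description<TAB>gene...`` per line."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            terms[f[0]] = frozenset(g for g in f[2:] if g)
    return terms


def genes_from_assignments(
    assignments: Iterable[PeakGeneAssignment],
    category: str | None = None,
    label: str = "peak_genes",
) -> GeneSet:
    """Unique genes from peak-TSS assignments, optionally restricted to
    the "promoter" or "distal" category; unannotated peaks are skipped."""
    if category is not None and category not in {"promoter", "distal"}:
        raise ValueError("category filter must be 'promoter', 'distal' or None")
    genes = {
        a.gene
        for a in assignments
        if a.gene is not None and (category is None or a.category == category)
    }
    return GeneSet(label, genes)


def hypergeom_enrichment_p(a: int, universe: int, n_a: int, n_b: int) -> float:
    """One-sided enrichment p-value P(X >= a), X ~ Hypergeom(universe, n_a, n_b)."""
    return float(stats.hypergeom.sf(a - 1, universe, n_a, n_b))


def fisher_overlap(
    A: GeneSet,
    B: GeneSet,
    universe: GeneSet,
    alternative: str = "greater",
) -> tuple[ContingencyTable, float]:
    """Fisher's exact test of the overlap between two gene sets.

    Default is the one-sided enrichment tail P(X >= a); pass
    ``alternative="two-sided"`` for the two-sided test. Members outside
    the universe are an error.
    """
    for s in (A, B):
        stray = s.members - universe.members
        if stray:
            raise ValueError(
                f"{s.label!r} has members outside the universe: "
                f"{sorted(stray)[:10]}"
            )
    a = len(A.members & B.members)
    b = len(A.members - B.members)
    c = len(B.members - A.members)
    d = len(universe) - a - b - c
    table = ContingencyTable(a, b, c, d)
    if alternative == "greater":
        p = hypergeom_enrichment_p(a, len(universe), len(A), len(B))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return table, min(1.0, p)


def overlap_matrix(
    peak_gene_sets: Sequence[GeneSet],
    de_gene_sets: Sequence[GeneSet],
    universe: GeneSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise overlap counts and Fisher p-values.

    Element (i, j) covers (peak_gene_sets[i], de_gene_sets[j]); the two
    arrays back the overlap-count and overlap-p heatmap pair.
    """
    counts = np.zeros((len(peak_gene_sets), len(de_gene_sets)), dtype=int)
    pvals = np.ones_like(counts, dtype=float)
    for i, A in enumerate(peak_gene_sets):
        for j, B in enumerate(de_gene_sets):
            table, p = fisher_overlap(A, B, universe)
            counts[i, j] = table.a
            pvals[i, j] = p
    return counts, pvals


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def term_enrichment(
    query: GeneSet,
    collection: Mapping[str, Iterable[str]],
    universe: GeneSet,
    top_k: int = 10,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment with BH-FDR, top-k by FDR.

    Each term is intersected with the universe before testing; terms empty
    after intersection are dropped. FDR is adjusted across all tested
    terms, then results are sorted by (fdr, p, term id) ascending and the
    first ``top_k`` returned.
    """
    if len(query) == 0:
        raise ValueError("empty query gene set")
    stray = query.members - universe.members
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    names: list[str] = []
    overlaps: list[int] = []
    pvals: list[float] = []
    for term, genes in collection.items():
        tg = frozenset(genes) & universe.members
        if not tg:
            continue
        a = len(query.members & tg)
        names.append(term)
        overlaps.append(a)
        pvals.append(hypergeom_enrichment_p(a, len(universe), len(query), len(tg)))
    if not names:
        raise ValueError("no terms remain after intersecting with the universe")
    fdrs = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term=t,
            overlap=o,
            p_value=p,
            fdr=float(f),
            neg_log10_fdr=min(NEG_LOG10_CAP, -math.log10(f)) if f > 0 else NEG_LOG10_CAP,
        )
        for t, o, p, f in zip(names, overlaps, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term))
    return results[:top_k]
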