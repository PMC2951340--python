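"""Per-window functional-term enrichment, FDR, and neighborhood calling.

Each (window, term) pair gets a 2x2 contingency table — genes in/out of the
window crossed with genes carrying/lacking the term — tested with a
one-sided Fisher exact test for over-representation. Raw p-values from all
windows (optionally pooled across every species in a run) are
Benjamini–Hochberg corrected, and overlapping significant windows of the
same term are merged into *functional neighborhoods*.

The universe of the 2x2 is, by default, the genes carrying at least one
annotation; unannotated genes are excluded (standard enrichment practice —
switchable via ``universe="all"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import AnnotationSet, GeneRecord
from .window_scan import GenomicWindow

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentTest",
    "Neighborhood",
    "SpeciesSummary",
    "UntestableTermError",
    "build_contingency",
    "fisher_exact_greater",
    "scan_enrichment",
    "fdr_correct",
    "call_neighborhoods",
    "summarize_species",
]


class UntestableTermError(ValueError):
    """A term with no annotated genes in the universe cannot be tested."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """a: in-window with term; b: in-window without; c/d: outside window."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentTest:
    window: GenomicWindow
    term_id: str
    table: ContingencyTable2x2
    p: float
    q: float | None = None
    significant: bool = False


@dataclass
class Neighborhood:
    """A called functional cluster: merged significant windows of one term.

    ``member_gene_ids`` are the genes in the span annotated with the term
    (the cluster members proper); ``all_gene_ids`` is every gene whose
    midpoint falls in the span, the denominator for gene density.
    """

    species_id: str
    term_id: str
    chrom: str
    start: int
    end: int
    member_gene_ids: list[str]
    all_gene_ids: list[str]
    best_q: float
    gene_density: float | None = None
    mean_gc: float | None = None
    orthology_fraction: float | None = None

    @property
    def length_mbp(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class SpeciesSummary:
    species_id: str
    n_neighborhoods: int
    pct_genes_in_neighborhoods: float
    mean_gene_density: float | None
    mean_gc: float | None
    per_chromosome_pct: dict[str, float] = field(default_factory=dict)


def build_contingency(
    window: GenomicWindow, term: str, annotation: AnnotationSet, universe: Iterable[str]
) -> ContingencyTable2x2:
    """2x2 counts of (in window) x (has term) over the gene universe."""
    universe = set(universe)
    term_genes = annotation.genes_with_term(term) & universe
    if not term_genes:
        raise UntestableTermError(f"term {term!r} annotates no gene in the universe")
    win_genes = set(window.gene_ids) & universe
    a = len(win_genes & term_genes)
    b = len(win_genes) - a
    c = len(term_genes) - a
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_greater(table: ContingencyTable2x2) -> float:
    """One-sided Fisher p for over-representation: P(A >= a) hypergeometric.

    Margins fixed: N genes total, K = a+c with the term, n = a+b in window.
    """
    N, K, n = table.n, table.a + table.c, table.a + table.b
    p = float(stats.hypergeom.sf(table.a - 1, N, K, n))
    return min(1.0, max(p, 0.0)) or np.nextafter(0, 1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")[1]
    return float(min(1.0, p))


def scan_enrichment(
    windows: Sequence[GenomicWindow],
    annotation: AnnotationSet,
    terms: Sequence[str] | None = None,
    min_term_genes: int = 5,
    universe: str = "annotated",
    genes: Sequence[GeneRecord] | None = None,
    alternative: str = "greater",
) -> list[EnrichmentTest]:
    """Fisher-test every (window, eligible term) pair; raw p only.

    A term is eligible when it annotates at least ``min_term_genes`` genes
    in the universe. The hypergeometric tails are evaluated vectorized over
    the whole window x term grid.
    """
    if not windows:
        raise ValueError("no windows to scan")
    if universe not in ("annotated", "all"):
        raise ValueError("universe must be 'annotated' or 'all'")
    window_gene_union: set[str] = set()
    for w in windows:
        window_gene_union |= set(w.gene_ids)
    if universe == "annotated":
        uni = sorted(window_gene_union & annotation.genes)
    else:
        if genes is not None:
            uni = sorted({g.gene_id for g in genes})
        else:
            uni = sorted(window_gene_union)
    idx = {g: i for i, g in enumerate(uni)}
    N = len(uni)
    if N == 0:
        raise ValueError("empty gene universe")

    if terms is None:
        terms = sorted(annotation.terms)
    eligible = []
    term_masks = []
    for t in terms:
        tg = [idx[g] for g in annotation.genes_with_term(t) if g in idx]
        if len(tg) >= min_term_genes:
            mask = np.zeros(N, dtype=bool)
            mask[tg] = True
            eligible.append(t)
            term_masks.append(mask)
    if not eligible:
        return []
    T = np.stack(term_masks)                      # (n_terms, N)
    K = T.sum(axis=1)                             # genes with term, genome-wide

    W = np.zeros((len(windows), N), dtype=bool)
    for i, w in enumerate(windows):
        for g in w.gene_ids:
            j = idx.get(g)
            if j is not None:
                W[i, j] = True
    n_in = W.sum(axis=1)                          # annotated genes per window
    A = W.astype(np.int64) @ T.T.astype(np.int64)  # (n_windows, n_terms)

    P = stats.hypergeom.sf(A - 1, N, K[None, :], n_in[:, None])
    P = np.clip(P, np.nextafter(0, 1), 1.0)

    tests: list[EnrichmentTest] = []
    for i, w in enumerate(windows):
        for j, t in enumerate(eligible):
            a = int(A[i, j])
            table = ContingencyTable2x2(a, int(n_in[i]) - a, int(K[j]) - a,
                                        N - int(n_in[i]) - int(K[j]) + a)
            if alternative == "greater":
                p = float(P[i, j])
            elif alternative == "two-sided":
                p = fisher_exact_two_sided(table)
            else:
                raise ValueError("alternative must be 'greater' or 'two-sided'")
            tests.append(EnrichmentTest(w, t, table, p))
    return tests


def fdr_correct(tests: Sequence[EnrichmentTest], alpha: float = 0.05) -> list[EnrichmentTest]:
    """Benjamini–Hochberg step-up over the pooled tests (all species in a run).

    Sets ``q`` and ``significant`` in place and returns the list.
    """
    if not tests:
        raise ValueError("no tests to correct")
    p = np.array([t.p for t in tests], dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    for t, qi, ri in zip(tests, q, reject):
        t.q = float(qi)
        t.significant = bool(ri)
    return list(tests)


def _merge_spans(spans: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_neighborhoods(
    tests: Sequence[EnrichmentTest],
    genes: Sequence[GeneRecord],
    annotation: AnnotationSet,
    species_id: str,
    merge_gap: int = 0,
) -> list[Neighborhood]:
    """Merge overlapping/abutting significant windows per term into neighborhoods.

    Members = genes in the merged span annotated with the term; all genes in
    the span enter the density and GC summaries. best_q is the minimum q of
    the supporting windows.
    """
    by_key: dict[tuple[str, str], list[EnrichmentTest]] = {}
    for t in tests:
        if t.significant:
            if t.q is None:
                raise ValueError("call_neighborhoods requires FDR-annotated tests")
            by_key.setdefault((t.term_id, t.window.chrom), []).append(t)

    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: (g.midpoint, g.gene_id))

    out: list[Neighborhood] = []
    for (term, chrom), group in sorted(by_key.items()):
        spans = _merge_spans([(t.window.start, t.window.end) for t in group], gap=merge_gap)
        chrom_genes = genes_by_chrom.get(chrom, [])
        mids = np.array([g.midpoint for g in chrom_genes])
        for s, e in spans:
            lo = int(np.searchsorted(mids, s, side="left"))
            hi = int(np.searchsorted(mids, e, side="left"))
            span_genes = chrom_genes[lo:hi]
            members = [g.gene_id for g in span_genes if annotation.has(g.gene_id, term)]
            best_q = min(
                t.q for t in group if s <= t.window.start and t.window.end <= e  # type: ignore[operator]
            )
            gcs = [g.gc_fraction for g in span_genes if g.gc_fraction is not None]
            out.append(Neighborhood(
                species_id=species_id, term_id=term, chrom=chrom, start=s, end=e,
                member_gene_ids=members,
                all_gene_ids=[g.gene_id for g in span_genes],
                best_q=best_q,
                gene_density=len(span_genes) / ((e - s) / 1e6),
                mean_gc=float(np.mean(gcs)) if gcs else None,
            ))
    return out


def summarize_species(
    neighborhoods: Sequence[Neighborhood],
    genes: Sequence[GeneRecord],
    annotation: AnnotationSet,
) -> SpeciesSummary:
    """Per-species summary: neighborhood count, % genes in neighborhoods,
    mean gene density and GC, and the same percentage per chromosome."""
    annotated = {g.gene_id for g in genes} & annotation.genes
    if not annotated:
        raise ValueError("species has no annotated genes")
    species_id = genes[0].species_id if genes else "species"
    member_union: set[str] = set()
    for n in neighborhoods:
        member_union |= set(n.member_gene_ids)
    member_union &= annotated
    pct = 100.0 * len(member_union) / len(annotated)

    densities = [n.gene_density for n in neighborhoods if n.gene_density is not None]
    gcs = [n.mean_gc for n in neighborhoods if n.mean_gc is not None]

    per_chrom: dict[str, float] = {}
    for chrom in sorted({g.chrom for g in genes}):
        chrom_annotated = {g.gene_id for g in genes if g.chrom == chrom} & annotated
        if not chrom_annotated:
            continue
        chrom_members = set()
        for n in neighborhoods:
            if n.chrom == chrom:
                chrom_members |= set(n.member_gene_ids)
        per_chrom[chrom] = 100.0 * len(chrom_members & chrom_annotated) / len(chrom_annotated)

    return SpeciesSummary(
        species_id=species_id,
        n_neighborhoods=len(neighborhoods),
        pct_genes_in_neighborhoods=pct,
        mean_gene_density=float(np.mean(densities)) if densities else None,
        mean_gc=float(np.mean(gcs)) if gcs else None,
        per_chromosome_pct=per_chrom,
    )
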