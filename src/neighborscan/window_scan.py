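"""Sliding windows along chromosomes and gene-to-window assignment.

Window size is chosen per species so a window holds ~50 genes on average;
windows advance in steps of half a window, so each interior gene midpoint
falls in exactly two windows. Genes are assigned to a window when their
midpoint lies in ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import GeneRecord

__all__ = ["GenomicWindow", "choose_window_size", "make_windows", "make_gene_count_windows"]


@dataclass
class GenomicWindow:
    window_id: int
    chrom: str
    start: int
    end: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window [{self.start}, {self.end}) is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


def choose_window_size(genes: Sequence[GeneRecord], target_gene_count: int = 50) -> int:
    """Window size (bp) so that windows hold ~target_gene_count genes on average.

    The genome extent is the per-chromosome maximum gene end, summed; the
    window is that extent divided by the gene count, times the target.
    """
    if target_gene_count <= 0:
        raise ValueError("target_gene_count must be >= 1")
    if not genes:
        raise ValueError("cannot size windows with zero genes")
    span_by_chrom: dict[str, int] = {}
    for g in genes:
        span_by_chrom[g.chrom] = max(span_by_chrom.get(g.chrom, 0), g.end)
    total_span = sum(span_by_chrom.values())
    return max(1, int(round(total_span / len(genes) * target_gene_count)))


def make_windows(
    genes: Sequence[GeneRecord],
    window_bp: int,
    step_bp: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicWindow]:
    """Tile every gene-bearing chromosome with overlapping windows.

    Windows start at 0 and advance by ``step_bp`` (default half a window)
    while the start is inside the chromosome span (max gene end unless
    ``chrom_lengths`` is given). A trailing window truncated at the span is
    kept only when it contains at least one gene midpoint; full windows are
    kept even when empty so the scan's denominator is well defined.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if step_bp is None:
        step_bp = max(1, window_bp // 2)
    if step_bp < 1:
        raise ValueError("step_bp must be >= 1")
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp (windows must overlap or abut)")

    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    windows: list[GenomicWindow] = []
    wid = 0
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.midpoint, g.gene_id))
        mids = np.array([g.midpoint for g in chrom_genes])
        span = max(g.end for g in chrom_genes)
        if chrom_lengths and chrom in chrom_lengths:
            span = max(span, chrom_lengths[chrom])
        start = 0
        while start < span:
            end = min(start + window_bp, span)
            lo = int(np.searchsorted(mids, start, side="left"))
            hi = int(np.searchsorted(mids, end, side="left"))
            ids = [chrom_genes[i].gene_id for i in range(lo, hi)]
            truncated = (start + window_bp) > span
            if not truncated or ids:
                windows.append(GenomicWindow(wid, chrom, start, end, ids))
                wid += 1
            start += step_bp
    return windows


def make_gene_count_windows(
    genes: Sequence[GeneRecord], genes_per_window: int = 50, step_genes: int | None = None
) -> list[GenomicWindow]:
    """Alternative rank-based mode: exactly k consecutive genes per window.

    Robust to gene-density variation; the window span is the bounding box of
    its member genes.
    """
    if genes_per_window < 2:
        raise ValueError("genes_per_window must be >= 2")
    if step_genes is None:
        step_genes = max(1, genes_per_window // 2)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    windows: list[GenomicWindow] = []
    wid = 0
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        i = 0
        while i < len(chrom_genes):
            block = chrom_genes[i:i + genes_per_window]
            if len(block) < 2:
                break
            windows.append(GenomicWindow(
                wid, chrom, min(g.start for g in block), max(g.end for g in block),
                [g.gene_id for g in block],
            ))
            wid += 1
            if i + genes_per_window >= len(chrom_genes):
                break
            i += step_genes
    return windows
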