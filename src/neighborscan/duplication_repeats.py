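"""Duplication and repeat content of functional neighborhoods.

Three independent checks of the tandem-duplication hypothesis, plus a
repeat-enrichment test:

* segmental duplications — a one-sided binomial test of whether the count
  of SDs falling fully inside neighborhoods exceeds the length-proportional
  expectation (SDs straddling a boundary are removed as ambiguous);
* protein-similarity hit profiles — mean number of high-identity hits per
  gene within a window (a single-copy region gives 1.0, an N-fold amplified
  family gives N), compared between neighborhood and background windows
  with a Welch t-test;
* paralog fractions — share of region genes with at least one paralog;
* repeat (e.g. SINE) enrichment — a seeded permutation test re-placing the
  neighborhood regions uniformly along their chromosomes. The permutation
  construction is this package's reconstruction of an enrichment test whose
  original form was informally specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import IntervalTrack

__all__ = [
    "SDTestResult",
    "HitProfile",
    "interval_counts_in_regions",
    "sd_binomial_test",
    "similarity_hits_per_window",
    "compare_hit_distributions",
    "feature_enrichment_permutation",
    "paralog_fraction",
]


@dataclass
class SDTestResult:
    k_in: int
    k_out: int
    L_in_mbp: float
    L_total_mbp: float
    p0: float            # expected in-fraction = L_in / L_total
    obs_prop: float      # k_in / (k_in + k_out)
    exp_prop: float      # = p0
    p: float             # one-sided binomial P(X >= k_in)


@dataclass
class HitProfile:
    window_id: int
    threshold: float
    hits_per_gene: float


def _merge(intervals: Iterable[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in intervals:
        by_chrom.setdefault(c, []).append((s, e))
    out: dict[str, list[tuple[int, int]]] = {}
    for c, spans in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(spans):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[c] = [(s, e) for s, e in merged]
    return out


def interval_counts_in_regions(
    track: IntervalTrack, regions: Iterable[tuple[str, int, int]]
) -> tuple[int, int, int]:
    """Classify each track interval as fully inside / fully outside regions.

    Intervals straddling a region boundary are ambiguous and removed.
    Returns (k_in, k_out, n_ambiguous); they sum to len(track).
    """
    merged = _merge(regions)
    k_in = k_out = n_amb = 0
    for chrom, s, e in track.intervals:
        spans = merged.get(chrom, [])
        status = "out"
        for rs, re_ in spans:
            if rs <= s and e <= re_:
                status = "in"
                break
            if s < re_ and rs < e:  # partial overlap
                status = "ambiguous"
                break
        if status == "in":
            k_in += 1
        elif status == "out":
            k_out += 1
        else:
            n_amb += 1
    return k_in, k_out, n_amb


def sd_binomial_test(
    k_in: int, k_out: int, L_in_mbp: float, L_total_mbp: float
) -> SDTestResult:
    """One-sided binomial test for SD enrichment inside neighborhoods.

    Null: each of the n = k_in + k_out unambiguous SDs lands inside with
    probability p0 = L_in / L_total; p = P(X >= k_in).
    """
    n = k_in + k_out
    if n < 1:
        raise ValueError("need at least one unambiguously placed interval")
    if not (0 < L_in_mbp < L_total_mbp):
        raise ValueError("require 0 < L_in < L_total")
    p0 = L_in_mbp / L_total_mbp
    p = float(stats.binomtest(k_in, n, p0, alternative="greater").pvalue)
    return SDTestResult(
        k_in=k_in, k_out=k_out, L_in_mbp=L_in_mbp, L_total_mbp=L_total_mbp,
        p0=p0, obs_prop=k_in / n, exp_prop=p0, p=p,
    )


def similarity_hits_per_window(
    window, hit_table: pd.DataFrame, threshold: float
) -> HitProfile:
    """Mean high-identity hits per gene among a window's genes.

    Every gene scores its self-hit (1) plus the number of *other* window
    genes whose pairwise identity is >= threshold. Symmetric in the hit
    table's (a, b) orientation and invariant to row order/duplication.
    """
    genes = list(window.gene_ids)
    if not genes:
        raise ValueError(f"window {window.window_id} is empty")
    gene_set = set(genes)
    partners: dict[str, set[str]] = {g: set() for g in genes}
    sub = hit_table[hit_table["pct_identity"] >= threshold]
    for ga, gb in zip(sub["gene_a"], sub["gene_b"]):
        if ga != gb and ga in gene_set and gb in gene_set:
            partners[ga].add(gb)
            partners[gb].add(ga)
    hits = [1 + len(partners[g]) for g in genes]
    return HitProfile(window.window_id, threshold, float(np.mean(hits)))


def compare_hit_distributions(
    values_neighborhood: Sequence[float], values_background: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch t-test between hit-per-gene profiles of the two groups."""
    x = np.asarray(values_neighborhood, float)
    y = np.asarray(values_background, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def _place_non_overlapping(lengths: np.ndarray, chrom_len: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping starts for intervals of given lengths.

    Collapses the free space, drops sorted uniform cut points into it, and
    re-inflates — the standard spacings construction.
    """
    total = int(lengths.sum())
    free = chrom_len - total
    if free < 0:
        raise ValueError("regions do not fit on their chromosome")
    order = rng.permutation(len(lengths))
    cuts = np.sort(rng.uniform(0, free, size=len(lengths)))
    starts = np.empty(len(lengths), dtype=np.int64)
    offset = 0
    for rank, idx in enumerate(order):
        starts[idx] = int(cuts[rank]) + offset
        offset += int(lengths[idx])
    return starts


def feature_enrichment_permutation(
    track: IntervalTrack,
    regions: Sequence[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Empirical p for feature (e.g. SINE) enrichment inside regions.

    Statistic: number of track features whose midpoint lies in a region.
    Null: regions are re-placed uniformly at random on their own
    chromosomes, lengths preserved, no overlap among placed regions.
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)

    mids_by_chrom: dict[str, np.ndarray] = {}
    for chrom, mid in track.midpoints():
        mids_by_chrom.setdefault(chrom, []).append(mid)  # type: ignore[arg-type]
    mids_by_chrom = {c: np.sort(np.asarray(v, float)) for c, v in mids_by_chrom.items()}

    regions_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
        if c not in chrom_lengths:
            raise ValueError(f"region chromosome {c!r} has no stated length")
        if e - s > chrom_lengths[c]:
            raise ValueError(f"region ({c}, {s}, {e}) longer than its chromosome")
        regions_by_chrom.setdefault(c, []).append((s, e))

    def count_in(placed: dict[str, np.ndarray], lengths: dict[str, np.ndarray]) -> int:
        total = 0
        for c, starts in placed.items():
            mids = mids_by_chrom.get(c)
            if mids is None or len(mids) == 0:
                continue
            ends = starts + lengths[c]
            lo = np.searchsorted(mids, starts, side="left")
            hi = np.searchsorted(mids, ends, side="left")
            total += int((hi - lo).sum())
        return total

    obs_starts = {c: np.array([s for s, _ in v], dtype=np.int64) for c, v in regions_by_chrom.items()}
    lens = {c: np.array([e - s for s, e in v], dtype=np.int64) for c, v in regions_by_chrom.items()}
    observed = count_in(obs_starts, lens)

    n_ge = 0
    for _ in range(n_perm):
        placed = {
            c: _place_non_overlapping(lens[c], chrom_lengths[c], rng)
            for c in regions_by_chrom
        }
        if count_in(placed, lens) >= observed:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def paralog_fraction(region_genes: Sequence[str], paralog_pairs: Iterable[tuple[str, str]]) -> float:
    """Fraction of region genes with >= 1 paralog partner anywhere in the genome."""
    genes = list(region_genes)
    if not genes:
        raise ValueError("empty region")
    paired: set[str] = set()
    for a, b in paralog_pairs:
        paired.add(a)
        paired.add(b)
    return sum(g in paired for g in genes) / len(genes)
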