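"""Break-of-synteny density in shared functional neighborhoods.

Neighborhoods of two species "share" a function when the same term labels a
neighborhood in both; coordinates stay in the reference genome (break
tracks are typically mapped to the reference). Breakpoint density (breaks
per Mbp, breaks located by interval midpoint) is contrasted between the
merged shared-neighborhood territory and the rest of the genome with a
Pearson chi-square on the length-proportional expectation, and — within
the shared territory — between neighborhoods below and above the median
orthology fraction.

Two rounding conventions for the expected counts are supported: ``none``
(exact proportional expecteds) and ``integer`` (expecteds rounded to whole
counts before the statistic); both are reported by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import IntervalTrack, OrthologMap
from .neighborhood_enrichment import Neighborhood

__all__ = [
    "RegionPartition",
    "ChiSquareResult",
    "shared_neighborhoods",
    "bos_density",
    "bos_chi_square",
    "orthology_fraction",
    "median_orthology_partition",
]


@dataclass
class RegionPartition:
    """Breakpoint counts and lengths for a two-way genome partition."""

    label_a: str
    label_b: str
    L_a: float  # Mbp
    L_b: float  # Mbp
    k_a: int
    k_b: int

    def __post_init__(self) -> None:
        if self.L_a <= 0 or self.L_b <= 0:
            raise ValueError("partition lengths must be positive")

    @property
    def d_a(self) -> float:
        """Breakpoint density in group a (per Mbp)."""
        return self.k_a / self.L_a

    @property
    def d_b(self) -> float:
        return self.k_b / self.L_b


@dataclass
class ChiSquareResult:
    expected_a: float
    expected_b: float
    chi2: float
    df: int
    p: float


def shared_neighborhoods(
    neigh_ref: Sequence[Neighborhood], neigh_other: Sequence[Neighborhood]
) -> list[Neighborhood]:
    """Reference-species neighborhoods whose term also labels one in the other species."""
    other_terms = {n.term_id for n in neigh_other}
    return [n for n in neigh_ref if n.term_id in other_terms]


def _merged_spans(regions: Sequence[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
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


def _count_midpoints_in(track: IntervalTrack, merged: dict[str, list[tuple[int, int]]]) -> int:
    k = 0
    for chrom, mid in track.midpoints():
        for s, e in merged.get(chrom, ()):
            if s <= mid < e:
                k += 1
                break
    return k


def bos_density(
    break_track: IntervalTrack,
    regions: Sequence[tuple[str, int, int]],
    genome_length_mbp: float,
    label_a: str = "neighborhoods",
    label_b: str = "rest_of_genome",
    min_break_bp: int | None = None,
) -> RegionPartition:
    """Breakpoint density inside merged regions vs the rest of the genome.

    Breaks are located by midpoint; overlapping regions are merged before
    summing lengths, so the partition is independent of region-list order
    and duplication. ``min_break_bp`` optionally drops small rearrangements
    (e.g. keep only those > 25 kb) before counting.
    """
    if min_break_bp is not None:
        break_track = break_track.filter_min_length(min_break_bp)
    merged = _merged_spans(regions)
    L_a = sum(e - s for spans in merged.values() for s, e in spans) / 1e6
    if L_a <= 0:
        raise ValueError("regions have zero total length")
    if L_a >= genome_length_mbp:
        raise ValueError("regions exceed the stated genome length")
    k_a = _count_midpoints_in(break_track, merged)
    k_b = len(break_track) - k_a
    return RegionPartition(label_a, label_b, L_a, genome_length_mbp - L_a, k_a, k_b)


def bos_chi_square(partition: RegionPartition, rounding: str = "none") -> ChiSquareResult:
    """Pearson chi-square (df=1, no continuity correction) on the partition.

    Expected counts split the total breaks proportionally to length;
    ``rounding='integer'`` rounds each expected to the nearest whole count
    before computing the statistic.
    """
    if rounding not in ("none", "integer"):
        raise ValueError("rounding must be 'none' or 'integer'")
    k_tot = partition.k_a + partition.k_b
    if k_tot < 1:
        raise ValueError("need at least one breakpoint")
    L_tot = partition.L_a + partition.L_b
    exp_a = k_tot * partition.L_a / L_tot
    exp_b = k_tot * partition.L_b / L_tot
    if rounding == "integer":
        exp_a, exp_b = float(round(exp_a)), float(round(exp_b))
    if exp_a == 0 or exp_b == 0:
        raise ValueError("zero expected count; chi-square undefined")
    chi2 = (partition.k_a - exp_a) ** 2 / exp_a + (partition.k_b - exp_b) ** 2 / exp_b
    p = float(stats.chi2.sf(chi2, df=1))
    return ChiSquareResult(exp_a, exp_b, float(chi2), 1, p)


def orthology_fraction(
    neighborhood: Neighborhood, ortholog_map: OrthologMap, species: str | None = None
) -> float | None:
    """Fraction of member genes with >= 1 ortholog in the reference species.

    Returns None (NA) for a neighborhood without members.
    """
    if not neighborhood.member_gene_ids:
        return None
    sp = species or neighborhood.species_id
    n = sum(ortholog_map.has_ortholog(g, sp) for g in neighborhood.member_gene_ids)
    return n / len(neighborhood.member_gene_ids)


def median_orthology_partition(
    shared: Sequence[Neighborhood],
    break_track: IntervalTrack,
    rounding: str = "integer",
    min_break_bp: int | None = None,
) -> tuple[RegionPartition, ChiSquareResult]:
    """Split shared neighborhoods at the median orthology fraction.

    LOW = fraction <= median, HIGH = fraction > median (ties go LOW).
    Breaks and merged lengths are counted per group within the shared
    territory only. The chi-square uses integer-rounded expecteds by
    default, the convention for this within-neighborhood comparison.
    """
    with_frac = [n for n in shared if n.orthology_fraction is not None]
    if len(with_frac) < 2:
        raise ValueError("need >= 2 shared neighborhoods with an orthology fraction")
    fracs = np.array([n.orthology_fraction for n in with_frac], dtype=float)
    med = float(np.median(fracs))
    low = [n for n in with_frac if n.orthology_fraction <= med]  # type: ignore[operator]
    high = [n for n in with_frac if n.orthology_fraction > med]  # type: ignore[operator]
    if not high:
        raise ValueError("degenerate partition: every neighborhood at or below the median")

    if min_break_bp is not None:
        break_track = break_track.filter_min_length(min_break_bp)

    def group_stats(group: list[Neighborhood]) -> tuple[float, int]:
        merged = _merged_spans([(n.chrom, n.start, n.end) for n in group])
        L = sum(e - s for spans in merged.values() for s, e in spans) / 1e6
        k = _count_midpoints_in(break_track, merged)
        return L, k

    L_low, k_low = group_stats(low)
    L_high, k_high = group_stats(high)
    part = RegionPartition("low_orthology", "high_orthology", L_low, L_high, k_low, k_high)
    return part, bos_chi_square(part, rounding=rounding)
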