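"""Seeded synthetic genomes with the statistical structure the scan assumes.

The generator emits a complete, mutually consistent input bundle — gene
coordinates, term annotations, an expression matrix, breakpoint / SD / SINE
tracks, ortholog and similarity tables, a species tree — plus a truth table
of the planted functional neighborhoods, so every pipeline stage can be
exercised and scored without external data.

Planted structure mirrors the phenomena the analysis targets:

* positionally clustered annotations — runs of consecutive genes carry a
  focal term with probability ``within_fraction`` against a low genome-wide
  background;
* elevated within-cluster expression correlation — a one-factor model,
  ``sqrt(rho)*F + sqrt(1-rho)*noise``, with a private factor per cluster
  (rho_in) and a genome-wide factor elsewhere (rho_out);
* elevated breakpoint rate inside designated regions (Poisson with rate
  ratio lambda_in/lambda_out);
* length-proportional (null) segmental-duplication placement and Poisson
  SINEs;
* orthology fractions differing between high- and low-orthology clusters;
* a similarity table listing within-family pairs at a set identity.

One master seed fans out to named substreams, so adding a component never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    AnnotationSet,
    ExpressionMatrix,
    GeneRecord,
    IntervalTrack,
    OrthologMap,
)

__all__ = [
    "PlantedCluster",
    "SyntheticConfig",
    "TruthRegion",
    "SyntheticBundle",
    "simulate_genome",
    "simulate_breaks",
    "score_recovery",
    "write_bundle",
    "DEFAULT_TREE",
]

DEFAULT_TREE = "((((human,chimp),(mouse,rat)),chicken),fish);"

GENE_LENGTH_BP = 1000  # fixed; lengths only matter for GC/density summaries


@dataclass(frozen=True)
class PlantedCluster:
    chrom: str
    start_gene_index: int     # index among the chromosome's genes, sorted by position
    n_genes: int
    term_id: str
    within_fraction: float = 0.6
    high_orthology: bool = False


def _default_planted() -> list[PlantedCluster]:
    return [
        PlantedCluster("chr1", 200, 50, "T01", 0.6, high_orthology=True),
        PlantedCluster("chr2", 500, 50, "T02", 0.6, high_orthology=False),
        PlantedCluster("chr3", 800, 50, "T03", 0.6, high_orthology=True),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic genome (defaults = benchmark conditions)."""

    species_id: str = "synthspecies"
    n_chromosomes: int = 4
    chrom_length: int = 25_000_000
    n_genes: int = 5000
    n_terms: int = 50
    background_term_prob: float = 0.02
    planted: list[PlantedCluster] = field(default_factory=_default_planted)
    # expression
    n_samples: int = 30
    rho_in: float = 0.8
    rho_out: float = 0.0
    noise_sd: float = 1.0
    # breakpoints
    lambda_out: float = 0.093        # per Mbp outside designated regions
    rate_ratio: float = 1.68         # lambda_in / lambda_out
    # segmental duplications / repeats
    sd_count: int = 200
    sd_length: int = 20_000
    sine_density: float = 5.0        # per Mbp
    sine_length: int = 300
    # orthology
    p_orth_high: float = 0.8
    p_orth_low: float = 0.2
    ref_species: str = "refspecies"
    # similarity table
    n_planted_families: int = 5
    family_size: int = 4
    family_identity: float = 98.5
    tree_newick: str = DEFAULT_TREE

    def __post_init__(self) -> None:
        for p in (self.background_term_prob, self.rho_in, self.rho_out,
                  self.p_orth_high, self.p_orth_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be positive")
        for pc in self.planted:
            if pc.within_fraction < self.background_term_prob:
                raise ValueError(
                    f"cluster {pc.term_id}: within_fraction below the background rate"
                )


@dataclass(frozen=True)
class TruthRegion:
    chrom: str
    start: int
    end: int
    term_id: str
    gene_ids: tuple[str, ...]
    high_orthology: bool = False


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    seed: int
    genes: list[GeneRecord]
    annotations: AnnotationSet
    expression: ExpressionMatrix
    break_track: IntervalTrack
    sd_track: IntervalTrack
    sine_track: IntervalTrack
    orthologs: OrthologMap
    similarity: pd.DataFrame
    tree_newick: str
    truth: list[TruthRegion]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.config.chrom_length
                for i in range(self.config.n_chromosomes)}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable across versions and component additions."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneRecord]:
    # sample 1-kb grid slots without replacement: uniform and non-overlapping
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    n_slots = cfg.chrom_length // GENE_LENGTH_BP
    genes: list[GeneRecord] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n > n_slots:
            raise ValueError(f"{chrom}: more genes than 1-kb slots")
        slots = np.sort(rng.choice(n_slots, size=n, replace=False))
        gcs = rng.uniform(0.35, 0.55, size=n)
        for slot, gc in zip(slots, gcs):
            start = int(slot) * GENE_LENGTH_BP
            genes.append(GeneRecord(
                f"g{gid:05d}", cfg.species_id, chrom, start, start + GENE_LENGTH_BP,
                strand="+" if rng.random() < 0.5 else "-",
                gc_fraction=float(gc),
            ))
            gid += 1
    return genes


def _annotate(
    cfg: SyntheticConfig,
    genes: list[GeneRecord],
    rng: np.random.Generator,
) -> tuple[AnnotationSet, list[TruthRegion]]:
    terms = [f"T{i + 1:02d}" for i in range(cfg.n_terms)]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    cluster_members: dict[tuple[str, int], tuple[PlantedCluster, list[GeneRecord]]] = {}
    focal_override: dict[tuple[str, str], bool] = {}
    for ci, pc in enumerate(cfg.planted):
        chrom_genes = by_chrom.get(pc.chrom, [])
        if pc.start_gene_index + pc.n_genes > len(chrom_genes):
            raise ValueError(
                f"planted cluster {pc.term_id} exceeds gene count on {pc.chrom}"
            )
        members = chrom_genes[pc.start_gene_index:pc.start_gene_index + pc.n_genes]
        cluster_members[(pc.chrom, ci)] = (pc, members)
        draws = rng.random(len(members)) < pc.within_fraction
        for g, hit in zip(members, draws):
            focal_override[(g.gene_id, pc.term_id)] = bool(hit)

    pairs: list[tuple[str, str]] = []
    n = len(genes)
    for t in terms:
        hits = rng.random(n) < cfg.background_term_prob
        for g, hit in zip(genes, hits):
            ov = focal_override.get((g.gene_id, t))
            if ov is not None:
                hit = ov
            if hit:
                pairs.append((g.gene_id, t))

    truth = []
    for (chrom, ci), (pc, members) in sorted(cluster_members.items(), key=lambda kv: kv[0][1]):
        annotated = tuple(g.gene_id for g in members
                          if (g.gene_id, pc.term_id) in set(pairs))
        truth.append(TruthRegion(
            chrom=chrom, start=min(g.start for g in members),
            end=max(g.end for g in members), term_id=pc.term_id,
            gene_ids=annotated, high_orthology=pc.high_orthology,
        ))
    return AnnotationSet(pairs), truth


def _expression(
    cfg: SyntheticConfig,
    genes: list[GeneRecord],
    truth: list[TruthRegion],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    cluster_of: dict[str, int] = {}
    for ci, tr in enumerate(truth):
        for gid in tr.gene_ids:
            cluster_of[gid] = ci
    s = cfg.n_samples
    factors = rng.standard_normal((len(truth), s))
    genome_factor = rng.standard_normal(s)
    rows = np.empty((len(genes), s))
    for i, g in enumerate(genes):
        eps = rng.standard_normal(s)
        ci = cluster_of.get(g.gene_id)
        if ci is not None:
            rho, f = cfg.rho_in, factors[ci]
        else:
            rho, f = cfg.rho_out, genome_factor
        rows[i] = cfg.noise_sd * (np.sqrt(rho) * f + np.sqrt(1.0 - rho) * eps)
    df = pd.DataFrame(rows, index=[g.gene_id for g in genes],
                      columns=[f"s{j + 1}" for j in range(s)])
    return ExpressionMatrix(df)


def simulate_breaks(
    regions: Sequence[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    lambda_out: float,
    rate_ratio: float,
    rng: np.random.Generator,
) -> IntervalTrack:
    """Poisson breakpoints: rate lambda_out/Mbp outside the designated
    regions, lambda_out*rate_ratio inside. Point events (length 1)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
        by_chrom.setdefault(c, []).append((s, e))
    intervals: list[tuple[str, int, int]] = []
    for chrom, L in sorted(chrom_lengths.items()):
        spans = sorted(by_chrom.get(chrom, []))
        segments: list[tuple[int, int, float]] = []
        pos = 0
        for s, e in spans:
            if s > pos:
                segments.append((pos, s, lambda_out))
            segments.append((s, e, lambda_out * rate_ratio))
            pos = e
        if pos < L:
            segments.append((pos, L, lambda_out))
        for s, e, lam in segments:
            mean = lam * (e - s) / 1e6
            k = rng.poisson(mean)
            for p in np.sort(rng.uniform(s, e, size=k)):
                intervals.append((chrom, int(p), int(p) + 1))
    return IntervalTrack("breaks", intervals, kind="breakpoint")


def _uniform_track(
    name: str, kind: str, count: int, length: int,
    chrom_lengths: dict[str, int], rng: np.random.Generator,
) -> IntervalTrack:
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    intervals = []
    picks = rng.choice(len(chroms), size=count, p=weights)
    for ci in picks:
        chrom = chroms[ci]
        start = int(rng.integers(0, max(1, chrom_lengths[chrom] - length)))
        intervals.append((chrom, start, start + length))
    return IntervalTrack(name, intervals, kind=kind)


def _poisson_track(
    name: str, kind: str, density_per_mbp: float, length: int,
    chrom_lengths: dict[str, int], rng: np.random.Generator,
) -> IntervalTrack:
    intervals = []
    for chrom, L in sorted(chrom_lengths.items()):
        k = rng.poisson(density_per_mbp * L / 1e6)
        starts = np.sort(rng.integers(0, max(1, L - length), size=k))
        intervals.extend((chrom, int(s), int(s) + length) for s in starts)
    return IntervalTrack(name, intervals, kind=kind)


def _orthologs(
    cfg: SyntheticConfig, genes: list[GeneRecord], truth: list[TruthRegion],
    rng: np.random.Generator,
) -> OrthologMap:
    high_genes: set[str] = set()
    for tr in truth:
        if tr.high_orthology:
            high_genes |= set(tr.gene_ids)
    pairs = []
    for g in genes:
        p = cfg.p_orth_high if g.gene_id in high_genes else cfg.p_orth_low
        if rng.random() < p:
            pairs.append((g.gene_id, f"ref_{g.gene_id}"))
    return OrthologMap(cfg.species_id, cfg.ref_species, pairs)


def _similarity(
    cfg: SyntheticConfig, genes: list[GeneRecord], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    gene_ids = [g.gene_id for g in genes]
    for _ in range(cfg.n_planted_families):
        fam = rng.choice(len(gene_ids), size=min(cfg.family_size, len(gene_ids)),
                         replace=False)
        fam_ids = [gene_ids[i] for i in sorted(fam)]
        for i in range(len(fam_ids)):
            for j in range(i + 1, len(fam_ids)):
                rows.append((fam_ids[i], fam_ids[j], cfg.family_identity))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_identity"])


def simulate_genome(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a full input bundle; same (config, seed) -> identical bundle."""
    cfg = config or SyntheticConfig()
    genes = _place_genes(cfg, _stream(seed, "genes"))
    annotations, truth = _annotate(cfg, genes, _stream(seed, "annotations"))
    expression = _expression(cfg, genes, truth, _stream(seed, "expression"))
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    regions = [(t.chrom, t.start, t.end) for t in truth]
    break_track = simulate_breaks(
        regions, chrom_lengths, cfg.lambda_out, cfg.rate_ratio, _stream(seed, "breaks"))
    sd_track = _uniform_track(
        "sds", "segmental_duplication", cfg.sd_count, cfg.sd_length,
        chrom_lengths, _stream(seed, "sds"))
    sine_track = _poisson_track(
        "sines", "repeat", cfg.sine_density, cfg.sine_length,
        chrom_lengths, _stream(seed, "sines"))
    orthologs = _orthologs(cfg, genes, truth, _stream(seed, "orthology"))
    similarity = _similarity(cfg, genes, _stream(seed, "similarity"))
    return SyntheticBundle(
        config=cfg, seed=seed, genes=genes, annotations=annotations,
        expression=expression, break_track=break_track, sd_track=sd_track,
        sine_track=sine_track, orthologs=orthologs, similarity=similarity,
        tree_newick=cfg.tree_newick, truth=truth,
    )


def score_recovery(called, truth: Sequence[TruthRegion]):
    """Score called neighborhoods against the planted truth.

    A planted cluster is *recovered* when a called neighborhood of the same
    term overlaps >= 50% of the planted span. Returns (recall, precision,
    jaccard-per-cluster); precision is NaN when nothing was called.
    """
    def overlap(a_start, a_end, b_start, b_end):
        return max(0, min(a_end, b_end) - max(a_start, b_start))

    jaccards: list[float] = []
    n_recovered = 0
    for tr in truth:
        span = tr.end - tr.start
        best_j = 0.0
        recovered = False
        for n in called:
            if n.term_id != tr.term_id or n.chrom != tr.chrom:
                continue
            ov = overlap(tr.start, tr.end, n.start, n.end)
            union = (tr.end - tr.start) + (n.end - n.start) - ov
            best_j = max(best_j, ov / union if union else 0.0)
            if ov >= 0.5 * span:
                recovered = True
        jaccards.append(best_j)
        n_recovered += recovered
    recall = n_recovered / len(truth) if truth else float("nan")

    if not called:
        precision = float("nan")
    else:
        tp = 0
        for n in called:
            for tr in truth:
                if (n.term_id == tr.term_id and n.chrom == tr.chrom
                        and overlap(tr.start, tr.end, n.start, n.end) >= 0.5 * (tr.end - tr.start)):
                    tp += 1
                    break
        precision = tp / len(called)
    return recall, precision, jaccards


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle as the plain-text files the CLI consumes."""
    from .genome_io import write_gene_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("genes", "genes.bed"), ("annotations", "annotations.tsv"),
        ("expression", "expression.tsv"), ("breaks", "breaks.bed"),
        ("sds", "sds.bed"), ("sines", "sines.bed"),
        ("orthologs", "orthologs.tsv"), ("similarity", "similarity.tsv"),
        ("tree", "tree.nwk"), ("truth", "truth.tsv"),
        ("chrom_lengths", "chrom_lengths.tsv"),
    ]}
    write_gene_table(bundle.genes, paths["genes"])
    with open(paths["annotations"], "w") as fh:
        for gene, term in sorted(bundle.annotations.pairs):
            fh.write(f"{gene}\t{term}\n")
    bundle.expression.data.to_csv(paths["expression"], sep="\t")
    for key, track in [("breaks", bundle.break_track), ("sds", bundle.sd_track),
                       ("sines", bundle.sine_track)]:
        with open(paths[key], "w") as fh:
            for c, s, e in track.intervals:
                fh.write(f"{c}\t{s}\t{e}\n")
    with open(paths["orthologs"], "w") as fh:
        for a, b in sorted(bundle.orthologs.pairs):
            fh.write(f"{a}\t{b}\n")
    bundle.similarity.to_csv(paths["similarity"], sep="\t", header=False, index=False)
    paths["tree"].write_text(bundle.tree_newick + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tstart\tend\tterm\thigh_orthology\tgene_ids\n")
        for t in bundle.truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.term_id}\t"
                     f"{int(t.high_orthology)}\t{';'.join(t.gene_ids)}\n")
    with open(paths["chrom_lengths"], "w") as fh:
        for c, L in sorted(bundle.chrom_lengths.items()):
            fh.write(f"{c}\t{L}\n")
    return paths
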