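"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are 0-based, half-open ``[start, end)`` internally. GFF3
input (1-based, closed) is converted on read; BED is used as-is. Strand is
stored on :class:`GeneRecord` but ignored by every downstream statistic.

Parsers are deliberately line-oriented so that malformed input is reported
with its line number.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "AnnotationSet",
    "IntervalTrack",
    "ExpressionMatrix",
    "OrthologMap",
    "ParseError",
    "read_gene_table",
    "read_annotations",
    "read_interval_track",
    "read_expression_matrix",
    "read_ortholog_pairs",
    "read_similarity_table",
    "write_neighborhoods",
    "read_neighborhood_bed",
    "read_neighborhoods_tsv",
    "write_gene_table",
]


class ParseError(ValueError):
    """Raised for malformed input lines; message carries the line number."""


@dataclass(frozen=True)
class GeneRecord:
    """A positioned, stranded gene (0-based, half-open coordinates)."""

    gene_id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for gene {self.gene_id!r}: "
                "require end > start >= 0"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")

    @property
    def midpoint(self) -> float:
        """Midpoint in bp; the single position used for window assignment."""
        return (self.start + self.end) / 2.0


class AnnotationSet:
    """Gene -> functional-term mapping (e.g. GO annotations).

    Duplicate (gene, term) pairs are collapsed. An optional ``parent_map``
    (term -> parent terms) enables opt-in propagation of annotations up the
    term hierarchy via :meth:`propagate`; by default annotations are taken
    at face value so runs are reproducible without an ontology file.
    """

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        parent_map: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.pairs: set[tuple[str, str]] = set()
        self._genes_by_term: dict[str, set[str]] = {}
        self._terms_by_gene: dict[str, set[str]] = {}
        for gene, term in pairs:
            if not term:
                raise ValueError("term_id must be non-empty")
            if not gene:
                raise ValueError("gene_id must be non-empty")
            if (gene, term) in self.pairs:
                continue
            self.pairs.add((gene, term))
            self._genes_by_term.setdefault(term, set()).add(gene)
            self._terms_by_gene.setdefault(gene, set()).add(term)
        self.parent_map = dict(parent_map) if parent_map else None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        return set(self._terms_by_gene)

    @property
    def terms(self) -> set[str]:
        return set(self._genes_by_term)

    def genes_with_term(self, term: str) -> set[str]:
        return set(self._genes_by_term.get(term, set()))

    def terms_for_gene(self, gene: str) -> set[str]:
        return set(self._terms_by_gene.get(gene, set()))

    def has(self, gene: str, term: str) -> bool:
        return (gene, term) in self.pairs

    def propagate(self) -> "AnnotationSet":
        """Return a new set with each annotation copied to all ancestor terms.

        Requires a parent map; cycles raise ``ValueError``.
        """
        if self.parent_map is None:
            raise ValueError("propagation requested but no parent map supplied")

        ancestors: dict[str, set[str]] = {}

        def climb(term: str, seen: tuple[str, ...]) -> set[str]:
            if term in ancestors:
                return ancestors[term]
            if term in seen:
                raise ValueError(f"cycle in parent map at term {term!r}")
            acc: set[str] = set()
            for parent in self.parent_map.get(term, ()):  # type: ignore[union-attr]
                acc.add(parent)
                acc |= climb(parent, seen + (term,))
            ancestors[term] = acc
            return acc

        new_pairs = set(self.pairs)
        for gene, term in self.pairs:
            for anc in climb(term, ()):
                new_pairs.add((gene, anc))
        return AnnotationSet(new_pairs, parent_map=self.parent_map)


VALID_TRACK_KINDS = ("breakpoint", "segmental_duplication", "repeat", "other")


@dataclass
class IntervalTrack:
    """A named set of positioned features (synteny breaks, SDs, SINEs, ...)."""

    name: str
    intervals: list[tuple[str, int, int]]
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in VALID_TRACK_KINDS:
            raise ValueError(f"kind must be one of {VALID_TRACK_KINDS}")
        cleaned = []
        for chrom, start, end in self.intervals:
            if start < 0:
                raise ValueError(f"negative coordinate in interval ({chrom}, {start}, {end})")
            if end < start:
                raise ValueError(f"end < start in interval ({chrom}, {start}, {end})")
            if end == start:
                # point events (e.g. breakpoints) are normalized to length 1
                end = start + 1
            cleaned.append((chrom, start, end))
        self.intervals = sorted(cleaned)

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self) -> list[tuple[str, float]]:
        return [(c, (s + e) / 2.0) for c, s, e in self.intervals]

    def filter_min_length(self, min_bp: int) -> "IntervalTrack":
        """Keep only intervals of length >= min_bp (e.g. rearrangements > 25 kb)."""
        kept = [(c, s, e) for c, s, e in self.intervals if e - s >= min_bp]
        return IntervalTrack(self.name, kept, kind=self.kind)


class ExpressionMatrix:
    """Gene-by-sample expression values (rows = genes, columns = samples)."""

    def __init__(self, data: pd.DataFrame) -> None:
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
        if data.shape[1] < 2:
            raise ValueError("expression matrix needs >= 2 samples")
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def rows(self, gene_ids: Sequence[str]) -> pd.DataFrame:
        present = [g for g in gene_ids if g in self.data.index]
        return self.data.loc[present]


class OrthologMap:
    """Unique gene pairs between two species; many-to-many allowed."""

    def __init__(self, species_a: str, species_b: str, pairs: Iterable[tuple[str, str]]):
        self.species_a = species_a
        self.species_b = species_b
        self.pairs: set[tuple[str, str]] = set(pairs)
        self._a_genes = {a for a, _ in self.pairs}
        self._b_genes = {b for _, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def has_ortholog(self, gene: str, species: str) -> bool:
        """True if *gene* of *species* has >=1 partner in the other species."""
        if species == self.species_a:
            return gene in self._a_genes
        if species == self.species_b:
            return gene in self._b_genes
        raise KeyError(f"species {species!r} not part of this map")


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | Path, comment: tuple[str, ...] = ("#",)) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def read_gene_table(
    path: str | Path, format: str = "bed", species_id: str = "species"
) -> list[GeneRecord]:
    """Read genes from BED (>=4 columns) or GFF3 (``gene`` features only).

    GFF3 1-based closed starts are shifted to the internal 0-based half-open
    convention. Records come back sorted by (chrom, start).
    """
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"format must be 'bed' or 'gff3', got {format!r}")
    records: list[GeneRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "bed":
                if len(fields) < 4:
                    raise ValueError("BED gene line needs >= 4 columns")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) >= 6 else "."
                rec = GeneRecord(name, species_id, chrom, start, end, strand)
            else:
                if len(fields) < 9:
                    raise ValueError("GFF3 line needs 9 columns")
                if fields[2].lower() != "gene":
                    continue
                chrom = fields[0]
                start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(fields[4])
                strand = fields[6] if fields[6] in ("+", "-") else "."
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if not gene_id:
                    raise ValueError("GFF3 gene feature without ID/gene_id/Name attribute")
                rec = GeneRecord(gene_id, species_id, chrom, start, end, strand)
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return records


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6 (score column carries 1000*gc_fraction when set)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda r: (r.chrom, r.start, r.gene_id)):
            score = 0 if g.gc_fraction is None else int(round(1000 * g.gc_fraction))
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{score}\t{g.strand}\n")


def read_annotations(path: str | Path, format: str = "tsv") -> AnnotationSet:
    """Read gene->term annotations from 2-column TSV or a GAF 2.x subset.

    GAF rows use column 2 (DB Object ID) and column 5 (term ID); comment
    lines starting with ``!`` or ``#`` are skipped. Duplicates collapse.
    """
    fmt = format.lower()
    if fmt not in ("tsv", "gaf"):
        raise ValueError(f"format must be 'tsv' or 'gaf', got {format!r}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path, comment=("#", "!")):
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "tsv":
                if len(fields) < 2:
                    raise ValueError("annotation TSV needs 2 columns (gene_id, term_id)")
                pairs.append((fields[0], fields[1]))
            else:
                if len(fields) < 5:
                    raise ValueError("GAF line needs >= 5 columns")
                pairs.append((fields[1], fields[4]))
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    if not pairs:
        raise ParseError(f"{path}: no annotation rows found")
    ann = AnnotationSet(pairs)
    log.info(
        "read %d annotation pairs (%d genes, %d terms) from %s",
        len(ann), len(ann.genes), len(ann.terms), path,
    )
    return ann


def read_interval_track(path: str | Path, kind: str = "other", name: str | None = None) -> IntervalTrack:
    """Read a BED3+ interval track; zero-length rows become length-1 points."""
    intervals: list[tuple[str, int, int]] = []
    n_zero = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        try:
            if len(fields) < 3:
                raise ValueError("BED interval line needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or end < 0:
                raise ValueError(f"negative coordinate ({start}, {end})")
            if end == start:
                n_zero += 1
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        intervals.append((chrom, start, end))
    if n_zero:
        warnings.warn(
            f"{path}: {n_zero} zero-length intervals normalized to length 1", stacklevel=2
        )
    return IntervalTrack(name or Path(path).stem, intervals, kind=kind)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """TSV with header row of sample ids; first column = gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def read_ortholog_pairs(path: str | Path, species_a: str, species_b: str) -> OrthologMap:
    """TSV with two columns: species_a gene, species_b gene."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog table needs 2 columns")
    return OrthologMap(species_a, species_b, zip(df[0], df[1]))


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    """Protein-similarity hits: columns gene_a, gene_b, pct_identity."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_a", "gene_b", "pct_identity"])
    df["pct_identity"] = df["pct_identity"].astype(float)
    return df


# ---------------------------------------------------------------------------
# neighborhood serialization

_NEIGH_COLUMNS = [
    "species", "term", "chrom", "start", "end", "q",
    "n_member_genes", "member_gene_ids",
]


def _bed_score(q: float) -> int:
    """-10*log10(q), rounded and capped at 1000 (q = 0 clamps to the cap)."""
    if q <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(q))))


def write_neighborhoods(neighborhoods, tsv_path: str | Path, bed_path: str | Path) -> None:
    """Serialize called neighborhoods as a TSV table plus a BED6 track."""
    rows = []
    for n in neighborhoods:
        rows.append({
            "species": n.species_id,
            "term": n.term_id,
            "chrom": n.chrom,
            "start": n.start,
            "end": n.end,
            "q": n.best_q,
            "n_member_genes": len(n.member_gene_ids),
            "member_gene_ids": ";".join(n.member_gene_ids),
        })
    pd.DataFrame(rows, columns=_NEIGH_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for n in sorted(neighborhoods, key=lambda n: (n.chrom, n.start)):
            fh.write(
                f"{n.chrom}\t{n.start}\t{n.end}\t{n.term_id}\t{_bed_score(n.best_q)}\t.\n"
            )


def read_neighborhood_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read back (chrom, start, end, term) rows from a neighborhood BED6."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}, line {lineno}: BED6 neighborhood row needs >= 4 columns")
        out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


def read_neighborhoods_tsv(path: str | Path):
    """Read a neighborhoods TSV (as written by :func:`write_neighborhoods`)."""
    from .neighborhood_enrichment import Neighborhood

    df = pd.read_csv(path, sep="\t", dtype={"member_gene_ids": str})
    out = []
    for row in df.itertuples(index=False):
        members = [] if pd.isna(row.member_gene_ids) or not row.member_gene_ids else str(
            row.member_gene_ids).split(";")
        out.append(Neighborhood(
            species_id=row.species, term_id=row.term, chrom=row.chrom,
            start=int(row.start), end=int(row.end),
            member_gene_ids=members, all_gene_ids=list(members),
            best_q=float(row.q),
        ))
    return out
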