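"""Coordinate conventions, interval algebra, and plain-text genomic I/O.

All coordinates are 0-based half-open (BED convention). Two features
overlap iff they share at least one base pair. Chromosome names are
matched verbatim; no ``chr`` prefix normalization is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "GeneAnnotation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "read_gtf_genes",
    "merge_intervals",
    "count_containing",
    "containing_mask",
]


class BedParseError(ValueError):
    """Raised when a BED/bedGraph record violates the format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared bp under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Gap in bp between ``pos`` and the interval; 0 if inside.

        ``pos == end`` (first position past a half-open interval) has
        distance 0 by this gap convention, like bedtools closest.
        """
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end
        return 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with a name and a non-negative signal score."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class SignalTrack:
    """Per-chromosome coverage arrays (e.g. rpm/bp), fixed bin size.

    Values are stored as float32; ``array length * bin_size`` covers the
    declared chromosome length (last bin may overhang the chromosome end).
    """

    def __init__(self, data: Mapping[str, np.ndarray], bin_size: int = 1) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.data: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            a = np.asarray(arr, dtype=np.float32)
            if (a < 0).any():
                raise ValueError(f"negative coverage values on {chrom}")
            self.data[chrom] = a

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], bin_size: int = 1) -> "SignalTrack":
        data = {
            c: np.zeros(-(-size // bin_size), dtype=np.float32)
            for c, size in chrom_sizes.items()
        }
        return cls(data, bin_size=bin_size)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp coverage over ``[start, end)``.

        With bin_size > 1 each bin's value is treated as constant per bp.
        """
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} missing from signal track")
        arr = self.data[chrom]
        if self.bin_size == 1:
            return float(arr[start:end].sum())
        # fractional bins at the edges
        b0, b1 = start // self.bin_size, (end - 1) // self.bin_size
        if b0 == b1:
            return float(arr[b0]) * (end - start)
        total = float(arr[b0]) * ((b0 + 1) * self.bin_size - start)
        total += float(arr[b0 + 1 : b1].sum()) * self.bin_size
        total += float(arr[b1]) * (end - b1 * self.bin_size)
        return total


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS-anchored gene record.

    ``tss`` is the single-bp transcription start position (strand-aware:
    ``body.start`` for + genes, ``body.end - 1`` for - genes when built
    from a GTF). It must lie within ``body``.
    """

    gene_id: str
    symbol: str
    body: GenomicInterval
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body {self.body} for {self.gene_id}"
            )

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss_interval(self) -> GenomicInterval:
        return GenomicInterval(self.body.chrom, self.tss, self.tss + 1, self.strand)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_BED_DIALECTS = ("bed3", "bed6", "narrowPeak")


def read_bed(path: str | Path, dialect: str = "bed6") -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into a list of :class:`Peak`.

    narrowPeak puts the signalValue (column 7) into ``score``; BED6 uses
    column 5. Missing score columns yield 0. Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}; expected one of {_BED_DIALECTS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and dialect != "bed3" else "."
            strand = "."
            score = 0.0
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise BedParseError(f"{path}:{lineno}: narrowPeak requires 10 columns")
                strand = fields[5]
                score = float(fields[6])
            elif dialect == "bed6" and len(fields) > 4:
                score = float(fields[4]) if fields[4] != "." else 0.0
                if len(fields) > 5:
                    strand = fields[5]
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                peaks.append(Peak(iv, name=name, score=score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path, dialect: str = "bed6") -> None:
    """Write peaks back out; BED6 round-trips coordinates bit-exactly."""
    if dialect not in ("bed3", "bed6"):
        raise ValueError("write_bed supports bed3 and bed6")
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                score = f"{p.score:g}"
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t{p.interval.strand}\n"
                )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> SignalTrack:
    """Read a bedGraph into a per-bp :class:`SignalTrack` (bin_size 1).

    Uncovered positions are 0. Overlapping records are resolved
    last-writer-wins with a logged warning. Records on chromosomes absent
    from ``chrom_sizes``, or extending past the declared length, raise.
    """
    track = SignalTrack.zeros(chrom_sizes, bin_size=1)
    covered: dict[str, IntervalTree] = {c: IntervalTree() for c in chrom_sizes}
    n_overlap = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom = fields[0]
            if chrom not in chrom_sizes:
                raise BedParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in chrom sizes"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed record") from exc
            if end <= start or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid span [{start},{end})")
            if end > chrom_sizes[chrom]:
                raise BedParseError(
                    f"{path}:{lineno}: record end {end} beyond {chrom!r} "
                    f"length {chrom_sizes[chrom]}"
                )
            if value < 0:
                raise BedParseError(f"{path}:{lineno}: negative coverage {value}")
            if covered[chrom].overlaps(start, end):
                n_overlap += 1
            covered[chrom].addi(start, end)
            track.data[chrom][start:end] = value
    if n_overlap:
        logger.warning(
            "%s: %d overlapping bedGraph records resolved last-writer-wins",
            path,
            n_overlap,
        )
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Emit non-zero runs of a per-bp track as bedGraph records."""
    if track.bin_size != 1:
        raise ValueError("write_bedgraph requires a per-bp track")
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


_GENE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss", "body_start", "body_end"]


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Gene annotation TSV with columns gene_id, symbol, chrom, strand,
    tss, body_start, body_end (header row required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str, "symbol": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise BedParseError(f"{path}: missing gene table columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        body = GenomicInterval(row.chrom, int(row.body_start), int(row.body_end))
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                body=body,
                strand=row.strand,
                tss=int(row.tss),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tss}"
                f"\t{g.body.start}\t{g.body.end}\n"
            )


def read_gtf_genes(path: str | Path) -> list[GeneAnnotation]:
    """Minimal GTF reader: ``gene`` feature lines only.

    GTF is 1-based closed; coordinates are converted to 0-based half-open.
    The TSS is the 5' end of the gene body according to strand.
    """
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            chrom, _, _, start1, end1, _, strand, _, attrs = fields[:9]
            start, end = int(start1) - 1, int(end1)
            attr_map = {}
            for item in attrs.strip().rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr_map[key] = val.strip().strip('"')
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise BedParseError(f"{path}:{lineno}: gene line lacks gene_id")
            symbol = attr_map.get("gene_name", gene_id)
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    symbol=symbol,
                    body=GenomicInterval(chrom, start, end),
                    strand=strand,
                    tss=tss,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(
    items: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose separation is <= ``gap`` bp, per chromosome.

    Input order is irrelevant; output is sorted (chrom, start). Two
    intervals merge iff ``next.start - prev.end <= gap``, so touching
    intervals always merge. Idempotent for any fixed ``gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_pos = sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def containing_mask(
    regions: Sequence[GenomicInterval], peaks: Iterable[Peak]
) -> np.ndarray:
    """Boolean mask: region i has >=1 bp intersection with >=1 peak."""
    trees = _peak_trees(peaks)
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlaps(r.start, r.end):
            mask[i] = True
    return mask


def count_containing(
    regions: Sequence[GenomicInterval], peaks: Iterable[Peak]
) -> int:
    """Number of regions intersecting at least one peak (each region once)."""
    return int(containing_mask(regions, peaks).sum())
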