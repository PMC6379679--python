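"""Statistics linking the SE/TE partition to transcription-factor binding.

Four questions, four operations:

* do super-enhancer regions contain TF peaks more often than typical
  enhancers? (Pearson chi-squared on a 2x2 containment table)
* do two TF peak sets co-localize genome-wide? (Fisher's exact test over
  disjoint genome windows, plus reciprocal overlap fractions)
* which genes are direct targets of a TF? (bound near the TSS or over
  the body, and responsive beyond a fold-change threshold on knockdown)
* what fraction of one TF's direct targets is co-occupied by a second
  TF?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genomic import GeneAnnotation, GenomicInterval, Peak, containing_mask

__all__ = [
    "ContingencyResult",
    "PeakOverlapResult",
    "DirectTargetCall",
    "DirectTargetResult",
    "CooccupancyResult",
    "pearson_chi2_2x2",
    "containment_chi2",
    "make_windows",
    "peak_overlap_fisher",
    "call_direct_targets",
    "cooccupancy_fraction",
]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 contingency test outcome.

    ``table`` rows are the two region/peak classes, columns are
    (with-feature, without-feature). ``odds_ratio`` is the sample odds
    ratio ad/bc (+inf when bc = 0 and ad > 0; nan for 0/0).
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    odds_ratio: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def pearson_chi2_2x2(
    table: Sequence[Sequence[int]], yates: bool = False
) -> ContingencyResult:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction
    by default."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "zero margin in contingency table; use Fisher's exact test instead"
        )
    stat, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return ContingencyResult(
        table=((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        statistic=float(stat),
        p_value=float(p),
        odds_ratio=_odds_ratio(*t.ravel().tolist()),
        method="pearson_chi2",
    )


def containment_chi2(
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
    peaks: Iterable[Peak],
    yates: bool = False,
) -> ContingencyResult:
    """Chi-squared test of 'contains >=1 peak' between two region classes.

    Table rows: class A, class B; columns: (with peak, without peak).
    """
    if not regions_a or not regions_b:
        raise ValueError("both region lists must be non-empty")
    peaks = list(peaks)
    a_with = int(containing_mask(list(regions_a), peaks).sum())
    b_with = int(containing_mask(list(regions_b), peaks).sum())
    table = [
        [a_with, len(regions_a) - a_with],
        [b_with, len(regions_b) - b_with],
    ]
    return pearson_chi2_2x2(table, yates=yates)


def make_windows(
    chrom_sizes: Mapping[str, int], width: int
) -> list[GenomicInterval]:
    """Tile each chromosome into disjoint windows of ``width`` bp
    (last window truncated)."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    windows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for s in range(0, size, width):
            windows.append(GenomicInterval(chrom, s, min(s + width, size)))
    return windows


def median_peak_width(*peak_sets: Sequence[Peak]) -> int:
    widths = [p.end - p.start for peaks in peak_sets for p in peaks]
    if not widths:
        raise ValueError("no peaks supplied")
    return int(np.median(widths))


@dataclass(frozen=True)
class PeakOverlapResult:
    """Genome-window Fisher test of co-localization of two peak sets,
    with reciprocal >=1 bp overlap counts and percentages."""

    contingency: ContingencyResult
    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int

    @property
    def fraction_a(self) -> float:
        """Fraction of set-A peaks overlapping set B (>=1 bp, each once)."""
        return self.n_a_overlapping_b / self.n_a

    @property
    def fraction_b(self) -> float:
        return self.n_b_overlapping_a / self.n_b

    @property
    def fraction_a_pct(self) -> float:
        """% of set-A peaks overlapping set B, nearest percent."""
        return float(round(100.0 * self.fraction_a))

    @property
    def fraction_b_pct(self) -> float:
        return float(round(100.0 * self.fraction_b))


def _count_overlapping_peaks(peaks: Sequence[Peak], others: Sequence[Peak]) -> int:
    trees: dict[str, IntervalTree] = {}
    for p in others:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    n = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlaps(p.start, p.end):
            n += 1
    return n


def peak_overlap_fisher(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    genome_windows: Sequence[GenomicInterval],
) -> PeakOverlapResult:
    """Fisher's exact test for co-localization of two peak sets.

    Each disjoint genome window is classified by (hit by A?, hit by B?);
    the 2x2 window-count table is tested two-sided by hypergeometric
    enumeration. Reciprocal peak-level overlap counts (>=1 bp rule, each
    peak counted once) are reported alongside.
    """
    ordered = sorted(genome_windows, key=lambda w: (w.chrom, w.start))
    for w1, w2 in zip(ordered, ordered[1:]):
        if w1.overlaps(w2):
            raise ValueError(f"genome windows overlap: {w1} vs {w2}")
    hit_a = containing_mask(ordered, peaks_a)
    hit_b = containing_mask(ordered, peaks_b)
    table = np.array(
        [
            [int((hit_a & hit_b).sum()), int((hit_a & ~hit_b).sum())],
            [int((~hit_a & hit_b).sum()), int((~hit_a & ~hit_b).sum())],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    result = ContingencyResult(
        table=((int(table[0, 0]), int(table[0, 1])), (int(table[1, 0]), int(table[1, 1]))),
        statistic=float("nan"),
        p_value=float(p),
        odds_ratio=_odds_ratio(*table.ravel().tolist()),
        method="fisher_exact",
    )
    return PeakOverlapResult(
        contingency=result,
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        n_a_overlapping_b=_count_overlapping_peaks(peaks_a, peaks_b),
        n_b_overlapping_a=_count_overlapping_peaks(peaks_b, peaks_a),
    )


@dataclass(frozen=True)
class DirectTargetCall:
    gene_id: str
    bound: bool
    log2fc_on_knockdown: float
    is_direct_target: bool


@dataclass(frozen=True)
class DirectTargetResult:
    """Per-gene direct-target calls plus genes lacking expression data."""

    calls: tuple[DirectTargetCall, ...]
    untested: tuple[str, ...]
    fc_threshold: float
    bind_window: int

    @property
    def direct_targets(self) -> list[str]:
        return [c.gene_id for c in self.calls if c.is_direct_target]

    @property
    def bound_genes(self) -> list[str]:
        return [c.gene_id for c in self.calls if c.bound]


def _bound_mask(
    genes: Sequence[GeneAnnotation], tf_peaks: Sequence[Peak], bind_window: int
) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for p in tf_peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    mask = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        lo = max(0, g.tss - bind_window)
        hi = g.tss + bind_window + 1
        if tree.overlaps(lo, hi) or tree.overlaps(g.body.start, g.body.end):
            mask[i] = True
    return mask


def call_direct_targets(
    tf_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    log2fc: Mapping[str, float],
    bind_window: int = 50_000,
    fc_threshold: float = 1.0,
) -> DirectTargetResult:
    """Direct targets: bound by the TF and responsive to its knockdown.

    bound: >=1 TF peak within TSS +/- bind_window or overlapping the gene
    body. Responsive: |log2FC| > fc_threshold (default 1.0, i.e. changed
    more than 2-fold in either direction). Genes absent from ``log2fc``
    are reported in ``untested`` rather than silently dropped.
    """
    bound = _bound_mask(genes, tf_peaks, bind_window)
    calls: list[DirectTargetCall] = []
    untested: list[str] = []
    for g, b in zip(genes, bound):
        if g.gene_id not in log2fc:
            untested.append(g.gene_id)
            continue
        fc = float(log2fc[g.gene_id])
        calls.append(
            DirectTargetCall(
                gene_id=g.gene_id,
                bound=bool(b),
                log2fc_on_knockdown=fc,
                is_direct_target=bool(b) and abs(fc) > fc_threshold,
            )
        )
    return DirectTargetResult(
        calls=tuple(calls),
        untested=tuple(untested),
        fc_threshold=fc_threshold,
        bind_window=bind_window,
    )


@dataclass(frozen=True)
class CooccupancyResult:
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> float:
        """Co-occupied fraction as a percentage, one decimal."""
        return round(100.0 * self.count / self.total, 1)


def cooccupancy_fraction(
    targets: Sequence[str],
    second_tf_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    bind_window: int = 50_000,
) -> CooccupancyResult:
    """Fraction of target genes bound by a second TF (same binding rule
    as :func:`call_direct_targets`)."""
    if not targets:
        raise ValueError("targets must be non-empty")
    target_set = set(targets)
    gene_list = [g for g in genes if g.gene_id in target_set]
    missing = target_set - {g.gene_id for g in gene_list}
    if missing:
        raise ValueError(f"targets missing from annotation: {sorted(missing)[:5]}...")
    bound = _bound_mask(gene_list, second_tf_peaks, bind_window)
    return CooccupancyResult(count=int(bound.sum()), total=len(targets))
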