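"""ROSE-style super-enhancer identification.

The workflow mirrors the standard H3K27ac super-enhancer pipeline:

1. remove candidate peaks fully contained in promoter windows
   (TSS +/- ``tss_exclusion``),
2. stitch the remaining peaks within ``stitch_distance`` of each other
   into candidate enhancer units,
3. quantify each stitched unit as background-subtracted summed coverage,
4. rank units by signal and place the super/typical cutoff at the point
   of the ascending rank-signal ("hockey stick") curve where a tangent
   of slope 1 touches — formalized as argmax(x - y) on the unit-scaled
   curve,
5. link enhancer units to genes by TSS proximity / body overlap, and
6. nominate consensus SE genes recurring across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeParams",
    "StitchedEnhancer",
    "LandscapeResult",
    "GeneAssignment",
    "stitch",
    "quantify",
    "call_cutoff",
    "build_landscape",
    "assign_genes",
    "nominate_consensus",
]


@dataclass(frozen=True)
class LandscapeParams:
    """Tunable distances of the SE-calling procedure (all bp, all >= 0).

    stitch_distance: maximum gap between peaks merged into one unit.
    tss_exclusion: promoter half-window; peaks fully inside a
        TSS +/- tss_exclusion window are dropped before stitching
        (0 disables the filter).
    assignment_window: TSS-to-enhancer distance for gene assignment.
    """

    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    assignment_window: int = 50_000

    def __post_init__(self) -> None:
        for name in ("stitch_distance", "tss_exclusion", "assignment_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StitchedEnhancer:
    """A stitched candidate enhancer unit with its constituent peaks."""

    region: GenomicInterval
    constituents: tuple[Peak, ...]
    signal: float = 0.0
    rank: int | None = None
    is_super: bool = False

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        for p in self.constituents:
            if not self.region.contains(p.interval):
                raise ValueError(f"constituent {p.interval} outside region {self.region}")


@dataclass(frozen=True)
class LandscapeResult:
    """Ranked enhancer landscape with the SE/TE partition.

    ``enhancers`` are sorted by rank (1 = highest signal). ``cutoff_index``
    is the position on the *ascending* signal curve at which the tangent
    condition holds; enhancers with signal strictly above
    ``cutoff_signal`` are super.
    """

    enhancers: tuple[StitchedEnhancer, ...]
    cutoff_signal: float
    cutoff_index: int
    sample_id: str = ""

    @property
    def super_enhancers(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if e.is_super]

    @property
    def typical_enhancers(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if not e.is_super]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.region.chrom for e in self.enhancers],
                "start": [e.region.start for e in self.enhancers],
                "end": [e.region.end for e in self.enhancers],
                "signal": [e.signal for e in self.enhancers],
                "rank": [e.rank for e in self.enhancers],
                "is_super": [e.is_super for e in self.enhancers],
                "n_constituents": [len(e.constituents) for e in self.enhancers],
            }
        )


@dataclass(frozen=True)
class GeneAssignment:
    """Genes linked to one enhancer: (gene_id, distance bp, relation)."""

    enhancer: StitchedEnhancer
    genes: tuple[tuple[str, int, str], ...]
    sample_id: str = ""


def _promoter_windows(
    genes: Iterable[GeneAnnotation], half_window: int
) -> list[GenomicInterval]:
    windows = []
    for g in genes:
        start = max(0, g.tss - half_window)
        windows.append(GenomicInterval(g.chrom, start, g.tss + half_window + 1))
    return windows


def stitch(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation] = (),
    params: LandscapeParams = LandscapeParams(),
) -> list[StitchedEnhancer]:
    """Stitch peaks into candidate enhancer units (unranked, signal 0).

    Peaks fully contained in any promoter window (TSS +/- tss_exclusion)
    are removed first, then the survivors are merged per chromosome with
    gap <= stitch_distance (filter-then-merge). Constituents of each unit
    are recorded in coordinate order.
    """
    if not peaks:
        raise ValueError("stitch requires a non-empty peak list")
    kept = list(peaks)
    if params.tss_exclusion > 0 and genes:
        promoters = _promoter_windows(genes, params.tss_exclusion)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for w in promoters:
            by_chrom.setdefault(w.chrom, []).append(w)
        kept = [
            p
            for p in peaks
            if not any(w.contains(p.interval) for w in by_chrom.get(p.chrom, ()))
        ]
        n_dropped = len(peaks) - len(kept)
        if n_dropped:
            logger.info("TSS exclusion removed %d promoter-contained peaks", n_dropped)
        if not kept:
            raise ValueError("all peaks removed by TSS exclusion; nothing to stitch")
    regions = merge_intervals([p.interval for p in kept], gap=params.stitch_distance)
    out = []
    for region in regions:
        members = tuple(
            sorted(
                (p for p in kept if region.contains(p.interval)),
                key=lambda p: (p.start, p.end),
            )
        )
        out.append(StitchedEnhancer(region=region, constituents=members))
    return out


def quantify(
    regions: Sequence[StitchedEnhancer],
    chip: SignalTrack,
    control: SignalTrack | None = None,
) -> list[StitchedEnhancer]:
    """Fill ``signal`` = sum(chip) - sum(control) over each region, floored at 0."""
    out = []
    for e in regions:
        r = e.region
        if r.chrom not in chip.data:
            raise KeyError(f"region chromosome {r.chrom!r} missing from ChIP track")
        sig = chip.region_sum(r.chrom, r.start, r.end)
        if control is not None:
            if r.chrom not in control.data:
                raise KeyError(f"region chromosome {r.chrom!r} missing from control track")
            sig -= control.region_sum(r.chrom, r.start, r.end)
        out.append(replace(e, signal=max(sig, 0.0)))
    return out


def call_cutoff(signals: Sequence[float]) -> tuple[float, int]:
    """Hockey-stick cutoff on the ascending rank-signal curve.

    Signals are sorted ascending; ranks are scaled to x in [0, 1] and
    signals to y in [0, 1]. The cutoff index is argmax(x - y) — for a
    convex ascending curve this is the point where the tangent has slope
    1. Ties break toward the highest index (fewest super-enhancers).
    Returns ``(cutoff_signal, cutoff_index)`` with the index into the
    ascending order; callers classify signal > cutoff_signal as super.

    Degenerate all-equal input yields ``(max signal, N-1)`` — zero
    super-enhancers — with a warning.
    """
    sig = np.sort(np.asarray(signals, dtype=float))
    n = len(sig)
    if n < 3:
        raise ValueError("call_cutoff requires at least 3 signals")
    if sig[0] == sig[-1]:
        warnings.warn(
            "all enhancer signals equal; degenerate landscape with no super-enhancers",
            stacklevel=2,
        )
        return float(sig[-1]), n - 1
    x = np.arange(n, dtype=float) / (n - 1)
    y = (sig - sig[0]) / (sig[-1] - sig[0])
    diff = x - y
    # ties toward the highest index => fewer SEs
    idx = int(n - 1 - np.argmax(diff[::-1]))
    return float(sig[idx]), idx


def build_landscape(
    peaks: Sequence[Peak],
    chip: SignalTrack,
    control: SignalTrack | None = None,
    genes: Sequence[GeneAnnotation] = (),
    params: LandscapeParams = LandscapeParams(),
    sample_id: str = "",
) -> LandscapeResult:
    """stitch -> quantify -> cutoff -> rank, returning the full landscape."""
    stitched = quantify(stitch(peaks, genes, params), chip, control)
    signals = [e.signal for e in stitched]
    cutoff_signal, cutoff_index = call_cutoff(signals)
    order = sorted(stitched, key=lambda e: -e.signal)
    ranked = tuple(
        replace(e, rank=i + 1, is_super=e.signal > cutoff_signal)
        for i, e in enumerate(order)
    )
    return LandscapeResult(
        enhancers=ranked,
        cutoff_signal=cutoff_signal,
        cutoff_index=cutoff_index,
        sample_id=sample_id,
    )


def assign_genes(
    landscape: LandscapeResult,
    genes: Sequence[GeneAnnotation],
    window: int | None = None,
    params: LandscapeParams = LandscapeParams(),
    super_only: bool = False,
) -> list[GeneAssignment]:
    """Link each enhancer to qualifying genes.

    A gene qualifies iff its TSS lies within the enhancer region extended
    by +/- window, or its body overlaps the region. Body overlap (or TSS
    inside the region) gives relation ``overlap`` with distance 0;
    otherwise ``proximal`` with distance = bp from region edge to TSS.
    Enhancers with no qualifying gene get an empty gene tuple.
    """
    if window is None:
        window = params.assignment_window
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    pool = landscape.super_enhancers if super_only else list(landscape.enhancers)
    for e in pool:
        r = e.region
        hits: list[tuple[str, int, str]] = []
        for g in by_chrom.get(r.chrom, ()):
            if g.body.overlaps(r):
                hits.append((g.gene_id, 0, "overlap"))
                continue
            if r.start <= g.tss < r.end:
                hits.append((g.gene_id, 0, "overlap"))
                continue
            d = r.distance_to_point(g.tss)
            if d <= window:
                hits.append((g.gene_id, d, "proximal"))
        hits.sort(key=lambda t: (t[1], t[0]))
        out.append(
            GeneAssignment(enhancer=e, genes=tuple(hits), sample_id=landscape.sample_id)
        )
    return out


def membership_table(
    assignments_by_sample: Mapping[str, Sequence[GeneAssignment]],
    super_only: bool = True,
) -> pd.DataFrame:
    """Boolean gene x sample table of SE-gene membership."""
    samples = list(assignments_by_sample)
    genes: set[str] = set()
    per_sample: dict[str, set[str]] = {}
    for s, assigns in assignments_by_sample.items():
        members = {
            gid
            for a in assigns
            if (a.enhancer.is_super or not super_only)
            for gid, _, _ in a.genes
        }
        per_sample[s] = members
        genes |= members
    idx = sorted(genes)
    return pd.DataFrame(
        {s: [g in per_sample[s] for g in idx] for s in samples}, index=idx
    )


def nominate_consensus(
    memberships: pd.DataFrame,
    sample_classes: Mapping[str, str],
    min_cell_lines: int = 3,
    min_tumors: int = 1,
) -> list[str]:
    """Consensus SE genes: present in >= min_cell_lines cell-line samples
    AND >= min_tumors tumor samples.

    ``memberships`` is a boolean gene x sample table; every column must be
    classified in ``sample_classes`` as ``cell_line`` or ``tumor``. Output
    is sorted by gene_id.
    """
    unknown = [s for s in memberships.columns if s not in sample_classes]
    if unknown:
        raise ValueError(f"unclassified samples: {unknown}")
    bad = {s: c for s, c in sample_classes.items() if c not in ("cell_line", "tumor")}
    if bad:
        raise ValueError(f"invalid sample classes (expected cell_line|tumor): {bad}")
    lines = [s for s in memberships.columns if sample_classes[s] == "cell_line"]
    tumors = [s for s in memberships.columns if sample_classes[s] == "tumor"]
    if min_cell_lines > len(lines):
        raise ValueError(
            f"min_cell_lines={min_cell_lines} exceeds available cell lines ({len(lines)})"
        )
    if min_tumors > len(tumors):
        raise ValueError(f"min_tumors={min_tumors} exceeds available tumors ({len(tumors)})")
    n_lines = memberships[lines].sum(axis=1) if lines else pd.Series(0, index=memberships.index)
    n_tumors = memberships[tumors].sum(axis=1) if tumors else pd.Series(0, index=memberships.index)
    keep = memberships.index[(n_lines >= min_cell_lines) & (n_tumors >= min_tumors)]
    return sorted(keep)
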