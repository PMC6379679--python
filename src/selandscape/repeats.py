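"""GGAA-microsatellite scanning and SE-vs-TE repeat enrichment.

GGAA multimers are the activating binding substrate of the EWS-FLI1
fusion protein; regions are scanned for maximal runs of consecutive
GGAA units on the forward strand and TTCC units (reported as
minus-strand GGAA). Matching is exact: N bases terminate runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genomic import GenomicInterval
from .tfstats import ContingencyResult, pearson_chi2_2x2

__all__ = ["RepeatRun", "scan_repeats", "region_repeat_table", "write_runs_bed"]

_UNIT_BY_STRAND = {"+": "GGAA", "-": "TTCC"}
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class RepeatRun:
    """A maximal run of ``n_units`` consecutive GGAA units.

    ``interval`` spans the run (width = 4 * n_units); minus-strand runs
    are TTCC matches on the forward sequence.
    """

    interval: GenomicInterval
    n_units: int
    strand: str

    def __post_init__(self) -> None:
        if self.interval.width != 4 * self.n_units:
            raise ValueError("run width must equal 4 * n_units")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def scan_repeats(
    sequence: str,
    min_units: int = 4,
    chrom: str = "seq",
    offset: int = 0,
) -> list[RepeatRun]:
    """All maximal GGAA/TTCC runs with >= ``min_units`` units.

    The scan is leftmost-greedy per strand, so reported same-strand runs
    never overlap and none is extendable by another unit. ``offset``
    shifts reported coordinates (for region-extracted sequences).
    Characters outside {A, C, G, T, N} raise with their position.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid base {ch!r} at position {i}")
    runs: list[RepeatRun] = []
    n = len(seq)
    for strand, unit in _UNIT_BY_STRAND.items():
        i = 0
        while i + 4 <= n:
            if seq[i : i + 4] == unit:
                j = i + 4
                while j + 4 <= n and seq[j : j + 4] == unit:
                    j += 4
                k = (j - i) // 4
                if k >= min_units:
                    runs.append(
                        RepeatRun(
                            interval=GenomicInterval(chrom, offset + i, offset + j),
                            n_units=k,
                            strand=strand,
                        )
                    )
                i = j
            else:
                i += 1
    runs.sort(key=lambda r: (r.interval.start, r.strand))
    return runs


def write_runs_bed(runs: Sequence[RepeatRun], path) -> None:
    """BED6 of repeat runs with n_units in the score column."""
    with open(path, "w") as fh:
        for i, r in enumerate(runs):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\tggaa_run_{i}\t{r.n_units}\t{r.strand}\n"
            )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Sequence accessor accepting a pyfaidx.Fasta or a dict of strings."""
    if isinstance(genome, Mapping):
        seq = genome[chrom]
        if end > len(seq):
            raise ValueError(
                f"region {chrom}:{start}-{end} exceeds chromosome length {len(seq)}"
            )
        return seq[start:end]
    rec = genome[chrom]
    if end > len(rec):
        raise ValueError(
            f"region {chrom}:{start}-{end} exceeds chromosome length {len(rec)}"
        )
    return str(rec[start:end])


def region_repeat_table(
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
    genome,
    min_units: int = 4,
) -> tuple[ContingencyResult, pd.DataFrame]:
    """Chi-squared test of GGAA-run containment between two region classes.

    Each region is scanned for qualifying runs; the 2x2 table counts
    regions with >= 1 run vs without, rows = (class A, class B). A
    per-region table with run counts is returned alongside.
    ``genome`` is a pyfaidx.Fasta handle or a dict chrom -> sequence.
    """
    if not regions_a or not regions_b:
        raise ValueError("both region lists must be non-empty")
    rows = []
    with_runs = {"A": 0, "B": 0}
    for label, regions in (("A", regions_a), ("B", regions_b)):
        for r in regions:
            runs = scan_repeats(
                _fetch(genome, r.chrom, r.start, r.end),
                min_units=min_units,
                chrom=r.chrom,
                offset=r.start,
            )
            if runs:
                with_runs[label] += 1
            rows.append(
                {
                    "region_class": label,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_runs": len(runs),
                    "max_units": max((x.n_units for x in runs), default=0),
                }
            )
    table = [
        [with_runs["A"], len(regions_a) - with_runs["A"]],
        [with_runs["B"], len(regions_b) - with_runs["B"]],
    ]
    return pearson_chi2_2x2(table), pd.DataFrame(rows)
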