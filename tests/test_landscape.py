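"""Stitching, quantification, hockey-stick cutoff, gene assignment, consensus."""

import numpy as np
import pandas as pd
import pytest

from selandscape.genomic import GeneAnnotation, GenomicInterval, Peak, SignalTrack
from selandscape.landscape import (
    LandscapeParams,
    LandscapeResult,
    StitchedEnhancer,
    assign_genes,
    build_landscape,
    call_cutoff,
    nominate_consensus,
    quantify,
    stitch,
)

from .conftest import make_interval, make_peak


def gene(gene_id, chrom, tss, strand="+", length=1000):
    body = GenomicInterval(chrom, tss, tss + length) if strand == "+" else GenomicInterval(
        chrom, max(0, tss - length + 1), tss + 1
    )
    return GeneAnnotation(gene_id, gene_id, body, strand, tss)


class TestStitch:
    def test_three_peaks_two_regions(self):
        peaks = [
            make_peak(start=0, end=100),
            make_peak(start=5000, end=5100),
            make_peak(start=20000, end=20100),
        ]
        out = stitch(peaks, params=LandscapeParams(tss_exclusion=0))
        spans = [(e.region.start, e.region.end) for e in out]
        assert spans == [(0, 5100), (20000, 20100)]
        assert len(out[0].constituents) == 2

    def test_single_peak_equals_itself(self):
        (e,) = stitch([make_peak(start=10, end=50)])
        assert (e.region.start, e.region.end) == (10, 50)
        assert e.constituents[0].start == 10

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            stitch([])

    def test_promoter_filter_matches_filter_then_merge_oracle(self, rng):
        # random peaks + random TSSs; oracle removes contained peaks by
        # brute force then merges
        params = LandscapeParams(stitch_distance=3000, tss_exclusion=2500)
        peaks = []
        pos = 0
        for _ in range(60):
            pos += int(rng.integers(200, 6000))
            width = int(rng.integers(100, 900))
            peaks.append(make_peak(start=pos, end=pos + width))
            pos += width
        genes = [
            gene(f"g{i}", "chr1", int(rng.integers(0, pos))) for i in range(15)
        ]
        windows = [
            GenomicInterval("chr1", max(0, g.tss - 2500), g.tss + 2501) for g in genes
        ]
        surviving = [
            p
            for p in peaks
            if not any(
                w.start <= p.start and p.end <= w.end for w in windows
            )
        ]
        from selandscape.genomic import merge_intervals

        expected = merge_intervals([p.interval for p in surviving], 3000)
        got = [e.region for e in stitch(peaks, genes, params)]
        assert got == expected


class TestQuantify:
    def _enhancer(self, start, end):
        iv = make_interval(start=start, end=end)
        return StitchedEnhancer(region=iv, constituents=(Peak(iv),))

    @pytest.mark.parametrize(
        "span,chip,control,expected",
        [
            ((0, 10), 2.0, None, 20.0),
            ((0, 10), 2.0, 3.0, 0.0),  # floored at zero
            ((0, 4), 2.0, 0.5, 6.0),
        ],
    )
    def test_constant_tracks(self, span, chip, control, expected):
        e = self._enhancer(*span)
        chip_t = SignalTrack({"chr1": np.full(20, chip)})
        ctrl_t = None if control is None else SignalTrack({"chr1": np.full(20, control)})
        (q,) = quantify([e], chip_t, ctrl_t)
        assert q.signal == pytest.approx(expected)

    def test_missing_chromosome_errors(self):
        e = self._enhancer(0, 10)
        with pytest.raises(KeyError, match="chr1"):
            quantify([e], SignalTrack({"chr2": np.ones(10)}))

    def test_constituent_sums_bounded_by_region_sum(self, rng):
        # control-free: sum over constituents <= region sum, equal when tiling
        chip = SignalTrack({"chr1": rng.random(1000).astype(np.float32)})
        region = make_interval(start=100, end=400)
        tiling = (Peak(make_interval(start=100, end=250)), Peak(make_interval(start=250, end=400)))
        sparse = (Peak(make_interval(start=120, end=180)),)
        whole = quantify([StitchedEnhancer(region, tiling)], chip)[0].signal
        parts = sum(chip.region_sum("chr1", p.start, p.end) for p in tiling)
        assert parts == pytest.approx(whole, rel=1e-6)
        sparse_sum = sum(chip.region_sum("chr1", p.start, p.end) for p in sparse)
        assert sparse_sum <= whole + 1e-6


class TestCallCutoff:
    def test_matches_bruteforce_on_convex_curve(self):
        n = 1000
        signals = ((np.arange(n) / (n - 1)) ** 4).tolist()
        cutoff, idx = call_cutoff(signals)
        sig = np.sort(signals)
        x = np.arange(n) / (n - 1)
        y = (sig - sig[0]) / (sig[-1] - sig[0])
        brute = max(range(n), key=lambda i: (x[i] - y[i], i))
        assert idx == brute
        assert cutoff == sig[brute]

    def test_linear_ramp_zero_super(self):
        signals = np.linspace(0, 1, 100)
        cutoff, idx = call_cutoff(signals)
        # x - y identically 0; tie broken to highest index
        assert idx == 99
        assert sum(s > cutoff for s in signals) == 0

    def test_all_equal_degenerate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cutoff, idx = call_cutoff([5.0] * 10)
        assert cutoff == 5.0 and idx == 9

    def test_affine_invariance(self, rng):
        signals = rng.lognormal(1, 1, size=500)
        _, idx = call_cutoff(signals)
        _, idx2 = call_cutoff(7.0 * signals + 3.0)
        assert idx == idx2

    def test_planted_amplified_signals_fall_above_cutoff(self, rng):
        baseline = rng.uniform(1.0, 3.0, size=1990)
        planted = 20.0 * np.median(baseline) * rng.uniform(0.9, 1.1, size=10)
        signals = np.concatenate([baseline, planted])
        cutoff, _ = call_cutoff(signals)
        assert all(p > cutoff for p in planted)
        assert sum(b > cutoff for b in baseline) <= 2

    def test_too_few_signals_error(self):
        with pytest.raises(ValueError):
            call_cutoff([1.0, 2.0])


def _landscape_from(enhancers, cutoff=0.0):
    return LandscapeResult(
        enhancers=tuple(enhancers), cutoff_signal=cutoff, cutoff_index=0, sample_id="s"
    )


class TestAssignGenes:
    def _enh(self, start, end, is_super=True):
        iv = make_interval(start=start, end=end)
        return StitchedEnhancer(iv, (Peak(iv),), signal=1.0, rank=1, is_super=is_super)

    def test_proximal_distance_and_window(self):
        e = self._enh(100_000, 110_000)
        genes = [
            gene("near", "chr1", 120_000),  # 10 kb right of edge
            gene("far", "chr1", 170_001),  # 60 kb away
        ]
        (a,) = assign_genes(_landscape_from([e]), genes, window=50_000)
        assert a.genes == (("near", 10_000, "proximal"),)

    def test_body_overlap_distance_zero(self):
        e = self._enh(100_000, 110_000)
        g = gene("ov", "chr1", 95_000, length=8_000)  # body 95000-103000
        (a,) = assign_genes(_landscape_from([e]), [g], window=50_000)
        assert a.genes == (("ov", 0, "overlap"),)

    def test_enhancer_without_genes_empty(self):
        e = self._enh(0, 100)
        (a,) = assign_genes(_landscape_from([e]), [gene("g", "chr2", 10)], window=1000)
        assert a.genes == ()


class TestNominateConsensus:
    @pytest.fixture
    def classes(self):
        return {
            **{f"L{i}": "cell_line" for i in range(1, 5)},
            **{f"T{i}": "tumor" for i in range(1, 4)},
        }

    def _table(self, rows):
        cols = [f"L{i}" for i in range(1, 5)] + [f"T{i}" for i in range(1, 4)]
        return pd.DataFrame(rows, columns=cols)

    def test_and_semantics(self, classes):
        table = self._table(
            {
                "kept_3_1": [1, 1, 1, 0, 1, 0, 0],
                "lines_only": [1, 1, 1, 1, 0, 0, 0],
                "tumors_only": [1, 1, 0, 0, 1, 1, 1],
            }.values()
        ).astype(bool)
        table.index = ["kept_3_1", "lines_only", "tumors_only"]
        out = nominate_consensus(table, classes, min_cell_lines=3, min_tumors=1)
        assert out == ["kept_3_1"]

    def test_threshold_exceeding_sample_count_errors(self, classes):
        table = self._table([[1] * 7]).astype(bool)
        with pytest.raises(ValueError, match="min_cell_lines"):
            nominate_consensus(table, classes, min_cell_lines=5, min_tumors=1)

    def test_unclassified_sample_errors(self, classes):
        table = self._table([[1] * 7]).astype(bool)
        del classes["T3"]
        with pytest.raises(ValueError, match="unclassified"):
            nominate_consensus(table, classes)

    def test_monotone_adding_membership_never_removes(self, classes, rng):
        table = pd.DataFrame(
            rng.random((30, 7)) < 0.4,
            index=[f"g{i}" for i in range(30)],
            columns=list(classes),
        )
        before = set(nominate_consensus(table, classes))
        flipped = table.copy()
        off = np.argwhere(~flipped.values)
        r, c = off[rng.integers(0, len(off))]
        flipped.iat[r, c] = True
        after = set(nominate_consensus(flipped, classes))
        assert before <= after


class TestBuildLandscape:
    def test_partition_and_rank_consistency(self, rng):
        peaks = []
        pos = 1000
        for _ in range(50):
            peaks.append(make_peak(start=pos, end=pos + 500, score=1.0))
            pos += 5000
        chip = SignalTrack({"chr1": rng.random(pos + 1000).astype(np.float32)})
        ls = build_landscape(peaks, chip, params=LandscapeParams(stitch_distance=1000, tss_exclusion=0))
        ranks = [e.rank for e in ls.enhancers]
        assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)
        for e in ls.enhancers:
            assert e.is_super == (e.signal > ls.cutoff_signal)
        assert len(ls.super_enhancers) + len(ls.typical_enhancers) == len(ls.enhancers)
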