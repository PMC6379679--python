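"""Seeded generators with planted truth for every pipeline stage.

The generators emulate the statistical structure of an H3K27ac
super-enhancer study: a rank-signal curve with a minority of
high-signal stitched peak clusters (the planted SEs), TF peaks
preferentially placed in SE constituents, GGAA microsatellites enriched
in SE sequence, and count matrices in which SE-assigned genes respond
more strongly to perturbation.

Every generator is a pure function of its ``SimConfig``: one global
seed fans out to per-stage child seeds, so a stage can be regenerated
independently yet reproducibly.

Coverage tracks are synthesized directly from peak score profiles
(rectangular pulses over a uniform noise floor) rather than from
simulated reads; that is sufficient to exercise quantification.
Background peak signals are drawn log-normal and winsorized at
mu + 2 sigma so that the background tail does not mimic planted
super-enhancers; the planted clusters then form the upswing of the
hockey stick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gene_table,
)
from .landscape import LandscapeResult

__all__ = [
    "SimConfig",
    "TruthTable",
    "LandscapeBundle",
    "generate_landscape",
    "generate_tf_peaks",
    "generate_sequences",
    "generate_expression",
    "recovery_jaccard",
]

# background peak layout (bp): spacing keeps independent background
# peaks from stitching at the default 12.5 kb stitch distance
_BG_GAP = (13_500, 18_000)
_PEAK_WIDTH = (600, 1_600)
_CLUSTER_PEAKS = (3, 8)
_CLUSTER_GAP = (500, 2_500)
_EDGE_MARGIN = 50_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Landscape: ``n_enhancer_peaks`` enhancer units of which
    ``n_planted_se`` are stitched clusters of 3–8 peaks whose summed
    signal is ``se_amplification`` x the background median unit signal.
    Background unit signals are log-normal(mu, sigma), winsorized at
    mu + 2 sigma. Signals are in arbitrary summed-coverage units
    (median unit ~ exp(peak_signal_mu), height = signal / width
    in rpm/bp-like units).

    Expression: control counts are negative binomial
    (mean ``expr_baseline_mean``, dispersion ``expr_dispersion``, var =
    m + a m^2); treated means are scaled by 2^effect with effect ~
    N(se_effect_mu, effect_sigma) for SE-assigned genes and
    N(te_effect_mu, effect_sigma) otherwise.
    """

    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 1_200
    n_enhancer_peaks: int = 2_000
    n_planted_se: int = 20
    se_amplification: float = 10.0
    peak_signal_mu: float = 7.0
    peak_signal_sigma: float = 0.25
    chip_noise_floor: float = 0.05
    control_level: float = 0.02
    tf_peak_count: int = 600
    p_tf_in_se: float = 0.8
    p_tf_in_te: float = 0.1
    repeat_rate_se: float = 0.5
    repeat_rate_te: float = 0.05
    expr_baseline_mean: float = 100.0
    expr_dispersion: float = 0.1
    n_replicates: int = 3
    se_effect_mu: float = -1.5
    te_effect_mu: float = -0.3
    effect_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_tf_in_se", "p_tf_in_te"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.se_amplification < 1:
            raise ValueError("se_amplification must be >= 1")
        for name in (
            "n_chromosomes",
            "chrom_length",
            "n_genes",
            "n_enhancer_peaks",
            "n_planted_se",
            "tf_peak_count",
            "n_replicates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**32)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))


@dataclass
class TruthTable:
    """Planted ground truth, consistent with the emitted files."""

    chrom_sizes: dict[str, int] = field(default_factory=dict)
    planted_se_regions: list[GenomicInterval] = field(default_factory=list)
    se_constituents: list[Peak] = field(default_factory=list)
    te_peaks: list[Peak] = field(default_factory=list)
    genes: list[GeneAnnotation] = field(default_factory=list)
    se_genes: set[str] = field(default_factory=set)
    tf_peak_labels: list[tuple[Peak, str]] = field(default_factory=list)
    planted_repeats: list[tuple[GenomicInterval, int, str]] = field(default_factory=list)
    true_effects: dict[str, float] = field(default_factory=dict)

    @property
    def te_regions(self) -> list[GenomicInterval]:
        return [p.interval for p in self.te_peaks]

    def validate(self) -> None:
        """Self-check: every planted element lies within the genome."""
        for iv in list(self.planted_se_regions) + [p.interval for p in self.te_peaks]:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None or iv.end > size:
                raise AssertionError(f"truth region {iv} outside genome")
        for region in self.planted_se_regions:
            members = [p for p in self.se_constituents if region.contains(p.interval)]
            if not members:
                raise AssertionError(f"planted SE {region} has no constituents")
        for iv, n_units, strand in self.planted_repeats:
            if iv.width != 4 * n_units:
                raise AssertionError(f"planted repeat {iv} width != 4*{n_units}")
        se_ids = {g.gene_id for g in self.genes}
        if not self.se_genes <= se_ids and se_ids:
            raise AssertionError("se_genes not a subset of generated genes")

    def to_json(self) -> str:
        def iv(x: GenomicInterval) -> dict:
            return {"chrom": x.chrom, "start": x.start, "end": x.end}

        payload = {
            "chrom_sizes": self.chrom_sizes,
            "planted_se_regions": [iv(r) for r in self.planted_se_regions],
            "se_constituents": [iv(p.interval) | {"score": p.score} for p in self.se_constituents],
            "n_te_peaks": len(self.te_peaks),
            "se_genes": sorted(self.se_genes),
            "tf_peak_labels": [iv(p.interval) | {"label": lab} for p, lab in self.tf_peak_labels],
            "planted_repeats": [
                iv(r) | {"n_units": n, "strand": s} for r, n, s in self.planted_repeats
            ],
            "true_effects": self.true_effects,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class LandscapeBundle:
    """In-memory synthetic inputs for one sample, plus the truth table."""

    config: SimConfig
    peaks: list[Peak]
    chip: SignalTrack
    control: SignalTrack
    genes: list[GeneAnnotation]
    truth: TruthTable

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / f"{prefix}.peaks.bed",
            "chip": outdir / f"{prefix}.chip.bedgraph",
            "control": outdir / f"{prefix}.control.bedgraph",
            "genes": outdir / f"{prefix}.genes.tsv",
            "chrom_sizes": outdir / f"{prefix}.chrom.sizes",
            "truth": outdir / f"{prefix}.truth.json",
        }
        write_bed(self.peaks, paths["peaks"])
        write_bedgraph(self.chip, paths["chip"])
        write_bedgraph(self.control, paths["control"])
        write_gene_table(self.genes, paths["genes"])
        with open(paths["chrom_sizes"], "w") as fh:
            for c, s in self.truth.chrom_sizes.items():
                fh.write(f"{c}\t{s}\n")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _draw_unit_layout(config: SimConfig, rng: np.random.Generator):
    """Place enhancer units (singles and clusters) along the genome.

    Returns (singles, clusters) where each cluster is a list of
    (start, end) constituent spans. Raises if the genome cannot hold the
    requested units.
    """
    n_bg = config.n_enhancer_peaks - config.n_planted_se
    if n_bg < 0:
        raise ValueError("n_planted_se exceeds n_enhancer_peaks")
    kinds = np.array([0] * n_bg + [1] * config.n_planted_se)
    rng.shuffle(kinds)
    chroms = sorted(config.chrom_sizes)
    singles: list[GenomicInterval] = []
    clusters: list[list[GenomicInterval]] = []
    ci = 0
    cursor = _EDGE_MARGIN
    for kind in kinds:
        if kind == 0:
            width = int(rng.integers(*_PEAK_WIDTH))
            span = width
            spans = [(0, width)]
        else:
            k = int(rng.integers(_CLUSTER_PEAKS[0], _CLUSTER_PEAKS[1] + 1))
            widths = rng.integers(*_PEAK_WIDTH, size=k)
            gaps = rng.integers(*_CLUSTER_GAP, size=k - 1)
            spans = []
            pos = 0
            for i, w in enumerate(widths):
                spans.append((pos, pos + int(w)))
                pos += int(w)
                if i < k - 1:
                    pos += int(gaps[i])
            span = pos
        # advance to next chromosome if this unit does not fit
        while cursor + span > config.chrom_length - _EDGE_MARGIN:
            ci += 1
            cursor = _EDGE_MARGIN
            if ci >= len(chroms):
                raise ValueError(
                    "genome capacity exceeded: reduce n_enhancer_peaks or "
                    "increase chrom_length/n_chromosomes"
                )
        chrom = chroms[ci]
        placed = [GenomicInterval(chrom, cursor + s, cursor + e) for s, e in spans]
        if kind == 0:
            singles.append(placed[0])
        else:
            clusters.append(placed)
        cursor += span + int(rng.integers(*_BG_GAP))
    return singles, clusters


def generate_landscape(config: SimConfig) -> LandscapeBundle:
    """Synthesize peaks, coverage tracks, genes and truth for one sample.

    Background units get winsorized log-normal signals; each planted
    cluster's summed signal is ``se_amplification`` x the median
    background unit signal, split across its constituents. ChIP coverage
    is the rectangular pulse profile of the peak heights over a uniform
    noise floor; the control track is a constant low level.
    """
    rng = config.child_rng("landscape")
    singles, clusters = _draw_unit_layout(config, rng)

    n_bg = len(singles)
    bg_signal = rng.lognormal(config.peak_signal_mu, config.peak_signal_sigma, size=n_bg)
    cap = float(np.exp(config.peak_signal_mu + 2.0 * config.peak_signal_sigma))
    bg_signal = np.minimum(bg_signal, cap)
    median_bg = float(np.median(bg_signal)) if n_bg else float(np.exp(config.peak_signal_mu))

    peaks: list[Peak] = []
    truth = TruthTable(chrom_sizes=config.chrom_sizes)
    for i, iv in enumerate(singles):
        p = Peak(iv, name=f"bg_{i}", score=float(bg_signal[i]))
        peaks.append(p)
        truth.te_peaks.append(p)

    for j, members in enumerate(clusters):
        total = config.se_amplification * median_bg
        weights = rng.uniform(0.5, 1.5, size=len(members))
        weights /= weights.sum()
        region = GenomicInterval(members[0].chrom, members[0].start, members[-1].end)
        truth.planted_se_regions.append(region)
        for m, iv in enumerate(members):
            p = Peak(iv, name=f"se{j}_{m}", score=float(total * weights[m]))
            peaks.append(p)
            truth.se_constituents.append(p)
    peaks.sort(key=lambda p: (p.chrom, p.start))

    chip = SignalTrack.zeros(config.chrom_sizes)
    control = SignalTrack.zeros(config.chrom_sizes)
    for c in chip.data:
        chip.data[c][:] = config.chip_noise_floor
        control.data[c][:] = config.control_level
    for p in peaks:
        height = p.score / p.interval.width
        chip.data[p.chrom][p.start : p.end] += np.float32(height)

    truth.genes.extend(_place_genes(config, rng, singles, clusters, truth))
    truth.validate()
    return LandscapeBundle(
        config=config,
        peaks=peaks,
        chip=chip,
        control=control,
        genes=truth.genes,
        truth=truth,
    )


def _place_genes(config, rng, singles, clusters, truth) -> list[GeneAnnotation]:
    """One TSS per unit for planted clusters, then random units for the rest.

    TSSs are offset 5–30 kb from the unit edge (inside the default 50 kb
    assignment window, outside the 2.5 kb promoter-exclusion window so
    gene placement never deletes constituent peaks).
    """
    genes: list[GeneAnnotation] = []
    gid = 0

    def add_gene(anchor: GenomicInterval, is_se: bool, name: str | None = None) -> None:
        nonlocal gid
        # kept below the minimum inter-unit gap minus the promoter
        # half-window, so promoter exclusion never deletes a constituent
        offset = int(rng.integers(5_000, 10_500))
        side = rng.integers(0, 2)
        tss = anchor.end + offset if side else max(0, anchor.start - offset)
        strand = "+" if rng.integers(0, 2) else "-"
        length = int(rng.integers(2_000, 20_000))
        if strand == "+":
            body = GenomicInterval(anchor.chrom, tss, tss + length, "+")
        else:
            start = max(0, tss - length + 1)
            body = GenomicInterval(anchor.chrom, start, tss + 1, "-")
        if name is None:
            name = f"G{gid:05d}"
            gid += 1
        genes.append(
            GeneAnnotation(gene_id=name, symbol=name, body=body, strand=strand, tss=tss)
        )
        if is_se:
            truth.se_genes.add(name)

    # planted SE genes carry stable ids across samples of a simulated
    # cohort, emulating recurrently SE-driven genes
    for j, members in enumerate(clusters):
        region = GenomicInterval(members[0].chrom, members[0].start, members[-1].end)
        add_gene(region, is_se=True, name=f"SEG{j:04d}")
    n_rest = max(0, config.n_genes - len(clusters))
    if singles:
        anchors = rng.integers(0, len(singles), size=n_rest)
        for a in anchors:
            add_gene(singles[int(a)], is_se=False)
    return genes


def generate_tf_peaks(
    config: SimConfig, truth: TruthTable, stage: str = "tf"
) -> list[Peak]:
    """TF peaks placed preferentially in super-enhancer units.

    Each planted SE unit hosts a TF peak with probability ``p_tf_in_se``
    (placed inside one of its constituents, chosen at random); each TE
    unit hosts one with ``p_tf_in_te``. One Bernoulli draw per stitched
    unit keeps the equal-rate setting a true null for the region-level
    containment test regardless of how many constituents an SE has. The
    remainder of ``tf_peak_count`` is placed uniformly in intergenic
    space (outside all enhancer units). Labels are appended to
    ``truth.tf_peak_labels``. A distinct ``stage`` name yields an
    independent second TF (its own child seed).
    """
    rng = config.child_rng(stage)
    tf_peaks: list[Peak] = []
    occupied = sorted(
        [p.interval for p in truth.se_constituents] + truth.te_regions,
        key=lambda iv: (iv.chrom, iv.start),
    )

    def sub_peak(iv: GenomicInterval, idx: int, label: str) -> None:
        width = min(200, iv.width)
        lo = iv.start
        hi = max(lo + 1, iv.end - width)
        s = int(rng.integers(lo, hi))
        p = Peak(GenomicInterval(iv.chrom, s, s + width), name=f"tf_{idx}")
        tf_peaks.append(p)
        truth.tf_peak_labels.append((p, label))

    for region in truth.planted_se_regions:
        if rng.random() < config.p_tf_in_se:
            members = [p for p in truth.se_constituents if region.contains(p.interval)]
            host = members[int(rng.integers(0, len(members)))]
            sub_peak(host.interval, len(tf_peaks), "se")
    for p in truth.te_peaks:
        if rng.random() < config.p_tf_in_te:
            sub_peak(p.interval, len(tf_peaks), "te")

    n_rest = max(0, config.tf_peak_count - len(tf_peaks))
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in occupied:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = sorted(truth.chrom_sizes)
    placed = 0
    attempts = 0
    while placed < n_rest and attempts < 100 * max(1, n_rest):
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, truth.chrom_sizes[chrom] - 200))
        cand = GenomicInterval(chrom, s, s + 200)
        if any(cand.overlaps(iv) for iv in by_chrom.get(chrom, ())):
            continue
        p = Peak(cand, name=f"tf_bg_{placed}")
        tf_peaks.append(p)
        truth.tf_peak_labels.append((p, "intergenic"))
        placed += 1
    tf_peaks.sort(key=lambda p: (p.chrom, p.start))
    return tf_peaks


def generate_sequences(
    config: SimConfig, truth: TruthTable, max_retries: int = 50
) -> dict[str, str]:
    """Random genome with GGAA runs planted into SE and TE regions.

    Background bases are i.i.d. uniform ACGT. Each SE region receives
    Poisson(``repeat_rate_se``) runs of (GGAA)_k, k ~ uniform{4..12},
    random strand; TE regions use ``repeat_rate_te``. Collisions are
    resolved by rejection sampling with bounded retries. Insertions are
    recorded in ``truth.planted_repeats``.
    """
    rng = config.child_rng("sequence")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome: dict[str, np.ndarray] = {}
    for chrom in sorted(truth.chrom_sizes):
        size = truth.chrom_sizes[chrom]
        genome[chrom] = bases[rng.integers(0, 4, size=size)].copy()

    def plant(region: GenomicInterval, rate: float) -> None:
        n_runs = rng.poisson(rate)
        taken: list[tuple[int, int]] = []
        for _ in range(n_runs):
            k = int(rng.integers(4, 13))
            length = 4 * k
            if length > region.width:
                continue
            for attempt in range(max_retries + 1):
                if attempt == max_retries:
                    raise RuntimeError(
                        f"could not place repeat run in {region} after {max_retries} tries"
                    )
                s = int(rng.integers(region.start, region.end - length + 1))
                if all(s + length <= a or s >= b for a, b in taken):
                    break
            strand = "+" if rng.integers(0, 2) else "-"
            unit = b"GGAA" if strand == "+" else b"TTCC"
            genome[region.chrom][s : s + length] = np.frombuffer(unit * k, dtype="S1")
            taken.append((s, s + length))
            truth.planted_repeats.append(
                (GenomicInterval(region.chrom, s, s + length), k, strand)
            )

    for region in truth.planted_se_regions:
        plant(region, config.repeat_rate_se)
    for region in truth.te_regions:
        plant(region, config.repeat_rate_te)
    return {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_expression(
    config: SimConfig, truth: TruthTable
) -> tuple["pd.DataFrame", "pd.DataFrame", dict[str, float]]:
    """Treated/control count matrices with planted per-gene effects.

    Control counts ~ NB(mean, dispersion) per replicate; treated means
    are scaled by 2^effect, effect ~ N(se_effect_mu, effect_sigma) for
    SE-assigned genes, N(te_effect_mu, effect_sigma) otherwise. Effects
    are recorded in ``truth.true_effects`` and returned.
    """
    import pandas as pd

    rng = config.child_rng("expression")
    gene_ids = [g.gene_id for g in truth.genes]
    if not gene_ids:
        raise ValueError("truth table has no genes; run generate_landscape first")
    is_se = np.array([g in truth.se_genes for g in gene_ids])
    effects = np.where(
        is_se,
        rng.normal(config.se_effect_mu, config.effect_sigma, size=len(gene_ids)),
        rng.normal(config.te_effect_mu, config.effect_sigma, size=len(gene_ids)),
    )
    m = config.expr_baseline_mean
    a = config.expr_dispersion

    def nb_draws(means: np.ndarray, n_rep: int) -> np.ndarray:
        if a <= 0:
            return rng.poisson(means[:, None], size=(len(means), n_rep))
        r = 1.0 / a
        p = r / (r + means)
        return rng.negative_binomial(r, p[:, None], size=(len(means), n_rep))

    base = np.full(len(gene_ids), m)
    cols_c = [f"control_{i + 1}" for i in range(config.n_replicates)]
    cols_t = [f"treated_{i + 1}" for i in range(config.n_replicates)]
    control = pd.DataFrame(nb_draws(base, config.n_replicates), index=gene_ids, columns=cols_c)
    treated = pd.DataFrame(
        nb_draws(base * np.exp2(effects), config.n_replicates),
        index=gene_ids,
        columns=cols_t,
    )
    truth.true_effects = dict(zip(gene_ids, effects.astype(float)))
    return treated, control, truth.true_effects


def recovery_jaccard(landscape: LandscapeResult, truth: TruthTable) -> float:
    """Jaccard between called super-enhancers and planted SE regions.

    A planted region counts as recovered if overlapped by >= 1 called
    SE; called SEs overlapping no planted region count against the
    union.
    """
    called = [e.region for e in landscape.super_enhancers]
    planted = truth.planted_se_regions
    if not planted and not called:
        return 1.0
    matched = sum(1 for p in planted if any(p.overlaps(c) for c in called))
    unmatched_called = sum(1 for c in called if not any(c.overlaps(p) for p in planted))
    return matched / (len(planted) + unmatched_called)
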