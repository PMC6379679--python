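"""End-to-end orchestration: simulate/landscape/consensus/TF/repeats/enrichment.

Stages run in dependency order; each writes its tabular outputs under
``outdir`` and contributes headline statistics to a single JSON run
report. The report's ``results`` section is a pure function of the
configuration (fixed seed), so re-running with the same config yields
an identical results hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .config import RunConfig
from .enrichment import (
    RankedResponse,
    compare_fc_distributions,
    compute_log2fc,
    gsea_permutation,
    sensitive_set,
)
from .genomic import read_bed, read_bedgraph, read_chrom_sizes, read_gene_table, write_bed
from .landscape import (
    LandscapeResult,
    assign_genes,
    build_landscape,
    membership_table,
    nominate_consensus,
)
from .repeats import region_repeat_table, scan_repeats, write_runs_bed
from .simulate import (
    LandscapeBundle,
    SimConfig,
    generate_expression,
    generate_landscape,
    generate_sequences,
    generate_tf_peaks,
    recovery_jaccard,
)
from .tfstats import (
    call_direct_targets,
    containment_chi2,
    cooccupancy_fraction,
    make_windows,
    median_peak_width,
    peak_overlap_fisher,
)

logger = logging.getLogger(__name__)

__all__ = ["run_all"]


def _header(config: RunConfig) -> str:
    return f"# selandscape {__version__} config_fingerprint={config.fingerprint()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def _landscape_outputs(
    result: LandscapeResult, assignments, outdir: Path, config: RunConfig
) -> None:
    sid = result.sample_id
    df = result.to_frame()
    _write_tsv(df, outdir / f"{sid}.landscape.tsv", config)
    write_bed(
        [e.constituents[0] for e in result.super_enhancers if e.constituents],
        outdir / f"{sid}.se_constituent_lead.bed",
    )
    for label, subset in (("se", result.super_enhancers), ("te", result.typical_enhancers)):
        with open(outdir / f"{sid}.{label}.bed", "w") as fh:
            for e in subset:
                fh.write(f"{e.region.chrom}\t{e.region.start}\t{e.region.end}\t"
                         f"rank_{e.rank}\t{e.signal:g}\t.\n")
    # hockey-stick plot data: ascending rank vs signal, unit-scaled
    sig = sorted(e.signal for e in result.enhancers)
    n = len(sig)
    lo, hi = sig[0], sig[-1]
    rows = {
        "rank_ascending": range(1, n + 1),
        "signal": sig,
        "x_scaled": [i / (n - 1) for i in range(n)],
        "y_scaled": [(s - lo) / (hi - lo) if hi > lo else 0.0 for s in sig],
    }
    hs = pd.DataFrame(rows)
    hs["is_cutoff"] = [i == result.cutoff_index for i in range(n)]
    _write_tsv(hs, outdir / f"{sid}.hockey.tsv", config)
    arows = []
    for a in assignments:
        for gid, dist, rel in a.genes:
            arows.append(
                {
                    "sample_id": sid,
                    "chrom": a.enhancer.region.chrom,
                    "start": a.enhancer.region.start,
                    "end": a.enhancer.region.end,
                    "is_super": a.enhancer.is_super,
                    "gene_id": gid,
                    "distance": dist,
                    "relation": rel,
                }
            )
    _write_tsv(pd.DataFrame(arows), outdir / f"{sid}.assignments.tsv", config)


def _contingency_dict(res) -> dict[str, Any]:
    return {
        "table": [list(r) for r in res.table],
        "statistic": None if res.statistic != res.statistic else res.statistic,
        "p_value": res.p_value,
        "odds_ratio": None if res.odds_ratio != res.odds_ratio else res.odds_ratio,
        "method": res.method,
    }


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run report."""
    t_start = time.time()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    params = {
        "seed": config.seed,
        "landscape": {
            "stitch_distance": config.landscape.stitch_distance,
            "tss_exclusion": config.landscape.tss_exclusion,
            "assignment_window": config.landscape.assignment_window,
        },
        "stats": {
            "min_units": config.stats.min_units,
            "bind_window": config.stats.bind_window,
            "n_perm": config.stats.n_perm,
            "weight_p": config.stats.weight_p,
            "fc_threshold": config.stats.fc_threshold,
        },
        "consensus": {
            "min_cell_lines": config.min_cell_lines,
            "min_tumors": config.min_tumors,
        },
        "fingerprint": config.fingerprint(),
        "version": __version__,
    }

    # ---- inputs: simulated or from disk -------------------------------
    bundles: dict[str, LandscapeBundle] = {}
    sim_genome = None
    tf_peaks = second_tf = None
    treated = control_mat = None
    genes = []
    if config.simulate is not None:
        sim_overrides = dict(config.simulate)
        sim_overrides.pop("seed", None)
        for i, sample in enumerate(config.samples):
            scfg = SimConfig(seed=config.seed + 101 * i, **sim_overrides)
            t0 = time.time()
            bundles[sample.sample_id] = generate_landscape(scfg)
            logger.info("simulated %s in %.1fs", sample.sample_id, time.time() - t0)
        ref = bundles[config.samples[0].sample_id]
        genes = ref.genes
        tf_peaks = generate_tf_peaks(ref.config, ref.truth)
        second_tf = generate_tf_peaks(ref.config, ref.truth, stage="tf2")
        sim_genome = generate_sequences(ref.config, ref.truth)
        treated, control_mat, _ = generate_expression(ref.config, ref.truth)
        results["simulate"] = {
            "n_samples": len(bundles),
            "n_planted_se": len(ref.truth.planted_se_regions),
        }
    else:
        if config.genes is not None:
            genes = read_gene_table(config.genes)
        chrom_sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        for sample in config.samples:
            peaks = read_bed(sample.peaks)
            if chrom_sizes is None:
                raise ValueError("chrom_sizes is required with on-disk samples")
            chip = read_bedgraph(sample.chip, chrom_sizes)
            ctrl = read_bedgraph(sample.control, chrom_sizes) if sample.control else None
            bundles[sample.sample_id] = LandscapeBundle(
                config=None, peaks=peaks, chip=chip, control=ctrl, genes=genes, truth=None
            )
        if config.tf_peaks is not None:
            tf_peaks = read_bed(config.tf_peaks)
        if config.second_tf_peaks is not None:
            second_tf = read_bed(config.second_tf_peaks)
        if config.expression_treated is not None and config.expression_control is not None:
            treated = pd.read_csv(config.expression_treated, sep="\t", index_col=0, comment="#")
            control_mat = pd.read_csv(config.expression_control, sep="\t", index_col=0, comment="#")
        if config.genome_fasta is not None:
            from pyfaidx import Fasta

            sim_genome = Fasta(str(config.genome_fasta))

    # ---- stage: landscape per sample ----------------------------------
    landscapes: dict[str, LandscapeResult] = {}
    assignments_by_sample = {}
    for sid, bundle in bundles.items():
        t0 = time.time()
        ls = build_landscape(
            bundle.peaks,
            bundle.chip,
            bundle.control,
            bundle.genes,
            config.landscape,
            sample_id=sid,
        )
        landscapes[sid] = ls
        assigns = assign_genes(ls, bundle.genes, params=config.landscape)
        assignments_by_sample[sid] = assigns
        _landscape_outputs(ls, assigns, outdir, config)
        entry = {
            "n_enhancers": len(ls.enhancers),
            "n_super": len(ls.super_enhancers),
            "cutoff_signal": round(ls.cutoff_signal, 3),
        }
        if bundle.truth is not None:
            entry["planted_recovery_jaccard"] = round(recovery_jaccard(ls, bundle.truth), 4)
        results.setdefault("landscape", {})[sid] = entry
        logger.info("landscape %s done in %.1fs", sid, time.time() - t0)

    # ---- stage: consensus ---------------------------------------------
    sample_classes = {s.sample_id: s.sample_class for s in config.samples}
    n_lines = sum(1 for c in sample_classes.values() if c == "cell_line")
    n_tumors = sum(1 for c in sample_classes.values() if c == "tumor")
    if n_lines >= config.min_cell_lines and n_tumors >= config.min_tumors:
        table = membership_table(assignments_by_sample, super_only=True)
        consensus = nominate_consensus(
            table, sample_classes, config.min_cell_lines, config.min_tumors
        )
        _write_tsv(table.astype(int), outdir / "se_membership.tsv", config, index=True)
        pd.Series(consensus, name="gene_id").to_csv(
            outdir / "consensus_genes.tsv", sep="\t", index=False
        )
        results["consensus"] = {"n_genes": len(consensus)}
    else:
        results["consensus"] = {
            "skipped": f"need >= {config.min_cell_lines} cell lines and "
            f">= {config.min_tumors} tumors; have {n_lines}/{n_tumors}"
        }

    ref_ls = landscapes[config.samples[0].sample_id]
    se_regions = [e.region for e in ref_ls.super_enhancers]
    te_regions = [e.region for e in ref_ls.typical_enhancers]

    # ---- stage: TF integration ----------------------------------------
    if tf_peaks is not None and se_regions and te_regions:
        chi = containment_chi2(se_regions, te_regions, tf_peaks)
        results["tf_containment"] = _contingency_dict(chi)
        if second_tf is not None:
            sizes = (
                bundles[config.samples[0].sample_id].truth.chrom_sizes
                if config.simulate is not None
                else read_chrom_sizes(config.chrom_sizes)
            )
            width = median_peak_width(tf_peaks, second_tf)
            overlap = peak_overlap_fisher(tf_peaks, second_tf, make_windows(sizes, width))
            results["tf_overlap"] = _contingency_dict(overlap.contingency) | {
                "window_width": width,
                "n_a": overlap.n_a,
                "n_b": overlap.n_b,
                "n_a_overlapping_b": overlap.n_a_overlapping_b,
                "fraction_a_pct": overlap.fraction_a_pct,
                "fraction_b_pct": overlap.fraction_b_pct,
            }

    # ---- stage: repeats -----------------------------------------------
    if sim_genome is not None and se_regions and te_regions:
        rep, per_region = region_repeat_table(
            se_regions, te_regions, sim_genome, min_units=config.stats.min_units
        )
        _write_tsv(per_region, outdir / "repeat_regions.tsv", config)
        from .repeats import _fetch

        se_runs = [
            run
            for r in se_regions
            for run in scan_repeats(
                _fetch(sim_genome, r.chrom, r.start, r.end),
                min_units=config.stats.min_units,
                chrom=r.chrom,
                offset=r.start,
            )
        ]
        write_runs_bed(se_runs, outdir / "se_repeat_runs.bed")
        results["repeats"] = _contingency_dict(rep) | {"min_units": config.stats.min_units}

    # ---- stage: response enrichment -----------------------------------
    if treated is not None and control_mat is not None:
        log2fc = compute_log2fc(treated, control_mat)
        _write_tsv(log2fc.reset_index().rename(columns={"index": "gene_id"}),
                   outdir / "log2fc.tsv", config)
        ranking = RankedResponse.from_series(log2fc, condition="treated_vs_control")
        se_assigned = {
            gid
            for a in assignments_by_sample[config.samples[0].sample_id]
            if a.enhancer.is_super
            for gid, _, _ in a.genes
        } & set(log2fc.index)
        te_assigned = set(log2fc.index) - se_assigned
        enr: dict[str, Any] = {"n_sensitive": len(sensitive_set(dict(log2fc)))}
        if se_assigned and te_assigned:
            res = gsea_permutation(
                ranking,
                se_assigned,
                n_perm=config.stats.n_perm,
                seed=config.seed,
                weight_p=config.stats.weight_p,
            )
            from .enrichment import gsea_es

            _, running_sum = gsea_es(ranking, se_assigned, config.stats.weight_p)
            trace = pd.DataFrame(
                {
                    "rank": range(1, len(running_sum) + 1),
                    "gene_id": ranking.ranking,
                    "running_sum": running_sum,
                }
            )
            _write_tsv(trace, outdir / "se_gsea_running_sum.tsv", config)
            pd.Series(res.leading_edge, name="gene_id").to_csv(
                outdir / "se_gsea_leading_edge.tsv", sep="\t", index=False
            )
            enr["se_gsea"] = {
                "es": round(res.es, 4),
                "nes": round(res.nes, 4),
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
            med_se, med_te, stat, p = compare_fc_distributions(
                [log2fc[g] for g in sorted(se_assigned)],
                [log2fc[g] for g in sorted(te_assigned)],
            )
            enr["fc_comparison"] = {
                "median_se": round(med_se, 4),
                "median_te": round(med_te, 4),
                "statistic": stat,
                "p_value": p,
            }
        if tf_peaks is not None and genes:
            dt = call_direct_targets(
                tf_peaks,
                genes,
                dict(log2fc),
                bind_window=config.stats.bind_window,
                fc_threshold=config.stats.fc_threshold,
            )
            enr["direct_targets"] = {
                "n_bound": len(dt.bound_genes),
                "n_direct": len(dt.direct_targets),
                "n_untested": len(dt.untested),
            }
            if second_tf is not None and dt.direct_targets:
                co = cooccupancy_fraction(
                    dt.direct_targets, second_tf, genes, config.stats.bind_window
                )
                enr["cooccupancy"] = {
                    "count": co.count,
                    "total": co.total,
                    "percent": co.percent,
                }
        results["response"] = enr

    # ---- report --------------------------------------------------------
    results_blob = json.dumps(results, sort_keys=True)
    report = {
        "params": params,
        "results": results,
        "results_hash": hashlib.sha256(results_blob.encode()).hexdigest(),
        "elapsed_s": round(time.time() - t_start, 1),
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("run complete in %.1fs -> %s", report["elapsed_s"], outdir)
    return report
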