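"""Perturbation-response analytics.

Fold changes from count matrices, the THZ1-style sensitive set,
preranked GSEA of SE/TE gene sets against a ranked fold-change list
(gene-set permutation null), and SE-vs-TE fold-change distribution
comparison.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: walking down the ranked list, gene-set hits increment by
``|log2FC|^p / sum_hits |log2FC|^p`` and misses decrement by
``1/(N - N_h)``; ES is the signed extremum. The null distribution is
built by drawing random gene sets of equal size from the universe
(gene-set permutation), the appropriate null for a single preranked
fold-change vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedResponse",
    "EnrichmentResult",
    "compute_log2fc",
    "sensitive_set",
    "gsea_es",
    "gsea_permutation",
    "gsea_batch",
    "compare_fc_distributions",
]


@dataclass(frozen=True)
class RankedResponse:
    """Per-gene log2 fold changes with a deterministic descending ranking.

    Ties are broken lexicographically on gene_id so the ranking — and
    everything downstream of it — is bit-reproducible.
    """

    log2fc: Mapping[str, float]
    condition: str = ""

    @classmethod
    def from_series(cls, s: pd.Series, condition: str = "") -> "RankedResponse":
        return cls(log2fc=dict(s), condition=condition)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.log2fc, key=lambda g: (-self.log2fc[g], g))

    @property
    def values_ranked(self) -> np.ndarray:
        return np.array([self.log2fc[g] for g in self.ranking], dtype=float)

    def __len__(self) -> int:
        return len(self.log2fc)


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    leading_edge: tuple[str, ...]
    seed: int
    gene_set_size: int = 0
    weight_p: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.es <= 1.0):
            raise ValueError(f"|ES| must be <= 1, got {self.es}")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p below the permutation floor 1/(n_perm+1)")


def compute_log2fc(
    counts_treated: pd.DataFrame,
    counts_control: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 fold change between mean CPM of two count matrices.

    Each replicate column is scaled to counts per million, then
    ``log2((mean treated CPM + pc) / (mean control CPM + pc))``.
    Both matrices must share the same gene universe (rows).
    """
    t_only = counts_treated.index.difference(counts_control.index)
    c_only = counts_control.index.difference(counts_treated.index)
    if len(t_only) or len(c_only):
        raise ValueError(
            "gene universe mismatch; only in treated: "
            f"{list(t_only[:5])}, only in control: {list(c_only[:5])}"
        )
    if (counts_treated.values < 0).any() or (counts_control.values < 0).any():
        raise ValueError("counts must be non-negative")
    control = counts_control.loc[counts_treated.index]

    def cpm(df: pd.DataFrame) -> pd.DataFrame:
        return df * 1e6 / df.sum(axis=0)

    mean_t = cpm(counts_treated).mean(axis=1)
    mean_c = cpm(control).mean(axis=1)
    fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    fc.name = "log2fc"
    return fc


def sensitive_set(
    log2fc: Mapping[str, float], threshold_fold: float = 2.0
) -> set[str]:
    """Genes down-regulated more than ``threshold_fold``-fold
    (strict inequality: log2FC < -log2(threshold_fold))."""
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must be > 1")
    cut = -np.log2(threshold_fold)
    return {g for g, fc in log2fc.items() if fc < cut}


def _increments(
    values: np.ndarray, hit: np.ndarray, weight_p: float
) -> np.ndarray:
    """Signed per-rank running-sum increments (sum over the list is 0)."""
    n = len(values)
    n_hit = int(hit.sum())
    w = np.abs(values) ** weight_p
    w_hit_total = w[hit].sum()
    inc = np.full(n, -1.0 / (n - n_hit))
    if w_hit_total > 0:
        inc[hit] = w[hit] / w_hit_total
    else:
        # all hit weights zero (e.g. fc exactly 0): fall back to uniform
        inc[hit] = 1.0 / n_hit
    return inc


def gsea_es(
    ranking: RankedResponse,
    gene_set: set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running sum for one gene set.

    Returns ``(es, running_sum)`` where ES is the running-sum value of
    largest absolute deviation from zero (signed).
    """
    universe = set(ranking.log2fc)
    hits_in = gene_set & universe
    if not hits_in:
        raise ValueError("gene set is disjoint from the ranked universe")
    if hits_in == universe:
        raise ValueError("gene set equals the ranked universe; ES undefined")
    order = ranking.ranking
    values = ranking.values_ranked
    hit = np.array([g in gene_set for g in order], dtype=bool)
    rs = np.cumsum(_increments(values, hit, weight_p))
    idx = int(np.argmax(np.abs(rs)))
    return float(rs[idx]), rs


def _leading_edge(order: Sequence[str], hit: np.ndarray, rs: np.ndarray) -> tuple[str, ...]:
    idx = int(np.argmax(np.abs(rs)))
    if rs[idx] >= 0:
        sel = np.zeros(len(order), dtype=bool)
        sel[: idx + 1] = True
    else:
        sel = np.zeros(len(order), dtype=bool)
        sel[idx:] = True
    return tuple(g for g, h, s in zip(order, hit, sel) if h and s)


def gsea_permutation(
    ranking: RankedResponse,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Gene-set permutation GSEA.

    The null is the ES of ``n_perm`` random gene sets of equal size drawn
    without replacement from the universe. As in standard GSEA, the
    nominal p is conditional on the observed sign:
    ``p = (1 + #{same-sign null with |ES_null| >= |ES|}) / (1 + #same-sign null)``,
    which is uniform under the null;
    ``NES = ES / mean(|same-sign null ES|)``. Fixed seed => bit-identical
    result.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = set(ranking.log2fc)
    k = len(gene_set & universe)
    if 2 * k > len(universe):
        warnings.warn(
            "gene set larger than half the universe; permutation null is degenerate",
            stacklevel=2,
        )
    order = ranking.ranking
    values = ranking.values_ranked
    hit = np.array([g in gene_set for g in order], dtype=bool)
    es, rs = gsea_es(ranking, gene_set, weight_p)

    n = len(order)
    rng = np.random.default_rng(seed)
    w = np.abs(values) ** weight_p
    null_es = np.empty(n_perm)
    base = -1.0 / (n - k)
    for i in range(n_perm):
        pick = rng.choice(n, size=k, replace=False)
        inc = np.full(n, base)
        wsum = w[pick].sum()
        if wsum > 0:
            inc[pick] = w[pick] / wsum
        else:
            inc[pick] = 1.0 / k
        r = np.cumsum(inc)
        null_es[i] = r[np.argmax(np.abs(r))]

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + n_extreme) / (1 + int(same_sign.sum()))
    denom_pool = np.abs(null_es[same_sign])
    if denom_pool.size == 0:
        denom_pool = np.abs(null_es)
    nes = es / denom_pool.mean() if denom_pool.mean() > 0 else float("nan")
    return EnrichmentResult(
        es=es,
        nes=float(nes),
        p_value=float(p),
        n_permutations=n_perm,
        leading_edge=_leading_edge(order, hit, rs),
        seed=seed,
        gene_set_size=k,
        weight_p=weight_p,
    )


def gsea_batch(
    ranking: RankedResponse,
    gene_sets: Mapping[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run several gene sets and attach Benjamini–Hochberg q-values."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for i, (name, gs) in enumerate(sorted(gene_sets.items())):
        res = gsea_permutation(ranking, gs, n_perm=n_perm, seed=seed + i, weight_p=weight_p)
        rows.append(
            {
                "gene_set": name,
                "size": res.gene_set_size,
                "es": res.es,
                "nes": res.nes,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def compare_fc_distributions(
    fc_a: Sequence[float], fc_b: Sequence[float]
) -> tuple[float, float, float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two fold-change lists.

    Uses the Mann–Whitney U statistic with tie correction; the exact
    null is used for small tie-free samples, the normal approximation
    otherwise. Returns ``(median_a, median_b, statistic, p)``.
    """
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(np.median(a)), float(np.median(b)), float(res.statistic), float(res.pvalue)
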