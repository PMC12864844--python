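"""Resampling statistics for enrichment and co-expression claims.

Three tools: an expression-matched stratified bootstrap that asks whether
m6A-marked genes are differentially expressed more often than expected
once the expression-detectability confound is controlled; a permutation
test for the Jaccard overlap of two gene sets drawn from a shared
universe; and the upper-tail hypergeometric test for lineage enrichment
of a co-expressed gene sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Collection, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "OverlapResult",
    "expression_matched_bootstrap",
    "jaccard",
    "jaccard_permutation",
    "lineage_hypergeometric",
    "de_gene_classifier",
]


@dataclass
class BootstrapResult:
    """Expression-matched bootstrap of the DE-proportion difference."""

    observed_diff: float  # DE proportion, m6A minus non-m6A, matched groups
    distribution: np.ndarray  # per-iteration differences
    p_value: float  # empirical two-sided
    ci: tuple[float, float]  # 2.5th-97.5th percentiles
    matching_quality: float  # |mean log10 baseMean difference| between groups
    unmatched_expression_gap: float
    n_m6a: int = 0
    n_other: int = 0
    per_group: int = 0


@dataclass
class OverlapResult:
    """Jaccard overlap of two gene sets with a permutation p-value."""

    size_a: int
    size_b: int
    intersection: int
    union: int
    jaccard: float
    p_value: float
    n_perm: int
    null_overlaps: np.ndarray = field(default_factory=lambda: np.array([]))


def de_gene_classifier(
    de_table: pd.DataFrame,
    padj_cut: float = 1e-5,
    lfc_cut: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Up/down-regulated gene lists with strict fold-change inequality;
    missing adjusted p-values count as 1 (never significant)."""
    padj = de_table["padj"].fillna(1.0)
    lfc = de_table["log2FoldChange"]
    up = de_table.loc[(padj < padj_cut) & (lfc > lfc_cut), "gene"].tolist()
    down = de_table.loc[(padj < padj_cut) & (lfc < -lfc_cut), "gene"].tolist()
    return up, down


def expression_matched_bootstrap(
    de_table: pd.DataFrame,
    *,
    min_basemean: float = 200.0,
    alpha: float = 0.05,
    n_bins: int = 10,
    frac: float = 0.8,
    n_iter: int = 1000,
    seed: int = 0,
    flat_quotas: bool = False,
) -> BootstrapResult:
    """Stratified bootstrap of DE proportions matched on expression.

    Genes with baseMean below ``min_basemean`` are dropped; missing padj is
    set to 1 and DE is defined as padj < ``alpha``. log10(baseMean) is cut
    into ``n_bins`` quantile bins; each iteration draws, per bin, the same
    number of genes with replacement from the m6A and non-m6A groups so
    that each group totals ``frac`` x min(group sizes). Bin quotas are
    proportional to pooled bin occupancy by default (``flat_quotas`` uses
    an even split instead); a bin empty in either group is skipped and its
    quota redistributed. The two-sided p-value doubles the smaller tail of
    the bootstrap difference distribution around zero.
    """
    df = de_table[de_table["baseMean"] >= min_basemean].copy()
    df["padj"] = df["padj"].fillna(1.0)
    df["is_de"] = df["padj"] < alpha
    df["logbm"] = np.log10(df["baseMean"])
    g1 = df[df["has_m6a"]]
    g0 = df[~df["has_m6a"]]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both m6A groups must be non-empty after filtering")
    per_group = int(round(frac * min(len(g1), len(g0))))
    edges = np.quantile(df["logbm"], np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    df["bin"] = pd.cut(df["logbm"], edges, labels=False)

    bins_present = []
    for b in range(n_bins):
        n1 = int(((df["bin"] == b) & df["has_m6a"]).sum())
        n0 = int(((df["bin"] == b) & ~df["has_m6a"]).sum())
        occ = int((df["bin"] == b).sum())
        if n1 == 0 or n0 == 0:
            if occ:
                log.warning("bin %d empty in one group; quota redistributed", b)
            continue
        bins_present.append((b, occ))
    if not bins_present:
        raise ValueError("no expression bin is populated in both groups")
    if flat_quotas:
        weights = np.ones(len(bins_present))
    else:
        weights = np.array([occ for _, occ in bins_present], dtype=float)
    quotas = np.floor(per_group * weights / weights.sum()).astype(int)
    # distribute the rounding remainder to the largest bins
    rem = per_group - quotas.sum()
    order = np.argsort(-weights)
    for i in range(rem):
        quotas[order[i % len(quotas)]] += 1

    rng = np.random.default_rng(seed)
    de1 = {b: g1.loc[df["bin"] == b, "is_de"].to_numpy() for b, _ in bins_present}
    de0 = {b: g0.loc[df["bin"] == b, "is_de"].to_numpy() for b, _ in bins_present}
    bm1 = {b: g1.loc[df["bin"] == b, "logbm"].to_numpy() for b, _ in bins_present}
    bm0 = {b: g0.loc[df["bin"] == b, "logbm"].to_numpy() for b, _ in bins_present}

    sum1 = np.zeros(n_iter)
    sum0 = np.zeros(n_iter)
    bmsum1 = np.zeros(n_iter)
    bmsum0 = np.zeros(n_iter)
    for (b, _), q in zip(bins_present, quotas):
        if q == 0:
            continue
        i1 = rng.integers(0, len(de1[b]), size=(n_iter, q))
        i0 = rng.integers(0, len(de0[b]), size=(n_iter, q))
        sum1 += de1[b][i1].sum(axis=1)
        sum0 += de0[b][i0].sum(axis=1)
        bmsum1 += bm1[b][i1].sum(axis=1)
        bmsum0 += bm0[b][i0].sum(axis=1)
    total = quotas.sum()
    diffs = sum1 / total - sum0 / total
    # headline difference: plain DE proportions of the filtered groups
    observed = float(g1["is_de"].mean() - g0["is_de"].mean())
    lo_tail = float(np.mean(diffs <= 0))
    hi_tail = float(np.mean(diffs >= 0))
    p = min(1.0, 2.0 * min(lo_tail, hi_tail))
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    matching = float(np.abs(bmsum1 / total - bmsum0 / total).mean())
    unmatched = abs(float(g1["logbm"].mean() - g0["logbm"].mean()))
    return BootstrapResult(
        observed_diff=observed,
        distribution=diffs,
        p_value=p,
        ci=ci,
        matching_quality=matching,
        unmatched_expression_gap=unmatched,
        n_m6a=len(g1),
        n_other=len(g0),
        per_group=int(total),
    )


def jaccard(set_a: Collection, set_b: Collection) -> float:
    """Intersection over union; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def jaccard_permutation(
    set_a: Collection,
    set_b: Collection,
    universe: Sequence,
    *,
    n_perm: int = 1_000_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> OverlapResult:
    """Permutation test of the overlap of two gene sets.

    Each iteration draws |A| and |B| genes without replacement from the
    universe and records the overlap; the empirical p-value is
    (1 + #{null overlap >= observed}) / (n_perm + 1), so it can never be
    exactly zero.
    """
    a, b = set(set_a), set(set_b)
    uni = list(universe)
    n = len(uni)
    if not a <= set(uni) or not b <= set(uni):
        raise ValueError("sets must be subsets of the universe")
    if len(a) > n or len(b) > n:
        raise ValueError("set larger than universe")
    obs_inter = len(a & b)
    obs_j = jaccard(a, b)
    rng = np.random.default_rng(seed)
    na, nb = len(a), len(b)
    count_ge = 0
    null = np.empty(n_perm, dtype=np.int32)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # membership masks via argpartition of random keys: first na/nb
        # ranks of a random permutation are a uniform without-replacement draw
        keys_a = rng.random((m, n)).argpartition(na - 1, axis=1)[:, :na]
        keys_b = rng.random((m, n)).argpartition(nb - 1, axis=1)[:, :nb]
        mask_a = np.zeros((m, n), dtype=bool)
        mask_b = np.zeros((m, n), dtype=bool)
        rows = np.arange(m)[:, None]
        mask_a[rows, keys_a] = True
        mask_b[rows, keys_b] = True
        ov = (mask_a & mask_b).sum(axis=1)
        null[done : done + m] = ov
        count_ge += int((ov >= obs_inter).sum())
        done += m
    p = (1 + count_ge) / (n_perm + 1)
    return OverlapResult(
        size_a=na,
        size_b=nb,
        intersection=obs_inter,
        union=len(a | b),
        jaccard=obs_j,
        p_value=float(p),
        n_perm=n_perm,
        null_overlaps=null,
    )


def lineage_hypergeometric(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N genes in the population, K of them associated with the lineage, a
    sample of n co-expressed genes of which k hit the lineage.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"infeasible counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
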