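"""Transcript-topology characterisation of called m6A sites.

Positions along length-normalised transcripts (metagene), distance to the
nearest exon-intron junction, spacing between a gene's dominant site and
its nearest neighbour, and the score correlation of adjacent sites.

Site tables are tidy frames with at least ``gene_id``, ``position`` and a
score column (default ``median_control``), as produced by
``scoring.aggregate_conditions``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TranscriptModel

log = logging.getLogger(__name__)

N_BINS = 10
SCALE = 1000

__all__ = [
    "MetageneProfile",
    "SpacingSummary",
    "position_bin",
    "metagene",
    "eij_distance",
    "nearest_secondary_spacing",
    "adjacent_score_correlation",
    "score_by_bin",
]


@dataclass
class MetageneProfile:
    """Length-normalised positional distribution of sites."""

    normalized_positions: np.ndarray  # in [0, SCALE)
    bins: np.ndarray  # 1..N_BINS
    bin_counts: np.ndarray  # length N_BINS
    bin_scores: list[np.ndarray] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.bin_counts.sum())


@dataclass
class SpacingSummary:
    """Distance from each gene's top site to its nearest other site."""

    per_gene: pd.DataFrame  # gene_id, top_position, nearest_distance
    median_distance: float


def position_bin(position: int, length: int) -> int:
    """Map a transcript position to metagene bin 1..10 (5'→3')."""
    if not (0 <= position < length):
        raise ValueError(f"position {position} outside transcript of length {length}")
    return min(N_BINS, int(N_BINS * position / length) + 1)


def metagene(
    sites: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    *,
    score_col: str = "median_control",
    exclude_single_exon: bool = False,
    min_exons: int | None = None,
    min_score: float | None = None,
    min_replicate_support: int | None = None,
    min_coverage: float | None = None,
    coverage_col: str | None = None,
    motif_include: str | None = None,
    motif_exclude: str | None = None,
) -> MetageneProfile:
    """Bin site positions into 10 equal bins of the length-normalised gene.

    Optional pre-filters mirror common figure conventions: exon count,
    score, replicate support, coverage and regular-expression motif
    inclusion/exclusion applied to the site's 13-nt context.
    """
    by_gene = {t.gene_id: t for t in transcripts}
    df = sites.copy()
    if exclude_single_exon:
        df = df[df["gene_id"].map(lambda g: len(by_gene[g].eij_positions) > 0)]
    if min_exons is not None:
        df = df[
            df["gene_id"].map(lambda g: len(by_gene[g].eij_positions) + 1 >= min_exons)
        ]
    if min_score is not None and score_col in df:
        df = df[df[score_col] > min_score]
    if min_replicate_support is not None and "replicate_support" in df:
        df = df[df["replicate_support"] >= min_replicate_support]
    if min_coverage is not None:
        col = coverage_col or "coverage_control"
        if col in df:
            df = df[df[col] >= min_coverage]
    if motif_include is not None and "context13" in df:
        df = df[df["context13"].str.contains(motif_include, regex=True)]
    if motif_exclude is not None and "context13" in df:
        df = df[~df["context13"].str.contains(motif_exclude, regex=True)]

    norm = np.empty(len(df))
    bins = np.empty(len(df), dtype=int)
    for i, (g, p) in enumerate(zip(df["gene_id"], df["position"])):
        length = by_gene[g].length
        if p >= length:
            raise ValueError(f"site {g}:{p} beyond transcript length {length}")
        norm[i] = SCALE * p / length
        bins[i] = position_bin(int(p), length)
    counts = np.bincount(bins, minlength=N_BINS + 1)[1:]
    scores: list[np.ndarray] = []
    if score_col in df:
        sc = df[score_col].to_numpy()
        scores = [sc[bins == b] for b in range(1, N_BINS + 1)]
    return MetageneProfile(
        normalized_positions=norm, bins=bins, bin_counts=counts, bin_scores=scores
    )


def eij_distance(position: int, transcript: TranscriptModel) -> float:
    """Distance (nt) to the nearest exon-intron junction; NaN if single-exon."""
    if not transcript.eij_positions:
        return float("nan")
    return float(min(abs(position - j) for j in transcript.eij_positions))


def nearest_secondary_spacing(
    sites: pd.DataFrame, *, score_col: str = "median_control"
) -> SpacingSummary:
    """For each gene with ≥2 sites: distance from the highest-scoring site
    to the nearest other site. Ties in the top score break to the 5'-most
    position. The headline statistic is the median over genes."""
    rows = []
    for gene_id, grp in sites.groupby("gene_id", sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        sc = grp[score_col].to_numpy()
        top_i = int(np.argmax(sc))  # argmax returns first max -> 5'-most
        d = int(np.min(np.abs(np.delete(pos, top_i) - pos[top_i])))
        rows.append((gene_id, int(pos[top_i]), d))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "top_position", "nearest_distance"])
    med = float(per_gene["nearest_distance"].median()) if len(per_gene) else float("nan")
    return SpacingSummary(per_gene=per_gene, median_distance=med)


def adjacent_score_correlation(
    sites: pd.DataFrame,
    max_gap: int = 40,
    *,
    score_col: str = "median_control",
) -> tuple[float, float, int]:
    """Pearson correlation of scores of adjacent sites.

    Pairs are all unique same-gene site pairs separated by at most
    ``max_gap`` nt. Returns (r, p, n_pairs); (nan, nan, n) with a warning
    when fewer than 3 pairs qualify.
    """
    xs: list[float] = []
    ys: list[float] = []
    for _, grp in sites.groupby("gene_id", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        sc = grp[score_col].to_numpy()
        for i, j in itertools.combinations(range(len(grp)), 2):
            if 0 < pos[j] - pos[i] <= max_gap:
                xs.append(float(sc[i]))
                ys.append(float(sc[j]))
    n = len(xs)
    if n < 3:
        log.warning("only %d adjacent pairs; correlation undefined", n)
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def score_by_bin(
    sites: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    *,
    score_col: str = "median_control",
) -> dict:
    """Per-bin score distributions plus a two-tailed Student t test
    comparing the 3'-most bin against all other bins pooled."""
    prof = metagene(sites, transcripts, score_col=score_col)
    last = prof.bin_scores[-1] if prof.bin_scores else np.array([])
    rest = (
        np.concatenate(prof.bin_scores[:-1])
        if prof.bin_scores
        else np.array([])
    )
    if len(last) < 2 or len(rest) < 2:
        t = p = float("nan")
    else:
        t, p = stats.ttest_ind(last, rest, equal_var=True)
    return {
        "profile": prof,
        "bin_means": [float(np.mean(s)) if len(s) else float("nan") for s in prof.bin_scores],
        "t_stat": float(t),
        "p_value": float(p),
        "n_last_bin": int(len(last)),
        "n_rest": int(len(rest)),
    }
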