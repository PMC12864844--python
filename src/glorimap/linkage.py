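"""Single-molecule co-methylation linkage between adjacent m6A sites.

In GLORI-treated reads the base at a site records the methylation state of
that molecule (A = methylated/protected, G = unmethylated/converted). For a
pair of nearby sites, reads spanning both give a 2x2 joint table of
methylation states whose independence is tested by chi-square: a
significant association would indicate that methylation events at the two
sites are coupled on the same molecule.

Pairs are screened the way intermediate-stoichiometry adjacent sites are
selected in practice: within a gap ceiling, both scores inside an
informative band, and one member being the gene's dominant (highest
median score) site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ReadSet

log = logging.getLogger(__name__)

__all__ = [
    "PairLinkage",
    "select_pairs",
    "joint_read_table",
    "linkage_chi_square",
    "chi2_2x2",
    "linkage_survey",
]


@dataclass
class PairLinkage:
    """Joint read evidence for one site pair (first letter = base at pos1)."""

    gene_id: str
    pos1: int
    pos2: int
    n_AA: int = 0
    n_AG: int = 0
    n_GA: int = 0
    n_GG: int = 0
    n_other: int = 0
    chi2_stat: float = float("nan")
    p_value: float = float("nan")

    @property
    def gap(self) -> int:
        return self.pos2 - self.pos1

    @property
    def n_spanning(self) -> int:
        return self.n_AA + self.n_AG + self.n_GA + self.n_GG + self.n_other

    def table(self) -> np.ndarray:
        return np.array([[self.n_AA, self.n_AG], [self.n_GA, self.n_GG]])


def select_pairs(
    sites: pd.DataFrame,
    max_gap: int = 40,
    score_lo: float = 0.4,
    score_hi: float = 0.7,
    *,
    score_col: str = "median_control",
    require_dominant: bool = True,
) -> list[tuple[str, int, int]]:
    """Candidate site pairs for the linkage test.

    A pair qualifies when (1) the sites are at most ``max_gap`` nt apart,
    (2) both have ``score_col`` inside [score_lo, score_hi] — the band in
    which both joint outcomes are observable — and (3) one member is the
    gene's dominant site, read as the site with the highest ``score_col``
    in the gene (set ``require_dominant=False`` to drop criterion 3).
    """
    pairs: list[tuple[str, int, int]] = []
    for gene_id, grp in sites.groupby("gene_id", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        sc = grp[score_col].to_numpy()
        if len(pos) < 2:
            continue
        dom = int(pos[np.argmax(sc)])
        in_band = (sc >= score_lo) & (sc <= score_hi)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if pos[j] - pos[i] > max_gap:
                    break
                if not (in_band[i] and in_band[j]):
                    continue
                if require_dominant and dom not in (pos[i], pos[j]):
                    continue
                pairs.append((gene_id, int(pos[i]), int(pos[j])))
    return pairs


def joint_read_table(
    reads: ReadSet, pair: tuple[str, int, int]
) -> PairLinkage | None:
    """Tally joint base states over reads spanning both sites.

    Reads with a non-A/G base at either site go to ``n_other`` and are
    excluded from the 2x2 test. Returns None (with a warning) when no read
    spans both positions.
    """
    gene_id, pos1, pos2 = pair
    if pos2 <= pos1:
        raise ValueError("pair positions must satisfy pos1 < pos2")
    df = reads.records
    grp = df[df["gene_id"] == gene_id]
    starts = grp["start"].to_numpy()
    seqs = grp["seq"].to_numpy()
    ends = starts + np.fromiter((len(s) for s in seqs), dtype=int, count=len(seqs))
    span = (starts <= pos1) & (ends > pos2)
    if not span.any():
        log.warning("no reads span pair %s:%d-%d; dropped", gene_id, pos1, pos2)
        return None
    out = PairLinkage(gene_id=gene_id, pos1=pos1, pos2=pos2)
    for start, seq in zip(starts[span], seqs[span]):
        b1 = seq[pos1 - start]
        b2 = seq[pos2 - start]
        if b1 in "AG" and b2 in "AG":
            attr = f"n_{b1}{b2}"
            setattr(out, attr, getattr(out, attr) + 1)
        else:
            out.n_other += 1
    return out


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, no
    continuity correction. NaN when any margin is zero (test undefined)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def linkage_chi_square(pair: PairLinkage, min_spanning: int = 10) -> PairLinkage:
    """Fill ``chi2_stat`` and ``p_value``; NaN when fewer than
    ``min_spanning`` informative (A/G-only) reads or a zero margin."""
    n_info = pair.n_AA + pair.n_AG + pair.n_GA + pair.n_GG
    if n_info < min_spanning:
        pair.chi2_stat = pair.p_value = float("nan")
        return pair
    pair.chi2_stat, pair.p_value = chi2_2x2(pair.table())
    return pair


def linkage_survey(
    pairs: list[tuple[str, int, int]],
    reads: ReadSet,
    *,
    min_spanning: int = 10,
) -> pd.DataFrame:
    """Run the linkage test over all candidate pairs.

    Returns a per-pair frame (counts, chi2, p). The frame's attrs carry the
    fraction of tests with p < 0.05 and a Kolmogorov-Smirnov statistic
    against the uniform distribution — a diagnostic of whether the p-value
    distribution is consistent with independent methylation.
    """
    rows = []
    for pr in pairs:
        pl = joint_read_table(reads, pr)
        if pl is None:
            continue
        pl = linkage_chi_square(pl, min_spanning=min_spanning)
        rows.append(
            {
                "gene_id": pl.gene_id,
                "pos1": pl.pos1,
                "pos2": pl.pos2,
                "gap": pl.gap,
                "n_AA": pl.n_AA,
                "n_AG": pl.n_AG,
                "n_GA": pl.n_GA,
                "n_GG": pl.n_GG,
                "n_other": pl.n_other,
                "n_spanning": pl.n_spanning,
                "chi2": pl.chi2_stat,
                "p": pl.p_value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "pos1", "pos2", "gap", "n_AA", "n_AG", "n_GA", "n_GG",
            "n_other", "n_spanning", "chi2", "p",
        ],
    )
    pvals = df["p"].dropna().to_numpy() if len(df) else np.array([])
    if len(pvals):
        ks = stats.kstest(pvals, "uniform")
        df.attrs["ks_stat"] = float(ks.statistic)
        df.attrs["ks_p"] = float(ks.pvalue)
        df.attrs["frac_p_lt_05"] = float(np.mean(pvals < 0.05))
    else:
        df.attrs["ks_stat"] = df.attrs["ks_p"] = df.attrs["frac_p_lt_05"] = float("nan")
    df.attrs["n_tested"] = int(len(pvals))
    return df
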