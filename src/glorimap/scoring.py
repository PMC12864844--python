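"""Per-adenosine GLORI scoring and m6A site calling.

The GLORI chemistry converts unmethylated adenosines to inosines, which
sequence as G; methylated adenosines are protected. At a reference-A
position the fraction A/(A+G) among mapped reads therefore estimates the
methylation stoichiometry. Sites are called per sample by a score
threshold, a combined A+G coverage threshold, and a one-sided Fisher's
exact test against the sample's pooled background of unconverted adenines,
then aggregated across replicates by the median.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ReadSet, TranscriptModel

log = logging.getLogger(__name__)

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

__all__ = [
    "NucleotideCounts",
    "SiteCall",
    "pileup_counts",
    "glori_score",
    "estimate_background",
    "fisher_stage_pvalues",
    "call_sites",
    "aggregate_conditions",
    "site_calls_to_frame",
]


@dataclass
class NucleotideCounts:
    """Per-position base tallies for one transcript in one sample.

    ``counts`` has shape (length, 4) in A, C, G, U order; coverage at a
    position is the row sum.
    """

    gene_id: str
    sample_id: str
    counts: np.ndarray

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def coverage(self, position: int) -> int:
        return int(self.counts[position].sum())

    def ag(self, position: int) -> tuple[int, int]:
        row = self.counts[position]
        return int(row[0]), int(row[2])


@dataclass
class SiteCall:
    """One called m6A site with per-sample evidence."""

    gene_id: str
    position: int
    scores: dict[str, float]
    ag_coverage: dict[str, int]
    pvalues: dict[str, float]
    fisher_p: float
    context13: str
    replicate_support: int
    median_scores: dict[str, float] = field(default_factory=dict)
    median_coverage: dict[str, float] = field(default_factory=dict)

    @property
    def median_control_score(self) -> float:
        return self.median_scores.get("control", float("nan"))


def pileup_counts(
    reads: ReadSet,
    transcripts: Sequence[TranscriptModel],
    *,
    min_reads_per_transcript: int = 10,
    max_read_span: int = 700,
) -> dict[str, dict[str, NucleotideCounts]]:
    """Exact per-position base tallies, one table per (sample, transcript).

    Transcripts with fewer than ``min_reads_per_transcript`` reads in a
    sample are dropped, as are individual reads spanning more than
    ``max_read_span`` nt; reads extending past the transcript end are
    skipped with a warning.
    """
    lengths = {t.gene_id: t.length for t in transcripts}
    out: dict[str, dict[str, NucleotideCounts]] = {}
    df = reads.records
    if df.empty:
        return out
    for (sample_id, gene_id), grp in df.groupby(["sample_id", "gene_id"], sort=True):
        length = lengths.get(gene_id)
        if length is None:
            log.warning("reads for unknown transcript %s skipped", gene_id)
            continue
        spans = grp["seq"].str.len()
        keep = spans <= max_read_span
        grp = grp[keep]
        if len(grp) < min_reads_per_transcript:
            continue
        counts = np.zeros((length, 4), dtype=np.int64)
        skipped = 0
        for start, seq in zip(grp["start"].to_numpy(), grp["seq"].to_numpy()):
            end = start + len(seq)
            if start < 0 or end > length:
                skipped += 1
                continue
            idx = np.frombuffer(seq.encode(), dtype="S1")
            for base, col in (("A", 0), ("C", 1), ("G", 2), ("U", 3), ("T", 3)):
                mask = idx == base.encode()
                if mask.any():
                    np.add.at(counts[:, col], start + np.flatnonzero(mask), 1)
        if skipped:
            log.warning(
                "%d reads outside bounds of %s skipped", skipped, gene_id
            )
        out.setdefault(sample_id, {})[gene_id] = NucleotideCounts(
            gene_id=gene_id, sample_id=sample_id, counts=counts
        )
    return out


def glori_score(
    counts: Mapping[str, NucleotideCounts] | NucleotideCounts,
    gene_id: str | None,
    position: int,
    *,
    reference: str | None = None,
    min_count: int = 10,
) -> float | None:
    """A/(A+G) at a reference-A position; None when A+G < ``min_count``."""
    nc = counts[gene_id] if isinstance(counts, Mapping) else counts
    if reference is not None and reference[position] != "A":
        raise ValueError(
            f"reference base at {nc.gene_id}:{position} is "
            f"{reference[position]!r}, not A"
        )
    a, g = nc.ag(position)
    if a + g < min_count:
        return None
    return a / (a + g)


def estimate_background(
    sample_counts: Mapping[str, NucleotideCounts],
    transcripts: Sequence[TranscriptModel],
) -> float:
    """Pooled unconverted-adenine fraction for one sample.

    Sums A and G counts over every reference-A position across all
    transcripts and returns total_A / (total_A + total_G). Pooling counts
    (rather than averaging per-position ratios) keeps low-coverage
    positions from dominating.
    """
    seqs = {t.gene_id: t.sequence for t in transcripts}
    tot_a = tot_g = 0
    for gene_id, nc in sample_counts.items():
        seq = seqs.get(gene_id)
        if seq is None:
            continue
        mask = np.frombuffer(seq.encode(), dtype="S1") == b"A"
        tot_a += int(nc.counts[mask, 0].sum())
        tot_g += int(nc.counts[mask, 2].sum())
    if tot_a + tot_g == 0:
        raise ValueError("no A/G counts at reference-A positions")
    return tot_a / (tot_a + tot_g)


def _fisher_greater(a: int, g: int, bg_a: int, bg_g: int) -> float:
    """One-sided Fisher's exact test: is A enriched at this position
    relative to the pooled (A, G) background?"""
    _, p = stats.fisher_exact([[a, g], [bg_a, bg_g]], alternative="greater")
    return float(p)


def fisher_stage_pvalues(
    sample_counts: Mapping[str, NucleotideCounts],
    transcripts: Sequence[TranscriptModel],
    background: float,
    *,
    min_count: int = 10,
    bg_scale: int = 1_000_000,
) -> pd.DataFrame:
    """Fisher-test p-value for every covered reference-A position.

    Diagnostic view of the test stage alone, before the score filter. The
    pooled background fraction is represented as integer pseudo-counts at
    ``bg_scale`` total.
    """
    seqs = {t.gene_id: t.sequence for t in transcripts}
    bg_a = int(round(background * bg_scale))
    bg_g = bg_scale - bg_a
    rows = []
    for gene_id, nc in sample_counts.items():
        seq = seqs.get(gene_id)
        if seq is None:
            continue
        a_pos = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") == b"A")
        for p_ in a_pos:
            a, g = nc.ag(int(p_))
            if a + g < min_count:
                continue
            pval = _fisher_greater(a, g, bg_a, bg_g)
            rows.append((gene_id, int(p_), a, g, a / (a + g), pval))
    return pd.DataFrame(
        rows, columns=["gene_id", "position", "A", "G", "score", "p"]
    )


def extract_context(position: int, sequence: str, flank: int = 6) -> str:
    """Context window around a site, N-padded at transcript ends."""
    left = sequence[max(0, position - flank) : position]
    right = sequence[position + 1 : position + 1 + flank]
    return (
        "N" * (flank - len(left))
        + left
        + sequence[position]
        + right
        + "N" * (flank - len(right))
    )


def call_sites(
    counts_by_sample: Mapping[str, Mapping[str, NucleotideCounts]],
    transcripts: Sequence[TranscriptModel],
    backgrounds: Mapping[str, float],
    *,
    min_score: float = 0.1,
    min_count: int = 10,
    alpha: float = 0.05,
    replicate_support: int = 1,
    bg_scale: int = 1_000_000,
) -> list[SiteCall]:
    """Call m6A sites across samples.

    Per sample, a reference-A position passes when its GLORI score exceeds
    ``min_score``, its combined A+G count is at least ``min_count``, and a
    one-sided Fisher's exact test against the sample's pooled background
    rejects at ``alpha``. A site is emitted when it passes in at least
    ``replicate_support`` samples; evidence from every sample with
    sufficient coverage is attached either way. No multiple-testing
    correction is applied at this stage.
    """
    seq_by_gene = {t.gene_id: t.sequence for t in transcripts}
    missing = set(counts_by_sample) - set(backgrounds)
    if missing:
        raise ValueError(f"no background estimate for samples: {sorted(missing)}")

    # candidate (gene, pos) -> per-sample evidence
    evidence: dict[tuple[str, int], dict[str, tuple[float, int, float, bool]]] = {}
    for sample_id, per_gene in counts_by_sample.items():
        bg = backgrounds[sample_id]
        bg_a = int(round(bg * bg_scale))
        bg_g = bg_scale - bg_a
        for gene_id, nc in per_gene.items():
            seq = seq_by_gene.get(gene_id)
            if seq is None:
                continue
            a_pos = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") == b"A")
            a_cnt = nc.counts[a_pos, 0]
            g_cnt = nc.counts[a_pos, 2]
            ag = a_cnt + g_cnt
            ok_cov = ag >= min_count
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(ag > 0, a_cnt / np.maximum(ag, 1), np.nan)
            for i in np.flatnonzero(ok_cov):
                s = float(score[i])
                passed = False
                pval = float("nan")
                if s > min_score:
                    pval = _fisher_greater(int(a_cnt[i]), int(g_cnt[i]), bg_a, bg_g)
                    passed = pval < alpha
                key = (gene_id, int(a_pos[i]))
                evidence.setdefault(key, {})[sample_id] = (
                    s,
                    int(ag[i]),
                    pval,
                    passed,
                )

    calls: list[SiteCall] = []
    for (gene_id, position), ev in sorted(evidence.items()):
        n_pass = sum(1 for (_, _, _, ok) in ev.values() if ok)
        if n_pass < replicate_support:
            continue
        pvals = {s: p for s, (_, _, p, ok) in ev.items() if ok}
        calls.append(
            SiteCall(
                gene_id=gene_id,
                position=position,
                scores={s: v[0] for s, v in ev.items()},
                ag_coverage={s: v[1] for s, v in ev.items()},
                pvalues={s: v[2] for s, v in ev.items() if np.isfinite(v[2])},
                fisher_p=min(pvals.values()) if pvals else float("nan"),
                context13=extract_context(position, seq_by_gene[gene_id]),
                replicate_support=n_pass,
            )
        )
    return calls


def aggregate_conditions(
    site_calls: Iterable[SiteCall],
    condition_map: Mapping[str, str],
    *,
    cutoffs: Sequence[float] = (0.1, 0.5, 0.9),
) -> pd.DataFrame:
    """Replicate-aggregated condition table.

    Fills each call's per-condition median score/coverage (median over the
    condition's replicates that had sufficient coverage) and returns a tidy
    frame with one row per site. The frame's ``attrs['cutoff_counts']``
    holds, per condition, the number of sites whose median exceeds each
    cutoff.
    """
    calls = list(site_calls)
    conditions = sorted(set(condition_map.values()))
    rows = []
    for c in calls:
        c.median_scores = {}
        c.median_coverage = {}
        row: dict[str, object] = {
            "gene_id": c.gene_id,
            "position": c.position,
            "context13": c.context13,
            "fisher_p": c.fisher_p,
            "replicate_support": c.replicate_support,
        }
        for cond in conditions:
            reps = [s for s in c.scores if condition_map.get(s) == cond]
            vals = [c.scores[s] for s in reps]
            covs = [c.ag_coverage[s] for s in reps]
            med = float(np.median(vals)) if vals else float("nan")
            medc = float(np.median(covs)) if covs else float("nan")
            c.median_scores[cond] = med
            c.median_coverage[cond] = medc
            row[f"median_{cond}"] = med
            row[f"coverage_{cond}"] = medc
        rows.append(row)
    df = pd.DataFrame(rows)
    counts: dict[str, dict[float, int]] = {}
    for cond in conditions:
        col = df[f"median_{cond}"] if not df.empty else pd.Series(dtype=float)
        counts[cond] = {c: int((col > c).sum()) for c in cutoffs}
    df.attrs["cutoff_counts"] = counts
    return df


def site_calls_to_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    """Flat per-site frame (one score/coverage column pair per sample)."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "gene_id": c.gene_id,
            "position": c.position,
            "context13": c.context13,
            "fisher_p": c.fisher_p,
            "replicate_support": c.replicate_support,
        }
        for s, v in c.scores.items():
            row[f"score_{s}"] = v
        for s, v in c.ag_coverage.items():
            row[f"cov_{s}"] = v
        for cond, v in c.median_scores.items():
            row[f"median_{cond}"] = v
        for cond, v in c.median_coverage.items():
            row[f"coverage_{cond}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
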