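"""Cross-species conservation of m6A-site sequence contexts.

Each site's 13-nt context is slid along the full sequence of a homologous
transcript; the window with the most matching nucleotides (best Hamming
score) is retained unless the best score is ambiguous (attained by more
than one window) or the Hamming distance exceeds a threshold (default 3).
Retained match vectors feed two per-position analyses: the proportion of
matches at each position against the pooled proportion at all other
positions, and the substitution rate split by reference base class
(C/G vs A/U) — both with Bonferroni correction over the 13 positions.
Matching is indel-free by construction; homologs with indels near the
site simply fail retention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

WINDOW = 13

__all__ = [
    "HomologMatch",
    "best_hamming_alignment",
    "scan_sites",
    "positional_conservation",
    "substitution_by_class",
]


@dataclass
class HomologMatch:
    """Best sliding-window match of one site context in one homolog."""

    site_id: str
    species: str
    best_offset: int
    hamming_distance: int
    match_vector: np.ndarray  # 13 booleans
    ambiguous: bool
    retained: bool


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def best_hamming_alignment(
    motif13: str,
    homolog_sequence: str,
    *,
    max_hamming: int = 3,
    site_id: str = "",
    species: str = "",
) -> HomologMatch | None:
    """Exhaustive sliding-window scan for the best Hamming match.

    Returns None when the homolog is shorter than the motif. The match is
    retained only if the best window is unique and its Hamming distance is
    at most ``max_hamming``; N positions in the motif never match.
    """
    motif = _normalize(motif13)
    if len(motif) != WINDOW:
        raise ValueError(f"motif must be {WINDOW} nt, got {len(motif)}")
    seq = _normalize(homolog_sequence)
    n = len(seq)
    if n < WINDOW:
        return None
    m = np.frombuffer(motif.encode(), dtype="S1")
    s = np.frombuffer(seq.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(s, WINDOW)
    match = windows == m[None, :]
    scores = match.sum(axis=1)
    best = int(scores.max())
    best_offsets = np.flatnonzero(scores == best)
    offset = int(best_offsets[0])
    vec = match[offset].copy()
    dist = WINDOW - best
    ambiguous = len(best_offsets) > 1
    return HomologMatch(
        site_id=site_id,
        species=species,
        best_offset=offset,
        hamming_distance=dist,
        match_vector=vec,
        ambiguous=ambiguous,
        retained=(not ambiguous) and dist <= max_hamming,
    )


def scan_sites(
    contexts: Mapping[str, str],
    homologs: Mapping[str, Mapping[str, str]],
    *,
    max_hamming: int = 3,
) -> list[HomologMatch]:
    """Scan every site context against every species.

    ``contexts`` maps site_id -> 13-nt motif; ``homologs`` maps species ->
    {site_id or gene_id -> homolog sequence}. When a species offers several
    transcripts for one site, the best retained match is kept.
    """
    out: list[HomologMatch] = []
    for species, seqs in homologs.items():
        for site_id, motif in contexts.items():
            key_matches = []
            gene = site_id.split(":")[0]
            for key, seq in seqs.items():
                if key not in (site_id, gene):
                    continue
                m = best_hamming_alignment(
                    motif, seq, max_hamming=max_hamming,
                    site_id=site_id, species=species,
                )
                if m is not None:
                    key_matches.append(m)
            if not key_matches:
                continue
            retained = [m for m in key_matches if m.retained]
            pool = retained or key_matches
            out.append(min(pool, key=lambda m: m.hamming_distance))
    return out


def _prop_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sample proportion test (chi-square with continuity correction,
    matching R's prop.test defaults)."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # degenerate margin: equal proportions carry no evidence of a
        # difference (e.g. both groups 100% matches); unequal ones are
        # untestable
        return 1.0 if x1 * n2 == x2 * n1 else float("nan")
    try:
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
    except ValueError:
        return float("nan")
    return float(p)


def positional_conservation(
    matches: Sequence[HomologMatch], *, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-position conservation of retained matches.

    For each motif position, the proportion of matches is tested against
    the pooled match proportion at the other 12 positions; p-values are
    Bonferroni-adjusted (x13, capped at 1). Offsets run -6..+6 with the
    methylated A at 0.
    """
    vecs = np.stack([m.match_vector for m in matches if m.retained])
    n = len(vecs)
    if n == 0:
        raise ValueError("no retained matches")
    col = vecs.sum(axis=0)
    total = int(col.sum())
    rows = []
    for i in range(WINDOW):
        x1, n1 = int(col[i]), n
        x2, n2 = total - x1, n * (WINDOW - 1)
        p = _prop_test(x1, n1, x2, n2)
        rows.append(
            {
                "offset": i - WINDOW // 2,
                "n": n,
                "match_proportion": x1 / n,
                "other_proportion": x2 / n2,
                "p": p,
                "p_bonferroni": min(1.0, WINDOW * p) if np.isfinite(p) else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    return df


def substitution_by_class(
    matches: Sequence[HomologMatch],
    reference_contexts: Mapping[str, str],
) -> pd.DataFrame:
    """Substitution proportions split by reference base class.

    At each motif position, the substitution (mismatch) fraction among
    sites whose reference base there is C or G is compared to the fraction
    among A/U sites with a two-sample proportion test, Bonferroni-adjusted.
    Positions where a class is empty report NaN for that class.
    """
    retained = [m for m in matches if m.retained]
    if not retained:
        raise ValueError("no retained matches")
    rows = []
    for i in range(WINDOW):
        sub = {True: [0, 0], False: [0, 0]}  # is_cg -> [mismatches, total]
        for m in retained:
            ref = _normalize(reference_contexts[m.site_id])
            b = ref[i]
            if b == "N":
                continue
            is_cg = b in "CG"
            sub[is_cg][1] += 1
            if not m.match_vector[i]:
                sub[is_cg][0] += 1
        (x_cg, n_cg), (x_au, n_au) = sub[True], sub[False]
        p = (
            _prop_test(x_cg, n_cg, x_au, n_au)
            if n_cg > 0 and n_au > 0
            else float("nan")
        )
        rows.append(
            {
                "offset": i - WINDOW // 2,
                "sub_rate_CG": x_cg / n_cg if n_cg else float("nan"),
                "sub_rate_AU": x_au / n_au if n_au else float("nan"),
                "n_CG": n_cg,
                "n_AU": n_au,
                "p": p,
                "p_bonferroni": min(1.0, WINDOW * p) if np.isfinite(p) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
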