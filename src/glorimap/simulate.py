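"""Synthetic GLORI data generation.

Emulates the statistical structure of a single-base m6A mapping experiment
in a low-GC transcriptome: random transcripts with exon-intron junctions
(EIJs), planted m6A sites obeying simple sequence rules (+1 C gives high
stoichiometry; +1 U together with +4 U gives moderate stoichiometry; any
other +1 base is incompatible with methylation), EIJ-proximal suppression
and a 3'-end placement bias, GLORI chemical conversion (unmethylated A read
as G, methylated A protected), homolog sequences with class-specific
substitution rates, differential-expression tables with an
expression-confounded m6A label, and gene sets with controlled overlap.

All generators are deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RNA_BASES = np.array(["A", "C", "G", "U"])

__all__ = [
    "SimParams",
    "TranscriptModel",
    "TrueSite",
    "ReadSet",
    "simulate_transcriptome",
    "plant_m6a_sites",
    "simulate_glori_reads",
    "deplete_sites",
    "simulate_homologs",
    "simulate_de_table",
    "simulate_coexpression_sets",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic GLORI experiment.

    Attributes
    ----------
    n_genes:
        Number of transcripts to simulate.
    length_range:
        Inclusive (min, max) transcript length in nt.
    gc_content:
        Target G+C fraction of simulated sequences (planarian-like default).
    exon_count_range:
        Inclusive (min, max) exons per transcript; k exons give k-1 EIJs.
    depth_mean:
        Mean number of reads per transcript per sample (Poisson).
    read_length:
        Read length in nt (reads are truncated at transcript ends).
    conversion_efficiency:
        Probability that an unmethylated A is read as G after treatment.
    stoich_high / stoich_mid:
        Beta(a, b) parameters for the stoichiometry of +1 C sites and of
        +1 U/+4 U sites respectively.
    site_rate:
        Mean fraction of rule-eligible A positions that carry a site.
    eij_exclusion_nt:
        No site is planted within this distance of an EIJ.
    three_prime_bias:
        Exponential weight favouring 3'-proximal site placement; 0 disables.
    n_replicates:
        Biological replicates per condition.
    seed:
        Master seed; fixed seed implies byte-identical outputs.
    """

    n_genes: int = 100
    length_range: tuple[int, int] = (800, 3000)
    gc_content: float = 0.32
    exon_count_range: tuple[int, int] = (1, 6)
    depth_mean: float = 100.0
    read_length: int = 150
    conversion_efficiency: float = 0.99
    stoich_high: tuple[float, float] = (20.0, 2.0)
    stoich_mid: tuple[float, float] = (6.0, 6.0)
    site_rate: float = 0.04
    eij_exclusion_nt: int = 100
    three_prime_bias: float = 2.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError(f"gc_content must be in [0,1], got {self.gc_content}")
        if not (0.0 <= self.conversion_efficiency <= 1.0):
            raise ValueError("conversion_efficiency must be in [0,1]")
        if not (0.0 <= self.site_rate <= 1.0):
            raise ValueError("site_rate must be in [0,1]")
        lo, hi = self.length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        elo, ehi = self.exon_count_range
        if elo < 1 or ehi < elo:
            raise ValueError(f"invalid exon_count_range {self.exon_count_range}")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TranscriptModel:
    """A transcript: the coordinate frame for all downstream analyses.

    ``eij_positions`` are 0-based transcript coordinates of exon-intron
    junctions; junction j lies between positions j-1 and j, so values are
    strictly inside (0, length).
    """

    gene_id: str
    sequence: str
    eij_positions: list[int] = field(default_factory=list)
    expression_weight: float = 1.0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        for j in self.eij_positions:
            if not (0 < j < self.length):
                raise ValueError(
                    f"{self.gene_id}: EIJ {j} outside (0, {self.length})"
                )
        self.eij_positions = sorted(self.eij_positions)


@dataclass(frozen=True)
class TrueSite:
    """Ground-truth methylation site planted by the simulator."""

    gene_id: str
    position: int
    stoichiometry: float
    rule_class: str  # "plus1C" | "plus1U_plus4U" | "none"


@dataclass
class ReadSet:
    """Reads in transcript coordinates, possibly spanning several samples.

    ``records`` columns: gene_id, start, seq, sample_id, molecule_id.
    """

    records: pd.DataFrame
    treated: bool = True

    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]

    def __len__(self) -> int:
        return len(self.records)


def simulate_transcriptome(params: SimParams) -> list[TranscriptModel]:
    """Draw ``params.n_genes`` random transcripts.

    Bases are i.i.d. with P(G)=P(C)=gc_content/2, so realised GC converges
    to the target for long transcripts. Exon boundaries are uniform distinct
    interior positions; expression weights are log-normal.
    """
    rng = params.rng(1)
    lo, hi = params.length_range
    elo, ehi = params.exon_count_range
    p = np.array(
        [
            (1 - params.gc_content) / 2,  # A
            params.gc_content / 2,  # C
            params.gc_content / 2,  # G
            (1 - params.gc_content) / 2,  # U
        ]
    )
    transcripts: list[TranscriptModel] = []
    width = max(4, len(str(params.n_genes)))
    for i in range(params.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(RNA_BASES, size=length, p=p))
        n_exons = int(rng.integers(elo, ehi + 1))
        if n_exons > 1:
            interior = rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)
            eij = sorted(int(j) for j in interior)
        else:
            eij = []
        weight = float(rng.lognormal(mean=0.0, sigma=0.8))
        transcripts.append(
            TranscriptModel(
                gene_id=f"g{i:0{width}d}",
                sequence=seq,
                eij_positions=eij,
                expression_weight=weight,
            )
        )
    return transcripts


def _eligible_positions(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """A positions satisfying a methylation-compatible rule.

    Returns (positions, is_plus1C) where non-plus1C entries are +1U/+4U.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(arr)
    is_a = arr == b"A"
    pos: list[int] = []
    high: list[bool] = []
    idx = np.flatnonzero(is_a)
    for i in idx:
        if i + 1 >= n:
            continue
        nxt = arr[i + 1]
        if nxt == b"C":
            pos.append(int(i))
            high.append(True)
        elif nxt == b"U" and i + 4 < n and arr[i + 4] == b"U":
            pos.append(int(i))
            high.append(False)
    return np.asarray(pos, dtype=int), np.asarray(high, dtype=bool)


def plant_m6a_sites(
    transcripts: Sequence[TranscriptModel], params: SimParams
) -> list[TrueSite]:
    """Plant methylation sites on rule-eligible adenosines.

    A candidate A must have +1 C (high-stoichiometry class) or +1 U with
    +4 U (moderate class), lie at least ``eij_exclusion_nt`` from every EIJ,
    and is selected with probability increasing toward the 3' end
    (exp(three_prime_bias * p/L), normalised to mean ``site_rate``).
    Stoichiometries are independent Beta draws; sites are uncoupled by
    construction.
    """
    rng = params.rng(2)
    a_hi, b_hi = params.stoich_high
    a_mid, b_mid = params.stoich_mid
    sites: list[TrueSite] = []
    for tr in transcripts:
        pos, is_high = _eligible_positions(tr.sequence)
        if len(pos) == 0:
            continue
        if tr.eij_positions:
            eij = np.asarray(tr.eij_positions)
            dist = np.min(np.abs(pos[:, None] - eij[None, :]), axis=1)
            keep = dist >= params.eij_exclusion_nt
            pos, is_high = pos[keep], is_high[keep]
        if len(pos) == 0:
            continue
        if params.three_prime_bias > 0:
            w = np.exp(params.three_prime_bias * pos / tr.length)
            prob = params.site_rate * w / w.mean()
        else:
            prob = np.full(len(pos), params.site_rate)
        prob = np.clip(prob, 0.0, 1.0)
        chosen = rng.random(len(pos)) < prob
        for p_, hi_ in zip(pos[chosen], is_high[chosen]):
            s = rng.beta(a_hi, b_hi) if hi_ else rng.beta(a_mid, b_mid)
            sites.append(
                TrueSite(
                    gene_id=tr.gene_id,
                    position=int(p_),
                    stoichiometry=float(s),
                    rule_class="plus1C" if hi_ else "plus1U_plus4U",
                )
            )
    return sites


def deplete_sites(sites: Iterable[TrueSite], factor: float) -> list[TrueSite]:
    """Scale stoichiometries by ``factor`` — a methylation-depleted condition
    (e.g. methyltransferase-complex knockdown)."""
    if not (0.0 <= factor <= 1.0):
        raise ValueError("depletion factor must be in [0,1]")
    return [replace(s, stoichiometry=s.stoichiometry * factor) for s in sites]


def simulate_glori_reads(
    transcripts: Sequence[TranscriptModel],
    sites: Sequence[TrueSite],
    params: SimParams,
    *,
    condition: str = "control",
    coupling: bool = False,
    with_untreated: bool = True,
    stream: int = 3,
) -> tuple[ReadSet, ReadSet | None]:
    """Simulate GLORI-treated reads (plus an untreated input library).

    Each read is one molecule. Per molecule, every site it covers is
    methylated with probability equal to its stoichiometry (independently
    across sites unless ``coupling``, which shares one latent uniform per
    molecule — a positive control for the linkage test). In treated reads a
    methylated A stays A and every other A becomes G with probability
    ``conversion_efficiency``; untreated reads are unconverted.

    Read depth per transcript is Poisson with mean proportional to
    ``expression_weight`` (normalised so the mean transcript gets
    ``depth_mean`` reads).
    """
    by_gene: dict[str, TranscriptModel] = {t.gene_id: t for t in transcripts}
    site_map: dict[str, list[TrueSite]] = {}
    for s in sites:
        tr = by_gene.get(s.gene_id)
        if tr is None:
            raise ValueError(f"site on unknown gene {s.gene_id}")
        if tr.sequence[s.position] != "A":
            raise ValueError(
                f"site {s.gene_id}:{s.position} reference base is not A"
            )
        site_map.setdefault(s.gene_id, []).append(s)

    rng = params.rng(stream)
    mean_w = float(np.mean([t.expression_weight for t in transcripts]))
    sample_ids = [f"{condition}_rep{r + 1}" for r in range(params.n_replicates)]

    treated_rows = []
    untreated_rows = []
    mol_counter = 0
    for tr in transcripts:
        seq_arr = np.frombuffer(tr.sequence.encode(), dtype="S1")
        a_pos = np.flatnonzero(seq_arr == b"A")
        g_sites = sorted(site_map.get(tr.gene_id, []), key=lambda s: s.position)
        s_pos = np.array([s.position for s in g_sites], dtype=int)
        s_stoich = np.array([s.stoichiometry for s in g_sites])
        lam = params.depth_mean * tr.expression_weight / mean_w
        max_start = max(0, tr.length - params.read_length)
        for sample_id in sample_ids:
            n_reads = int(rng.poisson(lam))
            if n_reads == 0:
                continue
            starts = rng.integers(0, max_start + 1, size=n_reads)
            for start in starts:
                end = min(start + params.read_length, tr.length)
                frag = seq_arr[start:end].copy()
                in_span = (s_pos >= start) & (s_pos < end)
                span_sites = s_pos[in_span]
                span_stoich = s_stoich[in_span]
                if coupling and len(span_sites):
                    u = rng.random()
                    methylated = u < span_stoich
                else:
                    methylated = rng.random(len(span_sites)) < span_stoich
                mol_id = f"m{mol_counter}"
                mol_counter += 1
                untreated_rows.append(
                    (tr.gene_id, int(start), frag.tobytes().decode(), sample_id, mol_id)
                )
                conv = frag.copy()
                span_a = a_pos[(a_pos >= start) & (a_pos < end)]
                unprotected = span_a[~np.isin(span_a, span_sites[methylated])]
                hit = rng.random(len(unprotected)) < params.conversion_efficiency
                conv[unprotected[hit] - start] = b"G"
                treated_rows.append(
                    (tr.gene_id, int(start), conv.tobytes().decode(), sample_id, mol_id)
                )

    cols = ["gene_id", "start", "seq", "sample_id", "molecule_id"]
    treated = ReadSet(pd.DataFrame(treated_rows, columns=cols), treated=True)
    untreated = None
    if with_untreated:
        df = pd.DataFrame(untreated_rows, columns=cols)
        df["sample_id"] = "input"
        untreated = ReadSet(df, treated=False)
    return treated, untreated


def simulate_homologs(
    transcripts: Sequence[TranscriptModel],
    sub_rate_AT: float,
    sub_rate_CG: float,
    seed: int,
    *,
    position_rates: Mapping[int, float] | None = None,
    site_positions: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, str]:
    """Mutate each transcript into an indel-free homolog.

    Each position substitutes independently: reference C/G at rate
    ``sub_rate_CG``, reference A/U at rate ``sub_rate_AT`` (to one of the
    other three bases, uniformly). ``position_rates`` optionally overrides
    the rate at fixed offsets relative to planted site positions (e.g.
    {+1: 0.3} elevates substitution immediately downstream of each site),
    mimicking locally elevated mutation rates.
    """
    for r in (sub_rate_AT, sub_rate_CG):
        if not (0.0 <= r < 1.0):
            raise ValueError("substitution rates must be in [0,1)")
    rng = np.random.default_rng([seed, 77])
    out: dict[str, str] = {}
    for tr in transcripts:
        arr = np.frombuffer(tr.sequence.encode(), dtype="S1").copy()
        is_cg = (arr == b"C") | (arr == b"G")
        rates = np.where(is_cg, sub_rate_CG, sub_rate_AT)
        if position_rates and site_positions:
            for p0 in site_positions.get(tr.gene_id, ()):
                for off, r in position_rates.items():
                    q = p0 + off
                    if 0 <= q < len(arr):
                        rates[q] = r
        hit = rng.random(len(arr)) < rates
        for i in np.flatnonzero(hit):
            base = arr[i].decode()
            alts = [b for b in "ACGU" if b != base]
            arr[i] = alts[int(rng.integers(0, 3))].encode()
        out[tr.gene_id] = arr.tobytes().decode()
    return out


def simulate_de_table(
    n_genes: int,
    frac_m6a: float,
    effect: float,
    seed: int,
    *,
    base_de_rate: float = 0.10,
    alpha: float = 0.05,
    missing_frac: float = 0.02,
) -> pd.DataFrame:
    """Differential-expression table with an expression-confounded m6A label.

    baseMean is log-normal. P(has_m6a) increases with expression rank — the
    detectability confound of coverage-limited site calling — and, after
    conditioning on expression, the probability of being differentially
    expressed differs between m6A and non-m6A genes by exactly ``effect``.
    Columns: gene, baseMean, log2FoldChange, padj, has_m6a.
    """
    if not (0.0 < frac_m6a < 1.0):
        raise ValueError("frac_m6a must be in (0,1)")
    rng = np.random.default_rng([seed, 11])
    base_mean = 10 ** rng.normal(2.6, 0.55, size=n_genes)
    rank = pd.Series(base_mean).rank(pct=True).to_numpy()
    p_m6a = np.clip(frac_m6a + 0.6 * (rank - 0.5), 0.02, 0.98)
    # re-centre so the marginal matches frac_m6a
    p_m6a *= frac_m6a / p_m6a.mean()
    p_m6a = np.clip(p_m6a, 0.0, 1.0)
    has_m6a = rng.random(n_genes) < p_m6a
    # DE probability depends on expression (confound) plus the planted effect
    p_de = np.clip(base_de_rate + 0.10 * (rank - 0.5) + effect * has_m6a, 0.0, 1.0)
    is_de = rng.random(n_genes) < p_de
    padj = np.where(
        is_de, rng.uniform(0.0, alpha, n_genes), rng.uniform(alpha, 1.0, n_genes)
    )
    lfc = rng.normal(0.0, 0.25, n_genes) + is_de * rng.choice(
        [-1.0, 1.0], n_genes
    ) * rng.uniform(0.5, 2.0, n_genes)
    padj = padj.astype(object)
    miss = rng.random(n_genes) < missing_frac
    padj[miss] = np.nan
    width = max(4, len(str(n_genes)))
    return pd.DataFrame(
        {
            "gene": [f"g{i:0{width}d}" for i in range(n_genes)],
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "padj": padj.astype(float),
            "has_m6a": has_m6a,
        }
    )


def simulate_coexpression_sets(
    universe_size: int,
    set_sizes: tuple[int, int],
    overlap: int,
    seed: int,
) -> tuple[list[str], set[str], set[str]]:
    """Gene universe plus two labelled sets sharing exactly ``overlap`` genes."""
    na, nb = set_sizes
    if overlap > min(na, nb):
        raise ValueError(f"overlap {overlap} exceeds min set size {min(na, nb)}")
    if na + nb - overlap > universe_size:
        raise ValueError("universe too small for requested sets")
    rng = np.random.default_rng([seed, 13])
    width = max(4, len(str(universe_size)))
    universe = [f"u{i:0{width}d}" for i in range(universe_size)]
    picks = rng.choice(universe_size, size=na + nb - overlap, replace=False)
    shared = picks[:overlap]
    only_a = picks[overlap : na]
    only_b = picks[na:]
    set_a = {universe[i] for i in np.concatenate([shared, only_a]).astype(int)}
    set_b = {universe[i] for i in np.concatenate([shared, only_b]).astype(int)}
    assert len(set_a & set_b) == overlap
    return universe, set_a, set_b
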