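"""Readers and writers for the pipeline's on-disk formats.

FASTA (DNA alphabet on disk, RNA in memory), exon BED (0-based half-open
intervals, one row per exon), site tables and read tables as TSV, and
reads from SAM (minus-strand alignments are reverse-complemented into
transcript sense before pileup). All coordinates are 0-based transcript
space.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .simulate import ReadSet, TranscriptModel, TrueSite

log = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_exon_bed",
    "write_exon_bed",
    "read_site_table",
    "write_site_table",
    "write_true_sites",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_reads_sam",
    "write_reads_sam",
    "table_header",
]


def table_header(config_hash: str | None = None) -> str:
    h = config_hash or "none"
    return f"# glorimap {__version__} config={h}\n"


def config_hash(obj: object) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: RNA sequence} (T converted to U on read)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write RNA sequences as DNA-alphabet FASTA (U emitted as T)."""
    records = [
        SeqRecord(Seq(seq.upper().replace("U", "T")), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_exon_bed(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """One BED row per exon: gene, start, end (0-based half-open)."""
    with open(path, "w") as fh:
        for tr in transcripts:
            bounds = [0] + list(tr.eij_positions) + [tr.length]
            for s, e in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{tr.gene_id}\t{s}\t{e}\n")


def read_exon_bed(path: str | Path) -> dict[str, list[int]]:
    """Exon BED -> {gene: sorted interior junction positions}."""
    edges: dict[str, set[int]] = {}
    spans: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected ≥3 BED columns")
            gene, s, e = parts[0], int(parts[1]), int(parts[2])
            edges.setdefault(gene, set()).update((s, e))
            spans[gene] = max(spans.get(gene, 0), e)
    return {
        g: sorted(x for x in es if 0 < x < spans[g]) for g, es in edges.items()
    }


def transcripts_from_files(
    fasta: str | Path, exon_bed: str | Path | None = None
) -> list[TranscriptModel]:
    seqs = read_fasta(fasta)
    eij = read_exon_bed(exon_bed) if exon_bed else {}
    return [
        TranscriptModel(gene_id=g, sequence=s, eij_positions=eij.get(g, []))
        for g, s in seqs.items()
    ]


def write_true_sites(sites: Iterable[TrueSite], path: str | Path) -> None:
    """BED-like 6-column truth table: gene, pos, pos+1, class, stoich, strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.position}\t{s.position + 1}\t"
                f"{s.rule_class}\t{s.stoichiometry:.6f}\t+\n"
            )


def write_site_table(
    sites: pd.DataFrame, path: str | Path, *, cfg_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(table_header(cfg_hash))
        sites.to_csv(fh, sep="\t", index=False)


def read_site_table(path: str | Path, *, one_based: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if one_based:
        df["position"] = df["position"] - 1
    return df


def write_reads_tsv(reads: ReadSet, path: str | Path) -> None:
    reads.records.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path, *, treated: bool = True) -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "seq": str})
    required = {"gene_id", "start", "seq", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "molecule_id" not in df:
        df["molecule_id"] = [f"m{i}" for i in range(len(df))]
    return ReadSet(df, treated=treated)


def read_reads_sam(path: str | Path, *, sample_id: str | None = None) -> ReadSet:
    """Reads from SAM/BAM in transcript coordinates.

    Unmapped, secondary and supplementary records are skipped; records
    aligned to the minus strand are reverse-complemented so the stored
    sequence is in transcript sense. Soft-clipped bases are trimmed via
    the aligned query sequence.
    """
    import pysam

    rows = []
    sid = sample_id or Path(path).stem
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_alignment_sequence
            if seq is None:
                continue
            if rec.is_reverse:
                seq = str(Seq(seq).reverse_complement())
            rows.append(
                (
                    rec.reference_name,
                    int(rec.reference_start),
                    seq.upper().replace("T", "U"),
                    sid,
                    rec.query_name or f"m{i}",
                )
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "start", "seq", "sample_id", "molecule_id"]
    )
    return ReadSet(df, treated=True)


def write_reads_sam(
    reads: ReadSet, transcripts: Sequence[TranscriptModel], path: str | Path
) -> None:
    """Write reads as plain-text SAM against the transcript 'reference'."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.gene_id, "LN": t.length} for t in transcripts],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in reads.records.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = str(row.molecule_id)
            a.query_sequence = row.seq.replace("U", "T")
            a.flag = 0
            a.reference_id = out.header.get_tid(row.gene_id)
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.cigarstring = f"{len(row.seq)}M"
            a.set_tag("RG", str(row.sample_id))
            out.write(a)
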