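"""Readers/writers for the tabular and sequence formats the pipeline consumes.

Coordinates are 0-based half-open internally; BLAST outfmt-6 columns
(1-based inclusive) and depth TSVs (1-based positions) are converted on
read. PAF is already 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .pangenome import AlignmentBlock, ContigRecord, PairwiseHit


def read_contig_fasta(path: str | Path) -> list[ContigRecord]:
    return [
        ContigRecord(rec.id, len(rec.seq), str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_contig_fasta(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            if c.sequence is None:
                raise ValueError(f"contig {c.id} has no sequence to write")
            fh.write(f">{c.id}\n{c.sequence}\n")


def read_blast6(path: str | Path) -> list[AlignmentBlock]:
    """BLAST outfmt-6 style: qseqid sseqid pident length qstart qend sstart send.

    pident is a percentage; query/subject coordinates are 1-based inclusive
    (subject start may exceed end on the minus strand — normalized on read).
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["qseqid", "sseqid", "pident", "length", "qstart", "qend",
               "sstart", "send"],
        usecols=range(8),
    )
    out = []
    for r in df.itertuples(index=False):
        ss, se = sorted((int(r.sstart), int(r.send)))
        out.append(
            AlignmentBlock(
                contig_id=str(r.qseqid),
                contig_start=int(r.qstart) - 1,
                contig_end=int(r.qend),
                ref_chrom=str(r.sseqid),
                ref_start=ss - 1,
                ref_end=se,
                identity=float(r.pident) / 100.0,
            )
        )
    return out


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Minimal PAF reader: identity = matching bases / alignment block length."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                continue
            matches, block = int(f[9]), int(f[10])
            out.append(
                AlignmentBlock(
                    contig_id=f[0],
                    contig_start=int(f[2]),
                    contig_end=int(f[3]),
                    ref_chrom=f[5],
                    ref_start=int(f[7]),
                    ref_end=int(f[8]),
                    identity=matches / block if block else 0.0,
                )
            )
    return out


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Native block TSV (header contig_id..identity, 0-based half-open,
    identity as a fraction) as written by the simulators."""
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentBlock(str(r.contig_id), int(r.contig_start), int(r.contig_end),
                       str(r.ref_chrom), int(r.ref_start), int(r.ref_end),
                       float(r.identity))
        for r in df.itertuples(index=False)
    ]


def read_alignment_table(path: str | Path) -> list[AlignmentBlock]:
    """Sniff the format: native block TSV (header), PAF (>= 12 columns,
    strand in column 5), else BLAST outfmt-6."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if first and first[0] == "contig_id":
        return read_alignment_blocks(path)
    if len(first) >= 12 and first[4] in "+-":
        return read_paf(path)
    return read_blast6(path)


def read_pairwise_hits(path: str | Path) -> list[PairwiseHit]:
    """TSV with columns query_id, subject_id, identity, query_start, query_end
    (0-based half-open query coordinates, identity as a fraction)."""
    df = pd.read_csv(path, sep="\t")
    return [
        PairwiseHit(str(r.query_id), str(r.subject_id), float(r.identity),
                    int(r.query_start), int(r.query_end))
        for r in df.itertuples(index=False)
    ]


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "label"],
                     skiprows=_has_header(path, "seq_id"))
    return dict(zip(df["seq_id"].astype(str), df["label"].astype(str)))


def read_group_map(path: str | Path) -> pd.Series:
    """Two-column TSV sample_id -> group/population label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     skiprows=_has_header(path, "sample_id"))
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].astype(str))


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column TSV sample_id -> numeric phenotype value."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "value"],
                     skiprows=_has_header(path, "sample_id"))
    return pd.Series(df["value"].astype(float).to_numpy(),
                     index=df["sample_id"].astype(str))


def read_score_track(path: str | Path) -> pd.DataFrame:
    """TSV chrom, 1-based pos, score (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "score"],
                     skiprows=_has_header(path, "chrom"))
    df["pos"] = df["pos"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def _has_header(path: str | Path, first_field: str) -> int:
    with open(path) as fh:
        head = fh.readline().split("\t")[0].strip()
    return 1 if head == first_field else 0
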