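"""Coverage-based gene presence/absence (PAV) calling.

A gene is called *present* in a sample when at least ``min_cov`` reads cover
at least a ``lost_cutoff`` fraction of the union of its exon bases
(defaults minCov = 2, lostCutoff = 0.2). The same criterion applies to
promoter windows (0-1, 1-2 and 2-3 kb upstream of the gene span,
strand-aware). Read depth per base is the depth proxy for read coverage.

Both thresholds are inclusive (>=): "at least 2 reads" and "at least 20%".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import merge_intervals

MIN_COV = 2
LOST_CUTOFF = 0.2


@dataclass
class GeneModel:
    """A gene with strand and normalized (sorted, merged) exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        self.exons = merge_intervals(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class DepthTrack:
    """Per-base read depth for one sample, dense per chromosome.

    Positions missing from an input file are depth 0; chromosomes missing
    entirely are all-zero.
    """

    sample_id: str
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.depths.get(chrom)
        if arr is None:
            return np.zeros(end - start, dtype=np.int32)
        out = np.zeros(end - start, dtype=arr.dtype)
        s, e = max(start, 0), min(end, arr.size)
        if s < e:
            out[s - start : e - start] = arr[s:e]
        return out

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_id: str | None = None,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> "DepthTrack":
        """Read a samtools-depth-like TSV: chrom, 1-based position, depth."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
        depths: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            n = (
                chrom_lengths[chrom]
                if chrom_lengths and chrom in chrom_lengths
                else int(sub["pos"].max())
            )
            arr = np.zeros(n, dtype=np.int32)
            arr[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
            depths[str(chrom)] = arr
        sid = sample_id if sample_id is not None else Path(path).stem
        return cls(sample_id=sid, depths=depths)

    def to_tsv(self, path: str | Path) -> None:
        """Write non-zero positions as chrom, 1-based position, depth."""
        with open(path, "w") as fh:
            for chrom in self.depths:
                arr = self.depths[chrom]
                nz = np.flatnonzero(arr)
                for p in nz:
                    fh.write(f"{chrom}\t{p + 1}\t{arr[p]}\n")


class PAVMatrix:
    """Binary genes x samples presence matrix with optional population labels."""

    def __init__(
        self,
        values: pd.DataFrame,
        populations: pd.Series | None = None,
    ) -> None:
        arr = values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("PAV matrix values must be 0/1")
        self.df = values.astype(np.uint8)
        self.df.index.name = "gene_id"
        if populations is not None:
            populations = populations.reindex(self.df.columns)
            if populations.isna().any():
                raise ValueError("population label missing for some samples")
        self.populations = populations

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of samples carrying each gene (k per gene)."""
        return self.df.sum(axis=1).astype(int)

    def frequencies(self) -> pd.Series:
        return self.presence_counts() / self.n_samples

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, populations: pd.Series | None = None
    ) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, populations)


def region_presence(
    track: DepthTrack,
    chrom: str,
    intervals: Sequence[tuple[int, int]],
    min_cov: int = MIN_COV,
    lost_cutoff: float = LOST_CUTOFF,
) -> bool:
    """Presence call for one interval union in one sample.

    Present iff the fraction of union bases with depth >= ``min_cov`` is
    >= ``lost_cutoff``.
    """
    if not intervals:
        raise ValueError("empty interval set")
    union = merge_intervals(intervals)
    total = sum(e - s for s, e in union)
    covered = 0
    for s, e in union:
        covered += int((track.depth(chrom, s, e) >= min_cov).sum())
    return covered / total >= lost_cutoff


def promoter_windows(
    gene: GeneModel,
    chrom_length: int | None = None,
    window: int = 1000,
    n_windows: int = 3,
) -> list[tuple[int, int]]:
    """Strand-aware upstream promoter windows (proximal to distal).

    Plus strand: ``[start-1kb, start)``, ``[start-2kb, start-1kb)``,
    ``[start-3kb, start-2kb)``; minus strand mirrored downstream of the span
    end. Windows are truncated at chromosome bounds; empty windows dropped.
    """
    start, end = gene.span
    out: list[tuple[int, int]] = []
    for i in range(n_windows):
        if gene.strand == "+":
            s, e = start - (i + 1) * window, start - i * window
        else:
            s, e = end + i * window, end + (i + 1) * window
        s = max(s, 0)
        if chrom_length is not None:
            e = min(e, chrom_length)
        if s < e:
            out.append((s, e))
    return out


def build_pav_matrix(
    gene_models: Sequence[GeneModel],
    tracks: Iterable[DepthTrack],
    min_cov: int = MIN_COV,
    lost_cutoff: float = LOST_CUTOFF,
    populations: pd.Series | None = None,
) -> PAVMatrix:
    """Call presence for every gene x sample.

    ``tracks`` may be a generator: each track is consumed once, so depth for
    large cohorts never needs to be resident all at once.
    """
    gene_ids = [g.gene_id for g in gene_models]
    columns: dict[str, np.ndarray] = {}
    for track in tracks:
        col = np.zeros(len(gene_models), dtype=np.uint8)
        for i, g in enumerate(gene_models):
            col[i] = region_presence(track, g.chrom, g.exons, min_cov, lost_cutoff)
        columns[track.sample_id] = col
    df = pd.DataFrame(columns, index=gene_ids)
    return PAVMatrix(df, populations)


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read exon records from BED6 (chrom, start, end, gene_id, score, strand)
    and group them into gene models."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes: list[GeneModel] = []
    for gid, sub in df.groupby("gene_id", sort=False):
        chroms = sub["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gid}: exons on multiple chromosomes")
        strands = sub["strand"].unique()
        if len(strands) > 1:
            raise ValueError(f"gene {gid}: inconsistent strand")
        exons = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        genes.append(GeneModel(gid, str(chroms[0]), str(strands[0]), exons))
    return genes


def write_gene_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t.\t{g.strand}\n")


def iter_tracks_from_dir(
    depth_dir: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> Iterator[DepthTrack]:
    """Yield one DepthTrack per ``*.depth.tsv`` / ``*.tsv`` file in a directory."""
    paths = sorted(Path(depth_dir).glob("*.tsv"))
    for p in paths:
        sid = p.name.removesuffix(".tsv").removesuffix(".depth")
        yield DepthTrack.from_tsv(p, sample_id=sid, chrom_lengths=chrom_lengths)
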