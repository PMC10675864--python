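"""Non-reference contig triage for pan-genome construction.

Contigs assembled from reads that fail to map to a reference are triaged
against precomputed reference-alignment records: short contigs are dropped,
contigs without a reliable alignment anchor are kept whole ("fully
unaligned"), anchored contigs contribute only their long unaligned tails
("partially unaligned"), the merged candidate set is de-duplicated at
90%-identity/90%-coverage, and sequences whose taxonomy assignment is
non-animal (archaea, viruses, bacteria, fungi, Viridiplantae) or generically
microbial are removed. Genes overlapping the retained non-reference regions
by more than 80% of their length are flagged as PAV genes.

All thresholds phrased as "larger than" / "over" / "more than" are strict
inequalities; "at least" is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import complement_intervals, merge_intervals, total_length

MIN_CONTIG_LEN = 500
MIN_ANCHOR_LEN = 300
MIN_ANCHOR_IDENTITY = 0.90
MIN_EXTRACT_LEN = 500
REDUNDANCY_IDENTITY = 0.90
REDUNDANCY_COVERAGE = 0.90
PAV_GENE_MIN_OVERLAP = 0.80

#: taxonomy labels whose sequences are treated as contamination
BANNED_TAXA = frozenset(
    {"archaea", "viruses", "bacteria", "fungi", "viridiplantae", "microbial"}
)


@dataclass(frozen=True)
class ContigRecord:
    """A candidate non-reference contig."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.id}: length != sequence length")


@dataclass(frozen=True)
class AlignmentBlock:
    """One contig-vs-reference alignment interval (0-based half-open)."""

    contig_id: str
    contig_start: int
    contig_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    identity: float

    def __post_init__(self) -> None:
        if self.contig_start >= self.contig_end:
            raise ValueError(f"{self.contig_id}: empty alignment block")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.contig_id}: identity outside [0, 1]")

    @property
    def contig_span(self) -> int:
        return self.contig_end - self.contig_start


@dataclass(frozen=True)
class PairwiseHit:
    """An all-vs-all hit used for redundancy removal (query coordinates)."""

    query_id: str
    subject_id: str
    identity: float
    query_start: int
    query_end: int


@dataclass(frozen=True)
class PavInterval:
    """A retained non-reference interval projected onto a genome."""

    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty PAV interval")


class ContigCategory(str, Enum):
    TOO_SHORT = "too_short"
    FULLY_ALIGNED = "fully_aligned"
    FULLY_UNALIGNED = "fully_unaligned"
    ANCHORED_TAIL = "anchored_tail"
    REDUNDANT = "redundant"
    CONTAMINANT = "contaminant"


def filter_short_contigs(
    contigs: Iterable[ContigRecord], min_len: int = MIN_CONTIG_LEN
) -> list[ContigRecord]:
    """Drop contigs shorter than ``min_len`` (length >= min_len retained)."""
    return [c for c in contigs if c.length >= min_len]


def find_reliable_regions(
    blocks: Iterable[AlignmentBlock],
    min_len: int = MIN_ANCHOR_LEN,
    min_identity: float = MIN_ANCHOR_IDENTITY,
) -> list[AlignmentBlock]:
    """Blocks strictly longer than ``min_len`` with identity strictly above
    ``min_identity`` — the "reliable alignment regions" that anchor a contig."""
    out = []
    for b in blocks:
        if b.contig_span > min_len and b.identity > min_identity:
            out.append(b)
    return out


def classify_contig(
    contig: ContigRecord, blocks: Sequence[AlignmentBlock], **kwargs
) -> str:
    """``"fully_unaligned"`` if no reliable block exists, else ``"anchored"``."""
    relevant = [b for b in blocks if b.contig_id == contig.id]
    return "anchored" if find_reliable_regions(relevant, **kwargs) else "fully_unaligned"


def extract_partial_unaligned(
    contig: ContigRecord,
    blocks: Sequence[AlignmentBlock],
    min_extract_len: int = MIN_EXTRACT_LEN,
    min_len: int = MIN_ANCHOR_LEN,
    min_identity: float = MIN_ANCHOR_IDENTITY,
) -> list[tuple[int, int]]:
    """Maximal contig intervals not covered by any reliable block, each
    strictly longer than ``min_extract_len``.

    The unaligned remainder of an anchored contig is the complement of its
    reliable blocks; low-identity alignment regions fall into the complement
    because they are never reliable.
    """
    relevant = [b for b in blocks if b.contig_id == contig.id]
    reliable = find_reliable_regions(relevant, min_len, min_identity)
    covered = [(b.contig_start, b.contig_end) for b in reliable]
    gaps = complement_intervals(contig.length, covered)
    return [(s, e) for s, e in gaps if (e - s) > min_extract_len]


def remove_redundancy(
    lengths: Mapping[str, int],
    hits: Iterable[PairwiseHit],
    min_identity: float = REDUNDANCY_IDENTITY,
    min_coverage: float = REDUNDANCY_COVERAGE,
) -> list[str]:
    """Greedy longest-first redundancy removal (CD-HIT convention).

    Candidates are visited by descending length, ties broken by
    lexicographic id. A candidate is discarded iff hits at identity >=
    ``min_identity`` to already-retained sequences cover >= ``min_coverage``
    of its length (union of hit intervals, no double counting). The retained
    set is returned in the input order of ``lengths``.
    """
    hit_list = list(hits)
    for h in hit_list:
        if h.query_id not in lengths:
            raise ValueError(f"hit references unknown query {h.query_id!r}")
        if h.subject_id not in lengths:
            raise ValueError(f"hit references unknown subject {h.subject_id!r}")

    by_query: dict[str, list[PairwiseHit]] = {}
    for h in hit_list:
        if h.identity >= min_identity and h.query_id != h.subject_id:
            by_query.setdefault(h.query_id, []).append(h)

    retained: set[str] = set()
    for sid in sorted(lengths, key=lambda s: (-lengths[s], s)):
        ivs = [
            (h.query_start, h.query_end)
            for h in by_query.get(sid, ())
            if h.subject_id in retained
        ]
        covered = total_length(ivs) if ivs else 0
        if covered < min_coverage * lengths[sid]:
            retained.add(sid)
    return [sid for sid in lengths if sid in retained]


def filter_contamination(
    seq_ids: Iterable[str],
    taxonomy: Mapping[str, str],
    banned: frozenset[str] = BANNED_TAXA,
) -> list[str]:
    """Drop sequences whose taxonomy label (case-insensitive) is banned;
    unlabeled sequences are kept."""
    banned_lc = {b.lower() for b in banned}
    return [
        sid
        for sid in seq_ids
        if taxonomy.get(sid, "").strip().lower() not in banned_lc
    ]


def flag_pav_genes(
    gene_intervals: Mapping[str, tuple[str, int, int]],
    pav_intervals: Iterable[PavInterval],
    min_overlap: float = PAV_GENE_MIN_OVERLAP,
) -> dict[str, bool]:
    """Flag genes with strictly more than ``min_overlap`` of their length
    inside PAV intervals.

    ``gene_intervals`` maps gene_id -> (chrom, start, end).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in pav_intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    unions = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}

    flags: dict[str, bool] = {}
    for gid, (chrom, start, end) in gene_intervals.items():
        if start >= end:
            raise ValueError(f"gene {gid}: empty interval")
        shared = 0
        for s, e in unions.get(chrom, ()):
            if s >= end:
                break
            shared += max(0, min(e, end) - max(s, start))
        flags[gid] = shared / (end - start) > min_overlap
    return flags


@dataclass
class TriageResult:
    """Per-contig disposition of the full triage pipeline."""

    categories: pd.DataFrame  # contig_id, category, retained (bool)
    retained_sequences: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    #: retained candidate id -> (source contig id, start, end on contig)


def triage_contigs(
    contigs: Sequence[ContigRecord],
    blocks: Sequence[AlignmentBlock],
    taxonomy: Mapping[str, str],
    self_hits: Sequence[PairwiseHit] = (),
    min_contig_len: int = MIN_CONTIG_LEN,
    anchor_len: int = MIN_ANCHOR_LEN,
    anchor_identity: float = MIN_ANCHOR_IDENTITY,
    extract_len: int = MIN_EXTRACT_LEN,
    redund_identity: float = REDUNDANCY_IDENTITY,
    redund_coverage: float = REDUNDANCY_COVERAGE,
) -> TriageResult:
    """Compose the full triage: length filter -> anchor classification ->
    partial extraction -> redundancy removal -> decontamination.

    Each input contig receives exactly one final category. Fully-unaligned
    contigs enter the candidate set whole; anchored contigs contribute their
    extracted tails (candidate ids ``{contig}|{start}-{end}``); candidates
    discarded by redundancy removal mark their source contig ``redundant``,
    and surviving candidates with a banned taxonomy label mark it
    ``contaminant``.
    """
    blocks_by_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        blocks_by_contig.setdefault(b.contig_id, []).append(b)

    category: dict[str, ContigCategory] = {}
    candidates: dict[str, tuple[str, int, int]] = {}  # cand id -> (contig, s, e)

    for c in contigs:
        if c.length < min_contig_len:
            category[c.id] = ContigCategory.TOO_SHORT
            continue
        cblocks = blocks_by_contig.get(c.id, [])
        status = classify_contig(
            c, cblocks, min_len=anchor_len, min_identity=anchor_identity
        )
        if status == "fully_unaligned":
            category[c.id] = ContigCategory.FULLY_UNALIGNED
            candidates[c.id] = (c.id, 0, c.length)
        else:
            tails = extract_partial_unaligned(
                c, cblocks, extract_len, anchor_len, anchor_identity
            )
            if tails:
                category[c.id] = ContigCategory.ANCHORED_TAIL
                for s, e in tails:
                    candidates[f"{c.id}|{s}-{e}"] = (c.id, s, e)
            else:
                category[c.id] = ContigCategory.FULLY_ALIGNED

    cand_lengths = {cid: e - s for cid, (_, s, e) in candidates.items()}
    usable_hits = [
        h for h in self_hits if h.query_id in cand_lengths and h.subject_id in cand_lengths
    ]
    kept = set(
        remove_redundancy(cand_lengths, usable_hits, redund_identity, redund_coverage)
    )
    for cid, (contig_id, _, _) in candidates.items():
        if cid not in kept:
            category[contig_id] = ContigCategory.REDUNDANT

    survivors = [cid for cid in candidates if cid in kept]
    source_tax = {cid: taxonomy.get(candidates[cid][0], "") for cid in survivors}
    clean = set(filter_contamination(survivors, source_tax))
    for cid in survivors:
        if cid not in clean:
            category[candidates[cid][0]] = ContigCategory.CONTAMINANT

    retained_final = {cid: candidates[cid] for cid in survivors if cid in clean}
    retained_contigs = {src for src, _, _ in retained_final.values()}
    df = pd.DataFrame(
        {
            "contig_id": [c.id for c in contigs],
            "category": [category[c.id].value for c in contigs],
            "retained": [c.id in retained_contigs for c in contigs],
        }
    )
    return TriageResult(categories=df, retained_sequences=retained_final)
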