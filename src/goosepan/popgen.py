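"""Population-genetic statistics and selection-window aggregation.

* Weir & Cockerham (1984) two-population Fst from unphased diploid
  genotypes: per-site variance components a (among populations),
  b (among individuals within populations), c (within individuals);
  per-site ratio a/(a+b+c) and the genome-wide weighted ratio
  sum(a)/sum(a+b+c). Missing genotypes are excluded per site; a site needs
  at least two genotyped individuals in each population.
* Windowed nucleotide diversity pi: per site the unbiased heterozygosity
  (n/(n-1)) * (1 - sum p_allele^2) over the n observed allele copies,
  summed per window and divided by the full window length.
* Selection-scan post-processing: per-position scores are averaged over
  non-overlapping 10-kb windows tiling each chromosome from position 1;
  windows in the top 5% of means carry "strong" signals; windows in the top
  20% that are adjacent or separated by a single window are merged into
  regions scored by the maximum member mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pav_call import GeneModel

WINDOW_SIZE = 10_000
STRONG_FRACTION = 0.05
MERGE_FRACTION = 0.20
MERGE_MAX_GAP = 1
GENE_FLANK = 5_000


@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples alt-allele dosages (-1 = missing)."""

    chrom: np.ndarray  # str per site
    pos: np.ndarray  # 1-based int per site
    gt: np.ndarray  # int8, sites x samples, values {0,1,2,-1}
    samples: list[str]
    populations: pd.Series | None = None  # sample id -> population label

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (self.pos.size, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.gt, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be dosages 0/1/2 or -1 missing")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(self.pos.size)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.gt = self.gt[order]
        if self.populations is not None:
            self.populations = self.populations.reindex(self.samples)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def sample_indices(self, population: str) -> np.ndarray:
        if self.populations is None:
            raise ValueError("no population labels attached")
        return np.flatnonzero((self.populations == population).to_numpy())

    def site_mask(self, chrom: str, start_pos: int, end_pos: int) -> np.ndarray:
        """Boolean mask of sites with 1-based position in [start_pos, end_pos]."""
        return (self.chrom == chrom) & (self.pos >= start_pos) & (self.pos <= end_pos)

    @classmethod
    def from_vcf(
        cls, path: str | Path, populations: pd.Series | None = None
    ) -> "GenotypeMatrix":
        """Read biallelic SNPs from a VCF (multi-allelic sites skipped)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        chroms, positions, rows = [], [], []
        for v in vcf:
            if len(v.ALT) != 1 or not v.is_snp:
                continue
            g = np.asarray(v.genotypes, dtype=np.int16)[:, :2]
            dos = np.where((g < 0).any(axis=1), -1, g.clip(min=0).sum(axis=1))
            chroms.append(v.CHROM)
            positions.append(v.POS)
            rows.append(dos.astype(np.int8))
        vcf.close()
        gt = (
            np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
        )
        return cls(np.array(chroms), np.array(positions, dtype=np.int64), gt,
                   samples, populations)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF v4.2 (REF=A, ALT=G placeholders, GT only)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in dict.fromkeys(self.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            code = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
            for i in range(self.n_sites):
                calls = "\t".join(code[int(d)] for d in self.gt[i])
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
                )


def _pop_site_stats(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped diploids, alt frequency, observed het frequency)."""
    called = gt >= 0
    n = called.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gt, 0).sum(axis=1) / (2.0 * n)
        h = (gt == 1).sum(axis=1) / n
    return n, p, h


def wc_fst(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    min_per_pop: int = 2,
) -> tuple[pd.DataFrame, float, float]:
    """Weir-Cockerham (1984) Fst between two populations.

    Returns (per-site table with components a, b, c and ratio; weighted Fst
    sum(a)/sum(a+b+c); mean of per-site ratios). Sites with fewer than
    ``min_per_pop`` genotyped individuals in either population, or
    monomorphic across both, contribute NaN per-site ratios and are excluded
    from both summaries.
    """
    if gm.populations is None:
        raise ValueError("population labels required")
    pops = [pop_a, pop_b]
    if len(set(pops)) < 2:
        raise ValueError("two distinct populations required")
    idx = [gm.sample_indices(p) for p in pops]
    for p, ix in zip(pops, idx):
        if ix.size == 0:
            raise ValueError(f"population {p!r} has no samples")

    r = 2
    stats_per_pop = [_pop_site_stats(gm.gt[:, ix]) for ix in idx]
    n_i = np.vstack([s[0] for s in stats_per_pop])  # r x sites
    p_i = np.vstack([s[1] for s in stats_per_pop])
    h_i = np.vstack([s[2] for s in stats_per_pop])

    valid = (n_i >= min_per_pop).all(axis=0)
    n_i = np.where(valid, n_i, np.nan)

    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / nsum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / nsum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        ratio = np.where(denom != 0, a / denom, np.nan)

    usable = valid & np.isfinite(denom) & (denom != 0)
    table = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos,
            "a": np.where(usable, a, np.nan),
            "b": np.where(usable, b, np.nan),
            "c": np.where(usable, c, np.nan),
            "fst": np.where(usable, ratio, np.nan),
        }
    )
    if usable.any():
        weighted = float(a[usable].sum() / denom[usable].sum())
        mean_site = float(np.nanmean(ratio[usable]))
    else:
        weighted = mean_site = float("nan")
    return table, weighted, mean_site


def windowed_pi(
    gm: GenotypeMatrix,
    window: int = WINDOW_SIZE,
    population: str | None = None,
) -> pd.DataFrame:
    """Per-window nucleotide diversity (per base).

    Site value: (n/(n-1)) * (1 - p^2 - q^2) over the n observed allele
    copies; window pi is the sum of site values divided by the full window
    length (windows with no genotyped sites are omitted).
    """
    if population is not None:
        gt = gm.gt[:, gm.sample_indices(population)]
    else:
        gt = gm.gt
    called = gt >= 0
    n = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gt, 0).sum(axis=1) / n
        site = np.where(n > 1, (n / (n - 1.0)) * (1.0 - p**2 - (1 - p) ** 2), np.nan)

    win_idx = (gm.pos - 1) // window + 1
    df = pd.DataFrame(
        {"chrom": gm.chrom, "window": win_idx, "site_pi": site}
    ).dropna(subset=["site_pi"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "window", "start", "end", "pi", "n_sites"])
    agg = df.groupby(["chrom", "window"], sort=True)["site_pi"].agg(["sum", "count"])
    out = agg.reset_index()
    out["start"] = (out["window"] - 1) * window + 1
    out["end"] = out["window"] * window
    out["pi"] = out["sum"] / window
    out = out.rename(columns={"count": "n_sites"})
    return out[["chrom", "window", "start", "end", "pi", "n_sites"]]


def window_mean_scores(
    scores: pd.DataFrame, window: int = WINDOW_SIZE
) -> pd.DataFrame:
    """Mean per-position selection score over non-overlapping windows.

    ``scores`` has columns chrom, pos (1-based), score. Windows tile each
    chromosome as [1, w], [w+1, 2w], ...; windows without scored positions
    are omitted. Output is sorted by chromosome then window index, invariant
    to input row order.
    """
    cols = ["chrom", "window", "start", "end", "mean_score", "n_sites"]
    if scores.empty:
        return pd.DataFrame(columns=cols)
    df = scores.copy()
    df["window"] = (df["pos"].astype(np.int64) - 1) // window + 1
    agg = df.groupby(["chrom", "window"], sort=True)["score"].agg(["mean", "count"])
    out = agg.reset_index().rename(columns={"mean": "mean_score", "count": "n_sites"})
    out["start"] = (out["window"] - 1) * window + 1
    out["end"] = out["window"] * window
    return out[cols]


def top_fraction_threshold(
    means: Sequence[float], fraction: float = STRONG_FRACTION
) -> tuple[float, np.ndarray]:
    """Order-statistic top-fraction cut: with m = ceil(fraction * count),
    the threshold is the m-th largest mean and every mean >= threshold is
    flagged (ties included, so >= m windows may be flagged)."""
    arr = np.asarray(means, dtype=float)
    if arr.size == 0:
        raise ValueError("no window means")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = math.ceil(fraction * arr.size)
    threshold = float(np.sort(arr)[::-1][m - 1])
    return threshold, arr >= threshold


@dataclass
class SelectionRegion:
    """A merged run of top-window indices on one chromosome."""

    chrom: str
    window_from: int
    window_to: int
    start: int  # 1-based inclusive
    end: int
    score: float  # max member window mean
    member_windows: list[int] = field(default_factory=list)
    strong: bool = False


def merge_top_windows(
    windows: pd.DataFrame,
    flagged: np.ndarray,
    max_gap: int = MERGE_MAX_GAP,
    strong: np.ndarray | None = None,
    window_size: int = WINDOW_SIZE,
) -> list[SelectionRegion]:
    """Merge flagged windows that are adjacent or separated by at most
    ``max_gap`` windows into regions scored by the maximum member mean.

    ``windows`` is the window_mean_scores table; ``flagged`` marks the
    top-20% set to merge and the optional ``strong`` marks top-5% windows —
    a region is strong iff it contains a strong member. Region spans cover
    the first to last member window, including bridged gaps.
    """
    regions: list[SelectionRegion] = []
    sub = windows.loc[np.asarray(flagged, dtype=bool)].sort_values(["chrom", "window"])
    strong_set = set()
    if strong is not None:
        sw = windows.loc[np.asarray(strong, dtype=bool)]
        strong_set = set(zip(sw["chrom"], sw["window"]))

    for chrom, grp in sub.groupby("chrom", sort=True):
        run: list[tuple[int, float]] = []
        for _, row in grp.iterrows():
            w, mean = int(row["window"]), float(row["mean_score"])
            if run and w - run[-1][0] > max_gap + 1:
                regions.append(_close_region(chrom, run, strong_set, window_size))
                run = []
            run.append((w, mean))
        if run:
            regions.append(_close_region(chrom, run, strong_set, window_size))
    return regions


def _close_region(
    chrom: str,
    run: list[tuple[int, float]],
    strong_set: set,
    window_size: int,
) -> SelectionRegion:
    members = [w for w, _ in run]
    return SelectionRegion(
        chrom=chrom,
        window_from=members[0],
        window_to=members[-1],
        start=(members[0] - 1) * window_size + 1,
        end=members[-1] * window_size,
        score=max(m for _, m in run),
        member_windows=members,
        strong=any((chrom, w) in strong_set for w in members),
    )


def select_sweep_regions(
    scores: pd.DataFrame,
    window: int = WINDOW_SIZE,
    strong_fraction: float = STRONG_FRACTION,
    merge_fraction: float = MERGE_FRACTION,
    max_gap: int = MERGE_MAX_GAP,
) -> tuple[pd.DataFrame, list[SelectionRegion]]:
    """Full window aggregation: window means, top-5% strong flags computed on
    the unmerged means, top-20% merging with gap bridging."""
    win = window_mean_scores(scores, window)
    if win.empty:
        return win, []
    means = win["mean_score"].to_numpy()
    _, strong = top_fraction_threshold(means, strong_fraction)
    _, merge_flags = top_fraction_threshold(means, merge_fraction)
    win = win.assign(strong=strong, top_merge=merge_flags)
    regions = merge_top_windows(win, merge_flags, max_gap, strong, window)
    return win, regions


def region_gene_flank_stats(
    regions: Sequence[SelectionRegion],
    genes: Sequence[GeneModel],
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    flank: int = GENE_FLANK,
) -> pd.DataFrame:
    """Weighted Fst over gene span +/- flank for genes overlapping a region.

    Gene spans are 0-based half-open; the flank window in 1-based site
    coordinates is [span_start + 1 - flank, span_end + flank]. Genes whose
    flank window contains no usable site get NaN Fst.
    """
    rows = []
    for g in genes:
        s, e = g.span
        hit = [
            r
            for r in regions
            if r.chrom == g.chrom and not (e < r.start - 1 + 1 or s + 1 > r.end)
        ]
        if not hit:
            continue
        lo, hi = max(1, s + 1 - flank), e + flank
        mask = gm.site_mask(g.chrom, lo, hi)
        if mask.any():
            sub = GenotypeMatrix(
                gm.chrom[mask], gm.pos[mask], gm.gt[mask], gm.samples, gm.populations
            )
            _, fst, _ = wc_fst(sub, pop_a, pop_b)
        else:
            fst = float("nan")
        rows.append(
            (g.gene_id, g.chrom, s, e, len(hit), any(r.strong for r in hit), fst)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "n_regions", "in_strong", "fst"],
    )
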