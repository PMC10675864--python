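"""Gene-region haplotype derivation and haplotype-phenotype association.

A candidate gene's haplotype region spans the gene plus 1 kb upstream and
500 bp downstream (strand-aware). Each sample's haplotype is the exact
vector of unphased genotype calls (alt-allele dosages) across the SNPs in
that region — no statistical phasing. Samples with any missing call are
excluded and reported. Haplotypes are ranked by descending carrier count
(ties by genotype string) and labeled Hap1, Hap2, ...

Association across haplotype groups uses the Kruskal-Wallis rank statistic.
For small cohorts (total qualifying n <= ``exact_limit``) the p-value is
exact, computed by enumerating every assignment of samples to the observed
group sizes; above that, the usual chi-square approximation applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .pav_call import GeneModel
from .popgen import GenotypeMatrix

UPSTREAM = 1_000
DOWNSTREAM = 500
EXACT_LIMIT = 12


def haplotype_region(
    gene: GeneModel,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """0-based half-open region: gene span extended ``up`` bases upstream of
    the transcription start and ``down`` bases downstream of the end,
    strand-aware, truncated at chromosome bounds."""
    s, e = gene.span
    if gene.strand == "+":
        lo, hi = s - up, e + down
    else:
        lo, hi = s - down, e + up
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


@dataclass
class HaplotypeAssignment:
    gene_id: str
    chrom: str
    region: tuple[int, int]  # 0-based half-open
    snp_positions: np.ndarray  # 1-based
    assignments: pd.Series  # sample -> haplotype id (excluded samples absent)
    table: pd.DataFrame  # haplotype_id, genotype_string, n
    excluded: list[str]  # samples with >= 1 missing call in the region


def call_haplotypes(
    gm: GenotypeMatrix,
    gene: GeneModel,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
    chrom_length: int | None = None,
) -> HaplotypeAssignment:
    """Enumerate genotype-string haplotypes over the SNPs in a gene region."""
    lo, hi = haplotype_region(gene, up, down, chrom_length)
    mask = gm.site_mask(gene.chrom, lo + 1, hi)
    if not mask.any():
        raise ValueError(
            f"no SNPs in region {gene.chrom}:{lo + 1}-{hi} of gene {gene.gene_id}"
        )
    sub = gm.gt[mask]  # sites x samples
    pos = gm.pos[mask]

    complete = (sub >= 0).all(axis=0)
    excluded = [s for s, ok in zip(gm.samples, complete) if not ok]
    kept = [s for s, ok in zip(gm.samples, complete) if ok]

    strings = ["/".join(map(str, sub[:, j])) for j in np.flatnonzero(complete)]
    counts: dict[str, int] = {}
    for g in strings:
        counts[g] = counts.get(g, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    hap_id = {g: f"Hap{i + 1}" for i, (g, _) in enumerate(ordered)}

    assignments = pd.Series(
        {s: hap_id[g] for s, g in zip(kept, strings)}, name="haplotype"
    )
    table = pd.DataFrame(
        [(hap_id[g], g, n) for g, n in ordered],
        columns=["haplotype_id", "genotype_string", "n"],
    )
    return HaplotypeAssignment(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        region=(lo, hi),
        snp_positions=pos,
        assignments=assignments,
        table=table,
        excluded=excluded,
    )


def _kw_statistic(values: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """Tie-corrected Kruskal-Wallis H for pre-assigned integer group labels."""
    n = values.size
    ranks = stats.rankdata(values)
    ssr = 0.0
    for g in range(n_groups):
        r = ranks[labels == g]
        ssr += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * ssr - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if tie_term == 0:
        return 0.0
    return h / tie_term


def _exact_kw_pvalue(groups: list[np.ndarray]) -> float:
    """Exact permutation p-value of the KW statistic: enumerate all ways to
    split the pooled sample into the observed group sizes."""
    values = np.concatenate(groups)
    sizes = [g.size for g in groups]
    labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    h_obs = _kw_statistic(values, labels, len(groups))

    n = values.size
    ge = 0
    total = 0
    # recursively choose index sets for each group from the remaining pool
    def recurse(remaining: tuple[int, ...], gi: int, assign: np.ndarray) -> None:
        nonlocal ge, total
        if gi == len(sizes) - 1:
            lab = assign.copy()
            lab[list(remaining)] = gi
            total += 1
            if _kw_statistic(values, lab, len(sizes)) >= h_obs - 1e-12:
                ge += 1
            return
        for combo in combinations(remaining, sizes[gi]):
            lab = assign.copy()
            lab[list(combo)] = gi
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, gi + 1, lab)

    recurse(tuple(range(n)), 0, np.full(n, -1))
    return ge / total


@dataclass
class HaplotypeTestResult:
    p: float  # NaN when no test was possible
    method: str  # "exact-permutation" | "chi-square" | "none"
    n_groups: int
    summaries: pd.DataFrame  # haplotype_id, n, mean, median, tested


def haplotype_phenotype_test(
    assignment: HaplotypeAssignment,
    phenotype: pd.Series,
    min_group: int = 2,
    exact_limit: int = EXACT_LIMIT,
) -> HaplotypeTestResult:
    """Kruskal-Wallis comparison of phenotype across haplotype groups.

    Only haplotypes carried by at least ``min_group`` samples enter the
    test; fewer than two qualifying groups yields a no-test sentinel
    (p = NaN). Per-haplotype n/mean/median summaries cover all haplotypes.
    """
    pheno = phenotype.reindex(assignment.assignments.index)
    if pheno.isna().any():
        raise ValueError("phenotype missing for assigned samples")
    by_hap = {
        hap: pheno[assignment.assignments == hap].to_numpy(dtype=float)
        for hap in assignment.table["haplotype_id"]
    }
    qualifying = [h for h, v in by_hap.items() if v.size >= min_group]

    summaries = pd.DataFrame(
        {
            "haplotype_id": list(by_hap),
            "n": [v.size for v in by_hap.values()],
            "mean": [float(np.mean(v)) if v.size else np.nan for v in by_hap.values()],
            "median": [
                float(np.median(v)) if v.size else np.nan for v in by_hap.values()
            ],
            "tested": [h in qualifying for h in by_hap],
        }
    )

    if len(qualifying) < 2:
        return HaplotypeTestResult(float("nan"), "none", len(qualifying), summaries)

    groups = [by_hap[h] for h in qualifying]
    total_n = sum(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        # all phenotype values identical: no rank variation, no evidence
        return HaplotypeTestResult(1.0, "degenerate", len(groups), summaries)
    if total_n <= exact_limit:
        p = _exact_kw_pvalue(groups)
        method = "exact-permutation"
    else:
        p = float(stats.kruskal(*groups)[1])
        method = "chi-square"
    return HaplotypeTestResult(p, method, len(groups), summaries)
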