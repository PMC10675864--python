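"""Pan-genome occupancy classification and saturation curves.

Genes are binned by the fraction of accessions carrying them:

* core      — present in all accessions (k = n)
* softcore  — 99% <= k/n < 100%
* shell     — 1% <= k/n < 99%
* cloud     — 0 < k/n < 1%

The published class bounds overlap at their edges; the partition above makes
the four classes disjoint while preserving "core = present in all". Genes
observed in no sample (k = 0) fall outside the pan-gene set and are labeled
``absent``. Boundary comparisons are exact integer arithmetic (100*k vs
99*n), never floating-point.

The saturation curve repeatedly subsamples accessions without replacement
and tracks the pan (present in >= 1 sampled accession) and core (present in
all sampled accessions) gene counts as functions of sample size.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pav_call import PAVMatrix

CATEGORIES = ("core", "softcore", "shell", "cloud")


def classify_gene(k: int, n: int) -> str:
    """Occupancy category for a gene present in ``k`` of ``n`` accessions."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if k == 0:
        return "absent"
    if k == n:
        return "core"
    if 100 * k >= 99 * n:
        return "softcore"
    if 100 * k >= n:
        return "shell"
    return "cloud"


def gene_categories(matrix: PAVMatrix) -> pd.DataFrame:
    """Per-gene table of presence count, sample count and category."""
    k = matrix.presence_counts()
    n = matrix.n_samples
    cat = [classify_gene(int(ki), n) for ki in k]
    return pd.DataFrame(
        {"k": k.astype(int), "n": n, "category": cat}, index=k.index
    ).rename_axis("gene_id")


def category_counts(matrix: PAVMatrix) -> dict[str, int]:
    """Counts per category over genes with k >= 1, plus their total.

    The four categories partition the observed pan-gene set, so the counts
    always sum to ``total`` (asserted).
    """
    cats = gene_categories(matrix)
    observed = cats[cats["category"] != "absent"]
    counts = {c: int((observed["category"] == c).sum()) for c in CATEGORIES}
    counts["total"] = len(observed)
    assert sum(counts[c] for c in CATEGORIES) == counts["total"]
    return counts


def core_fraction(counts: Mapping[str, int]) -> float:
    """Core genes as a percentage of the pan-gene total, one decimal."""
    total = counts.get("total", sum(counts[c] for c in CATEGORIES))
    if total <= 0:
        raise ValueError("empty pan-gene set")
    return round(100.0 * counts["core"] / total, 1)


def saturation_curve(
    matrix: PAVMatrix,
    sizes: Sequence[int] | None = None,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Pan/core gene counts under random subsampling of accessions.

    Subsampling is nested: each replicate draws one random permutation of
    the accessions and evaluates every size on its prefixes, so each prefix
    is a uniform without-replacement sample of that size and, within a
    replicate, pan is non-decreasing and core non-increasing in size by set
    monotonicity (hence so are the per-size means). Pan counts genes
    present in at least one drawn accession, core counts genes present in
    all of them. Returns long-form columns ``size, rep, pan, core``.
    """
    values = matrix.df.to_numpy()
    n = values.shape[1]
    if sizes is None:
        sizes = range(1, n + 1)
    sizes = list(sizes)
    if any(s < 1 or s > n for s in sizes):
        raise ValueError("subsample size outside [1, n_samples]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for rep in range(reps):
        perm = rng.permutation(n)
        cum = np.cumsum(values[:, perm], axis=1)
        for size in sizes:
            k = cum[:, size - 1]
            rows.append((size, rep, int((k >= 1).sum()), int((k == size).sum())))
    out = pd.DataFrame(rows, columns=["size", "rep", "pan", "core"])
    return out.sort_values(["size", "rep"], ignore_index=True)


def saturation_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean pan and core gene counts per subsample size."""
    return (
        curve.groupby("size")[["pan", "core"]].mean().rename(
            columns={"pan": "mean_pan", "core": "mean_core"}
        )
    ).reset_index()
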