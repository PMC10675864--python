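"""Gene-frequency differential analysis, enrichment, and PAV-phenotype association.

Group-versus-group gene frequencies are compared with a two-sided Fisher's
exact test on presence counts; p-values are Benjamini-Hochberg adjusted and
a gene is called differential when the adjusted p falls below the FDR
cutoff AND the frequency fold change strictly exceeds the fold cutoff
(defaults FDR < 0.001, fold > 2). Term enrichment of a hit set uses the
upper-tail hypergeometric test with BH adjustment. PAV-phenotype
association fits, per polymorphic gene, a covariate-adjusted linear model
of the phenotype on presence, with a Bonferroni threshold alpha / m over
the m genes actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pav_call import PAVMatrix


def fisher_two_sided(a: int, n_a: int, b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for presence counts a/n_a vs b/n_b.

    Minimum-likelihood definition: the sum of hypergeometric point
    probabilities not exceeding that of the observed table (relative
    tolerance 1e-7 on the comparison).
    """
    for v in (a, n_a, b, n_b):
        if v < 0:
            raise ValueError("negative count")
    if a > n_a or b > n_b:
        raise ValueError("presence count exceeds group size")
    table = [[a, n_a - a], [b, n_b - b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_gene_frequencies(
    matrix: PAVMatrix,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene Fisher comparison of presence frequencies between two groups.

    Genes absent in both groups are never tested (dropped from the table).
    ``groups`` maps sample id -> group label.
    """
    groups = groups.reindex(matrix.samples)
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must contain samples")

    values = matrix.df.to_numpy()
    count_a = values[:, in_a].sum(axis=1)
    count_b = values[:, in_b].sum(axis=1)
    testable = (count_a + count_b) > 0

    rows = []
    for gi in np.flatnonzero(testable):
        ca, cb = int(count_a[gi]), int(count_b[gi])
        p = fisher_two_sided(ca, n_a, cb, n_b)
        rows.append((matrix.genes[gi], ca, n_a, cb, n_b, ca / n_a, cb / n_b, p))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "count_a", "n_a", "count_b", "n_b", "freq_a", "freq_b", "p"],
    ).set_index("gene_id")
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def differential_genes(
    comparisons: pd.DataFrame,
    fdr: float = 0.001,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Apply the differential call: p_adj < fdr AND fold change > min_fold.

    Fold change is max(freq)/min(freq); one zero frequency with the other
    positive is treated as infinite fold (passes the gate). Direction is the
    sign of freq_a - freq_b.
    """
    df = comparisons.copy()
    fa, fb = df["freq_a"].to_numpy(), df["freq_b"].to_numpy()
    hi = np.maximum(fa, fb)
    lo = np.minimum(fa, fb)
    with np.errstate(divide="ignore"):
        fold = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    fold = np.where(hi == 0, np.nan, fold)  # absent in both: untestable
    df["fold_change"] = fold
    sig = (df["p_adj"].to_numpy() < fdr) & (fold > min_fold)
    call = np.where(~sig, "ns", np.where(fa > fb, "high_in_a", "low_in_a"))
    df["call"] = call
    return df


def hypergeom_enrichment(
    hits: set[str],
    gene_terms: pd.DataFrame,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment of a hit set.

    ``gene_terms`` has columns gene_id, term_id (optionally term_name).
    The universe defaults to all annotated genes; the hit set must be a
    subset of it. Per term with K annotated genes and x hits among n draws
    from a universe of N genes, p = P(X >= x); BH across terms; a term is
    significant when its adjusted p < alpha.
    """
    if universe is None:
        universe = set(gene_terms["gene_id"])
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hit set is not a subset of the universe")
    ann = gene_terms[gene_terms["gene_id"].isin(universe)]
    N, n = len(universe), len(hits)

    names = (
        ann.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in ann.columns
        else None
    )
    rows = []
    for term, sub in ann.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        x = len(members & hits)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        rows.append((term, K, x, p))
    df = pd.DataFrame(rows, columns=["term_id", "term_size", "hits", "p"]).set_index(
        "term_id"
    )
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["p_adj"] < alpha
    if names is not None:
        df.insert(0, "term_name", names.reindex(df.index))
    return df


@dataclass
class AssociationResult:
    table: pd.DataFrame  # per-gene beta, se, t, p, tested
    threshold: float  # alpha / number of genes tested
    n_tested: int


def pav_phenotype_assoc(
    matrix: PAVMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> AssociationResult:
    """Per-gene covariate-adjusted linear association of phenotype on presence.

    Monomorphic genes (present in none or all samples) are skipped with NaN
    p and do not count toward the Bonferroni denominator. The per-gene model
    is ``phenotype ~ intercept + covariates + presence``; the reported p is
    the two-sided t-test on the presence coefficient. Covariates are
    projected out of both phenotype and presence once (Frisch-Waugh), so the
    per-gene fit is a closed-form simple regression with the correct
    residual degrees of freedom.
    """
    y = phenotype.reindex(matrix.samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some samples")
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = covariates.reindex(matrix.samples).to_numpy(dtype=float)
        if np.isnan(C).any():
            raise ValueError("covariate missing for some samples")
        X = np.column_stack([X, C])
    q = X.shape[1]
    # residual-maker applied via least squares (stable for collinear covariates)
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ coef_y

    G = matrix.df.to_numpy(dtype=float)  # genes x samples
    k = G.sum(axis=1)
    poly = (k > 0) & (k < n)

    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough samples for the model")

    coef_g, *_ = np.linalg.lstsq(X, G.T, rcond=None)
    RG = G.T - X @ coef_g  # samples x genes, covariate-residualized presence

    sxx = (RG**2).sum(axis=0)
    sxy = RG.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = (ry**2).sum() - beta * sxy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)

    table = pd.DataFrame(
        {
            "k": k.astype(int),
            "beta": np.where(poly, beta, np.nan),
            "se": np.where(poly, se, np.nan),
            "t": np.where(poly, t, np.nan),
            "p": np.where(poly, p, np.nan),
            "tested": poly,
        },
        index=matrix.genes,
    ).rename_axis("gene_id")
    m = int(poly.sum())
    threshold = alpha / m if m else np.nan
    return AssociationResult(table=table, threshold=threshold, n_tested=m)
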