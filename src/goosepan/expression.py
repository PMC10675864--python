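"""Expression normalization, the TAU tissue-specificity index, and
crossing specificity with pan-genome occupancy.

TAU for a gene over n >= 2 group means x_1..x_n:

    tau = n/(n-1) - sum(x_i) / ((n-1) * max(x_i))

which is 0 for perfectly uniform expression and 1 for expression confined
to a single group. Group means are computed on library-size-normalized
values (CPM by default; FPKM supported when gene lengths are given).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TAU_THRESHOLD = 0.8


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size (column sum)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib < 0).any():
        raise ValueError("negative counts")
    lib = lib.replace(0, np.nan)
    return (counts * 1e6).div(lib, axis=1).fillna(0.0)


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (library * length)."""
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    lib = counts.sum(axis=0).astype(float).replace(0, np.nan)
    return (counts * 1e9).div(lib, axis=1).div(lengths, axis=0).fillna(0.0)


def tau(group_means) -> float:
    """Tissue-specificity index of one gene's group-mean vector.

    Returns NaN (undefined) when every group mean is zero.
    """
    x = np.asarray(group_means, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("tau needs at least two groups")
    if (x < 0).any():
        raise ValueError("group means must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return n / (n - 1) - x.sum() / ((n - 1) * m)


def group_means(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mean expression per gene per group (columns ordered by first
    appearance of each group among the samples)."""
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("group label missing for some samples")
    order = list(dict.fromkeys(groups))
    means = values.T.groupby(groups).mean().T
    return means[order]


def tau_table(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TAU, argmax group and max mean from a gene x group table.

    Argmax ties are resolved by the first group in column order and flagged.
    """
    arr = means.to_numpy(dtype=float)
    n = means.shape[1]
    mx = arr.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = n / (n - 1) - arr.sum(axis=1) / ((n - 1) * mx)
    t = np.where(mx > 0, t, np.nan)
    top_idx = arr.argmax(axis=1)
    tie = (arr == mx[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "tau": t,
            "group": np.asarray(means.columns)[top_idx],
            "max_mean": mx,
            "ambiguous_group": tie,
        },
        index=means.index,
    ).rename_axis("gene_id")


def specific_genes(
    taus: pd.DataFrame, threshold: float = TAU_THRESHOLD
) -> pd.DataFrame:
    """Genes with TAU >= threshold, keeping their assigned (argmax) group."""
    return taus[taus["tau"] >= threshold].copy()


def pav_expression_cross(
    specific: pd.DataFrame,
    categories: pd.Series,
    frequencies: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross tissue-specific genes with pan-genome occupancy.

    Returns (per-group category proportions summing to 1 across the four
    occupancy classes; per-group presence-frequency summary with median).
    ``categories`` maps gene_id -> occupancy class, ``frequencies`` maps
    gene_id -> presence frequency k/n.
    """
    from .pav_classify import CATEGORIES

    df = specific.copy()
    df["category"] = categories.reindex(df.index)
    df["frequency"] = frequencies.reindex(df.index)
    if df["category"].isna().any():
        raise ValueError("occupancy category missing for some specific genes")

    prop_rows = []
    freq_rows = []
    for grp, sub in df.groupby("group", sort=True):
        counts = sub["category"].value_counts()
        total = counts.sum()
        props = [counts.get(c, 0) / total for c in CATEGORIES]
        prop_rows.append([grp, total, *props])
        f = sub["frequency"].dropna()
        freq_rows.append(
            [grp, len(f), float(f.median()) if len(f) else np.nan,
             float(f.mean()) if len(f) else np.nan]
        )
    props = pd.DataFrame(
        prop_rows, columns=["group", "n_genes", *CATEGORIES]
    ).set_index("group")
    freqs = pd.DataFrame(
        freq_rows, columns=["group", "n_genes", "median_frequency", "mean_frequency"]
    ).set_index("group")
    return props, freqs
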