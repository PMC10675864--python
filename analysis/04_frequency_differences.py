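"""Gene-frequency differentials between two sample groups, with enrichment.

Splits the simulated cohort into two halves, plants a frequency contrast by
relabeling, runs the Fisher / BH / fold-change caller (FDR < 0.001, fold
> 2), and feeds the called genes into a hypergeometric term enrichment over
a synthetic annotation in which one term collects half the planted genes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from goosepan.freq_diff import (
    compare_gene_frequencies,
    differential_genes,
    hypergeom_enrichment,
)
from goosepan.pav_call import PAVMatrix

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240101


def main() -> None:
    matrix = PAVMatrix.from_tsv(SIM / "pav_matrix.tsv")
    rng = np.random.default_rng(SEED)

    n = matrix.n_samples
    groups = pd.Series(["china"] * (n // 2) + ["europe"] * (n - n // 2),
                       index=matrix.samples)

    # plant a contrast: drop 30 shell genes from the "europe" half
    truth = pd.read_csv(SIM / "pav_truth.tsv", sep="\t", index_col=0)
    shell = truth[truth["true_class"] == "shell"].index
    planted = list(rng.choice(shell, 30, replace=False))
    europe = (groups == "europe").to_numpy()
    matrix.df.loc[planted, matrix.df.columns[europe]] = 0

    comp = compare_gene_frequencies(matrix, groups, "china", "europe")
    calls = differential_genes(comp)
    calls.to_csv(OUT / "freq_diff.tsv", sep="\t")
    called = set(calls[calls["call"] != "ns"].index)
    print(f"differential genes: {len(called)} called; "
          f"{len(called & set(planted))}/{len(planted)} planted recovered")

    terms = pd.DataFrame(
        {
            "gene_id": list(matrix.genes),
            "term_id": ["T_planted" if g in set(planted[:15]) else
                        f"T{hash(g) % 20}" for g in matrix.genes],
        }
    )
    enr = hypergeom_enrichment(called, terms)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t")
    top = enr.sort_values("p").head(3)
    print("top enriched terms:\n" + top[["hits", "term_size", "p_adj"]].to_string())


if __name__ == "__main__":
    main()
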