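"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/sim/: a 200-sample x 1,000-gene PAV matrix drawn from
the observed occupancy spectrum (with truth), Balding-Nichols genotypes for
two 50-sample populations at F = 0.2, a quantitative phenotype with one
planted causal PAV gene, an expression count matrix with planted
tissue-specific genes, the 60-contig triage scenario, and a selection-score
track with three planted sweep windows.
"""

from pathlib import Path

from goosepan.simulate import (
    SimConfig,
    simulate_contig_scenario,
    simulate_expression,
    simulate_genotypes_bn,
    simulate_pav_population,
    simulate_phenotype,
    simulate_selection_scores,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20240101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=SEED)
    matrix, truth = simulate_pav_population(cfg)
    matrix.to_tsv(OUT / "pav_matrix.tsv")
    truth.to_csv(OUT / "pav_truth.tsv", sep="\t")
    print(f"PAV matrix: {len(matrix.genes)} genes x {matrix.n_samples} samples")

    causal = truth[truth["true_class"] == "shell"].index[0]
    pheno = simulate_phenotype(matrix, [causal], cfg)
    pheno.rename_axis("sample_id").to_csv(OUT / "phenotype.tsv", sep="\t")
    (OUT / "causal_gene.txt").write_text(causal + "\n")
    print(f"phenotype written; planted causal gene {causal}")

    geno_cfg = SimConfig(seed=SEED, n_samples=100, n_sites=5000, fst_target=0.2)
    gm = simulate_genotypes_bn(geno_cfg)
    gm.to_vcf(OUT / "genotypes.vcf")
    gm.populations.rename("group").rename_axis("sample_id").to_csv(
        OUT / "popmap.tsv", sep="\t"
    )
    print(f"genotypes: {gm.n_sites} sites, populations "
          f"{gm.populations.value_counts().to_dict()}")

    expr_cfg = SimConfig(seed=SEED, n_genes=1000, n_groups=9, specific_fold=50.0)
    counts, labels, expr_truth = simulate_expression(expr_cfg)
    counts.to_csv(OUT / "expression_counts.tsv", sep="\t", index_label="gene_id")
    labels.rename("group").rename_axis("sample_id").to_csv(
        OUT / "expression_groups.tsv", sep="\t"
    )
    expr_truth.to_csv(OUT / "expression_truth.tsv", sep="\t")
    print(f"expression: {counts.shape[0]} genes x {counts.shape[1]} samples, "
          f"{int(expr_truth['planted_specific'].sum())} planted specific genes")

    scenario = simulate_contig_scenario(SimConfig(seed=SEED))
    scenario.write(OUT / "contigs")
    print(f"contig scenario: {len(scenario.contigs)} contigs")

    track = simulate_selection_scores(1_000_000, [10, 40, 70], SimConfig(seed=SEED))
    track.to_csv(OUT / "selection_scores.tsv", sep="\t", index=False)
    print("selection scores: planted sweep windows 10, 40, 70")


if __name__ == "__main__":
    main()
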