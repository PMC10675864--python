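"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:
a two-class (or four-class) gene-frequency spectrum over samples, Poisson
read depth with presence/absence structure, Balding-Nichols population
differentiation at a target F, planted sweep windows on an exponential
score background, planted causal presence effects on a quantitative
phenotype, planted tissue-specific expression, and a hand-constructed
contig-triage scenario.

All randomness flows from the single integer seed in :class:`SimConfig`;
each generator derives its own independent stream deterministically, so a
fixed seed gives byte-identical outputs per generator regardless of the
order generators are invoked in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .pangenome import AlignmentBlock, ContigRecord, PairwiseHit
from .pav_call import DepthTrack, GeneModel, PAVMatrix

#: default occupancy spectrum mirroring the observed goose pan-genome mix
#: (75.9% core, 6.5% softcore, 13.3% shell, 4.3% cloud)
DEFAULT_CLASS_SPEC: tuple[tuple[str, float, float], ...] = (
    ("core", 0.759, 1.0),
    ("softcore", 0.065, 0.995),
    ("shell", 0.133, 0.5),
    ("cloud", 0.043, 0.005),
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs shared by all generators.

    ``class_spec`` lists (occupancy class, fraction of genes, presence
    frequency); the fractions must sum to 1. ``noise_depth_fraction`` is the
    fraction of exon bases of an *absent* gene that still receive depth >=
    minCov (kept below lostCutoff so truth stays recoverable).
    """

    seed: int = 0
    n_samples: int = 200
    n_genes: int = 1000
    class_spec: tuple[tuple[str, float, float], ...] = DEFAULT_CLASS_SPEC
    mean_depth: float = 10.0
    noise_depth_fraction: float = 0.05
    fst_target: float = 0.2
    n_sites: int = 5000
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_groups: int = 9
    specific_fold: float = 50.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_sites <= 0:
            raise ValueError("counts must be positive")
        if self.n_groups <= 0:
            raise ValueError("n_groups must be positive")
        total = sum(f for _, f, _ in self.class_spec)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_spec fractions sum to {total}, not 1")
        for name, frac, freq in self.class_spec:
            if frac < 0 or not 0 <= freq <= 1:
                raise ValueError(f"invalid class spec entry {name!r}")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0 <= self.noise_depth_fraction < 1:
            raise ValueError("noise_depth_fraction must be in [0, 1)")
        if self.mean_depth < 0 or self.noise_sd < 0 or self.specific_fold <= 0:
            raise ValueError("invalid rate/scale parameter")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, deterministic generator for a named stream."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        )


# ---------------------------------------------------------------------------
# PAV population


def simulate_pav_population(cfg: SimConfig) -> tuple[PAVMatrix, pd.DataFrame]:
    """Draw a genes x samples presence matrix from the class spectrum.

    Genes are assigned to classes by the spec fractions (largest-remainder
    apportionment, in spec order); each sample's presence is an independent
    Bernoulli draw at the class presence frequency. The truth table records
    the intended class and nominal frequency per gene.
    """
    rng = cfg.rng("pav_population")
    counts = _apportion(cfg.n_genes, [f for _, f, _ in cfg.class_spec])
    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    classes: list[str] = []
    freqs: list[float] = []
    for (name, _, freq), cnt in zip(cfg.class_spec, counts):
        classes += [name] * cnt
        freqs += [freq] * cnt

    prob = np.array(freqs)[:, None]
    values = (rng.random((cfg.n_genes, cfg.n_samples)) < prob).astype(np.uint8)
    samples = [f"s{j + 1:04d}" for j in range(cfg.n_samples)]
    matrix = PAVMatrix(pd.DataFrame(values, index=gene_ids, columns=samples))
    truth = pd.DataFrame(
        {"true_class": classes, "true_frequency": freqs}, index=gene_ids
    ).rename_axis("gene_id")
    return matrix, truth


def _apportion(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` into the fractions."""
    raw = [total * f for f in fractions]
    base = [int(x) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# gene models & depth tracks


def simulate_gene_models(
    n_genes: int,
    n_exons: int = 2,
    exon_len: int = 150,
    intron_len: int = 100,
    spacing: int = 200,
    chrom: str = "chr1",
) -> list[GeneModel]:
    """Lay ``n_genes`` uniform multi-exon genes along one chromosome."""
    genes = []
    cursor = spacing
    for i in range(n_genes):
        exons = []
        for _ in range(n_exons):
            exons.append((cursor, cursor + exon_len))
            cursor += exon_len + intron_len
        cursor += spacing - intron_len
        genes.append(GeneModel(f"g{i + 1:05d}", chrom, "+", exons))
    return genes


def chromosome_lengths(genes: Sequence[GeneModel], margin: int = 1000) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in genes:
        out[g.chrom] = max(out.get(g.chrom, 0), g.span[1] + margin)
    return out


def simulate_depth_tracks(
    matrix: PAVMatrix,
    genes: Sequence[GeneModel],
    cfg: SimConfig,
    min_cov: int = 2,
    hard_mode: bool = False,
) -> Iterator[DepthTrack]:
    """Yield one DepthTrack per sample consistent with the truth matrix.

    Present genes receive per-base Poisson(mean_depth) over their exons;
    absent genes are depth 0 except a ``noise_depth_fraction`` of exon bases
    which receive Poisson(mean_depth) draws floored at ``min_cov``. In
    ``hard_mode`` the per-gene noise fraction is drawn uniformly from
    [0, 2 * lostCutoff), straddling the caller's decision boundary.
    """
    gene_index = {g.gene_id: g for g in genes}
    missing = [gid for gid in matrix.genes if gid not in gene_index]
    if missing:
        raise ValueError(f"genes without exon models: {missing[:3]}...")
    lengths = chromosome_lengths(genes)
    positions = {
        g.gene_id: np.concatenate([np.arange(s, e) for s, e in g.exons])
        for g in genes
    }
    rng = cfg.rng("depth_tracks")
    values = matrix.df.to_numpy()
    for j, sample in enumerate(matrix.samples):
        depths = {c: np.zeros(n, dtype=np.int32) for c, n in lengths.items()}
        for i, gid in enumerate(matrix.genes):
            g = gene_index[gid]
            pos = positions[gid]
            if values[i, j]:
                depths[g.chrom][pos] = rng.poisson(cfg.mean_depth, pos.size)
            else:
                frac = (
                    rng.uniform(0, 0.4) if hard_mode else cfg.noise_depth_fraction
                )
                n_noise = int(round(frac * pos.size))
                if n_noise:
                    chosen = rng.choice(pos, size=n_noise, replace=False)
                    depths[g.chrom][chosen] = np.maximum(
                        rng.poisson(cfg.mean_depth, n_noise), min_cov
                    )
        yield DepthTrack(sample_id=sample, depths=depths)


# ---------------------------------------------------------------------------
# genotypes (Balding-Nichols)


def simulate_genotypes_bn(
    cfg: SimConfig,
    pop_sizes: Sequence[int] | None = None,
    pop_names: Sequence[str] = ("popA", "popB"),
    position_step: int = 100,
    chrom: str = "chr1",
) -> "GenotypeMatrix":
    """Two-population Balding-Nichols genotypes at the target F.

    Per site the ancestral frequency is uniform on [0.1, 0.9]; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) for F > 0 (equal
    to p at F = 0) and genotypes are Binomial(2, population frequency).
    """
    from .popgen import GenotypeMatrix

    if len(pop_names) < 2:
        raise ValueError("at least two populations required")
    if pop_sizes is None:
        half = cfg.n_samples // 2
        pop_sizes = [half, cfg.n_samples - half]
    if len(pop_sizes) != len(pop_names):
        raise ValueError("pop_sizes and pop_names length mismatch")

    rng = cfg.rng("genotypes_bn")
    F = cfg.fst_target
    p = rng.uniform(0.1, 0.9, cfg.n_sites)
    cols = []
    labels = []
    samples = []
    for name, size in zip(pop_names, pop_sizes):
        if F > 0:
            q = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        else:
            q = p
        cols.append(rng.binomial(2, q[:, None], (cfg.n_sites, size)))
        labels += [name] * size
        samples += [f"{name}_{i + 1:03d}" for i in range(size)]
    gt = np.concatenate(cols, axis=1).astype(np.int8)
    pos = np.arange(1, cfg.n_sites + 1, dtype=np.int64) * position_step
    return GenotypeMatrix(
        chrom=np.full(cfg.n_sites, chrom),
        pos=pos,
        gt=gt,
        samples=samples,
        populations=pd.Series(labels, index=samples),
    )


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(
    matrix: PAVMatrix,
    causal: dict[str, float] | Sequence[str],
    cfg: SimConfig,
) -> pd.Series:
    """Additive phenotype: sum of effect * presence plus Gaussian noise.

    ``causal`` is either a mapping gene -> effect size or a list of genes
    all receiving ``cfg.effect_size``.
    """
    if not isinstance(causal, dict):
        causal = {g: cfg.effect_size for g in causal}
    missing = [g for g in causal if g not in matrix.df.index]
    if missing:
        raise ValueError(f"causal genes absent from matrix: {missing}")
    rng = cfg.rng("phenotype")
    y = np.zeros(matrix.n_samples)
    for gene, eff in causal.items():
        y = y + eff * matrix.df.loc[gene].to_numpy(dtype=float)
    y = y + rng.normal(0.0, cfg.noise_sd, matrix.n_samples)
    return pd.Series(y, index=matrix.samples, name="phenotype")


def simulate_phenotype_from_groups(
    groups: pd.Series, effects: dict[str, float], cfg: SimConfig
) -> pd.Series:
    """Phenotype from categorical (e.g. haplotype) group membership."""
    missing = set(groups.unique()) - set(effects)
    if missing:
        raise ValueError(f"groups without an effect: {sorted(missing)}")
    rng = cfg.rng("phenotype_groups")
    y = groups.map(effects).to_numpy(dtype=float)
    y = y + rng.normal(0.0, cfg.noise_sd, y.size)
    return pd.Series(y, index=groups.index, name="phenotype")


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimConfig,
    reps_per_group: int = 3,
    specific_fraction: float = 0.05,
    base_mean: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Counts with planted single-group-specific genes.

    Per gene a lognormal baseline mean is shared across groups; a
    ``specific_fraction`` of genes (assigned round-robin to groups) have
    their mean multiplied by ``specific_fold`` in exactly one group. Counts
    are Poisson. Returns (counts genes x samples, sample -> group labels,
    truth with planted flag and planted group).
    """
    rng = cfg.rng("expression")
    n_genes = cfg.n_genes
    groups = [f"organ{k + 1}" for k in range(cfg.n_groups)]
    samples = [f"{g}_r{r + 1}" for g in groups for r in range(reps_per_group)]
    labels = pd.Series(
        [g for g in groups for _ in range(reps_per_group)], index=samples
    )

    base = base_mean * rng.lognormal(0.0, 1.0, n_genes)
    n_specific = int(round(specific_fraction * n_genes))
    specific_idx = rng.choice(n_genes, size=n_specific, replace=False)
    planted_group = {
        int(gi): groups[k % len(groups)] for k, gi in enumerate(specific_idx)
    }

    means = np.tile(base[:, None], (1, len(samples)))
    for gi, grp in planted_group.items():
        means[gi, (labels == grp).to_numpy()] *= cfg.specific_fold
    counts = rng.poisson(means)

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = pd.DataFrame(
        {
            "planted_specific": [i in planted_group for i in range(n_genes)],
            "planted_group": [planted_group.get(i, "") for i in range(n_genes)],
        },
        index=gene_ids,
    ).rename_axis("gene_id")
    return df, labels, truth


# ---------------------------------------------------------------------------
# contig triage scenario


@dataclass
class ContigScenario:
    contigs: list[ContigRecord]
    blocks: list[AlignmentBlock]
    self_hits: list[PairwiseHit]
    taxonomy: dict[str, str]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)  # contig_id, category

    def write(self, outdir) -> None:
        """Write FASTA + alignment/hit/taxonomy/truth TSVs."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "contigs.fa", "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.id}\n{c.sequence}\n")
        pd.DataFrame(
            [
                (b.contig_id, b.contig_start, b.contig_end, b.ref_chrom,
                 b.ref_start, b.ref_end, b.identity)
                for b in self.blocks
            ],
            columns=["contig_id", "contig_start", "contig_end", "ref_chrom",
                     "ref_start", "ref_end", "identity"],
        ).to_csv(outdir / "ref_alignments.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (h.query_id, h.subject_id, h.identity, h.query_start, h.query_end)
                for h in self.self_hits
            ],
            columns=["query_id", "subject_id", "identity", "query_start", "query_end"],
        ).to_csv(outdir / "self_hits.tsv", sep="\t", index=False)
        pd.Series(self.taxonomy, name="label").rename_axis("seq_id").to_csv(
            outdir / "taxonomy.tsv", sep="\t"
        )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_contig_scenario(cfg: SimConfig) -> ContigScenario:
    """A 60-contig scenario exercising every triage category.

    8 too-short, 10 fully aligned, 16 fully unaligned (6 of which are the
    retained partners of duplicates), 10 anchored with an extractable tail,
    6 redundant duplicates, 10 contaminant-labelled. Categories are forced
    by construction, so the triage pipeline must reproduce them exactly.
    """
    rng = cfg.rng("contig_scenario")

    def seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), n))

    contigs: list[ContigRecord] = []
    blocks: list[AlignmentBlock] = []
    hits: list[PairwiseHit] = []
    taxonomy: dict[str, str] = {}
    truth_rows: list[tuple[str, str]] = []

    def add(cid: str, s: str, category: str) -> ContigRecord:
        c = ContigRecord(cid, len(s), s)
        contigs.append(c)
        truth_rows.append((cid, category))
        return c

    for i in range(8):
        add(f"short{i + 1:02d}", seq(450), "too_short")

    for i in range(10):
        cid = f"aligned{i + 1:02d}"
        add(cid, seq(2000), "fully_aligned")
        blocks.append(AlignmentBlock(cid, 0, 2000, "chrR", 1_000_000 + 3000 * i,
                                     1_002_000 + 3000 * i, 0.97))

    # fully unaligned: no blocks, or blocks failing one reliability axis
    for i in range(10):
        cid = f"unaligned{i + 1:02d}"
        add(cid, seq(2000), "fully_unaligned")
        if i % 3 == 1:  # long enough but identity too low
            blocks.append(AlignmentBlock(cid, 0, 400, "chrR", 2_000_000 + 3000 * i,
                                         2_000_400 + 3000 * i, 0.85))
        elif i % 3 == 2:  # identity fine but block too short
            blocks.append(AlignmentBlock(cid, 0, 250, "chrR", 2_500_000 + 3000 * i,
                                         2_500_250 + 3000 * i, 0.95))

    # duplicate pairs: partner retained (earlier id, same length), dup dropped
    for i in range(6):
        partner = f"upartner{i + 1:02d}"
        dup = f"zdup{i + 1:02d}"
        s = seq(2000)
        add(partner, s, "fully_unaligned")
        add(dup, s, "redundant")
        hits.append(PairwiseHit(dup, partner, 1.0, 0, 2000))
        hits.append(PairwiseHit(partner, dup, 1.0, 0, 2000))

    for i in range(10):
        cid = f"anchored{i + 1:02d}"
        add(cid, seq(2500), "anchored_tail")
        blocks.append(AlignmentBlock(cid, 0, 800, "chrR", 3_000_000 + 4000 * i,
                                     3_000_800 + 4000 * i, 0.96))

    banned = ["bacteria", "viruses", "fungi", "archaea", "Viridiplantae"]
    for i in range(10):
        cid = f"contam{i + 1:02d}"
        add(cid, seq(1500), "contaminant")
        taxonomy[cid] = banned[i % len(banned)]

    # a couple of harmless labels on retained contigs
    taxonomy["unaligned01"] = "Metazoa"
    taxonomy["anchored01"] = "Aves"

    truth = pd.DataFrame(truth_rows, columns=["contig_id", "category"])
    return ContigScenario(contigs, blocks, hits, taxonomy, truth)


# ---------------------------------------------------------------------------
# selection scores


def simulate_selection_scores(
    chrom_length: int,
    planted_windows: Sequence[int],
    cfg: SimConfig,
    shift: float = 20.0,
    step: int = 100,
    window: int = 10_000,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Per-position score track: Exponential(1) background, planted 10-kb
    windows (1-based indices) shifted upward by ``shift``."""
    rng = cfg.rng("selection_scores")
    pos = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    score = rng.exponential(1.0, pos.size)
    win_idx = (pos - 1) // window + 1
    for w in planted_windows:
        score[win_idx == w] += shift
    return pd.DataFrame({"chrom": chrom, "pos": pos, "score": score})
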