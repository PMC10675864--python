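import numpy as np
import pandas as pd
import pytest

from goosepan.pav_call import DepthTrack, GeneModel, PAVMatrix
from goosepan.popgen import GenotypeMatrix


@pytest.fixture
def toy_matrix() -> PAVMatrix:
    """5 genes x 4 samples with one gene per occupancy situation."""
    df = pd.DataFrame(
        {
            "s1": [1, 1, 1, 0, 0],
            "s2": [1, 1, 0, 0, 0],
            "s3": [1, 1, 1, 1, 0],
            "s4": [1, 0, 0, 0, 0],
        },
        index=["core1", "g2", "g3", "g4", "never"],
    )
    return PAVMatrix(df)


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("geneP", "chr1", "+", [(10_000, 10_800), (11_200, 12_000)])


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("geneM", "chr1", "-", [(10_000, 10_800), (11_200, 12_000)])


def make_track(sample_id: str, chrom: str, length: int, depth_at: dict) -> DepthTrack:
    """Dense track with depth_at mapping (start, end) -> depth value."""
    arr = np.zeros(length, dtype=np.int32)
    for (s, e), d in depth_at.items():
        arr[s:e] = d
    return DepthTrack(sample_id=sample_id, depths={chrom: arr})


def make_genotypes(gt_rows, positions=None, chrom="chr1", pops=None) -> GenotypeMatrix:
    """GenotypeMatrix from a list of per-site dosage lists."""
    gt = np.asarray(gt_rows, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = [f"s{i + 1}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    populations = None
    if pops is not None:
        populations = pd.Series(list(pops), index=samples)
    return GenotypeMatrix(
        np.full(n_sites, chrom), np.asarray(positions), gt, samples, populations
    )
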