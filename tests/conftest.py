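"""Shared fixtures: tiny hand-built panels and generated test data."""

import numpy as np
import pytest

from breedtrace import GenotypeMatrix, Sample, SnpRecord
from breedtrace.genotype_io import MISSING
from breedtrace.synthetic import make_admixture_test_panel


def random_genotype_matrix(
    n: int, m: int, seed: int = 0, missing_rate: float = 0.1
) -> GenotypeMatrix:
    """Unstructured random panel for I/O and bookkeeping tests."""
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, m)) < missing_rate] = MISSING
    alleles = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    snps = [
        SnpRecord(
            snp_id=f"rs{j}",
            chromosome=int(j % 18) + 1,
            position_bp=1000 * (j + 1),
            allele_a=alleles[j % 4][0],
            allele_b=alleles[j % 4][1],
        )
        for j in range(m)
    ]
    samples = [
        Sample(sample_id=f"ind{i}", breed=f"breed{i % 3}") for i in range(n)
    ]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


@pytest.fixture
def random_panel() -> GenotypeMatrix:
    return random_genotype_matrix(20, 50, seed=42)


@pytest.fixture
def qc_fixture() -> GenotypeMatrix:
    """5 x 20 panel with hand-placed missingness.

    Sample s0 misses 3/20 cells (15% > 10% -> removed); after its removal
    SNP rs5 misses 1/4 of the remaining cells (25% > 5% -> removed), so
    QC must yield a 4 x 19 matrix.
    """
    g = random_genotype_matrix(5, 20, seed=7, missing_rate=0.0)
    calls = g.calls.copy()
    calls[0, [0, 1, 2]] = MISSING
    calls[1, 5] = MISSING
    return GenotypeMatrix(samples=g.samples, snps=g.snps, calls=calls)


@pytest.fixture(scope="session")
def standard_panel():
    """The K=3 recovery panel (3 x 60 pure + 30 admixed, m=2000, Fst 0.2)."""
    return make_admixture_test_panel(seed=1, n_snps=2000)


@pytest.fixture(scope="session")
def small_structured_panel():
    """Smaller version of the K=3 panel for fast unit tests."""
    return make_admixture_test_panel(
        seed=3, n_snps=500, n_per_pure=30, n_admixed=15
    )


def weir_cockerham_fst(calls: np.ndarray, pops) -> float:
    """Weir & Cockerham (1984) theta-hat, ratio of summed variance
    components over loci.  Independent oracle for the simulator's FST.
    """
    pops = np.asarray(pops)
    labs = np.unique(pops)
    r = len(labs)
    n_i = np.array([(pops == lab).sum() for lab in labs], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for j in range(calls.shape[1]):
        g = calls[:, j].astype(float)
        p_i = np.array([g[pops == lab].mean() / 2 for lab in labs])
        h_i = np.array([(g[pops == lab] == 1).mean() for lab in labs])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum / (a_sum + b_sum + c_sum)
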