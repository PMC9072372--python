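"""Synthetic genotype panels with known ancestry ground truth.

The generative model is Balding-Nichols: a shared ancestral allele
frequency per SNP, population frequencies Beta-dispersed around it with
spread set by a per-population FST, individual ancestry vectors drawn
from a Dirichlet around each breed's ancestry profile, and genotypes
Binomial(2, q_i . f_j).  This is the canonical likelihood-compatible
stand-in for a structured livestock panel: a couple of dozen breeds of
~50 animals each, most nearly pure, a few deliberately admixed, and a
diffuse outgroup playing the wild-boar role.

It deliberately omits linkage disequilibrium, pedigree structure and
selection; see docs/methods.md for what that implies for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Sample, SnpRecord

#: concentration value treated as "deterministic": Q_true rows equal the
#: breed profile exactly instead of being Dirichlet-sampled around it.
DETERMINISTIC = float("inf")


@dataclass(frozen=True)
class BreedSpec:
    """One labeled group: its size and its ancestry make-up."""

    name: str
    n_individuals: int
    ancestry_profile: tuple[float, ...]
    concentration: float = DETERMINISTIC

    def __post_init__(self) -> None:
        prof = np.asarray(self.ancestry_profile, dtype=float)
        if abs(prof.sum() - 1.0) > 1e-9:
            raise ValueError(f"breed {self.name}: ancestry_profile must sum to 1")
        if (prof < 0).any():
            raise ValueError(f"breed {self.name}: negative ancestry weight")
        if not self.concentration > 0:
            raise ValueError(f"breed {self.name}: concentration must be positive")
        if self.n_individuals < 1:
            raise ValueError(f"breed {self.name}: n_individuals must be >= 1")


@dataclass
class SimulationConfig:
    """Full description of one simulated panel."""

    n_ancestral_pops: int
    breeds: list[BreedSpec]
    n_snps: int
    fst_per_pop: tuple[float, ...] | float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        K = self.n_ancestral_pops
        if K < 1:
            raise ValueError("need at least one ancestral population")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if np.isscalar(self.fst_per_pop):
            self.fst_per_pop = (float(self.fst_per_pop),) * K
        self.fst_per_pop = tuple(float(f) for f in self.fst_per_pop)
        if len(self.fst_per_pop) != K:
            raise ValueError("fst_per_pop length must equal n_ancestral_pops")
        if not all(0 < f < 1 for f in self.fst_per_pop):
            raise ValueError("fst values must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        for b in self.breeds:
            if len(b.ancestry_profile) != K:
                raise ValueError(f"breed {b.name}: profile length != K")


@dataclass
class GroundTruth:
    """True ancestry proportions and population allele frequencies.

    Comparable to estimates only up to a permutation of the K components.
    """

    Q_true: np.ndarray  # n x K, rows sum to 1
    F_true: np.ndarray  # K x m, in [0, 1]
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def q_to_dataframe(self) -> pd.DataFrame:
        K = self.Q_true.shape[1]
        df = pd.DataFrame(self.Q_true, columns=[f"k{k + 1}" for k in range(K)])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def f_to_dataframe(self) -> pd.DataFrame:
        K = self.F_true.shape[0]
        df = pd.DataFrame(self.F_true.T, columns=[f"k{k + 1}" for k in range(K)])
        df.insert(0, "snp_id", self.snp_ids)
        return df


def simulate_panel(cfg: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw one genotype panel under the Balding-Nichols admixture model.

    Fully reproducible from ``cfg.seed``: one explicit RNG stream, no
    global state.
    """
    rng = np.random.default_rng(cfg.seed)
    K, m = cfg.n_ancestral_pops, cfg.n_snps
    n = sum(b.n_individuals for b in cfg.breeds)
    if n == 0:
        raise ValueError("no individuals to simulate")

    p = rng.uniform(*cfg.ancestral_maf_range, size=m)
    F = np.empty((K, m))
    for k, fst in enumerate(cfg.fst_per_pop):
        ratio = (1.0 - fst) / fst
        F[k] = rng.beta(p * ratio, (1.0 - p) * ratio)
    F = np.clip(F, 1e-12, 1.0 - 1e-12)

    Q = np.empty((n, K))
    samples: list[Sample] = []
    row = 0
    for b in cfg.breeds:
        prof = np.asarray(b.ancestry_profile, dtype=float)
        nb = b.n_individuals
        if np.isinf(b.concentration):
            Q[row : row + nb] = prof
        else:
            # Dirichlet over the support of the profile only: zero-weight
            # components stay exactly zero.
            support = prof > 0
            alpha = b.concentration * prof[support]
            draws = rng.dirichlet(alpha, size=nb)
            block = np.zeros((nb, K))
            block[:, support] = draws
            Q[row : row + nb] = block
        for i in range(nb):
            samples.append(Sample(sample_id=f"{b.name}_{i + 1}", breed=b.name))
        row += nb

    dose = Q @ F  # n x m expected allele-b frequency per individual
    calls = rng.binomial(2, dose).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = MISSING

    snps = [
        SnpRecord(
            snp_id=f"snp{j + 1}",
            chromosome=int(j % 18) + 1,
            position_bp=(j // 18 + 1) * 1000,
            allele_a="A",
            allele_b="G",
        )
        for j in range(m)
    ]
    g = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    truth = GroundTruth(
        Q_true=Q, F_true=F, sample_ids=g.sample_ids, snp_ids=g.snp_ids
    )
    return g, truth


def make_admixture_test_panel(
    seed: int = 0,
    n_snps: int = 2000,
    fst: float = 0.2,
    n_per_pure: int = 60,
    n_admixed: int = 30,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Three pure source breeds plus one evenly admixed group.

    The standard K=3 recovery panel: 3 x ``n_per_pure`` individuals with
    deterministic one-hot ancestry and ``n_admixed`` individuals centred
    on (1/3, 1/3, 1/3).
    """
    breeds = [
        BreedSpec("pureA", n_per_pure, (1.0, 0.0, 0.0)),
        BreedSpec("pureB", n_per_pure, (0.0, 1.0, 0.0)),
        BreedSpec("pureC", n_per_pure, (0.0, 0.0, 1.0)),
        BreedSpec("mixABC", n_admixed, (1 / 3, 1 / 3, 1 / 3), concentration=30.0),
    ]
    cfg = SimulationConfig(
        n_ancestral_pops=3,
        breeds=breeds,
        n_snps=n_snps,
        fst_per_pop=fst,
        missing_rate=missing_rate,
        seed=seed,
    )
    return simulate_panel(cfg)


def make_study_panel(
    seed: int = 0, n_snps: int = 2000, n_per_breed: int = 50
) -> tuple[GenotypeMatrix, GroundTruth]:
    """A 24-group panel emulating the structure of the real pig study.

    24 labeled groups of ~50 animals (~1,200 total): 20 near-pure
    "indigenous" breeds each dominated by its own ancestral component,
    three mosaic breeds mixing several ancestries (the Nero Siciliano /
    Sarda / Moravka pattern), and one diffuse outgroup standing in for
    the multi-country wild-boar sample.  K = 21 ancestral components:
    one per pure breed plus one for the outgroup; mosaics own no
    component of their own.
    """
    K = 21
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB12EED]))
    breeds: list[BreedSpec] = []
    for k in range(20):
        prof = np.zeros(K)
        prof[k] = 1.0
        breeds.append(
            BreedSpec(f"breed{k + 1:02d}", n_per_breed, tuple(prof), concentration=200.0)
        )
    # three mosaic breeds: each mixes 4 pure ancestries plus the outgroup
    for mname in ("mosaic1", "mosaic2", "mosaic3"):
        prof = np.zeros(K)
        donors = rng.choice(20, size=4, replace=False)
        w = rng.dirichlet(np.full(4, 5.0))
        prof[donors] = 0.85 * w
        prof[20] = 0.15
        prof /= prof.sum()
        breeds.append(BreedSpec(mname, n_per_breed, tuple(prof), concentration=15.0))
    # diffuse outgroup (wild-boar role): own component plus a smear of others
    prof = np.full(K, 0.3 / 20)
    prof[20] = 0.7
    breeds.append(BreedSpec("outgroup", n_per_breed, tuple(prof), concentration=8.0))

    fst = tuple(0.12 + 0.06 * (k % 3) for k in range(20)) + (0.25,)
    cfg = SimulationConfig(
        n_ancestral_pops=K,
        breeds=breeds,
        n_snps=n_snps,
        fst_per_pop=fst,
        missing_rate=0.01,
        seed=int(rng.integers(2**31)),
    )
    return simulate_panel(cfg)
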