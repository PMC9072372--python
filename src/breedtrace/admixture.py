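"""Maximum-likelihood admixture: ancestry proportions and ancestral
allele frequencies under the binomial mixture model.

Individual ``i``'s genotype at SNP ``j`` is modelled as
``Binomial(2, a_ij)`` with ``a_ij = sum_k q_ik f_kj``: ``Q`` (n x K) holds
ancestry proportions on the simplex, ``F`` (K x m) the allele-B
frequencies of the K ancestral populations.  Estimation is plain EM
(FRAPPE-style multiplicative updates), which shares its stationary
points with the quasi-Newton-accelerated reference tool but is simpler
to verify: the log-likelihood is non-decreasing at every step and all
constraints are preserved by construction.

The binomial coefficient term is constant in (Q, F) and is omitted from
all log-likelihood values.  Missing genotype cells are dropped from the
likelihood and from both EM sums.

The number of ancestral populations K is chosen by masked-cell
cross-validation: observed cells are split into folds, each fold in turn
is hidden, the model refit, and the binomial deviance of the hidden
cells under the refit model is the CV error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_io import GenotypeMatrix

_F_EPS = 1e-8      # F clipped to [eps, 1-eps]
_A_EPS = 1e-12     # dose clipped away from {0,1} inside logs


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                 # n x K, rows on the simplex
    F: np.ndarray                 # K x m, in [eps, 1-eps]
    loglik_trace: np.ndarray      # one entry per iteration, first = at init
    converged: bool
    n_iterations: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def q_to_dataframe(self, sample_ids, breeds=None) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"k{k + 1}" for k in range(self.K)])
        df.insert(0, "sample_id", list(sample_ids))
        if breeds is not None:
            df.insert(1, "breed", list(breeds))
        return df


@dataclass
class KSelectionCurve:
    ks: list[int]
    cv_errors: list[float]

    @property
    def chosen_k(self) -> int:
        errs = np.asarray(self.cv_errors)
        return self.ks[int(np.argmin(errs))]  # argmin takes the first = smallest K

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.ks, "cv_error": self.cv_errors})


@dataclass
class BreedAncestrySummary:
    """Mean ancestry proportions per breed (rows sum to 1)."""

    table: pd.DataFrame  # breeds x K

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("breed ancestry rows must sum to 1")


def _observed_arrays(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes as float with missing zeroed, plus the observation mask."""
    W = (~g.missing_mask()).astype(np.float64)
    G = g.calls.astype(np.float64)
    G[W == 0] = 0.0
    return G, W


def loglik(g: GenotypeMatrix, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial log-likelihood over the non-missing cells (no binom. coeff.)."""
    G, W = _observed_arrays(g)
    return _loglik_arrays(G, W, np.asarray(Q, float), np.asarray(F, float))


def _loglik_arrays(G, W, Q, F) -> float:
    A = np.clip(Q @ F, _A_EPS, 1.0 - _A_EPS)
    return float(np.sum(W * (G * np.log(A) + (2.0 - G) * np.log1p(-A))))


def _em_fit(
    G: np.ndarray,
    W: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> AdmixtureFit:
    n, m = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))
    M = W.sum(axis=1)  # observed SNPs per individual
    if (M == 0).any():
        raise ValueError("individual with zero observed genotypes")
    Gw = G * W
    G2w = (2.0 - G) * W

    # one dose matrix per iteration serves both the likelihood of the
    # incoming parameters and the EM responsibilities
    trace: list[float] = []
    converged = False
    reinitialized = False
    just_reinit = False
    for _ in range(max_iter):
        A = np.clip(Q @ F, _A_EPS, 1.0 - _A_EPS)
        trace.append(float(np.sum(Gw * np.log(A)) + np.sum(G2w * np.log1p(-A))))
        if (
            len(trace) >= 2
            and not just_reinit
            and trace[-1] - trace[-2] < tol * abs(trace[-2])
        ):
            converged = True
            break
        just_reinit = False
        R = Gw / A
        S = G2w / (1.0 - A)
        QtR = Q.T @ R
        QtS = Q.T @ S
        Q = Q * (R @ F.T + S @ (1.0 - F).T) / (2.0 * M)[:, None]
        num = F * QtR
        F = num / (num + (1.0 - F) * QtS)
        F = np.clip(F, _F_EPS, 1.0 - _F_EPS)
        # guard against a component losing all mass: reseed it once
        colsum = Q.sum(axis=0)
        dead = colsum < 1e-9
        if dead.any():
            if reinitialized:
                warnings.warn("admixture component collapsed twice; leaving as-is")
            else:
                Q[:, dead] = rng.dirichlet(np.ones(int(dead.sum()) + 1), size=n)[:, :-1]
                reinitialized = True
                just_reinit = True
        Q /= Q.sum(axis=1, keepdims=True)
    else:
        trace.append(_loglik_arrays(G, W, Q, F))
    return AdmixtureFit(
        K=K,
        Q=Q,
        F=F,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iterations=len(trace) - 1,
    )


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
) -> AdmixtureFit:
    """Fit the K-component admixture model by EM from random starts.

    ``n_restarts`` independent Dirichlet/uniform initializations are run
    and the fit with the best final log-likelihood kept.  ``tol`` is the
    relative log-likelihood change below which iteration stops.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n:
        raise ValueError(f"K={K} exceeds the number of individuals ({g.n})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    G, W = _observed_arrays(g)
    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(n_restarts):
        fit = _em_fit(G, W, K, rng, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def align_components(fit_a: AdmixtureFit, other) -> np.ndarray:
    """Resolve label switching between two fits (or a fit and ground truth).

    Returns ``perm`` with component ``k`` of ``fit_a`` matched to
    component ``perm[k]`` of ``other``, chosen to maximize the summed
    correlation between matched allele-frequency rows by optimal
    assignment.
    """
    F_a = fit_a.F
    F_b = other.F if isinstance(other, AdmixtureFit) else np.asarray(other.F_true)
    if F_a.shape[0] != F_b.shape[0]:
        raise ValueError(f"component counts differ: {F_a.shape[0]} vs {F_b.shape[0]}")
    K = F_a.shape[0]
    corr = np.corrcoef(F_a, F_b)[:K, K:]
    corr = np.nan_to_num(corr, nan=-1.0)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm


def masked_deviance(G, W_masked, mask, Q, F) -> float:
    """Mean binomial deviance of the masked cells under fitted doses."""
    A = np.clip(Q @ F, _A_EPS, 1.0 - _A_EPS)
    g = G[mask]
    a = A[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(g > 0, g * np.log(g / (2.0 * a)), 0.0)
        t2 = np.where(g < 2, (2.0 - g) * np.log((2.0 - g) / (2.0 - 2.0 * a)), 0.0)
    return float(np.mean(t1 + t2))


def cv_choose_k(
    g: GenotypeMatrix,
    ks=range(2, 25),
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 2000,
    n_restarts: int = 1,
) -> KSelectionCurve:
    """Choose K by masked-genotype cross-validation.

    The observed genotype cells are partitioned at random into ``folds``
    folds.  For each fold and each candidate K the fold's cells are
    hidden (treated as missing), the model refit, and the mean binomial
    deviance of the hidden cells under the refit doses recorded; the CV
    error of K is the mean over folds and the smallest K attaining the
    minimum is chosen.
    """
    ks = list(ks)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    G, W = _observed_arrays(g)
    obs_idx = np.flatnonzero(W.ravel() > 0)
    if obs_idx.size < folds:
        raise ValueError("not enough observed cells for the requested folds")
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, folds, size=obs_idx.size)
    # guarantee no empty fold on tiny inputs
    for f in range(folds):
        if not (fold_of == f).any():
            fold_of[rng.integers(obs_idx.size)] = f

    errors = np.zeros((len(ks), folds))
    for f in range(folds):
        mask_flat = np.zeros(W.size, dtype=bool)
        mask_flat[obs_idx[fold_of == f]] = True
        mask = mask_flat.reshape(W.shape)
        W_train = W.copy()
        W_train[mask] = 0.0
        if (W_train.sum(axis=1) == 0).any() or (W_train.sum(axis=0) == 0).any():
            raise ValueError("a fold masked every call of some row/column")
        for a, K in enumerate(ks):
            best = None
            for _ in range(n_restarts):
                fit = _em_fit(G, W_train, K, rng, tol, max_iter)
                if best is None or fit.loglik > best.loglik:
                    best = fit
            errors[a, f] = masked_deviance(G, W_train, mask, best.Q, best.F)
    return KSelectionCurve(ks=ks, cv_errors=errors.mean(axis=1).tolist())


def summarize_by_breed(fit: AdmixtureFit, labels) -> BreedAncestrySummary:
    """Mean ancestry proportions per breed label."""
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != fit.Q.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels for {fit.Q.shape[0]} individuals"
        )
    df = pd.DataFrame(fit.Q, columns=[f"k{k + 1}" for k in range(fit.K)])
    df["breed"] = labels
    table = df.groupby("breed", sort=True).mean()
    return BreedAncestrySummary(table=table)
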