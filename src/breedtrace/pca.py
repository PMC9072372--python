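"""Principal component analysis of genotype matrices.

Centered, unscaled by default (the convention of R's ``prcomp``, which
the breed-structure summaries follow); per-SNP unit-variance scaling is
available behind a flag because discriminant pipelines sometimes prefer
it.  Computed by SVD of the centered matrix — numerically preferable to
an explicit covariance eigendecomposition when SNPs far outnumber
animals — but the contract is stated in terms of the results: scores,
orthonormal loadings and eigenvalues equal to the score-column variances
(divisor n - 1).

Sign convention: each loading column is flipped so its largest-magnitude
entry is positive, making independent runs comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAModel:
    """Fitted PCA: centering/scaling statistics, loadings, scores, spectrum."""

    snp_means: np.ndarray       # m
    snp_scales: np.ndarray      # m (all ones when scaling off)
    loadings: np.ndarray        # m x p, orthonormal columns
    eigenvalues: np.ndarray     # p, non-increasing
    scores: np.ndarray          # n x p
    total_variance: float       # sum of ALL sample variances, not just kept PCs

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_scores_dataframe(self, sample_ids=None) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        df = pd.DataFrame(self.scores, columns=cols)
        if sample_ids is not None:
            df.insert(0, "sample_id", list(sample_ids))
        return df


def fit_pca(
    X: np.ndarray,
    center: bool = True,
    scale: bool = False,
    p: int | None = None,
) -> PCAModel:
    """Fit a PCA with ``p`` components on an n x m numeric matrix.

    ``p`` defaults to full rank, min(n - 1, m).  Eigenvalue k equals the
    sample variance of score column k; their full-rank sum equals the
    total variance of the (scaled) data.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two rows to fit a PCA")
    full_rank = min(n - 1, m)
    if p is None:
        p = full_rank
    if not 1 <= p <= full_rank:
        raise ValueError(f"p must lie in [1, {full_rank}], got {p}")

    means = X.mean(axis=0) if center else np.zeros(m)
    Xc = X - means
    if scale:
        scales = Xc.std(axis=0, ddof=1)
        if (scales == 0).any():
            raise ValueError("constant column: cannot scale to unit variance")
    else:
        scales = np.ones(m)
    Xc = Xc / scales

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total_variance = float(eigenvalues.sum())

    loadings = Vt[:p].T
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    return PCAModel(
        snp_means=means,
        snp_scales=scales,
        loadings=loadings,
        eigenvalues=eigenvalues[:p].copy(),
        scores=scores,
        total_variance=total_variance,
    )


def project(model: PCAModel, X_new: np.ndarray) -> np.ndarray:
    """Project external rows through the fitted centering/scaling/loadings.

    Only training statistics are used; projecting the training matrix
    itself reproduces ``model.scores``.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.loadings.shape[0]}"
        )
    return (X_new - model.snp_means) / model.snp_scales @ model.loadings


def variance_explained(model: PCAModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-PC and cumulative fractions of total variance."""
    fractions = model.eigenvalues / model.total_variance
    return fractions, np.cumsum(fractions)
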