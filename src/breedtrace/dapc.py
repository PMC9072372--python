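"""Discriminant Analysis of Principal Components (DAPC).

The genotype matrix is first reduced to a small number of principal
components, then a linear discriminant analysis is applied to the
retained PC scores: the discriminant axes are the leading eigenvectors
of the generalized eigenproblem B v = lambda W v, with B the
between-group and W the pooled within-group covariance of the scores.
Axes are normalized to unit within-group variance (v' W v = 1), so
Euclidean distance in discriminant space is Mahalanobis-like under the
shared within-group covariance; assignment posteriors are
exp(-d^2 / 2) over group centroids, normalized.

Everything the model needs to classify an external animal — SNP order,
per-SNP training means used both for imputation and centering, PC
loadings, discriminant axes and centroids — is carried in
:class:`DAPCModel`; no statistic of the validation data ever enters the
fit.

The number of retained PCs is tuned by repeated stratified k-fold
cross-validation with mean prediction error (or mean success) as the
objective, mirroring common practice for breed-assignment studies
(10-fold, 30 repeats, candidate grid capped at 300 PCs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.model_selection import StratifiedKFold

from .genotype_io import GenotypeMatrix, mean_impute
from . import pca as pca_mod

MODEL_FORMAT_VERSION = 1


@dataclass
class DAPCModel:
    pca: pca_mod.PCAModel          # fitted on TRAINING genotypes only
    n_pcs_retained: int
    discriminant_axes: np.ndarray  # n_pcs x d, d <= groups - 1
    group_centroids: np.ndarray    # groups x d
    group_labels: list[str]        # ordered; posterior columns follow it
    var_pcs_fraction: float        # cumulative variance of retained PCs
    snp_ids: list[str]             # training SNP order
    discriminant_eigenvalues: np.ndarray | None = None  # between/within ratios

    @property
    def n_discriminants(self) -> int:
        return self.discriminant_axes.shape[1]


@dataclass
class AssignmentTable:
    """Per-individual breed posteriors and hard assignments."""

    sample_ids: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    posteriors: np.ndarray         # individuals x groups, rows sum to 1
    group_labels: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.posteriors, columns=self.group_labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "true_label", self.true_labels)
        df.insert(2, "predicted_label", self.predicted_labels)
        return df

    @property
    def success(self) -> float:
        """Fraction of individuals assigned to their true label."""
        t = np.asarray(self.true_labels, dtype=object)
        p = np.asarray(self.predicted_labels, dtype=object)
        return float(np.mean(t == p))


@dataclass
class PcSelectionResult:
    grid: list[int]
    mean_error: list[float]
    mean_success: list[float]
    objective: str                 # "min_error" or "max_success"

    @property
    def chosen_n_pcs(self) -> int:
        if self.objective == "min_error":
            scores = np.asarray(self.mean_error)
            best = int(np.argmin(scores))   # first minimum = smallest n_pcs
        elif self.objective == "max_success":
            scores = np.asarray(self.mean_success)
            best = int(np.argmax(scores))
        else:
            raise ValueError(f"unknown objective {self.objective!r}")
        return self.grid[best]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_pcs": self.grid,
                "mean_error": self.mean_error,
                "mean_success": self.mean_success,
            }
        )


def _lda_axes(
    scores: np.ndarray, labels: np.ndarray, group_labels: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discriminant axes and centroids from PC scores.

    Solves B v = lambda W v with W the pooled within-group covariance and
    B the between-group covariance of group means; returns the leading
    d = min(n_pcs, groups - 1) eigenvectors normalized to v' W v = 1,
    plus the group centroids in discriminant space (group order fixed).
    """
    n, p = scores.shape
    G = len(group_labels)
    means = np.vstack([scores[labels == lab].mean(axis=0) for lab in group_labels])
    counts = np.array([(labels == lab).sum() for lab in group_labels])
    if (counts < 2).any():
        bad = [group_labels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with fewer than 2 training individuals: {bad}")
    grand = scores.mean(axis=0)

    W = np.zeros((p, p))
    for lab, mu in zip(group_labels, means):
        d = scores[labels == lab] - mu
        W += d.T @ d
    W /= n - G
    dm = means - grand
    B = (dm.T * counts) @ dm / (n - 1)

    try:
        evals, evecs = scipy.linalg.eigh(B, W)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        ridge = 1e-8 * np.trace(W) / p
        warnings.warn(f"singular within-group covariance; adding ridge {ridge:.3g}")
        evals, evecs = scipy.linalg.eigh(B, W + ridge * np.eye(p))
    order = np.argsort(evals)[::-1]
    d = min(p, G - 1)
    axes = evecs[:, order[:d]]
    # deterministic sign, as for PC loadings
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    axes = axes * flip
    centroids = means @ axes
    return axes, centroids, evals[order[:d]]


def fit_dapc(
    g_train: GenotypeMatrix, labels, n_pcs: int
) -> DAPCModel:
    """Fit a DAPC on training genotypes with ``n_pcs`` retained PCs."""
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != g_train.n:
        raise ValueError("labels length must equal the number of individuals")
    X = mean_impute(g_train)
    model_pca = pca_mod.fit_pca(X, center=True, scale=False, p=n_pcs)
    group_labels = sorted(set(labels))
    axes, centroids, evals = _lda_axes(model_pca.scores, labels, group_labels)
    var_frac = float(model_pca.eigenvalues.sum() / model_pca.total_variance)
    return DAPCModel(
        pca=model_pca,
        n_pcs_retained=n_pcs,
        discriminant_axes=axes,
        group_centroids=centroids,
        group_labels=group_labels,
        var_pcs_fraction=var_frac,
        snp_ids=list(g_train.snp_ids),
        discriminant_eigenvalues=evals,
    )


def _discriminant_coords(model: DAPCModel, g_new: GenotypeMatrix) -> np.ndarray:
    """Map external genotypes into the training discriminant space.

    Missing cells are imputed with the TRAINING per-SNP means (which,
    after mean imputation of the training matrix, equal the PCA centering
    means), then centered and projected with training statistics only.
    """
    if list(g_new.snp_ids) != model.snp_ids:
        pos = {sid: j for j, sid in enumerate(g_new.snp_ids)}
        missing = [sid for sid in model.snp_ids if sid not in pos]
        if missing:
            raise ValueError(f"validation panel lacks training SNPs: {missing[:5]}")
        g_new = g_new.subset(cols=[pos[sid] for sid in model.snp_ids])
    X = g_new.calls.astype(np.float64)
    miss = g_new.missing_mask()
    rows, cols = np.nonzero(miss)
    X[rows, cols] = model.pca.snp_means[cols]
    scores = pca_mod.project(model.pca, X)
    return scores @ model.discriminant_axes


def predict_dapc(model: DAPCModel, g_new: GenotypeMatrix, true_labels=None) -> AssignmentTable:
    """Assign external individuals to the training groups.

    Posterior over groups is proportional to exp(-0.5 * squared distance
    to each centroid) in discriminant space; ties in the argmax go to the
    first label in group order.
    """
    coords = _discriminant_coords(model, g_new)
    d2 = (
        (coords**2).sum(axis=1)[:, None]
        - 2.0 * coords @ model.group_centroids.T
        + (model.group_centroids**2).sum(axis=1)[None, :]
    )
    d2 -= d2.min(axis=1, keepdims=True)
    post = np.exp(-0.5 * d2)
    post /= post.sum(axis=1, keepdims=True)
    pred_idx = post.argmax(axis=1)
    labels = list(true_labels) if true_labels is not None else [s.breed for s in g_new.samples]
    return AssignmentTable(
        sample_ids=list(g_new.sample_ids),
        true_labels=labels,
        predicted_labels=[model.group_labels[i] for i in pred_idx],
        posteriors=post,
        group_labels=list(model.group_labels),
    )


def default_pc_grid(n_train: int, m: int, step: int = 25, cap: int = 300) -> list[int]:
    """Candidate retained-PC counts: step..cap, capped at min(n-1, m)."""
    hi = min(cap, n_train - 1, m)
    grid = [v for v in range(step, cap + 1, step) if v <= hi]
    return grid or [hi]


def select_n_pcs(
    g_train: GenotypeMatrix,
    labels,
    grid=None,
    folds: int = 10,
    repeats: int = 30,
    objective: str = "min_error",
    seed: int = 0,
) -> PcSelectionResult:
    """Tune the number of retained PCs by repeated stratified k-fold CV.

    For each repeat a fresh stratified partition is drawn; per candidate
    the model is fit on k-1 folds and the held fold predicted; error is
    1 - fraction correct.  The PCA is computed once per fold at the
    largest candidate and truncated per candidate (identical results,
    far cheaper).  A partition giving some label fewer than 2 training
    members is redrawn, up to 10 attempts.
    """
    labels = np.asarray(labels, dtype=object)
    X = mean_impute(g_train)
    n, m = X.shape
    if grid is None:
        grid = default_pc_grid(n, m)
    grid = sorted(set(int(v) for v in grid))
    if max(grid) > min(n - 1, m):
        raise ValueError(f"grid values must be <= {min(n - 1, m)}")

    rng = np.random.default_rng(seed)
    errors: list[list[float]] = [[] for _ in grid]  # per candidate, folds x repeats
    for _rep in range(repeats):
        for attempt in range(10):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            splits = list(skf.split(X, labels))
            ok = all(
                min(np.unique(labels[tr], return_counts=True)[1]) >= 2
                for tr, _ in splits
            )
            if ok:
                break
        else:
            raise ValueError("could not draw a stratified partition keeping "
                             ">=2 training members per label")
        for tr, va in splits:
            p_max = min(max(grid), len(tr) - 1, m)
            sub_pca = pca_mod.fit_pca(X[tr], p=p_max)
            group_labels = sorted(set(labels[tr]))
            scores_va_full = pca_mod.project(sub_pca, X[va])
            for gi, n_pcs in enumerate(grid):
                p_eff = min(n_pcs, p_max)
                axes, centroids, _ = _lda_axes(
                    sub_pca.scores[:, :p_eff], labels[tr], group_labels
                )
                coords = scores_va_full[:, :p_eff] @ axes
                d2 = (
                    (coords**2).sum(axis=1)[:, None]
                    - 2.0 * coords @ centroids.T
                    + (centroids**2).sum(axis=1)[None, :]
                )
                pred = [group_labels[i] for i in d2.argmin(axis=1)]
                errors[gi].append(float(np.mean(np.asarray(pred, object) != labels[va])))
    mean_error = [float(np.mean(e)) for e in errors]
    return PcSelectionResult(
        grid=list(grid),
        mean_error=mean_error,
        mean_success=[1.0 - e for e in mean_error],
        objective=objective,
    )


# ---------------------------------------------------------------------------
# serialization: single portable .npz with a JSON header (format version 1)


def save_dapc(model: DAPCModel, path) -> None:
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "group_labels": model.group_labels,
        "snp_ids": model.snp_ids,
        "n_pcs_retained": model.n_pcs_retained,
        "var_pcs_fraction": model.var_pcs_fraction,
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        snp_means=model.pca.snp_means,
        snp_scales=model.pca.snp_scales,
        loadings=model.pca.loadings,
        eigenvalues=model.pca.eigenvalues,
        scores=model.pca.scores,
        total_variance=np.array(model.pca.total_variance),
        discriminant_axes=model.discriminant_axes,
        group_centroids=model.group_centroids,
    )


def load_dapc(path) -> DAPCModel:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {header['format_version']}")
        model_pca = pca_mod.PCAModel(
            snp_means=z["snp_means"],
            snp_scales=z["snp_scales"],
            loadings=z["loadings"],
            eigenvalues=z["eigenvalues"],
            scores=z["scores"],
            total_variance=float(z["total_variance"]),
        )
        return DAPCModel(
            pca=model_pca,
            n_pcs_retained=int(header["n_pcs_retained"]),
            discriminant_axes=z["discriminant_axes"],
            group_centroids=z["group_centroids"],
            group_labels=list(header["group_labels"]),
            var_pcs_fraction=float(header["var_pcs_fraction"]),
            snp_ids=list(header["snp_ids"]),
        )
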