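"""External-validation experiments for breed traceability.

Two designs, named after the study conventions for DAPC assignment:

* **Scenario 1 (semi-supervised)** — stratified 80/20 train/validation
  split, every breed present on both sides, repeated; measures how well
  an animal can be traced back to its own breed.
* **Scenario 2 (un-supervised)** — each breed in turn is wholly removed
  from training and its animals are forced onto the remaining breeds;
  the resulting assignment distribution measures between-breed
  similarity (a breed cannot be assigned to itself, so the confusion
  diagonal is structurally zero).

A subsampling curve reruns either scenario on stratified subsets of the
data (30%..100%) to probe robustness to sample size.

Overall success is the micro-average: validation individuals pooled,
fraction whose predicted breed equals the true breed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from . import dapc as dapc_mod


@dataclass
class ScenarioConfig:
    """Settings for one scenario run, including DAPC tuning.

    ``n_pcs`` fixes the retained-PC count and skips tuning; otherwise
    ``pc_grid``/``cv_folds``/``cv_repeats``/``objective`` are forwarded
    to :func:`breedtrace.dapc.select_n_pcs` on the training set of each
    repeat.
    """

    scenario: str = "semi_supervised"     # or "un_supervised"
    repeats: int = 10
    train_fraction: float = 0.8           # scenario 1 only
    subsample_fraction: float = 1.0
    seed: int = 0
    pc_grid: list[int] | None = None
    cv_folds: int = 10
    cv_repeats: int = 30
    objective: str = "min_error"
    n_pcs: int | None = None              # fixed override, skips tuning
    pool_individuals: bool = False        # scenario 2: pool instead of averaging

    def __post_init__(self) -> None:
        if self.scenario not in ("semi_supervised", "un_supervised"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ScenarioResult:
    """Per-repeat successes and tuning outcomes plus the mean confusion."""

    scenario: str
    successes: list[float]                  # one per repeat
    n_pcs_used: list[int]                   # one per repeat (scenario 1)
    var_pcs_fractions: list[float]
    confusion: pd.DataFrame                 # true/held-out breed x predicted

    @property
    def overall_success(self) -> float:
        return float(np.mean(self.successes))

    def summary_table(self) -> pd.DataFrame:
        """Replicate-by-replicate summary (assignment success, nPCs, VarPCs)."""
        return pd.DataFrame(
            {
                "replicate": np.arange(1, len(self.successes) + 1),
                "assignment_success": self.successes,
                "n_pcs": self.n_pcs_used,
                "var_pcs_fraction": self.var_pcs_fractions,
            }
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _check_breed_sizes(labels: np.ndarray, minimum: int = 2) -> None:
    labs, counts = np.unique(labels, return_counts=True)
    small = labs[counts < minimum]
    if small.size:
        raise ValueError(
            f"breeds with fewer than {minimum} individuals: {list(small)}"
        )


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-breed validation indices: round-half-up of the fraction, min 1."""
    train_idx, val_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_val = max(1, _round_half_up(val_fraction * idx.size))
        n_val = min(n_val, idx.size - 1)
        perm = rng.permutation(idx)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _stratified_subsample(
    labels: np.ndarray, fraction: float, rng: np.random.Generator, min_per_breed: int = 2
) -> np.ndarray:
    """Indices of a stratified subsample keeping original order.

    Fraction 1.0 returns all indices unchanged, so a full-data subsample
    run is bit-identical to the plain scenario at equal seed.
    """
    if fraction >= 1.0:
        return np.arange(labels.size)
    keep = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_keep = max(min_per_breed, _round_half_up(fraction * idx.size))
        if n_keep > idx.size:
            raise ValueError(
                f"fraction {fraction} too small for breed {lab!r} "
                f"({idx.size} individuals)"
            )
        keep.append(rng.choice(idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def _tune_and_fit(
    g_train: GenotypeMatrix, labels_train: np.ndarray, cfg: ScenarioConfig, seed: int
) -> dapc_mod.DAPCModel:
    if cfg.n_pcs is not None:
        n_pcs = min(cfg.n_pcs, g_train.n - 1, g_train.m)
    else:
        grid = cfg.pc_grid or dapc_mod.default_pc_grid(g_train.n, g_train.m)
        grid = [min(v, g_train.n - 1, g_train.m) for v in grid]
        sel = dapc_mod.select_n_pcs(
            g_train,
            labels_train,
            grid=grid,
            folds=cfg.cv_folds,
            repeats=cfg.cv_repeats,
            objective=cfg.objective,
            seed=seed,
        )
        n_pcs = sel.chosen_n_pcs
    return dapc_mod.fit_dapc(g_train, labels_train, n_pcs)


def _confusion_frame(
    rows: list[tuple[str, str]], true_order: list[str], pred_order: list[str]
) -> pd.DataFrame:
    """Row-normalized true x predicted proportions for one repeat."""
    mat = pd.DataFrame(0.0, index=true_order, columns=pred_order)
    for t, p in rows:
        mat.loc[t, p] += 1.0
    sums = mat.sum(axis=1)
    return mat.div(sums.where(sums > 0, 1.0), axis=0)


def run_scenario1(
    g: GenotypeMatrix, labels, cfg: ScenarioConfig
) -> ScenarioResult:
    """Stratified hold-out traceability (scenario 1)."""
    labels = np.asarray(labels, dtype=object)
    _check_breed_sizes(labels)
    breed_order = sorted(set(labels))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    successes, n_pcs_used, var_fracs, confusions = [], [], [], []
    for _rep in range(cfg.repeats):
        tr, va = _stratified_split(labels, 1.0 - cfg.train_fraction, rng)
        g_tr, g_va = g.subset(rows=tr), g.subset(rows=va)
        model = _tune_and_fit(g_tr, labels[tr], cfg, int(rng.integers(2**31)))
        table = dapc_mod.predict_dapc(model, g_va, true_labels=labels[va])
        successes.append(table.success)
        n_pcs_used.append(model.n_pcs_retained)
        var_fracs.append(model.var_pcs_fraction)
        confusions.append(
            _confusion_frame(
                list(zip(table.true_labels, table.predicted_labels)),
                breed_order,
                breed_order,
            )
        )
    confusion = sum(confusions[1:], confusions[0]) / len(confusions)
    return ScenarioResult(
        scenario="semi_supervised",
        successes=successes,
        n_pcs_used=n_pcs_used,
        var_pcs_fractions=var_fracs,
        confusion=confusion,
    )


def run_scenario2(
    g: GenotypeMatrix, labels, cfg: ScenarioConfig
) -> ScenarioResult:
    """Leave-one-breed-out assignment (scenario 2).

    For each breed the validation set is the whole breed and training is
    everything else (optionally subsampled, stratified); the retained-PC
    count is re-tuned for every left-out breed since the training set
    changes.  Confusion rows give, for each held-out breed, the
    distribution of its animals over the other breeds, averaged over
    repeats (or pooled when ``cfg.pool_individuals``).
    """
    labels = np.asarray(labels, dtype=object)
    breed_order = sorted(set(labels))
    if len(breed_order) < 2:
        raise ValueError("scenario 2 needs at least two breeds")
    _check_breed_sizes(labels)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    successes, confusions = [], []
    pooled_rows: list[tuple[str, str]] = []
    for _rep in range(cfg.repeats):
        rows = []
        for breed in breed_order:
            va = np.flatnonzero(labels == breed)
            tr = np.flatnonzero(labels != breed)
            if cfg.subsample_fraction < 1.0:
                sub = _stratified_subsample(labels[tr], cfg.subsample_fraction, rng)
                tr = tr[sub]
            model = _tune_and_fit(
                g.subset(rows=tr), labels[tr], cfg, int(rng.integers(2**31))
            )
            assert breed not in model.group_labels
            table = dapc_mod.predict_dapc(model, g.subset(rows=va), true_labels=[breed] * va.size)
            rows.extend(zip(table.true_labels, table.predicted_labels))
        pooled_rows.extend(rows)
        confusions.append(_confusion_frame(rows, breed_order, breed_order))
        successes.append(0.0)  # held-out breed can never match: structural
    if cfg.pool_individuals:
        confusion = _confusion_frame(pooled_rows, breed_order, breed_order)
    else:
        confusion = sum(confusions[1:], confusions[0]) / len(confusions)
    return ScenarioResult(
        scenario="un_supervised",
        successes=successes,
        n_pcs_used=[],
        var_pcs_fractions=[],
        confusion=confusion,
    )


def run_subsample_curve(
    g: GenotypeMatrix,
    labels,
    cfg: ScenarioConfig,
    fractions=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> dict[float, ScenarioResult]:
    """Rerun a scenario on stratified subsamples of increasing size.

    Each repeat draws a fresh stratified subsample at the given fraction
    and runs one repeat of the scenario on it; fraction 1.0 reproduces
    the plain scenario result bit-for-bit at equal seed.
    """
    labels = np.asarray(labels, dtype=object)
    if cfg.scenario == "semi_supervised":
        runner, min_per_breed = run_scenario1, 3  # 2 train + 1 validation
    else:
        runner, min_per_breed = run_scenario2, 2
    results: dict[float, ScenarioResult] = {}
    for frac in fractions:
        if frac >= 1.0:
            results[1.0] = runner(g, labels, cfg)
            continue
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 3, int(round(frac * 1000))])
        )
        reps = []
        for _rep in range(cfg.repeats):
            keep = _stratified_subsample(labels, frac, sub_rng, min_per_breed=min_per_breed)
            one = replace(cfg, repeats=1, seed=int(sub_rng.integers(2**31)))
            reps.append(runner(g.subset(rows=keep), labels[keep], one))
        results[frac] = ScenarioResult(
            scenario=cfg.scenario,
            successes=[r.successes[0] for r in reps],
            n_pcs_used=[r.n_pcs_used[0] for r in reps if r.n_pcs_used],
            var_pcs_fractions=[
                r.var_pcs_fractions[0] for r in reps if r.var_pcs_fractions
            ],
            confusion=sum((r.confusion for r in reps[1:]), reps[0].confusion)
            / len(reps),
        )
    return results


def export_confusion(result: ScenarioResult, path) -> None:
    """Write the breed x breed confusion matrix as CSV (row label first)."""
    result.confusion.to_csv(path, index_label="breed")


def read_confusion(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="breed")
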