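"""Replicated k-fold cross-validation over every model type.

The protocol mirrors standard genomic-prediction practice on inbred panels:
variance components are estimated on each training fold, held-out lines are
predicted by BLUP, and accuracy is the Pearson correlation between observed
and predicted phenotypes, averaged over all folds and replicates. Any
training-set-dependent step (TWAS scan, random gene draw) is re-done inside
each fold so no test information leaks into model building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_io import Panel
from .kernels import (
    Kernel,
    KernelSet,
    interaction_kernel,
    linear_kernel,
    standardize_columns,
)
from .mixed_model import blup_predict, reml_fit, variance_proportions
from . import twas as twas_mod

MODEL_TYPES = ("GBLUP", "TBLUP", "GTBLUP", "GTIBLUP", "TWAS_TBLUP", "RANDOM_GENES", "RF")


@dataclass
class CVDesign:
    """Fold assignment for each replicate; every line is tested once per replicate."""

    line_ids: list[str]
    k: int
    n_reps: int
    assignment: np.ndarray  # (n_reps, n_lines) fold indices
    seed: int

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def fold_indices(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment[rep] == fold)
        train = np.flatnonzero(self.assignment[rep] != fold)
        return train, test


class Accuracy(NamedTuple):
    r: float
    degenerate: bool


@dataclass
class CVMetrics:
    """Per-(replicate, fold) accuracies and training variance proportions."""

    model: str
    folds: pd.DataFrame  # columns: replicate, fold, r, degenerate, converged, prop_*
    extra: dict = field(default_factory=dict)

    @property
    def prop_columns(self) -> list[str]:
        return [c for c in self.folds.columns if c.startswith("prop_")]

    @property
    def mean_r(self) -> float:
        return summarize_cv(self.folds["r"].to_numpy())[0]

    @property
    def sem_r(self) -> float:
        return summarize_cv(self.folds["r"].to_numpy())[1]

    def mean_proportions(self) -> dict[str, float]:
        return {
            c.removeprefix("prop_"): summarize_cv(self.folds[c].to_numpy())[0]
            for c in self.prop_columns
        }

    def sem_proportions(self) -> dict[str, float]:
        return {
            c.removeprefix("prop_"): summarize_cv(self.folds[c].to_numpy())[1]
            for c in self.prop_columns
        }

    @property
    def n_failed(self) -> int:
        return int(self.folds["r"].isna().sum())


def make_cv_design(line_ids, k: int = 5, n_reps: int = 30, seed: int = 0) -> CVDesign:
    """Per replicate, a fresh seeded shuffle split into k near-equal folds."""
    line_ids = [str(x) for x in line_ids]
    n = len(line_ids)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} lines for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty((n_reps, n), dtype=int)
    for rep in range(n_reps):
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignment[rep, chunk] = fold
    return CVDesign(line_ids=line_ids, k=k, n_reps=n_reps, assignment=assignment, seed=seed)


def pearson_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> Accuracy:
    """Sample Pearson r; a zero-variance prediction scores 0 with a flag."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between observed and predicted")
    if len(y_true) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(y_pred) == 0.0 or np.std(y_true) == 0.0:
        return Accuracy(0.0, True)
    r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Accuracy(r, False)


def summarize_cv(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error over all non-missing replicate x fold values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no non-missing values to summarize")
    if len(v) == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

def phenotyped_line_ids(panel: Panel, trait: str) -> list[str]:
    """Lines carrying the trait; CV designs must be built on exactly these."""
    pheno = panel.phenotypes
    mask = ~pheno.missing_mask(trait)
    return [lid for lid, ok in zip(pheno.line_ids, mask) if ok]


def run_model_cv(
    model_type: str,
    panel: Panel,
    cv: CVDesign,
    trait: str,
    params: dict | None = None,
) -> CVMetrics:
    """Replicated k-fold CV of one model; fits use training lines only."""
    model_type = model_type.upper()
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}; choose from {MODEL_TYPES}")
    params = dict(params or {})

    keep_ids = phenotyped_line_ids(panel, trait)
    if cv.line_ids != keep_ids:
        raise ValueError(
            "CV design lines do not match the phenotyped lines for this trait; "
            "build the design with make_cv_design(phenotyped_line_ids(panel, trait), ...)"
        )
    pos = {lid: i for i, lid in enumerate(panel.phenotypes.line_ids)}
    row_idx = np.array([pos[lid] for lid in keep_ids])
    y = panel.phenotypes.trait_values(trait)[row_idx]

    if model_type == "RF":
        return _run_rf_cv(panel, cv, y, keep_ids, params)

    Wstd = Zstd = None
    if model_type in ("GBLUP", "GTBLUP", "GTIBLUP"):
        Wstd = _standardized_genotypes(panel, keep_ids)
    if model_type != "GBLUP":
        Zstd = _standardized_expression(panel, keep_ids)

    if model_type in ("GBLUP", "TBLUP", "GTBLUP", "GTIBLUP"):
        kernels = []
        if Wstd is not None:
            kernels.append(linear_kernel(Wstd, label="GRM"))
        if Zstd is not None:
            kernels.append(linear_kernel(Zstd, label="TRM"))
        if model_type == "GTIBLUP":
            kernels.append(interaction_kernel(kernels[0], kernels[1], label="IRM"))
        folds = cv_kernel_model(y, KernelSet(kernels), cv)
        return CVMetrics(model=model_type, folds=folds)

    # per-fold gene selection models (TWAS_TBLUP / RANDOM_GENES)
    return _run_selected_gene_cv(model_type, panel, cv, y, keep_ids, Zstd, params)


def cv_kernel_model(y: np.ndarray, kset: KernelSet, cv: CVDesign) -> pd.DataFrame:
    """Shared CV loop for any fixed multi-kernel BLUP model."""
    rows = []
    labels = kset.labels
    for rep in range(cv.n_reps):
        for fold in range(cv.k):
            train, test = cv.fold_indices(rep, fold)
            row: dict = {"replicate": rep, "fold": fold}
            try:
                sub = KernelSet(
                    [
                        Kernel(k.subset(train), [kset.line_ids[i] for i in train],
                               k.n_features_used, k.label)
                        for k in kset.kernels
                    ]
                )
                fit = reml_fit(y[train], sub)
            except (ValueError, FloatingPointError) as exc:
                warnings.warn(f"fold ({rep},{fold}) fit failed: {exc}", stacklevel=2)
                rows.append({**row, "r": np.nan, "degenerate": False, "converged": False})
                continue
            if not fit.converged:
                rows.append({**row, "r": np.nan, "degenerate": False, "converged": False})
                continue
            pred = blup_predict(fit, kset, train, test, y[train])
            acc = pearson_accuracy(y[test], pred)
            props = variance_proportions(fit).proportions
            row.update(r=acc.r, degenerate=acc.degenerate, converged=True)
            for lab in labels + ["residual"]:
                row[f"prop_{lab}"] = props[lab]
            rows.append(row)
    df = pd.DataFrame(rows)
    n_failed = int(df["r"].isna().sum())
    if n_failed:
        warnings.warn(f"{n_failed} fold(s) excluded for non-convergence", stacklevel=2)
    return df


def _standardized_genotypes(panel: Panel, keep_ids: list[str]):
    G = panel.genotypes
    if G is None:
        raise ValueError("model requires a genotype layer")
    idx = _line_index(G.line_ids, keep_ids)
    dosages = G.dosages[idx]
    if np.isnan(dosages).any():
        raise ValueError("genotypes contain missing calls; run impute_missing first")
    return standardize_columns(dosages, G.variant_ids, keep_ids)


def _standardized_expression(panel: Panel, keep_ids: list[str]):
    E = panel.expression
    if E is None:
        raise ValueError("model requires an expression layer")
    idx = _line_index(E.line_ids, keep_ids)
    return standardize_columns(E.abundances[idx], E.gene_ids, keep_ids)


def _line_index(have: list[str], want: list[str]) -> np.ndarray:
    pos = {lid: i for i, lid in enumerate(have)}
    missing = [lid for lid in want if lid not in pos]
    if missing:
        raise ValueError(f"lines missing from layer: {missing[:5]}")
    return np.array([pos[lid] for lid in want])


def _run_selected_gene_cv(
    model_type: str,
    panel: Panel,
    cv: CVDesign,
    y: np.ndarray,
    keep_ids: list[str],
    Zstd,
    params: dict,
) -> CVMetrics:
    E = panel.expression
    idx = _line_index(E.line_ids, keep_ids)
    abundances = E.abundances[idx]
    gene_ids = E.gene_ids
    p_max = params.get("p_max", 1e-4)
    k_genes = params.get("k_genes", 500)

    rows = []
    selected: dict[tuple[int, int], set[str]] = {}
    for rep in range(cv.n_reps):
        for fold in range(cv.k):
            train, test = cv.fold_indices(rep, fold)
            if model_type == "TWAS_TBLUP":
                scan = twas_mod.twas_scan(y[train], abundances[train], gene_ids)
                genes = twas_mod.select_genes(scan, p_max)
            else:
                genes = twas_mod.random_gene_set(gene_ids, k_genes, seed=[cv.seed, 91, rep, fold])
            genes &= set(Zstd.feature_ids)  # zero-variance genes were dropped
            selected[(rep, fold)] = genes
            row: dict = {"replicate": rep, "fold": fold, "n_genes": len(genes)}
            if not genes:
                # empty selection degrades to the intercept-only predictor
                acc_r, degen = 0.0, True
                rows.append({**row, "r": acc_r, "degenerate": degen, "converged": True})
                continue
            cols = Zstd.column_index(sorted(genes))
            Zsel = Zstd.values[:, cols]
            K = Kernel(Zsel @ Zsel.T / len(cols), keep_ids, len(cols), "TRM-sel")
            kset = KernelSet([K])
            sub = KernelSet([Kernel(K.values[np.ix_(train, train)],
                                    [keep_ids[i] for i in train], len(cols), "TRM-sel")])
            fit = reml_fit(y[train], sub)
            pred = blup_predict(fit, kset, train, test, y[train])
            acc = pearson_accuracy(y[test], pred)
            props = variance_proportions(fit).proportions
            rows.append(
                {
                    **row,
                    "r": acc.r,
                    "degenerate": acc.degenerate,
                    "converged": fit.converged,
                    "prop_TRM-sel": props["TRM-sel"],
                    "prop_residual": props["residual"],
                }
            )
    return CVMetrics(model=model_type, folds=pd.DataFrame(rows), extra={"selected_genes": selected})


def _run_rf_cv(panel: Panel, cv: CVDesign, y: np.ndarray, keep_ids: list[str], params: dict) -> CVMetrics:
    from .nonparametric import fit_forest, predict_forest

    E = panel.expression
    idx = _line_index(E.line_ids, keep_ids)
    X = pd.DataFrame(E.abundances[idx], columns=E.gene_ids)
    n_trees = params.get("n_trees", 1000)
    rows = []
    for rep in range(cv.n_reps):
        for fold in range(cv.k):
            train, test = cv.fold_indices(rep, fold)
            seed = int(np.random.SeedSequence([cv.seed, 17, rep, fold]).generate_state(1)[0] % (2**31))
            model = fit_forest(y[train], X.iloc[train], n_trees=n_trees, seed=seed)
            pred = predict_forest(model, X.iloc[test])
            acc = pearson_accuracy(y[test], pred)
            rows.append(
                {"replicate": rep, "fold": fold, "r": acc.r, "degenerate": acc.degenerate,
                 "converged": True}
            )
    return CVMetrics(model="RF", folds=pd.DataFrame(rows))
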