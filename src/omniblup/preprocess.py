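"""Variant, expression and phenotype preparation, and variant-to-gene mapping.

Filter inequalities are strict: a variant is kept only if MAF > ``maf_min``
and call rate > ``call_rate_min``; a gene is kept only if its across-line
mean abundance is strictly greater than the expression threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationMap, ExpressionMatrix, GenotypeMatrix, PhenotypeTable


class EmptyFilterError(ValueError):
    """Every feature was removed by a filter; relax the threshold."""


@dataclass
class VariantGeneMap:
    """Variant id -> gene ids mapped by position, with the window used."""

    variant_to_genes: dict[str, set[str]]
    window_bp: int = 0

    def genes_to_variants(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for v, gs in self.variant_to_genes.items():
            for g in gs:
                inv.setdefault(g, set()).add(v)
        return inv

    def variants_for_genes(self, genes) -> set[str]:
        gene_set = set(genes)
        return {v for v, gs in self.variant_to_genes.items() if gs & gene_set}


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.8
) -> GenotypeMatrix:
    """Keep variants with MAF strictly > ``maf_min`` and call rate strictly > ``call_rate_min``."""
    keep = (G.maf() > maf_min) & (G.call_rate() > call_rate_min)
    keep &= ~np.isnan(G.maf())
    if not keep.any():
        raise EmptyFilterError(
            f"no variants pass MAF > {maf_min} and call rate > {call_rate_min}; "
            "lower the thresholds"
        )
    return G.subset_variants(np.flatnonzero(keep))


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with its variant's mean over non-missing calls."""
    dosages = G.dosages.copy()
    missing = np.isnan(dosages)
    if missing.any():
        n_obs = (~missing).sum(axis=0)
        assert (n_obs > 0).all(), "all-missing variant should not survive filtering"
        col_means = np.nansum(dosages, axis=0) / n_obs
        idx = np.where(missing)
        dosages[idx] = col_means[idx[1]]
    return GenotypeMatrix(
        line_ids=list(G.line_ids), dosages=dosages, variants=G.variants, max_dosage=G.max_dosage
    )


def filter_expressed_genes(
    E: ExpressionMatrix, mean_threshold: float = -1.828
) -> ExpressionMatrix:
    """Keep genes whose across-line mean abundance is strictly > ``mean_threshold``.

    The default threshold separates the expressed mode of a bimodal log2FPKM
    distribution; it is a configuration value here, not re-derived.
    """
    keep = E.abundances.mean(axis=0) > mean_threshold
    if not keep.any():
        raise EmptyFilterError(f"no genes pass mean expression > {mean_threshold}")
    return E.subset_genes(np.flatnonzero(keep))


def adjust_phenotypes(
    pheno: PhenotypeTable, covariate_names: list[str]
) -> PhenotypeTable:
    """Replace each trait by OLS residuals on intercept + covariates, plus the grand mean.

    Categorical covariates are dummy-coded. Lines with a missing covariate are
    dropped (recorded in ``dropped_lines``); columns aliased with earlier ones
    (or the intercept) are dropped with a warning.
    """
    if not covariate_names:
        return PhenotypeTable(
            line_ids=list(pheno.line_ids),
            traits=pheno.traits.copy(),
            covariates=None if pheno.covariates is None else pheno.covariates.copy(),
        )
    if pheno.covariates is None:
        raise ValueError("phenotype table has no covariates attached")
    missing_cols = [c for c in covariate_names if c not in pheno.covariates.columns]
    if missing_cols:
        raise ValueError(f"unknown covariates {missing_cols}")

    cov = pheno.covariates[covariate_names]
    ok = ~cov.isna().any(axis=1).to_numpy()
    dropped = [lid for lid, keep in zip(pheno.line_ids, ok) if not keep]
    cov = cov.loc[ok]
    design = _design_matrix(cov)

    traits = pheno.traits.loc[ok].reset_index(drop=True).copy()
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < design.shape[1] + 1:
            continue  # too few observations to adjust
        X = design[obs]
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ beta
        traits.loc[obs, trait] = resid + y[obs].mean()
    return PhenotypeTable(
        line_ids=[lid for lid, keep in zip(pheno.line_ids, ok) if keep],
        traits=traits,
        covariates=cov.reset_index(drop=True),
        dropped_lines=dropped,
    )


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    """Intercept + dummy-coded covariates, greedily dropping aliased columns."""
    blocks = [pd.Series(1.0, index=cov.index, name="intercept")]
    for name in cov.columns:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            blocks.extend(dummies[c] for c in dummies.columns)
    full = pd.concat(blocks, axis=1)
    X = full.iloc[:, [0]].to_numpy()
    kept, aliased = ["intercept"], []
    for j in range(1, full.shape[1]):
        cand = np.column_stack([X, full.iloc[:, j].to_numpy()])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X = cand
            kept.append(full.columns[j])
        else:
            aliased.append(full.columns[j])
    if aliased:
        warnings.warn(f"dropping aliased covariate columns: {aliased}", stacklevel=2)
    return X


def map_variants_to_genes(
    G: GenotypeMatrix, spans: AnnotationMap, window_bp: int = 1000
) -> VariantGeneMap:
    """Map each variant to the genes whose (span +/- window) contains its position.

    Intervals are 1-based inclusive; a variant may map to several overlapping
    genes, and unmapped variants are simply absent from the map.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene, (chrom, start, end) in spans.gene_spans.items():
        by_chrom.setdefault(chrom, []).append((start - window_bp, end + window_bp, gene))
    arrays = {
        chrom: (
            np.array([iv[0] for iv in ivs]),
            np.array([iv[1] for iv in ivs]),
            np.array([iv[2] for iv in ivs], dtype=object),
        )
        for chrom, ivs in by_chrom.items()
    }

    out: dict[str, set[str]] = {}
    chroms = G.variants["chrom"].to_numpy()
    positions = G.variants["pos"].to_numpy()
    ids = G.variants["id"].to_numpy()
    for vid, chrom, pos in zip(ids, chroms, positions):
        if chrom not in arrays:
            continue
        lo, hi, genes = arrays[chrom]
        hit = (lo <= pos) & (pos <= hi)
        if hit.any():
            out[str(vid)] = set(genes[hit])
    return VariantGeneMap(variant_to_genes=out, window_bp=window_bp)
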