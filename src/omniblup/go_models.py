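"""Per-GO-term two-layer variance-component models and scan diagnostics.

For a term ``q``, the in-set kernel is built from the features (variants or
transcripts) assigned to the term's genes and the out-set kernel from all
remaining features, both from columns standardized once on the full feature
matrix, so fitting ``y = 1 mu + u_in + u_out + e`` re-weights the term's
features relative to the genomic/transcriptomic background. The scan runs
one such model per eligible term over a shared CV design, so term accuracies
are paired and comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cv_engine import CVDesign, cv_kernel_model, pearson_accuracy, summarize_cv
from .data_io import AnnotationMap, Panel
from .kernels import KernelSet, StandardizedFeatures, partition_kernels
from .preprocess import VariantGeneMap

GO_MODES = ("GO-GBLUP", "GO-TBLUP", "GO-GTBLUP")


@dataclass
class GOModelSummary:
    """One term's CV outcome under one GO-informed model."""

    term: str
    mode: str
    n_genes: int
    n_features: int  # in-kernel features on the mode's primary layer
    mean_r: float
    sem_r: float
    mean_in_proportion: float  # summed over in-term components for GO-GTBLUP
    baseline_mean_r: float = float("nan")
    n_features_variants: int | None = None
    n_features_genes: int | None = None
    rank: int | None = None
    is_top: bool = False


def enumerate_go_terms(
    ann: AnnotationMap, feature_universe, min_genes: int = 5
) -> dict[str, list[str]]:
    """Terms with at least ``min_genes`` genes inside the universe, with gene lists."""
    universe = set(feature_universe)
    out: dict[str, list[str]] = {}
    for term, genes in sorted(ann.term_to_genes().items()):
        inside = sorted(genes & universe)
        if len(inside) >= min_genes:
            out[term] = inside
    return out


def common_terms(a: dict[str, list[str]], b: dict[str, list[str]]) -> list[str]:
    """Terms eligible on both layers (used by the combined GO-GTBLUP scan)."""
    return sorted(set(a) & set(b))


def run_go_scan(
    mode: str,
    panel: Panel,
    cv: CVDesign,
    trait: str,
    terms: dict[str, list[str]],
    Wstd: StandardizedFeatures | None = None,
    Zstd: StandardizedFeatures | None = None,
    variant_gene_map: VariantGeneMap | None = None,
    baseline_mean_r: float = float("nan"),
) -> list[GOModelSummary]:
    """Fit the per-term partitioned model for every eligible term.

    ``Wstd``/``Zstd`` are the globally standardized feature matrices on the
    phenotyped lines (see cv_engine helpers); GO-GBLUP additionally needs the
    variant-to-gene map to assemble each term's variant in-set.
    """
    if mode not in GO_MODES:
        raise ValueError(f"unknown GO scan mode {mode!r}")
    if mode in ("GO-GBLUP", "GO-GTBLUP") and (Wstd is None or variant_gene_map is None):
        raise ValueError(f"{mode} requires standardized genotypes and a variant-gene map")
    if mode in ("GO-TBLUP", "GO-GTBLUP") and Zstd is None:
        raise ValueError(f"{mode} requires standardized expression")

    pos = {lid: i for i, lid in enumerate(panel.phenotypes.line_ids)}
    idx = np.array([pos[lid] for lid in cv.line_ids])
    y = panel.phenotypes.trait_values(trait)[idx]

    summaries: list[GOModelSummary] = []
    for term, genes in terms.items():
        kernels = []
        n_var = n_gen = None
        try:
            if mode in ("GO-GBLUP", "GO-GTBLUP"):
                in_variants = sorted(variant_gene_map.variants_for_genes(genes))
                in_variants = [v for v in in_variants if v in set(Wstd.feature_ids)]
                if not in_variants:
                    warnings.warn(f"{term}: no variants map to its genes; skipped", stacklevel=2)
                    continue
                kg_in, kg_out = partition_kernels(
                    Wstd, in_variants, f"{term}-g-in", "g-out", partition_name=term
                )
                kernels += [kg_in, kg_out]
                n_var = kg_in.n_features_used
            if mode in ("GO-TBLUP", "GO-GTBLUP"):
                in_genes = [g for g in genes if g in set(Zstd.feature_ids)]
                if not in_genes:
                    warnings.warn(f"{term}: no expressed genes; skipped", stacklevel=2)
                    continue
                kt_in, kt_out = partition_kernels(
                    Zstd, in_genes, f"{term}-t-in", "t-out", partition_name=term
                )
                kernels += [kt_in, kt_out]
                n_gen = kt_in.n_features_used
        except ValueError as exc:
            warnings.warn(f"{term}: {exc}; skipped", stacklevel=2)
            continue

        folds = cv_kernel_model(y, KernelSet(kernels), cv)
        in_cols = [c for c in folds.columns if c.startswith("prop_") and "-in" in c]
        in_prop = folds[in_cols].sum(axis=1).to_numpy()
        mean_r, sem_r = summarize_cv(folds["r"].to_numpy())
        summaries.append(
            GOModelSummary(
                term=term,
                mode=mode,
                n_genes=len(genes),
                n_features=n_gen if mode != "GO-GBLUP" else n_var,
                mean_r=mean_r,
                sem_r=sem_r,
                mean_in_proportion=summarize_cv(in_prop)[0],
                baseline_mean_r=baseline_mean_r,
                n_features_variants=n_var,
                n_features_genes=n_gen,
            )
        )
    return summaries


def rank_go_terms(summaries: list[GOModelSummary], top_k: int = 3) -> list[GOModelSummary]:
    """Descending by mean_r; ties by larger in-term proportion, then term id."""
    if not summaries:
        raise ValueError("no summaries to rank")
    ordered = sorted(
        summaries, key=lambda s: (-s.mean_r, -s.mean_in_proportion, s.term)
    )
    for i, s in enumerate(ordered):
        s.rank = i + 1
        s.is_top = i < top_k
    return ordered


def go_scan_diagnostics(summaries: list[GOModelSummary]) -> dict:
    """Correlation of term accuracy with term size and with training proportion.

    Low accuracy-size correlation together with high accuracy-proportion
    correlation indicates the scan captures term-specific signal rather than
    rewarding big terms under an infinitesimal architecture.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 term summaries for diagnostics")
    r = np.array([s.mean_r for s in summaries], dtype=float)
    size = np.array([s.n_features for s in summaries], dtype=float)
    prop = np.array([s.mean_in_proportion for s in summaries], dtype=float)
    acc_size = pearson_accuracy(size, r)
    acc_prop = pearson_accuracy(prop, r)
    return {
        "r_accuracy_size": acc_size.r,
        "r_accuracy_proportion": acc_prop.r,
        "degenerate_size": acc_size.degenerate,
        "degenerate_proportion": acc_prop.degenerate,
        "n_terms": len(summaries),
    }
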