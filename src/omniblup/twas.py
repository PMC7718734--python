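"""Transcriptome-wide association scan and gene selection.

Each gene is tested by ordinary least squares of the (pre-adjusted) line-mean
phenotype on an intercept plus that gene's abundance, with a two-sided t test
on the slope at n - 2 degrees of freedom. Selection keeps genes with p
strictly below the threshold; the random-gene control samples uniformly
without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TWASResult:
    """Per-gene slope, standard error, t statistic and two-sided p value."""

    table: pd.DataFrame  # columns: gene, slope, se, t, p, n

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene"])

    def p_values(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def twas_scan(y_train: np.ndarray, abundances: np.ndarray, gene_ids) -> TWASResult:
    """Vectorized per-gene simple linear regression of phenotype on expression.

    Constant genes carry no information and are assigned slope 0, p = 1.
    """
    y = np.asarray(y_train, dtype=float)
    X = np.asarray(abundances, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("TWAS scan requires at least 10 training lines")
    if X.shape[0] != n:
        raise ValueError("expression rows do not match phenotype length")

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)

    nonconst = sxx > 1e-24 * max(1.0, float(np.abs(X).max()) ** 2)
    slope = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.nan)
    tstat = np.zeros(X.shape[1])
    p = np.ones(X.shape[1])

    sxx_nc = sxx[nonconst]
    slope_nc = sxy[nonconst] / sxx_nc
    sse = np.maximum(syy - slope_nc * sxy[nonconst], 0.0)
    df = n - 2
    s2 = sse / df
    se_nc = np.sqrt(s2 / sxx_nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_nc = np.where(se_nc > 0, slope_nc / se_nc, np.inf * np.sign(slope_nc))
    p_nc = 2.0 * stats.t.sf(np.abs(t_nc), df)

    slope[nonconst] = slope_nc
    se[nonconst] = se_nc
    tstat[nonconst] = t_nc
    p[nonconst] = p_nc
    table = pd.DataFrame(
        {
            "gene": [str(g) for g in gene_ids],
            "slope": slope,
            "se": se,
            "t": tstat,
            "p": p,
            "n": n,
        }
    )
    return TWASResult(table=table)


def select_genes(res: TWASResult, p_max: float) -> set[str]:
    """Genes with p strictly below ``p_max``; may be empty at stringent thresholds."""
    mask = res.table["p"].to_numpy() < p_max
    return set(res.table.loc[mask, "gene"])


def random_gene_set(gene_ids, k: int, seed) -> set[str]:
    """Uniform sample of ``k`` genes without replacement, reproducible from seed."""
    gene_ids = [str(g) for g in gene_ids]
    if k > len(gene_ids):
        raise ValueError(f"cannot sample {k} genes from {len(gene_ids)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(gene_ids), size=k, replace=False)
    return {gene_ids[i] for i in picked}
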