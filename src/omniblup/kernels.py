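"""Relationship kernels: genomic (GRM), transcriptomic (TRM), Hadamard
interaction (IRM) and GO-partition kernels.

A linear kernel is ``W W' / p`` where ``W`` holds column-centered features
scaled to unit *population* variance (divisor n) and ``p`` is the number of
retained columns. Under that scaling the mean of the kernel diagonal is
exactly 1 and every row sums to 0, which the rest of the pipeline relies on.
Kernels are built once on all lines (train and test together); variance
components are still estimated on training lines only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StandardizedFeatures:
    """Lines x features matrix with columns centered and scaled to unit variance."""

    values: np.ndarray
    feature_ids: list[str]
    line_ids: list[str]
    dropped_features: list[str] = field(default_factory=list)

    @property
    def n_features_used(self) -> int:
        return self.values.shape[1]

    def column_index(self, ids) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature ids (first few): {missing[:5]}")
        return np.array([pos[f] for f in ids], dtype=int)


@dataclass
class Kernel:
    """n x n symmetric line-similarity component."""

    values: np.ndarray
    line_ids: list[str]
    n_features_used: int
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match line count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, rows: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
        cols = rows if cols is None else cols
        return self.values[np.ix_(rows, cols)]


@dataclass
class KernelSet:
    """Ordered named kernels entering one mixed model (residual uses I implicitly)."""

    kernels: list[Kernel]

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("KernelSet needs at least one kernel")
        ref = self.kernels[0].line_ids
        for k in self.kernels[1:]:
            if k.line_ids != ref:
                raise ValueError("kernels in a set must share identical line ids and order")

    @property
    def line_ids(self) -> list[str]:
        return self.kernels[0].line_ids

    @property
    def labels(self) -> list[str]:
        return [k.label for k in self.kernels]

    def __len__(self) -> int:
        return len(self.kernels)

    def matrices(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None):
        if rows is None:
            return [k.values for k in self.kernels]
        return [k.subset(rows, cols) for k in self.kernels]


def standardize_columns(
    M: np.ndarray, feature_ids, line_ids, zero_var_tol: float = 1e-12
) -> StandardizedFeatures:
    """Center each column and scale by its population (divisor-n) standard deviation.

    Zero-variance columns carry no line contrast and are dropped (reported in
    ``dropped_features``).
    """
    M = np.asarray(M, dtype=float)
    if np.isnan(M).any():
        raise ValueError("standardize_columns requires a complete matrix (impute first)")
    feature_ids = [str(f) for f in feature_ids]
    sd = M.std(axis=0)  # population convention, ddof=0
    keep = sd > zero_var_tol
    if not keep.any():
        raise ValueError("all columns have zero variance")
    dropped = [f for f, k in zip(feature_ids, keep) if not k]
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return StandardizedFeatures(
        values=Z,
        feature_ids=[f for f, k in zip(feature_ids, keep) if k],
        line_ids=list(line_ids),
        dropped_features=dropped,
    )


def linear_kernel(F: StandardizedFeatures, label: str = "") -> Kernel:
    """``W W' / p`` similarity over the retained standardized columns."""
    p = F.n_features_used
    if p == 0:
        raise ValueError("no retained features to build a kernel from")
    values = F.values @ F.values.T / p
    return Kernel(values=values, line_ids=list(F.line_ids), n_features_used=p, label=label)


def interaction_kernel(K1: Kernel, K2: Kernel, label: str = "IRM") -> Kernel:
    """Hadamard (element-wise) product kernel; PSD by the Schur product theorem."""
    if K1.line_ids != K2.line_ids:
        raise ValueError("interaction requires identical line ids in identical order")
    return Kernel(
        values=K1.values * K2.values,
        line_ids=list(K1.line_ids),
        n_features_used=K1.n_features_used * K2.n_features_used,
        label=label,
    )


def partition_kernels(
    F: StandardizedFeatures,
    in_ids,
    label_in: str = "in",
    label_out: str = "out",
    partition_name: str = "",
) -> tuple[Kernel, Kernel]:
    """Split features into an in-set kernel and its complement kernel.

    Columns were standardized once on all features before subsetting, so
    ``|in| K_in + |out| K_out = p K_full`` exactly.
    """
    in_set = set(in_ids)
    mask = np.array([f in in_set for f in F.feature_ids])
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    name = f" for {partition_name}" if partition_name else ""
    if n_in == 0:
        raise ValueError(f"empty in-partition{name}")
    if n_out == 0:
        raise ValueError(f"empty out-partition (in-set covers all features){name}")
    W_in, W_out = F.values[:, mask], F.values[:, ~mask]
    K_in = Kernel(W_in @ W_in.T / n_in, list(F.line_ids), n_in, label_in)
    K_out = Kernel(W_out @ W_out.T / n_out, list(F.line_ids), n_out, label_out)
    return K_in, K_out
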