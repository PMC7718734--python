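"""REML estimation and BLUP prediction for intercept-plus-multiple-kernel
linear mixed models.

Model: ``y = 1 mu + sum_c u_c + e`` with ``u_c ~ N(0, K_c sigma2_c)`` and
``e ~ N(0, I sigma2_e)``, so ``V = sum_c sigma2_c K_c + sigma2_e I``. The
restricted log-likelihood (intercept profiled out) is

    lR = -1/2 [ (n-1) log 2 pi + log|V| + log(1' V^-1 1) + y' P y ]

Variance components are constrained non-negative; a component driven to the
boundary is clamped at zero and flagged. Single-kernel models use a one-time
eigendecomposition and a 1-D profiled search; multi-kernel models use
average-information (AI) REML steps with step-halving and an EM fallback,
which is guaranteed to ascend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .kernels import KernelSet

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponentFit:
    """REML estimates for one residual and one-or-more kernel components."""

    sigma2: np.ndarray  # per-kernel variances, order matches the KernelSet
    sigma2_e: float
    mu_hat: float
    restricted_loglik: float
    converged: bool
    n_iter: int
    boundary_flags: list[bool]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if (self.sigma2 < 0).any() or self.sigma2_e <= 0:
            raise ValueError("variance components must be >= 0 with positive residual")


@dataclass
class VarianceProportions:
    """Per-component share of the total fitted variance (residual included)."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError("variance proportions must sum to 1")


def restricted_loglik(
    y: np.ndarray, kernel_mats: list[np.ndarray], sigma2: np.ndarray, sigma2_e: float
) -> tuple[float, float]:
    """Restricted log-likelihood and GLS intercept at the given components."""
    n = len(y)
    V = sigma2_e * np.eye(n)
    for s, K in zip(sigma2, kernel_mats):
        V += s * K
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        V = V + (1e-10 * np.trace(V) / n) * np.eye(n)
        c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_1 = linalg.cho_solve((c, low), ones)
    xvx = ones @ Vi_1
    mu = (ones @ Vi_y) / xvx
    yPy = y @ Vi_y - (ones @ Vi_y) ** 2 / xvx
    return -0.5 * ((n - 1) * LOG2PI + logdet_v + np.log(xvx) + yPy), mu


def reml_fit(
    y: np.ndarray,
    kernels: KernelSet,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> VarianceComponentFit:
    """Maximize the restricted likelihood over non-negative variance components."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("REML fitting requires at least 20 training lines")
    if len(kernels.line_ids) != n:
        raise ValueError("kernels not aligned to y")
    if np.var(y, ddof=1) <= 0:
        raise ValueError("phenotype has zero variance")
    mats = kernels.matrices()
    if len(mats) == 1:
        return _reml_single_eigen(y, mats[0], kernels.labels)
    return _reml_ai(y, mats, kernels.labels, max_iter=max_iter, tol=tol)


# ---------------------------------------------------------------------------
# single kernel: exact 1-D profiled search on the eigenbasis
# ---------------------------------------------------------------------------

def _reml_single_eigen(y: np.ndarray, K: np.ndarray, labels: list[str]) -> VarianceComponentFit:
    n = len(y)
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)  # PSD up to round-off
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def profiled_neg_ll(h: float) -> float:
        w = h * d + (1.0 - h)
        yWy = np.sum(yt**2 / w)
        xWx = np.sum(xt**2 / w)
        xWy = np.sum(xt * yt / w)
        ypy = yWy - xWy**2 / xWx
        s2 = ypy / (n - 1)
        ll = -0.5 * (
            (n - 1) * LOG2PI
            + (n - 1) * np.log(s2)
            + np.sum(np.log(w))
            + np.log(xWx)
            + (n - 1)
        )
        return -ll

    hi = 1.0 - 1e-6
    grid = np.linspace(0.0, hi, 64)
    vals = np.array([profiled_neg_ll(h) for h in grid])
    j = int(np.argmin(vals))
    lo_b = grid[max(j - 1, 0)]
    hi_b = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        profiled_neg_ll, bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-12},
    )
    h = float(res.x) if res.fun <= vals[j] else float(grid[j])

    w = h * d + (1.0 - h)
    yWy = np.sum(yt**2 / w)
    xWx = np.sum(xt**2 / w)
    xWy = np.sum(xt * yt / w)
    s2 = (yWy - xWy**2 / xWx) / (n - 1)
    sigma2 = np.array([h * s2])
    sigma2_e = max((1.0 - h) * s2, 1e-12 * np.var(y, ddof=1))
    ll, mu = restricted_loglik(y, [K], sigma2, sigma2_e)
    return VarianceComponentFit(
        sigma2=sigma2,
        sigma2_e=sigma2_e,
        mu_hat=mu,
        restricted_loglik=ll,
        converged=True,
        n_iter=int(getattr(res, "nfev", 0)),
        boundary_flags=[h < 1e-10],
        labels=list(labels),
    )


# ---------------------------------------------------------------------------
# multiple kernels: AI-REML with EM fallback and zero clamping
# ---------------------------------------------------------------------------

def _reml_ai(
    y: np.ndarray,
    mats: list[np.ndarray],
    labels: list[str],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> VarianceComponentFit:
    n = len(y)
    vary = float(np.var(y, ddof=1))
    comps = mats + [np.eye(n)]  # residual as the last component
    C = len(comps)
    theta = np.full(C, vary / C)
    floor_e = 1e-10 * vary
    clamp_tol = 1e-10 * vary
    clamped = np.zeros(C, dtype=bool)
    ones = np.ones(n)

    def loglik_at(th: np.ndarray):
        V = sum(t * K for t, K in zip(th, comps))
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(n))
        Vi1 = Vinv @ ones
        xvx = float(ones @ Vi1)
        P = Vinv - np.outer(Vi1, Vi1) / xvx
        Py = P @ y
        ll = -0.5 * ((n - 1) * LOG2PI + logdet_v + np.log(xvx) + float(y @ Py))
        return ll, P, Py

    state = loglik_at(theta)
    if state is None:
        raise FloatingPointError("non-finite restricted likelihood at initialization")
    ll, P, Py = state
    converged = False
    it = 0

    def ai_candidate(score: np.ndarray, AI: np.ndarray, free: np.ndarray) -> np.ndarray | None:
        """Active-set AI proposal: components pushed negative are fixed at zero
        and the step is re-solved for the rest, so a boundary component cannot
        stall progress along the free directions."""
        active = free.copy()
        forced_zero = np.zeros(C, dtype=bool)
        for _ in range(C + 1):
            if not active.any():
                return None
            A = AI[np.ix_(active, active)]
            g = score[active]
            ridge = 1e-10 * max(float(A.max(initial=0.0)), 1.0)
            try:
                d = np.linalg.solve(A + ridge * np.eye(A.shape[0]), g)
            except np.linalg.LinAlgError:
                return None
            cand = theta.copy()
            cand[forced_zero] = 0.0
            cand[active] = theta[active] + d
            neg = np.zeros(C, dtype=bool)
            neg[: C - 1] = cand[: C - 1] < 0
            neg[C - 1] = cand[C - 1] < floor_e
            neg &= active
            if not neg.any():
                cand[-1] = max(cand[-1], floor_e)
                return cand
            forced_zero |= neg
            active &= ~neg
        return None

    for it in range(1, max_iter + 1):
        q = np.column_stack([K @ Py for K in comps])  # n x C
        trPK = np.array([np.einsum("ij,ji->", P, K) for K in comps])
        yPKPy = Py @ q
        score = -0.5 * (trPK - yPKPy)

        # release clamped components whose gradient points inward
        clamped &= ~(score > 0)
        free = ~clamped
        Pq = P @ q
        AI = 0.5 * (q.T @ Pq)

        new_theta = new_state = None
        took_ai = False
        cand = ai_candidate(score, AI, free) if free.any() else None
        if cand is not None:
            # ascent safeguard: shrink toward the current point if needed
            for frac in (1.0, 0.5, 0.25, 0.1):
                trial = theta + frac * (cand - theta)
                trial[: C - 1] = np.maximum(trial[: C - 1], 0.0)
                trial[-1] = max(trial[-1], floor_e)
                st = loglik_at(trial)
                if st is not None and st[0] >= ll - 1e-10:
                    new_theta, new_state = trial, st
                    took_ai = frac == 1.0
                    break
        if new_theta is None:
            # EM fallback: guaranteed-ascent fixed-point update
            trial = theta + theta**2 * (yPKPy - trPK) / n
            trial = np.maximum(trial, 0.0)
            trial[-1] = max(trial[-1], floor_e)
            st = loglik_at(trial)
            if st is None:
                break
            new_theta, new_state = trial, st

        theta = new_theta
        clamped = clamped | (np.arange(C) < C - 1) & (theta < clamp_tol)
        theta[:-1][clamped[:-1]] = 0.0
        theta[-1] = max(theta[-1], floor_e)
        ll_new, P, Py = new_state
        small_change = abs(ll_new - ll) < tol * max(1.0, abs(ll))
        # a flat gradient over the free directions guards against stopping
        # mid-crawl when steps were dampened near a boundary
        flat = bool(np.max(np.abs(score[free]) if free.any() else 0.0) * vary < 1e-5)
        if small_change and (took_ai or flat):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    sigma2 = theta[:-1].copy()
    sigma2_e = float(max(theta[-1], floor_e))
    ll_final, mu = restricted_loglik(y, mats, sigma2, sigma2_e)
    if not converged:
        warnings.warn("REML did not converge within max_iter", stacklevel=2)
    return VarianceComponentFit(
        sigma2=sigma2,
        sigma2_e=sigma2_e,
        mu_hat=mu,
        restricted_loglik=ll_final,
        converged=converged,
        n_iter=it,
        boundary_flags=list(clamped[:-1]) + [False],
        labels=list(labels),
    )


# ---------------------------------------------------------------------------
# summaries and prediction
# ---------------------------------------------------------------------------

def variance_proportions(fit: VarianceComponentFit) -> VarianceProportions:
    """Each component's variance over the total (kernel variances + residual)."""
    total = float(np.sum(fit.sigma2) + fit.sigma2_e)
    labels = fit.labels or [f"K{i}" for i in range(len(fit.sigma2))]
    props = {lab: float(s) / total for lab, s in zip(labels, fit.sigma2)}
    props["residual"] = fit.sigma2_e / total
    return VarianceProportions(proportions=props)


def blup_predict(
    fit: VarianceComponentFit,
    kernels_full: KernelSet,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    y_train: np.ndarray,
) -> np.ndarray:
    """Conditional-mean prediction of held-out lines.

    ``yhat = mu + sum_c sigma2_c K_c[test, train] V^-1 (y_train - mu)`` with
    ``V = sum_c sigma2_c K_c[train, train] + sigma2_e I`` and ``mu`` the GLS
    intercept under ``V``. The residual does not enter the cross-covariance
    because test and train residuals are independent.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets overlap")
    y_train = np.asarray(y_train, dtype=float)
    nt = len(train_idx)
    V = fit.sigma2_e * np.eye(nt)
    cross = np.zeros((len(test_idx), nt))
    for s, kern in zip(fit.sigma2, kernels_full.kernels):
        if s == 0.0:
            continue
        V += s * kern.subset(train_idx)
        cross += s * kern.subset(test_idx, train_idx)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError:
        V = V + (1e-8 * np.trace(V) / nt) * np.eye(nt)
        warnings.warn("training covariance numerically singular; jittered diagonal", stacklevel=2)
        c, low = linalg.cho_factor(V, lower=True)
    ones = np.ones(nt)
    Vi_1 = linalg.cho_solve((c, low), ones)
    Vi_y = linalg.cho_solve((c, low), y_train)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    alpha = linalg.cho_solve((c, low), y_train - mu)
    return mu + cross @ alpha
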