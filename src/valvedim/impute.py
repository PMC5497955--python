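"""Multivariate-normal imputation of missing composite-trait measurements.

The composite soft-part and basal-capsule matrices carry a small amount
of missing data (a few percent, missing completely at random as far as
dissection damage goes).  Rather than dropping specimens, missing cells
are imputed under a multivariate-normal model:

1. EM maximum likelihood for the mean and covariance under MAR.
2. Bootstrap-EM stochastic completions: each draw bootstrap-resamples
   rows, re-runs EM to propagate parameter uncertainty, then samples
   each row's missing cells from their conditional normal given the
   observed cells.  Many draws (500 by default) are averaged cellwise
   to give point estimates of the missing values.

Royston's H test (1992 variant) checks the multivariate-normality
assumption on the complete-case rows.

Observed cells are never modified by any path through this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ImputationModel",
    "MissingnessReport",
    "MVNImputer",
    "missingness_report",
    "em_mvn",
    "draw_imputations",
    "average_imputations",
    "royston_test",
]

_RIDGE = 1e-8  # covariance regularization for near-singular cases


@dataclass
class ImputationModel:
    """EM estimates of the MVN mean/covariance for one dataset."""

    variable_names: list[str]
    em_mean: np.ndarray
    em_cov: np.ndarray
    n_draws: int = 500
    seed: int | None = None
    converged: bool = True
    iterations: int = 0


@dataclass(frozen=True)
class MissingnessReport:
    dataset: str
    fraction_missing: float  # percent of all cells
    per_variable: dict[str, int] = field(default_factory=dict)


def missingness_report(matrix, variable_names=None,
                       dataset: str = "") -> MissingnessReport:
    """Percent of missing cells, with a per-variable breakdown."""
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    miss = np.isnan(x)
    names = (list(variable_names) if variable_names is not None
             else [f"v{j}" for j in range(x.shape[1])])
    per = {name: int(miss[:, j].sum()) for j, name in enumerate(names)}
    return MissingnessReport(dataset=dataset,
                             fraction_missing=float(100.0 * miss.mean()),
                             per_variable=per)


def _conditional(mean, cov, obs_idx, mis_idx, x_obs):
    """Conditional normal of the missing block given the observed block."""
    s_oo = cov[np.ix_(obs_idx, obs_idx)]
    s_mo = cov[np.ix_(mis_idx, obs_idx)]
    s_mm = cov[np.ix_(mis_idx, mis_idx)]
    sol = np.linalg.solve(s_oo + _RIDGE * np.eye(len(obs_idx)),
                          (x_obs - mean[obs_idx]))
    beta = np.linalg.solve(s_oo + _RIDGE * np.eye(len(obs_idx)), s_mo.T).T
    cond_mean = mean[mis_idx] + s_mo @ sol
    cond_cov = s_mm - beta @ s_mo.T
    return cond_mean, cond_cov


def em_mvn(matrix, variable_names=None, *, max_iter: int = 500,
           tol: float = 1e-8) -> ImputationModel:
    """EM maximum-likelihood MVN fit under missing-at-random.

    On complete data this returns the column means and the ML covariance
    (divisor n) after a single iteration.  Convergence is declared when
    the largest absolute change in any mean or covariance entry falls
    below ``tol``; non-convergence is flagged, not raised.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("matrix must be 2-D with >= 2 rows")
    n, p = x.shape
    miss = np.isnan(x)
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        raise ValueError(
            f"variable(s) with no observed values: "
            f"{np.flatnonzero(fully_missing).tolist()}")
    names = (list(variable_names) if variable_names is not None
             else [f"v{j}" for j in range(p)])

    # init: observed means / diagonal variances
    mean = np.nanmean(x, axis=0)
    var = np.nanvar(x, axis=0)
    var[var <= 0] = 1.0
    cov = np.diag(var)

    if not miss.any():
        cov_full = np.cov(x.T, bias=True).reshape(p, p)
        return ImputationModel(names, mean, cov_full, converged=True,
                               iterations=1)

    patterns: dict[tuple, list[int]] = {}
    for i in range(n):
        patterns.setdefault(tuple(miss[i]), []).append(i)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        filled = x.copy()
        cc = np.zeros((p, p))  # accumulated conditional covariance
        for patt, rows in patterns.items():
            mis_idx = np.flatnonzero(patt)
            if len(mis_idx) == 0:
                continue
            obs_idx = np.flatnonzero(~np.asarray(patt))
            if len(obs_idx) == 0:
                for i in rows:
                    filled[i] = mean
                cc += len(rows) * cov
                continue
            for i in rows:
                cond_mean, cond_cov = _conditional(mean, cov, obs_idx,
                                                   mis_idx, x[i, obs_idx])
                filled[i, mis_idx] = cond_mean
            cc[np.ix_(mis_idx, mis_idx)] += len(rows) * cond_cov
        new_mean = filled.mean(axis=0)
        centered = filled - new_mean
        new_cov = (centered.T @ centered + cc) / n
        delta = max(np.abs(new_mean - mean).max(),
                    np.abs(new_cov - cov).max())
        mean, cov = new_mean, new_cov
        if delta < tol:
            converged = True
            break
    cov = (cov + cov.T) / 2.0 + _RIDGE * np.eye(p)
    return ImputationModel(names, mean, cov, converged=converged,
                           iterations=it)


def draw_imputations(model: ImputationModel, matrix, m: int, *,
                     seed: int | None = None,
                     bootstrap: bool = True) -> list[np.ndarray]:
    """``m`` stochastic completions of ``matrix``.

    With ``bootstrap=True`` (the bootstrap-EM scheme) each draw
    re-estimates the MVN parameters by EM on a row-resampled copy before
    sampling missing cells from their conditional normal; with
    ``bootstrap=False`` all draws condition on the single EM fit (much
    faster; parameter uncertainty ignored).  Observed cells are copied
    through untouched.  A fixed seed gives bit-identical output.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    miss = np.isnan(x)
    rng = np.random.default_rng(seed if seed is not None else model.seed)
    draws: list[np.ndarray] = []
    for _ in range(m):
        if not miss.any():
            draws.append(x.copy())
            continue
        if bootstrap:
            idx = rng.integers(0, n, size=n)
            boot = x[idx]
            # retry if the resample lost every observation of a variable
            tries = 0
            while np.isnan(boot).all(axis=0).any() and tries < 100:
                idx = rng.integers(0, n, size=n)
                boot = x[idx]
                tries += 1
            fit = em_mvn(boot, model.variable_names)
            mean, cov = fit.em_mean, fit.em_cov
        else:
            mean, cov = model.em_mean, model.em_cov
        d = x.copy()
        for i in range(n):
            mis_idx = np.flatnonzero(miss[i])
            if len(mis_idx) == 0:
                continue
            obs_idx = np.flatnonzero(~miss[i])
            if len(obs_idx) == 0:
                cond_mean, cond_cov = mean, cov
            else:
                cond_mean, cond_cov = _conditional(mean, cov, obs_idx,
                                                   mis_idx, x[i, obs_idx])
            cond_cov = (cond_cov + cond_cov.T) / 2.0
            d[i, mis_idx] = rng.multivariate_normal(
                cond_mean, cond_cov + _RIDGE * np.eye(len(mis_idx)),
                method="eigh", check_valid="ignore")
        draws.append(d)
    return draws


def average_imputations(draws) -> np.ndarray:
    """Cellwise mean of completed matrices; observed cells unchanged.

    Cells on which every draw agrees (the observed data, copied through
    each draw) are returned bit-exactly, not via the mean, so observed
    values are never perturbed by summation round-off.
    """
    if len(draws) == 0:
        raise ValueError("need >= 1 draws")
    shapes = {d.shape for d in draws}
    if len(shapes) != 1:
        raise ValueError(f"draw shape mismatch: {sorted(shapes)}")
    stack = np.stack(draws)
    out = np.mean(stack, axis=0)
    constant = (stack == stack[0]).all(axis=0)
    out[constant] = stack[0][constant]
    return out


class MVNImputer:
    """Fit/transform wrapper around the EM + bootstrap-EM machinery.

    ``fit`` runs EM on the matrix; ``transform`` averages ``n_draws``
    stochastic completions.  Intended for one dataset within one
    species; the pipeline enforces that grouping.
    """

    def __init__(self, n_draws: int = 500, seed: int | None = None,
                 bootstrap: bool = True):
        self.n_draws = n_draws
        self.seed = seed
        self.bootstrap = bootstrap

    def fit(self, matrix, variable_names=None) -> "MVNImputer":
        self.model_ = em_mvn(matrix, variable_names)
        self.model_.n_draws = self.n_draws
        self.model_.seed = self.seed
        return self

    def transform(self, matrix) -> np.ndarray:
        draws = draw_imputations(self.model_, matrix, self.n_draws,
                                 seed=self.seed, bootstrap=self.bootstrap)
        return average_imputations(draws)

    def fit_transform(self, matrix, variable_names=None) -> np.ndarray:
        return self.fit(matrix, variable_names).transform(matrix)


def _royston_z(w: float, n: int) -> float:
    """Royston's (1992) normalizing transformation of Shapiro-Wilk W."""
    if n < 4 or n > 2000:
        raise ValueError(f"Royston test requires 4 <= n <= 2000, got {n}")
    if n <= 11:
        g = -2.273 + 0.459 * n
        m = 0.5440 - 0.39978 * n + 0.025054 * n ** 2 - 0.0006714 * n ** 3
        s = math.exp(1.3822 - 0.77857 * n + 0.062767 * n ** 2
                     - 0.0042897 * n ** 3)
        return (-math.log(g - math.log(1.0 - w)) - m) / s
    ln = math.log(n)
    m = -1.5861 - 0.31082 * ln - 0.083751 * ln ** 2 + 0.0038915 * ln ** 3
    s = math.exp(-0.4803 - 0.082676 * ln + 0.0030302 * ln ** 2)
    return (math.log(1.0 - w) - m) / s


def royston_test(matrix) -> tuple[float, float]:
    """Royston's H test of multivariate normality.

    Combines per-variable Shapiro-Wilk statistics, transformed to
    normal equivalents, with an equivalent-degrees-of-freedom correction
    for inter-variable correlation (1992 variant).  Returns ``(H, p)``
    with p from the chi-square(e) upper tail.  Requires a complete
    matrix; run on the complete-case subset otherwise.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
    n, p = x.shape
    if n < 4:
        raise ValueError(f"need >= 4 complete rows, got {n}")
    z = np.empty(p)
    for j in range(p):
        w = stats.shapiro(x[:, j]).statistic
        z[j] = _royston_z(float(w), n)
    r = np.square(stats.norm.ppf(stats.norm.cdf(-z) / 2.0))
    if p == 1:
        e = 1.0
    else:
        u = 0.715
        v = (0.21364 + 0.015124 * math.log(n) ** 2
             - 0.0018034 * math.log(n) ** 3)
        lam = 5.0
        corr = np.corrcoef(x.T)
        off = corr[~np.eye(p, dtype=bool)]
        c = np.power(np.abs(off), lam) * (1.0 - u * np.power(1.0 - np.abs(off), u) / v)
        cbar = float(np.mean(c))
        e = p / (1.0 + (p - 1) * cbar)
    h = float(e * np.sum(r) / p)
    pval = float(stats.chi2.sf(h, e))
    return h, pval
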