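"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: the Lasso oracle is a
from-scratch cyclic coordinate descent with soft thresholding, and the
Likert-correlation oracle discretizes closed-form bivariate normals by
brute-force Monte Carlo.
"""

from __future__ import annotations

import numpy as np


def soft_threshold(z: float, gamma: float) -> float:
    return np.sign(z) * max(abs(z) - gamma, 0.0)


def cd_lasso(X: np.ndarray, y: np.ndarray, alpha: float,
             tol: float = 1e-12, max_iter: int = 200_000) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent for (1/2n)||y - Xw - b||^2 + alpha*||w||_1.

    The intercept is handled by centering. Columns of X need not be
    standardized, but must not be constant.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    col_ss = (Xc**2).sum(axis=0) / n
    w = np.zeros(p)
    r = yc.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = (Xc[:, j] @ r) / n + col_ss[j] * w[j]
            new = soft_threshold(rho, alpha) / col_ss[j]
            if new != w[j]:
                r -= Xc[:, j] * (new - w[j])
                delta = max(delta, abs(new - w[j]))
                w[j] = new
        if delta < tol:
            break
    b = y_mean - x_mean @ w
    return w, b


def null_threshold(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest alpha at which the L1 solution is identically zero:
    max_j |x_j_centred . y_centred| / n."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / len(y))


def normal_cdf_category_proportions(thresholds: np.ndarray) -> np.ndarray:
    """Expected Likert category proportions for a standard-normal latent."""
    from scipy.stats import norm

    cuts = np.concatenate([[-np.inf], np.asarray(thresholds, float), [np.inf]])
    return np.diff(norm.cdf(cuts))


def discretized_pair_correlation(rho: float, thresholds: np.ndarray,
                                 n: int = 400_000, seed: int = 0) -> float:
    """Monte-Carlo Pearson correlation of two thresholded standard normals
    with latent correlation ``rho``."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    c1 = np.searchsorted(thresholds, z1) + 1
    c2 = np.searchsorted(thresholds, z2) + 1
    return float(np.corrcoef(c1, c2)[0, 1])
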