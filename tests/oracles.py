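"""Independent oracles used by the tests.

These deliberately avoid the library calls used by the production code:
likelihoods are written out by hand and maximised with generic optimisers,
and raster buffer counts test every pixel centre directly.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def logistic_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    from scipy.special import gammaln

    eta = X @ beta
    return float(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())


def brute_force_mle(loglik, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct likelihood maximisation: coarse Nelder-Mead then BFGS polish."""
    p = X.shape[1]

    def nll(b):
        return -loglik(b, X, y)

    start = np.zeros(p)
    rough = optimize.minimize(nll, start, method="Nelder-Mead",
                              options={"maxiter": 5000, "xatol": 1e-10,
                                       "fatol": 1e-12})
    polished = optimize.minimize(nll, rough.x, method="BFGS",
                                 options={"gtol": 1e-12, "maxiter": 1000})
    return polished.x


def ordinal_loglik(
    beta: np.ndarray, cutpoints: np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """Proportional-odds log-likelihood by direct category-probability sums.

    ``y`` holds 1-based category indices; P(Y<=k) = invlogit(theta_k - x.b).
    """
    theta = np.concatenate([[-np.inf], cutpoints, [np.inf]])
    eta = X @ beta if X.size else np.zeros(len(y))
    invlogit = lambda z: 1.0 / (1.0 + np.exp(-z))
    total = 0.0
    for i, yi in enumerate(y):
        hi = invlogit(theta[int(yi)] - eta[i]) if np.isfinite(theta[int(yi)]) else 1.0
        lo = invlogit(theta[int(yi) - 1] - eta[i]) if np.isfinite(theta[int(yi) - 1]) else 0.0
        total += np.log(hi - lo)
    return float(total)


def percent_cover_bruteforce(mask, point_x: float, point_y: float,
                             radius_m: float) -> float:
    """Cover by testing every pixel centre's Euclidean distance."""
    nrows, ncols = mask.values.shape
    n_veg = 0
    n_all = 0
    for r in range(nrows):
        for c in range(ncols):
            x = mask.origin_x + (c + 0.5) * mask.pixel_size
            y = mask.origin_y + (nrows - r - 0.5) * mask.pixel_size
            if (x - point_x) ** 2 + (y - point_y) ** 2 <= radius_m**2:
                if mask.valid[r, c]:
                    n_all += 1
                    if mask.values[r, c]:
                        n_veg += 1
    if n_all == 0:
        raise ValueError("no eligible pixels")
    return 100.0 * n_veg / n_all
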