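"""Independent brute-force oracles used by the sampler tests.

These deliberately avoid the package's own likelihood code: the K=2
Dirichlet-multinomial likelihood is evaluated through
``scipy.stats.betabinom`` and the posterior is normalized on a dense
(pi1, log theta) grid.
"""

import numpy as np
from scipy.special import logsumexp
from scipy.stats import betabinom


def grid_posterior_k2(X, theta_scale=1000.0, n_pi=10_001, n_u=600,
                      u_lo=np.log(1e-2), u_hi=np.log(1e9)):
    """Grid marginal posterior of pi1 for K=2, one group.

    Likelihood: product of beta-binomial pmfs over replicates with
    alpha = theta*pi1, beta = theta*(1-pi1).  Priors: uniform on pi1
    (symmetric Dirichlet(1)) and half-Cauchy(theta_scale) on theta,
    integrated numerically over log theta.

    Returns (pi_grid, weights) with weights summing to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.sum(axis=1)
    pi_grid = np.linspace(1e-6, 1 - 1e-6, n_pi)
    u_grid = np.linspace(u_lo, u_hi, n_u)
    log_joint = np.zeros((n_pi, n_u))
    for k, u in enumerate(u_grid):
        theta = np.exp(u)
        col = np.zeros(n_pi)
        for xj, nj in zip(X[:, 0], N):
            col += betabinom.logpmf(xj, nj, theta * pi_grid, theta * (1 - pi_grid))
        # half-Cauchy density on theta, transformed to log-theta space
        col += np.log(2 / (np.pi * theta_scale)) - np.log1p((theta / theta_scale) ** 2) + u
        log_joint[:, k] = col
    log_marg = logsumexp(log_joint, axis=1)
    w = np.exp(log_marg - logsumexp(log_marg))
    return pi_grid, w / w.sum()


def grid_mean(pi_grid, w):
    return float((pi_grid * w).sum())


def ks_draws_vs_grid(draws, pi_grid, w):
    """KS distance between an empirical sample CDF and the grid CDF."""
    draws = np.sort(np.asarray(draws))
    cdf_grid = np.cumsum(w)
    ecdf = np.searchsorted(draws, pi_grid, side="right") / draws.size
    return float(np.abs(ecdf - cdf_grid).max())
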