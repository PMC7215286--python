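"""Exact small-instance posteriors for validating the MCMC sampler.

When the index weights are fixed and the random effects are switched
off, variant 1 collapses to a two-parameter Poisson regression
log(theta_i) = b0 + b1 * s_i with a flat prior on b0 and a Normal prior
on b1.  On a handful of tracts that posterior can be integrated on a
dense grid, giving reference moments the sampler must reproduce.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .model_core import poisson_loglik

__all__ = ["grid_posterior_moments_2d"]


def grid_posterior_moments_2d(
    y, E, s,
    beta1_prior_mean: float = 0.0,
    beta1_prior_sd: float = 10.0,
    grid_points: int = 400,
    half_width_sds: float = 8.0,
) -> dict[str, float]:
    """Posterior means and SDs of (b0, b1) by dense 2-D quadrature.

    The grid is centred on the posterior mode (found numerically) and
    extends ``half_width_sds`` Laplace standard deviations each way.

    Returns dict with keys ``beta0_mean``, ``beta0_sd``, ``beta1_mean``,
    ``beta1_sd``.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    s = np.asarray(s, dtype=float)

    def neg_logpost(b):
        b0, b1 = b
        lp = -0.5 * ((b1 - beta1_prior_mean) / beta1_prior_sd) ** 2
        return -(poisson_loglik(y, E, b0 + b1 * s) + lp)

    opt = minimize(neg_logpost, x0=np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    mode = opt.x
    # Laplace curvature by finite differences for grid scaling
    h = 1e-4
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (neg_logpost(mode + ei + ej) - neg_logpost(mode + ei - ej)
                          - neg_logpost(mode - ei + ej) + neg_logpost(mode - ei - ej)
                          ) / (4 * h * h)
    cov = np.linalg.inv(hess)
    sds = np.sqrt(np.diag(cov))

    g0 = np.linspace(mode[0] - half_width_sds * sds[0],
                     mode[0] + half_width_sds * sds[0], grid_points)
    g1 = np.linspace(mode[1] - half_width_sds * sds[1],
                     mode[1] + half_width_sds * sds[1], grid_points)
    B0, B1 = np.meshgrid(g0, g1, indexing="ij")
    logp = np.empty_like(B0)
    # vectorized over the b1 axis for each b0 value
    for i, b0 in enumerate(g0):
        eta = b0 + np.outer(g1, s)  # (grid, n)
        ll = eta @ y - np.exp(eta) @ E
        lp = -0.5 * ((g1 - beta1_prior_mean) / beta1_prior_sd) ** 2
        logp[i, :] = ll + lp
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    m0 = float((p * B0).sum())
    m1 = float((p * B1).sum())
    v0 = float((p * (B0 - m0) ** 2).sum())
    v1 = float((p * (B1 - m1) ** 2).sum())
    return {"beta0_mean": m0, "beta0_sd": float(np.sqrt(v0)),
            "beta1_mean": m1, "beta1_sd": float(np.sqrt(v1))}
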