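"""The hierarchical Poisson relative-risk model.

Counts follow y_i ~ Poisson(theta_i * E_i) with expected counts E_i as
offset, and four nested structures for the log relative risk:

1. ``log(theta_i) = b0 + b1 * s_i + u_i``                 (unstructured)
2. ``log(theta_i) = b0 + b1 * s_i + v_i``                 (spatial, ICAR)
3. ``log(theta_i) = b0 + b1 * s_i + u_i + v_i``           (convolution)
4. ``log(theta_i) = b0 + b1 * s_i + a_i u_i + (1-a_i) v_i``  (mixture)

where ``s_i = sum_j w_j q_ij`` is the disadvantage index: a convex
combination of decile scores with weights w on the C-simplex under a
Dirichlet prior.  u_i are exchangeable Normal(0, sigma_u^2) effects; v_i
follow an intrinsic CAR prior whose full conditional is the neighbor
mean with precision tau_v * delta_i; a_i in (0,1) mixes the two under a
Beta prior.  The intercept is flat; b1 has a Normal prior; all scale
parameters have Uniform(0, bound) priors on the standard-deviation
scale.

The ICAR prior is improper (invariant to a constant shift per connected
component); identifiability is restored by a sum-to-zero constraint on v
per component, enforced by the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

from .preprocess import DecileMatrix, ExpectedCounts
from .tract_io import AdjacencyGraph, TractTable

__all__ = [
    "ModelSpec",
    "ParameterState",
    "ModelData",
    "ndi",
    "log_relative_risk",
    "poisson_loglik",
    "icar_logdensity",
    "log_prior",
    "log_posterior",
    "deviance",
    "VARIANT_USES_U",
    "VARIANT_USES_V",
    "VARIANT_USES_MIXING",
]

VARIANT_USES_U = {1: True, 2: False, 3: True, 4: True}
VARIANT_USES_V = {1: False, 2: True, 3: True, 4: True}
VARIANT_USES_MIXING = {1: False, 2: False, 3: False, 4: True}


@dataclass
class ModelSpec:
    """Model variant, priors and MCMC protocol.

    Parameters
    ----------
    variant : 1–4, see module docstring.
    n_covariates : number of index covariates C (12 in the motivating
        study).
    dirichlet_alpha : Dirichlet concentration for the index weights;
        all-ones (flat on the simplex) by default.
    beta1_prior_mean : prior mean of the index coefficient.  0 by
        default; ``paper_prior_preset()`` returns a spec with mean 1,
        the value printed in the source analysis.
    sigma_bound : upper bound of the Uniform(0, bound) priors on
        sigma_u, sigma_v and sigma_1 (default 100).
    mixing_prior : (a, b) of the Beta prior on each mixing value
        (default (1, 1), uniform).
    global_mixing : if True a single mixing value is shared by all
        tracts instead of one per tract.
    iterations, burn_in, thin, seed : MCMC protocol.  The reference
        protocol is 60,000 iterations, 30,000 burn-in, thin 1, one
        chain; defaults here are a lighter desk profile.

    fixed_weights / fix_u_at_zero / fixed_sigma1 / fixed_sigma_u /
    fixed_sigma_v freeze parts of the model; used for validation runs
    (e.g. reducing variant 1 to an exactly integrable two-parameter
    posterior) and for prior-sensitivity checks.
    """

    variant: int = 1
    n_covariates: int = 12
    dirichlet_alpha: np.ndarray | None = None
    beta1_prior_mean: float = 0.0
    sigma_bound: float = 100.0
    mixing_prior: tuple[float, float] = (1.0, 1.0)
    global_mixing: bool = False
    iterations: int = 6000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    prior_only: bool = False
    fixed_weights: np.ndarray | None = None
    fix_u_at_zero: bool = False
    fixed_sigma1: float | None = None
    fixed_sigma_u: float | None = None
    fixed_sigma_v: float | None = None
    store_mixing_trace: bool = False

    def __post_init__(self) -> None:
        if self.variant not in (1, 2, 3, 4):
            raise ValueError(f"variant must be 1..4, got {self.variant}")
        if self.dirichlet_alpha is None:
            self.dirichlet_alpha = np.ones(self.n_covariates)
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if len(self.dirichlet_alpha) != self.n_covariates:
            raise ValueError("dirichlet_alpha length != n_covariates")
        if np.any(self.dirichlet_alpha <= 0):
            raise ValueError("dirichlet_alpha entries must be positive")
        if self.sigma_bound <= 0:
            raise ValueError("sigma_bound must be positive")
        if self.mixing_prior[0] <= 0 or self.mixing_prior[1] <= 0:
            raise ValueError("mixing_prior parameters must be positive")
        if self.fixed_weights is not None:
            w = np.asarray(self.fixed_weights, dtype=float)
            if len(w) != self.n_covariates or abs(w.sum() - 1) > 1e-8 or np.any(w < 0):
                raise ValueError("fixed_weights must be a length-C simplex vector")
            self.fixed_weights = w
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")

    @property
    def uses_u(self) -> bool:
        return VARIANT_USES_U[self.variant] and not self.fix_u_at_zero

    @property
    def uses_v(self) -> bool:
        return VARIANT_USES_V[self.variant]

    @property
    def uses_mixing(self) -> bool:
        return VARIANT_USES_MIXING[self.variant]

    @classmethod
    def paper_protocol(cls, **kwargs) -> "ModelSpec":
        """Spec with the reference MCMC protocol (60,000/30,000/thin 1)."""
        kwargs.setdefault("iterations", 60_000)
        kwargs.setdefault("burn_in", 30_000)
        kwargs.setdefault("thin", 1)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dirichlet_alpha"] = self.dirichlet_alpha.tolist()
        if self.fixed_weights is not None:
            d["fixed_weights"] = np.asarray(self.fixed_weights).tolist()
        d["mixing_prior"] = list(self.mixing_prior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        if d.get("dirichlet_alpha") is not None:
            d["dirichlet_alpha"] = np.asarray(d["dirichlet_alpha"], dtype=float)
        if d.get("fixed_weights") is not None:
            d["fixed_weights"] = np.asarray(d["fixed_weights"], dtype=float)
        if "mixing_prior" in d:
            d["mixing_prior"] = tuple(d["mixing_prior"])
        return cls(**d)


@dataclass
class ParameterState:
    """One point in parameter space.

    ``a`` is the vector of mixing values of the mixture variant (the
    per-tract convex weight on the unstructured effect); scales are kept
    on the standard-deviation scale, precisions tau = 1/sigma^2 are
    always derived.
    """

    beta0: float
    beta1: float
    w: np.ndarray
    u: np.ndarray
    v: np.ndarray
    a: np.ndarray
    sigma_u: float
    sigma_v: float
    sigma1: float

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta0=self.beta0, beta1=self.beta1, w=self.w.copy(),
            u=self.u.copy(), v=self.v.copy(), a=self.a.copy(),
            sigma_u=self.sigma_u, sigma_v=self.sigma_v, sigma1=self.sigma1,
        )

    @classmethod
    def initial(cls, n: int, spec: ModelSpec) -> "ParameterState":
        """Neutral, reproducible starting point."""
        w = (spec.fixed_weights if spec.fixed_weights is not None
             else spec.dirichlet_alpha / spec.dirichlet_alpha.sum())
        return cls(
            beta0=0.0, beta1=0.0, w=np.asarray(w, dtype=float).copy(),
            u=np.zeros(n), v=np.zeros(n), a=np.full(n, 0.5),
            sigma_u=spec.fixed_sigma_u or 1.0,
            sigma_v=spec.fixed_sigma_v or 1.0,
            sigma1=spec.fixed_sigma1 or 1.0,
        )


@dataclass
class ModelData:
    """Aligned inputs the likelihood needs: counts, offsets, decile
    scores and the neighbor graph (with component/rank bookkeeping for
    the improper ICAR prior)."""

    y: np.ndarray
    E: np.ndarray
    q: np.ndarray
    graph: AdjacencyGraph | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        n = len(self.y)
        if len(self.E) != n or self.q.shape[0] != n:
            raise ValueError("y, E and q row counts differ")
        if np.any((self.E == 0) & (self.y > 0)):
            raise ValueError("tract with E=0 but y>0: impossible under the model")
        self._components = None
        self._edges = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.q.shape[1]

    @property
    def components(self) -> list[np.ndarray]:
        if self._components is None:
            if self.graph is None:
                raise ValueError("no adjacency graph supplied")
            self._components = self.graph.connected_components()
        return self._components

    @property
    def icar_rank(self) -> int:
        """Rank of the graph Laplacian: n minus number of components."""
        return self.n - len(self.components)

    @classmethod
    def from_parts(
        cls,
        table: TractTable,
        deciles: DecileMatrix,
        expected: ExpectedCounts,
        graph: AdjacencyGraph | None = None,
    ) -> "ModelData":
        return cls(y=table.counts, E=expected.expected, q=deciles.q, graph=graph)


def ndi(q, w) -> np.ndarray:
    """Disadvantage index: per-tract weighted sum of decile scores."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    w = np.asarray(w, dtype=float)
    if q.shape[1] != len(w):
        raise ValueError(f"q has {q.shape[1]} columns but w has {len(w)} entries")
    return q @ w


def log_relative_risk(state: ParameterState, index: np.ndarray, variant: int) -> np.ndarray:
    """Linear predictor log(theta) for the requested variant."""
    eta = state.beta0 + state.beta1 * np.asarray(index, dtype=float)
    if variant == 1:
        return eta + state.u
    if variant == 2:
        return eta + state.v
    if variant == 3:
        return eta + state.u + state.v
    if variant == 4:
        return eta + state.a * state.u + (1.0 - state.a) * state.v
    raise ValueError(f"invalid variant {variant}")


def poisson_loglik(y, E, log_theta) -> float:
    """Poisson log-likelihood with offset, log y! included.

    Tracts with E=0 and y=0 contribute 0; E=0 with y>0 is an error.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    lt = np.asarray(log_theta, dtype=float)
    if np.any((E == 0) & (y > 0)):
        raise ValueError("E=0 with y>0 has zero likelihood under the model")
    ok = E > 0
    with np.errstate(divide="ignore"):
        ll = (y[ok] * (np.log(E[ok]) + lt[ok])
              - E[ok] * np.exp(lt[ok])
              - gammaln(y[ok] + 1.0))
    return float(ll.sum())


def icar_logdensity(v, tau_v: float, graph: AdjacencyGraph,
                    include_rank_term: bool = False) -> float:
    """Intrinsic CAR log-density (up to the improper-prior constant).

    Pairwise-difference form ``-(tau/2) * sum_{i~j, i<j} (v_i - v_j)^2``.
    This joint density induces the full conditional
    ``v_i | v_-i ~ Normal(mean of neighbors, 1/(tau * delta_i))``.
    With ``include_rank_term`` the term ``(rank(L)/2) * log(tau)`` is
    added — required when the density is compared across tau values
    (the scale update).
    """
    v = np.asarray(v, dtype=float)
    e = graph.edge_array()
    quad = float(np.sum((v[e[:, 0]] - v[e[:, 1]]) ** 2)) if len(e) else 0.0
    out = -0.5 * tau_v * quad
    if include_rank_term:
        n_comp = sum(1 for _ in graph.connected_components())
        out += 0.5 * (graph.n - n_comp) * np.log(tau_v)
    return out


def _log_normal_pdf(x, mean, sigma) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mean) / sigma) ** 2


def _dirichlet_logpdf(w, alpha) -> float:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0) or abs(w.sum() - 1) > 1e-8:
        return -np.inf
    return float(np.sum((alpha - 1) * np.log(w))
                 + gammaln(alpha.sum()) - gammaln(alpha).sum())


def _beta_logpdf(a, p, q) -> float:
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0) or np.any(a >= 1):
        return -np.inf
    c = gammaln(p + q) - gammaln(p) - gammaln(q)
    return float(np.sum((p - 1) * np.log(a) + (q - 1) * np.log(1 - a) + c))


def log_prior(state: ParameterState, spec: ModelSpec,
              graph: AdjacencyGraph | None = None,
              icar_rank_term: bool = True) -> float:
    """Joint log prior of a state (−inf outside the support)."""
    for s in (state.sigma_u, state.sigma_v, state.sigma1):
        if not (0 < s < spec.sigma_bound):
            return -np.inf
    lp = 0.0  # flat intercept contributes 0
    lp += float(_log_normal_pdf(state.beta1, spec.beta1_prior_mean, state.sigma1))
    if spec.fixed_weights is None:
        lp += _dirichlet_logpdf(state.w, spec.dirichlet_alpha)
    if spec.uses_u:
        lp += float(np.sum(_log_normal_pdf(state.u, 0.0, state.sigma_u)))
    if spec.uses_v:
        if graph is None:
            raise ValueError("variant with spatial effects needs an adjacency graph")
        lp += icar_logdensity(state.v, 1.0 / state.sigma_v**2, graph,
                              include_rank_term=icar_rank_term)
    if spec.uses_mixing:
        lp += _beta_logpdf(state.a, *spec.mixing_prior)
    return lp


def log_posterior(state: ParameterState, data: ModelData, spec: ModelSpec) -> float:
    lp = log_prior(state, spec, data.graph)
    if not np.isfinite(lp):
        return -np.inf
    if spec.prior_only:
        return lp
    s = ndi(data.q, state.w)
    return lp + poisson_loglik(data.y, data.E, log_relative_risk(state, s, spec.variant))


def deviance(y, E, log_theta) -> float:
    """D = -2 * Poisson log-likelihood (log y! constant included)."""
    return -2.0 * poisson_loglik(y, E, log_theta)
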