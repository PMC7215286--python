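"""Metropolis-within-Gibbs sampler for the hierarchical Poisson model.

The update cycle per iteration:

* random-walk Metropolis on the intercept and the index coefficient;
* per-coordinate random-walk on the additive-logistic transform of the
  simplex weights (Jacobian-corrected, so the Dirichlet prior is the
  stationary law in a prior-only run);
* elementwise random-walk on the unstructured effects (valid in
  parallel: given everything else the Poisson likelihood factorizes
  over tracts);
* single-site updates of the spatial effects, scheduled by a proper
  graph coloring so that no two neighbors move in the same block; the
  prior part of each acceptance ratio is exactly the intrinsic-CAR full
  conditional (neighbor mean, precision tau_v * delta_i);
* elementwise logit-scale random-walk on the mixing values (mixture
  variant);
* random-walk on each standard deviation inside its Uniform(0, bound)
  support.

After every sweep the spatial field is recentred to sum to zero per
connected component; for the pure-spatial and convolution variants the
removed level is absorbed into the intercept so the likelihood is
untouched (an exact reparameterization).  Island tracts keep v_i = 0.

Proposal scales adapt by batched Robbins–Monro toward an acceptance
rate of 0.44 and are frozen when burn-in ends, so the post-burn-in
chain is a fixed-kernel Markov chain.  All randomness flows from one
seeded PCG64 generator and the number of draws per iteration is
data-independent, making runs bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model_core import ModelData, ModelSpec, ParameterState, ndi

__all__ = ["PosteriorSamples", "run_chain", "save_samples", "load_samples"]

_ADAPT_BATCH = 50
_TARGET_ACCEPT = 0.44


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws and bookkeeping.

    ``theta`` holds the per-tract relative-risk trace (G, n) in float32
    (a memory guard for long chains); scalar traces are float64.
    ``m`` is the burn-in length and ``G`` the number of retained draws,
    the two symbols of the exceedance-probability formula.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    w: np.ndarray
    sigma_u: np.ndarray
    sigma_v: np.ndarray
    sigma1: np.ndarray
    deviance: np.ndarray
    theta: np.ndarray
    u_mean: np.ndarray
    v_mean: np.ndarray
    a_mean: np.ndarray
    acceptance: dict[str, float]
    spec: ModelSpec
    seed: int
    m: int
    thin: int
    a_trace: np.ndarray | None = None

    @property
    def G(self) -> int:
        return len(self.beta0)

    @property
    def n(self) -> int:
        return self.theta.shape[1]

    def mean_state(self) -> ParameterState:
        """Posterior means of every component entering the likelihood
        (the plug-in state used for the DIC's D(theta-bar))."""
        return ParameterState(
            beta0=float(self.beta0.mean()), beta1=float(self.beta1.mean()),
            w=self.w.mean(axis=0), u=self.u_mean.copy(), v=self.v_mean.copy(),
            a=self.a_mean.copy(),
            sigma_u=float(self.sigma_u.mean()), sigma_v=float(self.sigma_v.mean()),
            sigma1=float(self.sigma1.mean()),
        )

    def scalar_traces(self) -> dict[str, np.ndarray]:
        out = {"beta0": self.beta0, "beta1": self.beta1, "deviance": self.deviance,
               "sigma_u": self.sigma_u, "sigma_v": self.sigma_v, "sigma1": self.sigma1}
        for j in range(self.w.shape[1]):
            out[f"w{j + 1}"] = self.w[:, j]
        return out


class _Blocks:
    """Mutable sampler state: current parameters, cached linear
    predictor, proposal scales and acceptance counters."""

    def __init__(self, data: ModelData, spec: ModelSpec, rng: np.random.Generator):
        self.data = data
        self.spec = spec
        self.rng = rng
        n = data.n
        if np.any(data.E <= 0) and not spec.prior_only:
            raise ValueError(
                "sampler requires E_i > 0 for every tract; "
                "exclude zero-household tracts before fitting"
            )
        self.state = ParameterState.initial(n, spec)
        self.C = data.n_covariates
        # additive-logistic coordinates of w (last component is reference)
        self.z = np.log(self.state.w[:-1]) - np.log(self.state.w[-1])
        self.index = ndi(data.q, self.state.w)
        self.eta = self._full_eta()
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("non-finite linear predictor at initialization")
        # constant part of the log-likelihood (y log E - log y!)
        ok = data.E > 0
        self.ll_const = float(np.sum(data.y[ok] * np.log(data.E[ok]))
                              - np.sum(gammaln(data.y + 1.0)))
        if spec.uses_v and data.graph is None:
            raise ValueError("variant with spatial effects needs an adjacency graph")
        if data.graph is not None:
            self.W = data.graph.sparse_matrix()
            self.degrees = data.graph.degrees.astype(float)
            self.edges = data.graph.edge_array()
            colors = data.graph.greedy_coloring()
            self.color_classes = [np.where(colors == c)[0]
                                  for c in range(colors.max() + 1)]
            self.islands = data.graph.islands
            self.components = [c for c in data.components if len(c) > 1]
            self.icar_rank = data.icar_rank
        self.log_scales: dict[str, np.ndarray | float] = {
            "beta0": np.log(0.1), "beta1": np.log(0.05),
            "w": np.full(max(self.C - 1, 1), np.log(0.2)),
            "u": np.log(0.5), "v": np.log(0.5), "a": np.log(1.0),
            "sigma_u": np.log(0.3), "sigma_v": np.log(0.3), "sigma1": np.log(1.0),
        }
        self.acc: dict[str, float] = {k: 0.0 for k in self.log_scales}
        self.tries: dict[str, float] = {k: 0.0 for k in self.log_scales}
        self.acc_total: dict[str, float] = {k: 0.0 for k in self.log_scales}
        self.tries_total: dict[str, float] = {k: 0.0 for k in self.log_scales}
        self.batch = 0

    # -- likelihood helpers ------------------------------------------------

    def _full_eta(self) -> np.ndarray:
        from .model_core import log_relative_risk

        return log_relative_risk(self.state, self.index, self.spec.variant)

    def _ll_total(self, eta: np.ndarray) -> float:
        if self.spec.prior_only:
            return 0.0
        d = self.data
        with np.errstate(over="ignore"):
            return float(d.y @ eta - d.E @ np.exp(eta))

    def _ll_site(self, eta: np.ndarray, idx) -> np.ndarray:
        if self.spec.prior_only:
            return np.zeros(len(idx))
        d = self.data
        with np.errstate(over="ignore"):
            return d.y[idx] * eta - d.E[idx] * np.exp(eta)

    # -- bookkeeping -------------------------------------------------------

    def _record(self, name: str, accepted: float, tries: float) -> None:
        self.acc[name] += accepted
        self.tries[name] += tries
        self.acc_total[name] += accepted
        self.tries_total[name] += tries

    def adapt(self, iteration: int) -> None:
        """Batched Robbins–Monro adaptation of the proposal scales;
        called during burn-in only."""
        if (iteration + 1) % _ADAPT_BATCH:
            return
        self.batch += 1
        step = min(0.5, 2.0 / np.sqrt(self.batch))
        for name, ls in self.log_scales.items():
            if self.tries[name] > 0:
                rate = self.acc[name] / self.tries[name]
                self.log_scales[name] = ls + step * (rate - _TARGET_ACCEPT)
            self.acc[name] = 0.0
            self.tries[name] = 0.0

    def acceptance_rates(self) -> dict[str, float]:
        return {k: (self.acc_total[k] / self.tries_total[k])
                for k in self.acc_total if self.tries_total[k] > 0}

    # -- update blocks -----------------------------------------------------

    def update_fixed_effects(self) -> None:
        st, rng = self.state, self.rng
        # intercept (flat prior) — skipped in prior-only runs, where the
        # improper prior admits no stationary law for beta0
        z0, z1 = rng.standard_normal(2)
        lu0, lu1 = np.log(rng.uniform(size=2))
        if not self.spec.prior_only:
            d0 = float(np.exp(self.log_scales["beta0"])) * z0
            eta_new = self.eta + d0
            if lu0 < self._ll_total(eta_new) - self._ll_total(self.eta):
                st.beta0 += d0
                self.eta = eta_new
                self._record("beta0", 1, 1)
            else:
                self._record("beta0", 0, 1)
        d1 = float(np.exp(self.log_scales["beta1"])) * z1
        b1_new = st.beta1 + d1
        dprior = (-0.5 * ((b1_new - self.spec.beta1_prior_mean) / st.sigma1) ** 2
                  + 0.5 * ((st.beta1 - self.spec.beta1_prior_mean) / st.sigma1) ** 2)
        eta_new = self.eta + d1 * self.index
        if lu1 < dprior + self._ll_total(eta_new) - self._ll_total(self.eta):
            st.beta1 = b1_new
            self.eta = eta_new
            self._record("beta1", 1, 1)
        else:
            self._record("beta1", 0, 1)

    def update_weights(self) -> None:
        """Per-coordinate moves in additive-logistic space.

        In z-coordinates the Dirichlet prior times the simplex Jacobian
        is proportional to exp(sum_j alpha_j log w_j), which is what the
        acceptance ratio uses.
        """
        if self.spec.fixed_weights is not None:
            return
        st, rng = self.state, self.rng
        alpha = self.spec.dirichlet_alpha
        scales = np.exp(self.log_scales["w"])
        steps = rng.standard_normal(self.C - 1) * scales
        lus = np.log(rng.uniform(size=self.C - 1))
        for j in range(self.C - 1):
            z_new = self.z.copy()
            z_new[j] += steps[j]
            ez = np.exp(np.concatenate([z_new, [0.0]]) - max(z_new.max(), 0.0))
            w_new = ez / ez.sum()
            dprior = float(alpha @ (np.log(w_new) - np.log(st.w)))
            index_new = ndi(self.data.q, w_new)
            eta_new = self.eta + st.beta1 * (index_new - self.index)
            if lus[j] < dprior + self._ll_total(eta_new) - self._ll_total(self.eta):
                self.z = z_new
                st.w = w_new
                self.index = index_new
                self.eta = eta_new
                self._record("w", 1, 1)
            else:
                self._record("w", 0, 1)

    def update_random_effects(self) -> None:
        st, rng, d = self.state, self.rng, self.data
        n = d.n
        if self.spec.uses_u:
            coef = st.a if self.spec.uses_mixing else 1.0
            sc = float(np.exp(self.log_scales["u"]))
            du = rng.standard_normal(n) * sc
            lus = np.log(rng.uniform(size=n))
            u_new = st.u + du
            eta_new = self.eta + coef * du
            idx = np.arange(n)
            dll = self._ll_site(eta_new, idx) - self._ll_site(self.eta, idx)
            dpr = -0.5 * (u_new**2 - st.u**2) / st.sigma_u**2
            accept = lus < dll + dpr
            st.u = np.where(accept, u_new, st.u)
            self.eta = np.where(accept, eta_new, self.eta)
            self._record("u", accept.sum(), n)
        if self.spec.uses_v:
            tau = 1.0 / st.sigma_v**2
            coef = (1.0 - st.a) if self.spec.uses_mixing else np.ones(n)
            sc = float(np.exp(self.log_scales["v"]))
            dv_all = rng.standard_normal(n) * sc
            lus_all = np.log(rng.uniform(size=n))
            for cls in self.color_classes:
                cls = np.setdiff1d(cls, self.islands, assume_unique=True)
                if len(cls) == 0:
                    continue
                nb_sum = np.asarray(self.W @ st.v)[cls] if self.W.nnz else np.zeros(len(cls))
                v_old = st.v[cls]
                v_new = v_old + dv_all[cls]
                dpr = -0.5 * tau * (self.degrees[cls] * (v_new**2 - v_old**2)
                                    - 2.0 * (v_new - v_old) * nb_sum)
                eta_new = self.eta[cls] + coef[cls] * (v_new - v_old)
                dll = self._ll_site(eta_new, cls) - self._ll_site(self.eta[cls], cls)
                accept = lus_all[cls] < dpr + dll
                st.v[cls] = np.where(accept, v_new, v_old)
                self.eta[cls] = np.where(accept, eta_new, self.eta[cls])
                self._record("v", accept.sum(), len(cls))
            self._recentre_v()

    def _recentre_v(self) -> None:
        """Sum-to-zero per connected component.

        With a single component and unit coefficient on v (pure-spatial
        and convolution variants) the level moves into the intercept —
        an exact likelihood-invariant gauge move.  Otherwise (mixture
        variant, or several components sharing one intercept) the level
        is simply dropped and the linear predictor rebuilt; successive
        sweeps keep the removed level near zero.
        """
        st = self.state
        if not self.components:
            return
        if (self.spec.variant in (2, 3) and len(self.components) == 1
                and not self.spec.prior_only):
            comp = self.components[0]
            c = float(st.v[comp].mean())
            st.v[comp] -= c
            st.beta0 += c  # eta unchanged: intercept shift cancels v shift
            return
        changed = False
        for comp in self.components:
            c = float(st.v[comp].mean())
            if c != 0.0:
                st.v[comp] -= c
                changed = True
        if changed:
            self.refresh_eta()

    def update_mixing(self) -> None:
        if not self.spec.uses_mixing:
            return
        st, rng, d = self.state, self.rng, self.data
        p, q = self.spec.mixing_prior
        n = d.n
        sc = float(np.exp(self.log_scales["a"]))
        if self.spec.global_mixing:
            z = float(np.log(st.a[0]) - np.log1p(-st.a[0]))
            z_new = z + sc * rng.standard_normal()
            a_new = 1.0 / (1.0 + np.exp(-z_new))
            dpr = (p * (np.log(a_new) - np.log(st.a[0]))
                   + q * (np.log1p(-a_new) - np.log1p(-st.a[0])))
            eta_new = self.eta + (a_new - st.a[0]) * (st.u - st.v)
            if np.log(rng.uniform()) < dpr + self._ll_total(eta_new) - self._ll_total(self.eta):
                st.a[:] = a_new
                self.eta = eta_new
                self._record("a", 1, 1)
            else:
                self._record("a", 0, 1)
            return
        z = np.log(st.a) - np.log1p(-st.a)
        z_new = z + sc * rng.standard_normal(n)
        lus = np.log(rng.uniform(size=n))
        a_new = 1.0 / (1.0 + np.exp(-z_new))
        # Beta(p,q) prior times the logit Jacobian a(1-a)
        dpr = (p * (np.log(a_new) - np.log(st.a))
               + q * (np.log1p(-a_new) - np.log1p(-st.a)))
        eta_new = self.eta + (a_new - st.a) * (st.u - st.v)
        idx = np.arange(n)
        dll = self._ll_site(eta_new, idx) - self._ll_site(self.eta, idx)
        accept = lus < dpr + dll
        st.a = np.where(accept, a_new, st.a)
        self.eta = np.where(accept, eta_new, self.eta)
        self._record("a", accept.sum(), n)

    def update_scales(self) -> None:
        st, rng = self.state, self.rng
        bound = self.spec.sigma_bound
        z = rng.standard_normal(3)
        lu = np.log(rng.uniform(size=3))
        if self.spec.uses_u and self.spec.fixed_sigma_u is None:
            s_new = st.sigma_u + float(np.exp(self.log_scales["sigma_u"])) * z[0]
            if 0 < s_new < bound:
                ssq = float(st.u @ st.u)
                delta = (-self.data.n * (np.log(s_new) - np.log(st.sigma_u))
                         - 0.5 * ssq * (1.0 / s_new**2 - 1.0 / st.sigma_u**2))
                if lu[0] < delta:
                    st.sigma_u = s_new
                    self._record("sigma_u", 1, 1)
                else:
                    self._record("sigma_u", 0, 1)
            else:
                self._record("sigma_u", 0, 1)
        if self.spec.uses_v and self.spec.fixed_sigma_v is None:
            s_new = st.sigma_v + float(np.exp(self.log_scales["sigma_v"])) * z[1]
            if 0 < s_new < bound:
                e = self.edges
                quad = float(np.sum((st.v[e[:, 0]] - st.v[e[:, 1]]) ** 2)) if len(e) else 0.0
                delta = (-self.icar_rank * (np.log(s_new) - np.log(st.sigma_v))
                         - 0.5 * quad * (1.0 / s_new**2 - 1.0 / st.sigma_v**2))
                if lu[1] < delta:
                    st.sigma_v = s_new
                    self._record("sigma_v", 1, 1)
                else:
                    self._record("sigma_v", 0, 1)
            else:
                self._record("sigma_v", 0, 1)
        if self.spec.fixed_sigma1 is None:
            s_new = st.sigma1 + float(np.exp(self.log_scales["sigma1"])) * z[2]
            if 0 < s_new < bound:
                rsq = (st.beta1 - self.spec.beta1_prior_mean) ** 2
                delta = (-(np.log(s_new) - np.log(st.sigma1))
                         - 0.5 * rsq * (1.0 / s_new**2 - 1.0 / st.sigma1**2))
                if lu[2] < delta:
                    st.sigma1 = s_new
                    self._record("sigma1", 1, 1)
                else:
                    self._record("sigma1", 0, 1)
            else:
                self._record("sigma1", 0, 1)

    def sweep(self) -> None:
        self.update_fixed_effects()
        self.update_weights()
        self.update_random_effects()
        self.update_mixing()
        self.update_scales()

    def refresh_eta(self) -> None:
        """Rebuild the cached linear predictor to stop float drift."""
        self.eta = self._full_eta()


def run_chain(data: ModelData, spec: ModelSpec) -> PosteriorSamples:
    """Run one chain and return retained post-burn-in draws.

    Deterministic given (data, spec): the same seed yields bit-identical
    output across processes.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    blocks = _Blocks(data, spec, rng)
    n = data.n
    n_keep = (spec.iterations - spec.burn_in) // spec.thin
    beta0 = np.empty(n_keep)
    beta1 = np.empty(n_keep)
    w = np.empty((n_keep, blocks.C))
    sig_u = np.empty(n_keep)
    sig_v = np.empty(n_keep)
    sig1 = np.empty(n_keep)
    dev = np.empty(n_keep)
    theta = np.empty((n_keep, n), dtype=np.float32)
    a_trace = (np.empty((n_keep, n), dtype=np.float32)
               if spec.store_mixing_trace and spec.uses_mixing else None)
    u_sum = np.zeros(n)
    v_sum = np.zeros(n)
    a_sum = np.zeros(n)
    k = 0
    for it in range(spec.iterations):
        blocks.sweep()
        if it < spec.burn_in:
            blocks.adapt(it)
        if (it + 1) % 500 == 0:
            blocks.refresh_eta()
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            st = blocks.state
            beta0[k] = st.beta0
            beta1[k] = st.beta1
            w[k] = st.w
            sig_u[k] = st.sigma_u
            sig_v[k] = st.sigma_v
            sig1[k] = st.sigma1
            dev[k] = -2.0 * (blocks.ll_const + blocks._ll_total(blocks.eta))
            theta[k] = np.exp(np.minimum(blocks.eta, 80.0))
            if a_trace is not None:
                a_trace[k] = st.a
            u_sum += st.u
            v_sum += st.v
            a_sum += st.a
            k += 1
    if k != n_keep:  # pragma: no cover
        raise RuntimeError("retained-draw bookkeeping mismatch")
    return PosteriorSamples(
        beta0=beta0, beta1=beta1, w=w, sigma_u=sig_u, sigma_v=sig_v,
        sigma1=sig1, deviance=dev, theta=theta,
        u_mean=u_sum / n_keep, v_mean=v_sum / n_keep, a_mean=a_sum / n_keep,
        acceptance=blocks.acceptance_rates(), spec=spec, seed=spec.seed,
        m=spec.burn_in, thin=spec.thin, a_trace=a_trace,
    )


def save_samples(samples: PosteriorSamples, path) -> None:
    """Persist draws plus spec snapshot and acceptance ledger (npz)."""
    arrays = dict(
        beta0=samples.beta0, beta1=samples.beta1, w=samples.w,
        sigma_u=samples.sigma_u, sigma_v=samples.sigma_v, sigma1=samples.sigma1,
        deviance=samples.deviance, theta=samples.theta,
        u_mean=samples.u_mean, v_mean=samples.v_mean, a_mean=samples.a_mean,
        meta=np.array(json.dumps({
            "spec": samples.spec.to_dict(),
            "acceptance": samples.acceptance,
            "seed": samples.seed, "m": samples.m, "thin": samples.thin,
        })),
    )
    if samples.a_trace is not None:
        arrays["a_trace"] = samples.a_trace
    np.savez_compressed(path, **arrays)


def load_samples(path) -> PosteriorSamples:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return PosteriorSamples(
            beta0=z["beta0"], beta1=z["beta1"], w=z["w"],
            sigma_u=z["sigma_u"], sigma_v=z["sigma_v"], sigma1=z["sigma1"],
            deviance=z["deviance"], theta=z["theta"],
            u_mean=z["u_mean"], v_mean=z["v_mean"], a_mean=z["a_mean"],
            acceptance=meta["acceptance"], spec=ModelSpec.from_dict(meta["spec"]),
            seed=meta["seed"], m=meta["m"], thin=meta["thin"],
            a_trace=z["a_trace"] if "a_trace" in z.files else None,
        )
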