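"""Convergence checks, model comparison, interval summaries, hotspot
detection and result export.

Convergence is assessed with the Geweke diagnostic: a z-score comparing
the mean of an early segment of a chain with the mean of a late segment,
using spectral-density-at-zero variance estimates so autocorrelation is
accounted for; |z| < 2 is read as consistent with convergence.

Model comparison uses the deviance information criterion
DIC = mean(D) + pD with effective parameter count
pD = mean(D) - D(theta-bar); a drop of 10 or more is treated as a
meaningful improvement in fit.

Tracts are flagged as significantly elevated when the posterior
exceedance probability q_ic = (1/G) * sum_g I(theta_i^(g) > c) exceeds a
cutoff (defaults c = 1, cutoff 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelData, log_relative_risk, ndi, deviance as model_deviance
from .sampler import PosteriorSamples

__all__ = [
    "FitSummary",
    "geweke_z",
    "geweke_converged",
    "dic",
    "dic_meaningful_improvement",
    "credible_interval",
    "exceedance_probabilities",
    "equal_weight_threshold",
    "summarize_fit",
    "export_results",
]

DIC_MEANINGFUL_DELTA = 10.0
GEWEKE_THRESHOLD = 2.0
EXCEEDANCE_C = 1.0
EXCEEDANCE_CUTOFF = 0.90


def equal_weight_threshold(n_covariates: int) -> float:
    """Interpretation threshold for index weights.

    If every covariate contributed equally each weight would be
    1/C (0.083 for a 12-variable index); estimated weights above this
    mark variables that explain more than their share of the
    index–outcome association.
    """
    return 1.0 / n_covariates


def _spectral_variance_at_zero(x: np.ndarray) -> float:
    """Lag-windowed estimate of the spectral density at frequency zero.

    Bartlett window with truncation lag proportional to sqrt(length) —
    a standard choice; the diagnostic itself does not prescribe one.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    lag_max = max(1, int(np.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for k in range(1, lag_max + 1):
        gamma_k = float(xc[k:] @ xc[:-k]) / n
        s += 2.0 * (1.0 - k / (lag_max + 1)) * gamma_k
    return max(s, 0.0)


def geweke_z(trace, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for one scalar chain.

    z = (mean of first `first` fraction - mean of last `last` fraction)
    over the square root of the summed spectral variances of the two
    segments.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 100:
        raise ValueError("geweke_z: trace shorter than 100 draws")
    if x.std() == 0:
        raise ValueError("geweke_z: zero-variance trace; z undefined")
    n = len(x)
    a = x[: int(np.floor(first * n))]
    b = x[n - int(np.floor(last * n)):]
    var_a = _spectral_variance_at_zero(a) / len(a)
    var_b = _spectral_variance_at_zero(b) / len(b)
    denom = np.sqrt(var_a + var_b)
    if denom == 0:
        raise ValueError("geweke_z: zero spectral variance in both segments")
    return float((a.mean() - b.mean()) / denom)


def geweke_converged(z: float, threshold: float = GEWEKE_THRESHOLD) -> bool:
    return abs(z) < threshold


def dic(deviance_trace, deviance_at_means: float) -> tuple[float, float]:
    """(DIC, pD) from a deviance trace and the plug-in deviance.

    pD = mean(D) - D(theta-bar); DIC = mean(D) + pD, equivalently
    D(theta-bar) + 2 pD.
    """
    dbar = float(np.asarray(deviance_trace, dtype=float).mean())
    pd_ = dbar - float(deviance_at_means)
    return dbar + pd_, pd_


def dic_meaningful_improvement(dic_smaller: float, dic_larger: float,
                               delta: float = DIC_MEANINGFUL_DELTA) -> bool:
    """True when the first DIC improves on the second by at least
    `delta` (default 10)."""
    return (dic_larger - dic_smaller) >= delta


def credible_interval(trace, level: float = 0.95,
                      null_value: float | None = None):
    """Equal-tailed credible interval, optionally with a significance
    flag.

    With ``null_value`` given (1 for relative-risk scale parameters),
    the estimate is flagged significant iff the interval does not
    contain that value; containment is inclusive, so a degenerate
    interval [1, 1] is not significant.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("credible_interval: empty trace")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    if null_value is None:
        return float(lo), float(hi)
    significant = not (lo <= null_value <= hi)
    return float(lo), float(hi), significant


def exceedance_probabilities(theta_trace, c: float = EXCEEDANCE_C,
                             cutoff: float = EXCEEDANCE_CUTOFF):
    """Per-tract exceedance probabilities and elevated-risk flags.

    q_ic is the fraction of retained draws with theta_i > c; tracts with
    q_ic > cutoff are flagged.
    """
    t = np.atleast_2d(np.asarray(theta_trace, dtype=float))
    q = (t > c).mean(axis=0)
    return q, q > cutoff


@dataclass
class FitSummary:
    """Posterior summaries of one fitted model."""

    params: pd.DataFrame
    dic: float
    pd: float
    mean_deviance: float
    deviance_at_means: float
    theta_mean: np.ndarray
    exceedance: np.ndarray
    elevated: np.ndarray
    geweke: dict[str, float] = field(default_factory=dict)
    variant: int = 0

    @property
    def all_converged(self) -> bool:
        return all(geweke_converged(z) for z in self.geweke.values())


def summarize_fit(samples: PosteriorSamples, data: ModelData,
                  c: float = EXCEEDANCE_C,
                  cutoff: float = EXCEEDANCE_CUTOFF,
                  level: float = 0.95) -> FitSummary:
    """Full posterior summary: parameter table, Geweke z per monitored
    scalar, DIC/pD (plug-in deviance at the posterior-mean state), and
    exceedance-based hotspot flags."""
    spec = samples.spec
    rows = []
    traces = samples.scalar_traces()
    # relative risk per unit of the index
    traces = {**traces, "rr_beta1": np.exp(samples.beta1)}
    for name, tr in traces.items():
        lo, hi = credible_interval(tr, level)
        row = {"parameter": name, "mean": float(np.mean(tr)),
               "sd": float(np.std(tr, ddof=1)), "lower": lo, "upper": hi}
        if name == "rr_beta1":
            row["significant"] = bool(credible_interval(tr, level, null_value=1.0)[2])
        rows.append(row)
    params = pd.DataFrame(rows).set_index("parameter")

    mean_state = samples.mean_state()
    index = ndi(data.q, mean_state.w)
    lt_bar = log_relative_risk(mean_state, index, spec.variant)
    d_at_means = model_deviance(data.y, data.E, lt_bar)
    dbar = float(samples.deviance.mean())
    dic_val, pd_val = dic(samples.deviance, d_at_means)

    geweke = {}
    monitored = ["beta0", "beta1", "deviance"]
    if spec.fixed_weights is None:
        monitored += [f"w{j + 1}" for j in range(samples.w.shape[1])]
    for name in monitored:
        tr = samples.scalar_traces()[name]
        if len(tr) >= 100 and tr.std() > 0:
            geweke[name] = geweke_z(tr)

    q, flags = exceedance_probabilities(samples.theta, c=c, cutoff=cutoff)
    return FitSummary(
        params=params, dic=dic_val, pd=pd_val, mean_deviance=dbar,
        deviance_at_means=d_at_means,
        theta_mean=samples.theta.mean(axis=0).astype(float),
        exceedance=q, elevated=flags, geweke=geweke, variant=spec.variant,
    )


def export_results(summary: FitSummary, tract_ids, out_prefix,
                   polygons=None, covariate_names=None) -> dict[str, str]:
    """Write per-tract and weight tables (CSV) and, when polygons are
    supplied, a GeoJSON with posterior relative risks and hotspot flags
    as feature properties.

    Returns a dict of the written file paths.
    """
    import os

    tract_ids = np.asarray(tract_ids, dtype=str)
    if len(tract_ids) != len(summary.theta_mean):
        raise ValueError("tract id count does not match fitted tract count")
    written = {}
    tract_df = pd.DataFrame({
        "tract_id": tract_ids,
        "theta_mean": summary.theta_mean,
        "exceedance": summary.exceedance,
        "elevated": summary.elevated.astype(int),
    })
    tract_path = f"{out_prefix}_tracts.csv"
    tract_df.to_csv(tract_path, index=False)
    written["tracts"] = tract_path

    wrows = summary.params.loc[[p for p in summary.params.index
                                if p.startswith("w")], :].copy()
    wrows["important"] = wrows["mean"] > equal_weight_threshold(len(wrows))
    if covariate_names is not None and len(covariate_names) == len(wrows):
        wrows.insert(0, "variable", list(covariate_names))
    weights_path = f"{out_prefix}_weights.csv"
    wrows.to_csv(weights_path)
    written["weights"] = weights_path

    if polygons is not None:
        missing = [t for t in tract_ids if t not in polygons]
        if missing:
            raise ValueError(f"tracts missing from polygon set: {missing[:10]}")
        from .tract_io import write_geojson_polygons

        props = {
            t: {"theta_mean": float(tract_df.theta_mean.iloc[i]),
                "exceedance": float(tract_df.exceedance.iloc[i]),
                "elevated": int(tract_df.elevated.iloc[i])}
            for i, t in enumerate(tract_ids)
        }
        geo_path = f"{out_prefix}_risk.geojson"
        write_geojson_polygons({t: polygons[t] for t in tract_ids}, geo_path,
                               properties=props)
        written["geojson"] = geo_path
    return written
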