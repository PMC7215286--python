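"""Covariate orientation, decile scoring, offsets and spatial screening.

Raw socioeconomic covariates enter the disadvantage index as decile
scores so that variables on different scales contribute comparably, the
influence of outliers is limited, and survey-estimate noise is coarsened
away.  Before scoring, each variable is oriented so that larger values
correspond to the hypothesized direction of disadvantage: amount-type
variables (income, rent, housing cost) are inverted as ``max(x) - x_i``
and proportion-type variables are complemented as ``1 - x_i``.

Expected counts ``E_i = r * h_i`` — the study-wide events-per-household
rate times a tract's households — serve as the Poisson offset that turns
the model's per-tract parameter into a relative risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tract_io import AdjacencyGraph, TractTable

__all__ = [
    "DecileMatrix",
    "ExpectedCounts",
    "invert_scale",
    "complement_proportion",
    "decile_scores",
    "apply_orientation",
    "filter_missing",
    "expected_counts",
    "outcome_rates",
    "moran_i",
    "suggest_orientation",
]

ORIENTATIONS = ("identity", "invert", "complement")


@dataclass
class DecileMatrix:
    """Integer decile scores (0–9) per tract and covariate.

    The 0–9 coding makes the weighted index range over [0, 9]: a tract in
    the lowest decile of every variable contributes nothing to the index.
    """

    q: np.ndarray
    orientation: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, dtype=np.int64))
        if self.q.min(initial=0) < 0 or self.q.max(initial=0) > 9:
            raise ValueError("decile scores must lie in 0..9")
        if not self.orientation:
            self.orientation = ["identity"] * self.q.shape[1]
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.q.shape[1])]

    @property
    def n(self) -> int:
        return self.q.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.q.shape[1]


@dataclass
class ExpectedCounts:
    """Overall rate and per-tract expected counts E_i = r * h_i."""

    rate: float
    expected: np.ndarray

    def __post_init__(self) -> None:
        self.expected = np.asarray(self.expected, dtype=float)
        if np.any(self.expected < 0):
            raise ValueError("expected counts must be non-negative")


def invert_scale(values) -> np.ndarray:
    """Orient an amount-type variable: ``out_i = max(x) - x_i``.

    The maximum maps to 0 and the order is reversed, so that e.g. lower
    income becomes higher inverse income (more disadvantage).
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size == 0:
        raise ValueError("invert_scale: all values missing")
    return np.nanmax(v) - v


def complement_proportion(values) -> np.ndarray:
    """Orient a proportion-type variable: ``out_i = 1 - x_i``."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (v < 0) | (v > 1)
    if np.any(bad & ~np.isnan(v)):
        raise ValueError("complement_proportion: values outside [0, 1]")
    return 1.0 - v


def decile_scores(values) -> np.ndarray:
    """Empirical decile scores 0–9.

    Scores are assigned by cutting at the 10%, 20%, …, 90% empirical
    quantiles; tied values share their block's score, the lowest block
    scoring 0.  The scoring is monotone and invariant to strictly
    monotone transforms of the input.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("decile_scores: missing values present; filter first")
    if v.size < 10:
        warnings.warn(
            f"decile scoring with only {v.size} values; boundaries are coarse",
            stacklevel=2,
        )
    cuts = np.quantile(v, np.arange(1, 10) / 10.0)
    # side='left' puts a value equal to a boundary in the lower block,
    # so ties always share one score
    return np.searchsorted(cuts, v, side="left").astype(np.int64)


def apply_orientation(x: np.ndarray, orientation: list[str]) -> np.ndarray:
    """Apply per-column orientation transforms to a covariate matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if len(orientation) != x.shape[1]:
        raise ValueError("orientation length does not match covariate count")
    out = np.empty_like(x)
    for j, mode in enumerate(orientation):
        if mode == "identity":
            out[:, j] = x[:, j]
        elif mode == "invert":
            out[:, j] = invert_scale(x[:, j])
        elif mode == "complement":
            out[:, j] = complement_proportion(x[:, j])
        else:
            raise ValueError(f"unknown orientation {mode!r}; use one of {ORIENTATIONS}")
    return out


def score_covariates(
    table: TractTable, orientation: list[str] | None = None
) -> DecileMatrix:
    """Orient then decile-score every covariate of a (filtered) table."""
    orientation = orientation or ["identity"] * table.n_covariates
    oriented = apply_orientation(table.x, orientation)
    q = np.column_stack([decile_scores(oriented[:, j]) for j in range(oriented.shape[1])])
    return DecileMatrix(q=q, orientation=list(orientation),
                        covariate_names=list(table.covariate_names))


def filter_missing(table: TractTable) -> tuple[TractTable, list[dict]]:
    """Drop tracts with any missing covariate cell.

    Returns the filtered table and an exclusion report listing, per
    removed tract, its id and the names of the missing variables.
    """
    mask = table.missing_mask
    report = []
    for i in np.where(mask)[0]:
        missing_vars = [table.covariate_names[j]
                        for j in np.where(np.isnan(table.x[i]))[0]]
        report.append({"tract_id": str(table.tract_id[i]), "missing": missing_vars})
    return table.subset(~mask), report


def expected_counts(y, h) -> ExpectedCounts:
    """Expected counts from the overall events-per-household rate.

    r = Σy / Σh and E_i = r·h_i, so that Σ E_i = Σ y_i exactly — the
    internal standardization that makes relative risks average to 1.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    total_h = h.sum()
    if total_h <= 0:
        raise ValueError("expected_counts: total households must be positive")
    r = float(y.sum() / total_h)
    return ExpectedCounts(rate=r, expected=r * h)


def outcome_rates(y, h) -> tuple[np.ndarray, list[int]]:
    """Per-tract crude rates y_i / h_i.

    Tracts with zero households are excluded from the rate vector and
    reported by index.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    excluded = np.where(h == 0)[0].tolist()
    keep = h > 0
    return y[keep] / h[keep], excluded


def moran_i(
    values,
    graph: AdjacencyGraph,
    permutations: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    row_standardized: bool = False,
) -> tuple[float, float]:
    """Moran's I with a permutation p-value.

    I = (n / S0) * (z' W z) / (z' z) with binary symmetric weights W
    (row-standardized available by flag) and z the centred values.  The
    pseudo p-value is (#{permuted I at least as extreme} + 1) /
    (permutations + 1), one-sided 'greater' by default.
    """
    v = np.asarray(values, dtype=float)
    if v.std() == 0:
        raise ValueError("moran_i: constant values; statistic undefined")
    if permutations < 99:
        raise ValueError("moran_i: use at least 99 permutations")
    W = graph.sparse_matrix()
    if row_standardized:
        deg = np.maximum(graph.degrees, 1)
        from scipy import sparse

        W = sparse.diags(1.0 / deg) @ W
    s0 = W.sum()
    n = len(v)

    def stat(z):
        zc = z - z.mean()
        return float(n / s0 * (zc @ (W @ zc)) / (zc @ zc))

    i_obs = stat(v)
    rng = np.random.default_rng(seed)
    perm = np.empty(permutations)
    for k in range(permutations):
        perm[k] = stat(rng.permutation(v))
    if alternative == "greater":
        extreme = np.sum(perm >= i_obs)
    elif alternative == "less":
        extreme = np.sum(perm <= i_obs)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(perm) >= abs(i_obs))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (extreme + 1) / (permutations + 1)
    return i_obs, float(p)


def suggest_orientation(
    table: TractTable,
    proportion_like: list[bool] | None = None,
) -> list[str]:
    """Suggest per-variable orientations from univariate score statistics.

    For each covariate the sign of the score statistic of a univariate
    Poisson model (counts vs the standardized covariate, household
    offset) decides: a negative association suggests re-orienting the
    variable (``complement`` if it looks like a proportion in [0, 1],
    else ``invert``).  A convenience for analysts, not a substitute for
    subject-matter judgement; pass the result to ``score_covariates``
    explicitly.
    """
    y = table.counts.astype(float)
    h = table.households.astype(float)
    e = expected_counts(y, h).expected
    out = []
    for j in range(table.n_covariates):
        x = table.x[:, j]
        ok = ~np.isnan(x) & (h > 0)
        xs = (x[ok] - np.nanmean(x[ok]))
        score = float(np.sum(xs * (y[ok] - e[ok])))  # Poisson score at beta=0
        if score >= 0:
            out.append("identity")
        else:
            is_prop = (proportion_like[j] if proportion_like is not None
                       else bool(np.nanmin(x) >= 0 and np.nanmax(x) <= 1))
            out.append("complement" if is_prop else "invert")
    return out
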