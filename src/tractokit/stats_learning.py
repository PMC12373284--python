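"""Statistics and learning utilities for tidy tract-profile tables.

Four independent pieces:

* a per-node ordinary-least-squares group model with BH-FDR correction
  across the nodes of one (tract, metric) pair;
* median imputation applied within train and test sets separately;
* the exponential learning-curve model
  ``R2(x) = alpha - (alpha - beta) * exp(-(x - x_min) / kappa)``, where
  alpha is pinned to the best observed score and (beta, kappa) are fitted
  by nonlinear least squares — kappa is the number of additional training
  samples at which 63% (1 - 1/e) of the alpha-beta gap is attained;
* 1-D augmentation operators (jitter, scaling, time-warping) for
  samples x nodes x channels profile tensors, each parametrized by a
  single magnitude scaled to the per-channel value range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import truncnorm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PointwiseResult",
    "LearningCurveFit",
    "pointwise_group_model",
    "bh_fdr",
    "median_impute",
    "learning_curve",
    "fit_learning_curve",
    "augment",
]


# ---------------------------------------------------------------------------
# Per-node group model


@dataclass
class PointwiseResult:
    """Per-node OLS group-term estimates with FDR-corrected rejections."""

    tract_name: str
    metric: str
    estimates: np.ndarray      # group coefficient per node
    std_errors: np.ndarray
    pvalues: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray       # boolean mask after BH-FDR
    alpha: float
    group_levels: tuple        # (reference, tested)

    def __post_init__(self):
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, tuple, list]:
    """Intercept + group indicator + numeric/encoded covariates."""
    levels = tuple(sorted(cov["group"].astype(str).unique()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    group = (cov["group"].astype(str) == levels[1]).to_numpy(dtype=float)
    cols = [np.ones(len(cov)), group]
    names = ["intercept", "group"]
    for name in cov.columns:
        if name in ("subject_id", "group"):
            continue
        col = cov[name]
        if col.dtype.kind in "biufc":
            cols.append(col.to_numpy(dtype=float))
        else:
            vals = sorted(col.astype(str).unique())
            if len(vals) > 2:
                raise ValueError(f"covariate '{name}' must be numeric or binary")
            cols.append((col.astype(str) == vals[-1]).to_numpy(dtype=float))
        names.append(name)
    return np.column_stack(cols), levels, names


def pointwise_group_model(
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    tract_name: str,
    metric: str,
    alpha: float = 0.05,
) -> PointwiseResult:
    """Fit ``value ~ group + covariates`` by OLS at every node.

    ``profiles`` is a tidy long table (subject_id, tract_name, node_id,
    metric, value); ``covariates`` has one row per subject with a binary
    ``group`` column plus any further covariates (e.g. age, sex).  The
    reported p-value per node is the two-sided t-test on the group
    coefficient; rejections come from BH-FDR at ``alpha`` across the nodes
    of this (tract, metric) pair.  The design matrix is shared across
    nodes, so all fits are solved in one pass of the normal equations.
    """
    sub = profiles[(profiles["tract_name"] == tract_name) & (profiles["metric"] == metric)]
    if sub.empty:
        raise ValueError(f"no rows for tract '{tract_name}', metric '{metric}'")
    wide = sub.pivot(index="subject_id", columns="node_id", values="value")
    nodes = sorted(wide.columns)
    missing = wide.columns[wide.isna().any()].tolist()
    if missing:
        raise ValueError(f"nodes with missing observations: {missing}")

    cov = covariates.set_index("subject_id").loc[wide.index].reset_index()
    for g, cnt in cov["group"].value_counts().items():
        if cnt < 2:
            raise ValueError(f"group '{g}' has fewer than 2 observations")
    X, levels, _ = _design_matrix(cov)
    Y = wide[nodes].to_numpy(dtype=float)          # (n_subj, n_nodes)

    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                        # (p, n_nodes)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])

    est = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    constant = np.ptp(Y, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} node(s) have a constant response; p set to 1",
            stacklevel=2,
        )
        est = np.where(constant, 0.0, est)
        pvals = np.where(constant, 1.0, pvals)

    rejected, p_adj = bh_fdr(pvals, alpha)
    return PointwiseResult(
        tract_name=tract_name,
        metric=metric,
        estimates=est,
        std_errors=se,
        pvalues=pvals,
        p_adjusted=p_adj,
        rejected=rejected,
        alpha=alpha,
        group_levels=levels,
    )


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over the supplied p-value family.

    Returns ``(rejected mask, adjusted p-values)``; empty input gives
    empty output.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


# ---------------------------------------------------------------------------
# Median imputation


def median_impute(train: pd.DataFrame, test: pd.DataFrame,
                  columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace NaNs with each set's OWN per-feature median.

    Train medians never leak into the test set.  A feature entirely
    missing within a set raises an error naming the feature.
    """
    out = []
    for label, table in (("train", train), ("test", test)):
        table = table.copy()
        cols = columns if columns is not None else [
            c for c in table.columns if table[c].dtype.kind in "biufc"
        ]
        for c in cols:
            if table[c].isna().all():
                raise ValueError(f"feature '{c}' is entirely missing in the {label} set")
            table[c] = table[c].fillna(table[c].median())
        out.append(table)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Exponential learning curve


@dataclass
class LearningCurveFit:
    """Fitted exponential learning curve.

    ``alpha`` is the highest observed score (pinned, not fitted);
    ``beta`` the fitted score at the smallest training size ``x_min``;
    ``kappa`` the rate parameter in training-sample units: at
    ``x = x_min + kappa`` the curve has closed 1 - 1/e (~63%) of the
    alpha-beta gap.
    """

    alpha: float
    beta: float
    kappa: float
    x_min: float
    rss: float

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.x_min <= 0:
            raise ValueError("x_min must be positive")

    def predict(self, x) -> np.ndarray:
        return learning_curve(x, self.alpha, self.beta, self.kappa, self.x_min)


def learning_curve(x, alpha: float, beta: float, kappa: float, x_min: float):
    """``alpha - (alpha - beta) * exp(-(x - x_min) / kappa)``."""
    x = np.asarray(x, dtype=float)
    return alpha - (alpha - beta) * np.exp(-(x - x_min) / kappa)


def fit_learning_curve(sizes, scores, alpha: float | None = None) -> LearningCurveFit:
    """Fit (beta, kappa) of the exponential learning curve to score data.

    ``alpha`` is pinned, not fitted: by default to the highest observed
    score, or to a caller-supplied asymptote when one is known (e.g. a
    generator's true asymptote, or a plateau estimated from much larger
    runs).  The observed-max rule slightly underestimates the asymptote —
    and hence kappa — whenever the largest size still sits on the rising
    part of the curve.  ``x_min`` is the smallest size.  (beta, kappa) are
    found by nonlinear least squares with multiple kappa starts (x_min,
    2*x_min, max(sizes)) and a positivity bound on kappa; the lowest-RSS
    solution wins.
    """
    sizes = np.asarray(sizes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if sizes.shape != scores.shape or sizes.ndim != 1:
        raise ValueError("sizes and scores must be 1-D arrays of equal length")
    if len(np.unique(sizes)) < 3:
        raise ValueError("need at least 3 distinct training sizes")
    alpha = float(scores.max()) if alpha is None else float(alpha)
    x_min = float(sizes.min())

    def residuals(params):
        beta, kappa = params
        return learning_curve(sizes, alpha, beta, kappa, x_min) - scores

    best = None
    diagnostics = []
    for kappa0 in (x_min, 2.0 * x_min, float(sizes.max())):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[float(scores.min()), kappa0],
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            )
        except Exception as exc:
            diagnostics.append(f"start kappa={kappa0}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"start kappa={kappa0}: {sol.message}")
            continue
        rss = float((sol.fun ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("learning-curve fit failed from all starts: " + "; ".join(diagnostics))
    rss, (beta, kappa) = best
    return LearningCurveFit(alpha=alpha, beta=float(beta), kappa=float(kappa),
                            x_min=x_min, rss=rss)


# ---------------------------------------------------------------------------
# Augmentation


def _channel_ranges(tensor: np.ndarray) -> np.ndarray:
    return np.ptp(tensor, axis=(0, 1))


def augment(tensor, op: str, magnitude: float, seed: int,
            ranges=None) -> np.ndarray:
    """Apply a 1-D augmentation to a (samples, nodes, channels) tensor.

    ``magnitude`` is a single number scaled to each channel's value range
    (a channel being one tract/metric pair):

    * ``jitter`` — add iid Gaussian noise, SD = magnitude * channel range;
    * ``scaling`` — per sample and channel, multiply deviations from the
      channel mean by a factor drawn from a unit-mean normal with SD
      ``magnitude``, truncated at 0;
    * ``timewarp`` — per sample, displace 4 interior knots of the node
      axis by N(0, magnitude), build a monotone piecewise-linear warp with
      fixed endpoints, and re-interpolate each channel.

    ``magnitude = 0`` is the identity for all three; shape is preserved.
    """
    x = np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"tensor must be (samples, nodes, channels), got {x.shape}")
    if magnitude < 0:
        raise ValueError(f"magnitude must be >= 0, got {magnitude}")
    if magnitude == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    n_samp, n_nodes, n_chan = x.shape

    if op == "jitter":
        ranges = _channel_ranges(x) if ranges is None else np.asarray(ranges, dtype=float)
        noise = rng.normal(size=x.shape) * (magnitude * ranges)[None, None, :]
        return x + noise

    if op == "scaling":
        a = (0.0 - 1.0) / magnitude  # truncate the factor distribution at 0
        factors = truncnorm.rvs(a, np.inf, loc=1.0, scale=magnitude,
                                size=(n_samp, n_chan), random_state=rng)
        mean = x.mean(axis=(0, 1))
        return mean + factors[:, None, :] * (x - mean)

    if op == "timewarp":
        u = np.linspace(0.0, 1.0, n_nodes)
        knots = np.linspace(0.0, 1.0, 6)
        out = np.empty_like(x)
        eps = 1e-6
        for s in range(n_samp):
            displaced = knots.copy()
            displaced[1:-1] += rng.normal(0.0, magnitude, size=4)
            displaced[1:-1] = np.sort(np.clip(displaced[1:-1], eps, 1.0 - eps))
            warped = np.interp(u, knots, displaced)   # monotone, endpoints fixed
            for c in range(n_chan):
                out[s, :, c] = np.interp(warped, u, x[s, :, c])
        return out

    raise ValueError(f"unknown augmentation op: {op!r}")
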