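"""Between-array quantile normalization, empirical-Bayes batch adjustment,
and a PCA-based batch check for log2 expression matrices.

The batch adjustment is the parametric empirical-Bayes procedure commonly
known as ComBat: features are standardized, per-batch additive (gamma) and
multiplicative (delta) effects are estimated, shrunk toward batch-level
priors (normal for gamma, inverse-gamma for delta, moment-matched), and
removed.  No covariates enter the standardization model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_core import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean distribution of order statistics.

    After normalization the sorted values of every column equal the
    across-column mean of order statistics; within-column rank order is
    preserved.  Tied values within a column receive the mean of the
    order-statistic means across their tied ranks.
    """
    X = matrix.values
    n_feat, n_samp = X.shape
    if n_samp < 2:
        log.warning("quantile_normalize: single column, returning input unchanged")
        return ExpressionMatrix(matrix.data.copy())
    mean_order = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_feat)
        assigned[order] = mean_order
        sorted_vals = col[order]
        # Average assigned values over runs of tied input values.
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        sums = np.add.reduceat(mean_order, starts)
        lengths = np.diff(np.concatenate((starts, [n_feat])))
        tied_means = sums / lengths
        group_of = np.repeat(np.arange(len(starts)), lengths)
        assigned[order] = tied_means[group_of]
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids)
    )


@dataclass
class BatchModel:
    """Estimated and shrunk batch-effect parameters (one column per batch)."""

    batches: list[str]
    gamma_hat: pd.DataFrame
    delta_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    gamma_bar: dict[str, float]
    tau2: dict[str, float]
    a_prior: dict[str, float]
    b_prior: dict[str, float]

    def __post_init__(self) -> None:
        if (self.delta_star.to_numpy() <= 0).any():
            raise ValidationError("shrunk batch scale parameters must be positive")


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _eb_iterate(
    Z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior-mode iteration for one batch's gamma*/delta*."""
    n = Z.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (tau2 * n * gamma_hat + delta * gamma_bar) / (tau2 * n + delta)
        ssq = ((Z - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(gamma_new - gamma).max() / max(np.abs(gamma).max(), 1e-12),
            np.abs(delta_new - delta).max() / max(np.abs(delta).max(), 1e-12),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta


def combat_adjust(
    matrix: ExpressionMatrix, batches: Mapping[str, str]
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove additive and multiplicative batch effects (parametric EB).

    ``batches`` maps every sample id to a batch label; every batch needs at
    least two samples for its scale to be estimable.  With a single batch
    the data are returned unchanged (to numerical tolerance) together with a
    model whose shrunk effects are null.
    """
    samples = matrix.sample_ids
    missing = [s for s in samples if s not in batches]
    if missing:
        raise ValidationError(f"samples without batch label: {missing[:3]}")
    labels = np.array([str(batches[s]) for s in samples])
    batch_names = [str(b) for b in sorted(set(labels))]
    counts = {b: int((labels == b).sum()) for b in batch_names}
    for b, c in counts.items():
        if c < 2:
            raise ValidationError(f"batch {b!r} has {c} sample(s); need >= 2")

    X = matrix.values.astype(float)
    n_feat, n_samp = X.shape
    masks = {b: labels == b for b in batch_names}

    batch_means = np.column_stack([X[:, masks[b]].mean(axis=1) for b in batch_names])
    weights = np.array([counts[b] / n_samp for b in batch_names])
    grand_mean = batch_means @ weights
    fit = np.zeros_like(X)
    for k, b in enumerate(batch_names):
        fit[:, masks[b]] = batch_means[:, [k]]
    var_pooled = ((X - fit) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd_pooled = np.sqrt(var_pooled)

    Z = (X - grand_mean[:, None]) / sd_pooled[:, None]

    gamma_hat = np.column_stack([Z[:, masks[b]].mean(axis=1) for b in batch_names])
    delta_hat = np.column_stack(
        [Z[:, masks[b]].var(axis=1, ddof=1) for b in batch_names]
    )
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    gamma_bar, tau2, a_prior, b_prior = {}, {}, {}, {}
    if len(batch_names) == 1:
        gamma_star[:] = 0.0
        delta_star[:] = 1.0
        b0 = batch_names[0]
        gamma_bar[b0], tau2[b0] = 0.0, 0.0
        a_prior[b0] = b_prior[b0] = float("nan")
        adjusted = X.copy()
    else:
        for k, b in enumerate(batch_names):
            gbar = float(gamma_hat[:, k].mean())
            t2 = float(gamma_hat[:, k].var(ddof=1))
            a = _aprior(delta_hat[:, k])
            bp = _bprior(delta_hat[:, k])
            g_star, d_star = _eb_iterate(
                Z[:, masks[b]], gamma_hat[:, k], delta_hat[:, k], gbar, t2, a, bp
            )
            gamma_star[:, k], delta_star[:, k] = g_star, d_star
            gamma_bar[b], tau2[b], a_prior[b], b_prior[b] = gbar, t2, a, bp
            log.info(
                "combat batch %s: gamma_bar=%.4g tau2=%.4g a=%.4g b=%.4g",
                b, gbar, t2, a, bp,
            )
        adjusted = np.empty_like(X)
        for k, b in enumerate(batch_names):
            adjusted[:, masks[b]] = (
                (Z[:, masks[b]] - gamma_star[:, [k]]) / np.sqrt(delta_star[:, [k]])
            ) * sd_pooled[:, None] + grand_mean[:, None]

    features = matrix.feature_ids
    model = BatchModel(
        batches=batch_names,
        gamma_hat=pd.DataFrame(gamma_hat, index=features, columns=batch_names),
        delta_hat=pd.DataFrame(delta_hat, index=features, columns=batch_names),
        gamma_star=pd.DataFrame(gamma_star, index=features, columns=batch_names),
        delta_star=pd.DataFrame(np.maximum(delta_star, 1e-12),
                                index=features, columns=batch_names),
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
    )
    out = ExpressionMatrix(pd.DataFrame(adjusted, index=features, columns=samples))
    return out, model


@dataclass
class PcaBatchReport:
    """Kruskal-Wallis association of leading principal components with batch."""

    applicable: bool
    n_components: int
    p_values: list[float]
    flagged: list[bool]
    threshold: float = 0.01

    @property
    def any_flagged(self) -> bool:
        return any(self.flagged)


def pca_batch_check(
    matrix: ExpressionMatrix,
    batches: Mapping[str, str],
    n_components: int = 5,
    threshold: float = 0.01,
) -> PcaBatchReport:
    """Centered sample-space PCA; flag components whose scores associate with batch.

    Uses ``k = min(n_components, n_samples - 1)`` components and a
    Kruskal-Wallis test of each component's scores against batch labels,
    flagging p below ``threshold``.  With a single batch the check is not
    applicable.
    """
    samples = matrix.sample_ids
    if len(samples) < 3:
        raise ValidationError("PCA batch check needs >= 3 samples")
    labels = [str(batches[s]) for s in samples]
    if len(set(labels)) < 2:
        return PcaBatchReport(False, 0, [], [], threshold)
    k = min(n_components, len(samples) - 1)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(matrix.values.T)
    p_values: list[float] = []
    for j in range(k):
        groups = {}
        for lab, val in zip(labels, scores[:, j]):
            groups.setdefault(lab, []).append(val)
        try:
            _, p = stats.kruskal(*groups.values())
        except ValueError:  # all scores identical in a degenerate component
            p = 1.0
        p_values.append(float(p))
    flagged = [p < threshold for p in p_values]
    if any(flagged):
        log.warning("PCA batch check: %d/%d component(s) associated with batch",
                    sum(flagged), k)
    return PcaBatchReport(True, k, p_values, flagged, threshold)
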