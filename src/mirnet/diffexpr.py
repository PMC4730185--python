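"""Paired tumor-vs-adjacent differential expression with empirical-Bayes
moderated t-statistics, Benjamini-Hochberg FDR, and the |FC|/FDR filter.

The model is a one-sample moderated t on within-patient log2 differences:
per-feature sample variances s2 are assumed to follow a scaled F
distribution around a prior variance s0^2 with d0 prior degrees of freedom;
(d0, s0^2) are fitted by moment-matching the log sample variances
(digamma/trigamma equations).  The moderated variance is

    s_tilde^2 = (d0 * s0^2 + (n - 1) * s2) / (d0 + n - 1)

and t = mean / sqrt(s_tilde^2 / n) is referred to a t distribution with
d0 + n - 1 degrees of freedom.  Fold changes are reported with the signed
linear convention: -1.67 means 1.67-fold lower in tumor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, PairedDesign, ValidationError


def paired_differences(
    matrix: ExpressionMatrix, design: PairedDesign
) -> pd.DataFrame:
    """Within-patient log2 differences (tumor minus adjacent), features x patients.

    Columns are looked up by sample id, so the matrix's column order is
    irrelevant.
    """
    for p in design.patient_ids:
        for col in (design.tumor_col[p], design.adjacent_col[p]):
            if col not in matrix.data.columns:
                raise ValidationError(f"patient {p!r}: sample {col!r} missing from matrix")
    tumor = matrix.data[[design.tumor_col[p] for p in design.patient_ids]].to_numpy()
    adjacent = matrix.data[[design.adjacent_col[p] for p in design.patient_ids]].to_numpy()
    return pd.DataFrame(tumor - adjacent, index=matrix.feature_ids,
                        columns=design.patient_ids)


@dataclass(frozen=True)
class EBPrior:
    """Shrinkage hyperparameters: prior df d0 (may be +inf) and prior variance s0^2.

    d0 = 0 is accepted as the no-shrinkage limit (ordinary t)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("prior degrees of freedom must be >= 0")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValidationError("prior variance must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        raise ValidationError("trigamma inverse needs a positive argument")
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi,
                                 xtol=1e-12, rtol=1e-12))


def fit_eb_prior(s2: np.ndarray, df: int) -> EBPrior:
    """Moment-match the scaled-F model to observed per-feature variances.

    Works on z = log s2: under the model, z - digamma(df/2) + log(df/2) has
    mean log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the trigamma(df/2) sampling floor.  When the
    empirical variance does not exceed that floor, d0 = +inf (all variances
    shrunk fully to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        raise ValidationError("need >= 2 positive variances to fit the prior")
    if df < 1:
        raise ValidationError("residual degrees of freedom must be >= 1")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return EBPrior(d0=math.inf, s0_sq=math.exp(emean))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(emean + float(special.digamma(half_d0)) - math.log(half_d0))
    return EBPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(diffs: pd.DataFrame, prior: EBPrior) -> pd.DataFrame:
    """Per-feature moderated t on paired differences.

    Returns a DataFrame indexed by feature with columns log2fc, fold_change,
    s2, t, df, p.  d0 = 0 gives the ordinary one-sample t; d0 = +inf fully
    shrinks every variance to s0^2 (large-df, normal-like reference).
    """
    n = diffs.shape[1]
    if n < 2:
        raise ValidationError("moderated t needs >= 2 patients")
    X = diffs.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    d0 = prior.d0
    if math.isinf(d0):
        s_tilde2 = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s_tilde2 = (d0 * prior.s0_sq + (n - 1) * s2) / (d0 + n - 1)
        df_total = d0 + n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s_tilde2 / n)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    fold_change = np.sign(mean) * np.exp2(np.abs(mean))
    fold_change = np.where(mean == 0, 1.0, fold_change)
    return pd.DataFrame(
        {
            "log2fc": mean,
            "fold_change": fold_change,
            "s2": s2,
            "t": t,
            "df": df_total,
            "p": p,
        },
        index=diffs.index,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach BH q-values and the strict |FC| > fc AND q < fdr call.

    Both inequalities are strict: a fold change of exactly the threshold is
    not differentially expressed.
    """
    if fc_threshold <= 0 or q_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    out = results.copy()
    if "q" not in out.columns:
        out["q"] = bh_fdr(out["p"].to_numpy())
    out["is_de"] = (np.abs(out["fold_change"]) > fc_threshold) & (
        out["q"] < q_threshold
    )
    return out


def de_analysis(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full paired DE: differences -> prior fit -> moderated t -> BH -> filter."""
    diffs = paired_differences(matrix, design)
    prior = fit_eb_prior(diffs.to_numpy().var(axis=1, ddof=1), df=diffs.shape[1] - 1)
    results = moderated_t(diffs, prior)
    results["q"] = bh_fdr(results["p"].to_numpy())
    return de_filter(results, fc_threshold, q_threshold)
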