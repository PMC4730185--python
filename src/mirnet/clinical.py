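"""Association of miRNAs and relevant targets with clinical covariates.

Categorical covariates use the Kruskal-Wallis rank-sum test on tumor-column
expression; relapse uses the log-rank test (expression dichotomized at its
median) and a univariate Cox proportional-hazards model (expression
continuous).  BH FDR is computed per covariate across features and flagged
at q < 0.2.  Missing ("unknown") clinical values are dropped test-wise,
never imputed.

The Cox fit is a scalar Newton maximization of the Breslow partial
likelihood; it also reports the score test at beta = 0, which on tie-free
data with a binary covariate coincides with the log-rank chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .diffexpr import bh_fdr
from .io_core import (
    CLINICAL_CATEGORICAL,
    ClinicalTable,
    ExpressionMatrix,
    PairedDesign,
    ValidationError,
)

log = logging.getLogger(__name__)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Midrank Kruskal-Wallis H with tie correction; p from chi-square(k-1).

    Rows with a missing value or group label are dropped pairwise.  If every
    remaining value is identical, H is 0 by convention (complete ties) with
    p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = np.isfinite(values) & np.array([g is not None and g == g for g in groups])
    values, groups = values[keep], groups[keep]
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 non-empty groups")
    samples = [values[groups == lab] for lab in labels]
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def logrank(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; chi-square statistic with 1 df.

    Requires at least one observed event overall after missing-data removal.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.asarray(groups, dtype=object)
    keep = (
        np.isfinite(time)
        & np.isfinite(event)
        & np.array([g is not None and g == g for g in groups])
    )
    time, event, groups = time[keep], event[keep], groups[keep]
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValidationError("log-rank needs exactly 2 groups")
    if event.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    a = groups == labels[0]
    res = logrank_test(time[a], time[~a], event_observed_A=event[a],
                       event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    se: float
    p: float
    score_chi2: float
    n: int
    n_events: int


def _cox_score_info(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Breslow log partial likelihood, score and information at beta."""
    order = np.argsort(time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    eta = beta * xv
    eta -= eta.max()  # overflow guard; constants cancel in all three outputs
    w = np.exp(eta)
    # Suffix sums: risk set of an event at t_i is {j : t_j >= t_i}.
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]
    # For tied times the risk set starts at the first index of the tie group.
    first = np.searchsorted(t, t, side="left")
    ev = d > 0
    f = first[ev]
    ll = float((eta[ev] - np.log(s0[f])).sum())
    score = float((xv[ev] - s1[f] / s0[f]).sum())
    info = float((s2[f] / s0[f] - (s1[f] / s0[f]) ** 2).sum())
    return ll, score, info


def cox_ph(time, event, covariate, max_iter: int = 100,
           tol: float = 1e-8) -> CoxResult:
    """Univariate Cox proportional hazards (Breslow ties, Newton iterations).

    Returns the hazard ratio per unit covariate, a two-sided Wald p, and the
    score chi-square at beta = 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    x = np.asarray(covariate, dtype=float)
    keep = np.isfinite(time) & np.isfinite(event) & np.isfinite(x)
    time, event, x = time[keep], event[keep], x[keep]
    if event.sum() < 1:
        raise ValidationError("Cox model needs at least one event")
    if np.all(x == x[0]):
        raise ValidationError("covariate is constant")
    x_center = x - x.mean()

    _, u0, i0 = _cox_score_info(0.0, time, event, x_center)
    if i0 <= 0:
        raise ValidationError("covariate carries no information at beta = 0")
    score_chi2 = u0 * u0 / i0

    beta = 0.0
    for _ in range(max_iter):
        ll, u, i = _cox_score_info(beta, time, event, x_center)
        if abs(u) < tol:
            break
        if i <= 0:
            raise ValidationError("non-positive information during Newton iteration")
        step = u / i
        # Step-halving to keep the partial likelihood from diverging.
        new_beta = beta + step
        for _ in range(30):
            ll_new, _, _ = _cox_score_info(new_beta, time, event, x_center)
            if ll_new >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta = new_beta
    else:
        raise ValidationError("Cox Newton iteration did not converge")
    _, _, info = _cox_score_info(beta, time, event, x_center)
    se = 1.0 / np.sqrt(info)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return CoxResult(
        beta=float(beta), hr=float(np.exp(beta)), se=float(se), p=float(p),
        score_chi2=float(score_chi2), n=len(x), n_events=int(event.sum()),
    )


def associate_features(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    clinical: ClinicalTable,
    feature_subset: list[str],
    q_threshold: float = 0.2,
) -> pd.DataFrame:
    """Associate each feature's tumor expression with every clinical covariate.

    Dispatch: relapse -> log-rank (median-split expression) and Cox
    (continuous expression); all other covariates -> Kruskal-Wallis.  BH FDR
    is computed per (covariate, test) across features; significance is
    flagged at q < ``q_threshold``.  Features or covariates whose test is
    degenerate (e.g. entirely missing) are skipped with a log entry.
    """
    if not feature_subset:
        return pd.DataFrame(
            columns=["feature_id", "covariate", "test", "statistic", "p", "q",
                     "effect", "significant"]
        )
    clinical.validate_against(design)
    patients = clinical.patient_ids
    tumor_cols = [design.tumor_col[p] for p in patients]
    rows: list[dict] = []
    for feature in feature_subset:
        if feature not in matrix.data.index:
            raise ValidationError(f"feature {feature!r} missing from matrix")
        expr = matrix.data.loc[feature, tumor_cols].to_numpy(float)
        for cov in CLINICAL_CATEGORICAL:
            labels = clinical.table[cov].to_numpy(object)
            if pd.isna(labels).all():
                log.info("covariate %s entirely missing; skipped", cov)
                continue
            try:
                h, p = kruskal_wallis(expr, labels)
            except ValidationError as exc:
                log.info("kruskal %s ~ %s skipped: %s", feature, cov, exc)
                continue
            rows.append(dict(feature_id=feature, covariate=cov, test="kruskal",
                             statistic=h, p=p, effect=np.nan))
        time = clinical.table["relapse_time"].to_numpy(float)
        event = clinical.table["relapse_event"].to_numpy(float)
        try:
            split = np.where(expr > np.median(expr), "high", "low")
            chi2, p = logrank(time, event, split)
            rows.append(dict(feature_id=feature, covariate="relapse", test="logrank",
                             statistic=chi2, p=p, effect=np.nan))
        except ValidationError as exc:
            log.info("logrank %s skipped: %s", feature, exc)
        try:
            cox = cox_ph(time, event, expr)
            rows.append(dict(feature_id=feature, covariate="relapse", test="cox",
                             statistic=cox.beta / cox.se, p=cox.p, effect=cox.hr))
        except ValidationError as exc:
            log.info("cox %s skipped: %s", feature, exc)

    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["covariate", "test"]).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out[["feature_id", "covariate", "test", "statistic", "p", "q",
                "effect", "significant"]]
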