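"""Pre-ranked gene-set enrichment: weighted running-sum statistic,
gene-sampling permutation null, NES, FDR, and leading-edge extraction.

The enrichment score walks the ranked list in order: at a member ("hit") the
running sum rises by |score|^weight normalized by the total hit weight, at a
non-member it falls by 1/(N - n_hits); the ES is the running sum's maximal
deviation from zero.  Because no phenotype labels exist for an externally
ranked list, the null is formed by random gene sets of the same size drawn
without replacement from the list.  When the number of distinct sets of that
size does not exceed the permutation budget the null is enumerated
exhaustively, and the nominal p then equals the exact permutation tail
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import RankedGeneList
from .io_core import GeneSetCollection, ValidationError

log = logging.getLogger(__name__)


@dataclass
class GseaResult:
    set_id: str
    size: int
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    leading_edge: tuple[str, ...]

    @property
    def direction(self) -> int:
        return 1 if self.es >= 0 else -1


def enrichment_score(
    ranked: RankedGeneList,
    set_members,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Running-sum enrichment score, the full walk, and the leading edge.

    The leading edge contains the hits at or before the extremum for a
    positive ES, and at or after it for a negative ES.  If every hit carries
    zero weight (possible for the sparse combined metric) the hit increments
    fall back to uniform 1/n_hits so the walk stays defined.
    """
    members = set(set_members)
    genes = ranked.genes
    n = len(genes)
    hits = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValidationError("gene set has no member in the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the whole ranked list")
    weights = np.abs(ranked.scores) ** weight_exponent
    hit_w = np.where(hits, weights, 0.0)
    total_w = hit_w.sum()
    if total_w > 0:
        increments = hit_w / total_w
    else:
        increments = np.where(hits, 1.0 / n_hits, 0.0)
    increments = increments - (~hits) / (n - n_hits)
    running = np.cumsum(increments)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if running[imax] >= -running[imin]:
        es = float(running[imax])
        lead_mask = hits & (np.arange(n) <= imax)
    else:
        es = float(running[imin])
        lead_mask = hits & (np.arange(n) >= imin)
    leading = list(genes[lead_mask])
    return es, running, leading


def _es_from_positions(
    abs_weights: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many gene-set placements given sorted hit positions.

    ``positions`` is (n_sets, k), ascending within each row.  Only the
    running-sum values just after each hit (local maxima candidates) and just
    before each hit (local minima candidates), plus the zero start, can be
    the extremum.
    """
    k = positions.shape[1]
    w = abs_weights[positions]
    W = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    uniform = (np.arange(1, k + 1) / k)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cum_frac = np.where(W > 0, cum / np.where(W > 0, W, 1.0), uniform)
    miss_frac = (positions - np.arange(k)[None, :]) / (n - k)
    top = cum_frac - miss_frac
    prev = np.concatenate([np.zeros((len(positions), 1)), cum_frac[:, :-1]], axis=1)
    bottom = prev - miss_frac
    es_pos = np.maximum(top.max(axis=1), 0.0)
    es_neg = np.minimum(bottom.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def _null_es(
    abs_weights: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: str = "auto",
) -> tuple[np.ndarray, bool]:
    """Null ES distribution for sets of size k; returns (es values, exhaustive?)."""
    n = len(abs_weights)
    n_distinct = comb(n, k)
    if exhaustive == "always" or (exhaustive == "auto" and n_distinct <= n_perm):
        positions = np.array(list(combinations(range(n), k)), dtype=np.intp)
        return _es_from_positions(abs_weights, positions, n), True
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    positions = np.sort(idx, axis=1)
    return _es_from_positions(abs_weights, positions, n), False


def preranked_gsea(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 2,
    seed: int = 0,
    exhaustive: str = "auto",
) -> list[GseaResult]:
    """Enrichment of every gene set against one ranked list.

    Per set: ES as above; null = ES of ``n_perm`` random same-size gene sets
    (or all distinct sets when few enough); nominal p = one-sided tail
    fraction among same-sign null ES (add-one smoothed when sampled, exact
    when enumerated); NES = ES / mean(|same-sign null ES|).  The FDR q is the
    GSEA-style ratio of pooled-null to observed NES tail fractions, clipped
    to [0, 1] and monotonized by a cumulative minimum within each sign so a
    weaker |NES| never gets a smaller q.  Deterministic under ``seed``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for FDR reporting")
    if not len(collection):
        log.warning("preranked_gsea: empty collection")
        return []
    rng = np.random.default_rng(seed)
    genes_in_list = set(ranked.genes)
    n = len(ranked.genes)
    abs_weights = np.abs(ranked.scores) ** weight_exponent

    records = []
    null_nes_pool: list[np.ndarray] = []
    for set_id in sorted(collection.sets):
        members = [g for g in collection.sets[set_id] if g in genes_in_list]
        size = len(members)
        if size < min_size:
            log.info("set %s skipped: %d members in list (< %d)",
                     set_id, size, min_size)
            continue
        if size == n:
            log.info("set %s skipped: covers the whole list", set_id)
            continue
        es, _, leading = enrichment_score(ranked, members, weight_exponent)
        null, was_exhaustive = _null_es(abs_weights, size, n_perm, rng, exhaustive)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        # tolerance so mathematically tied null ES (computed by a different
        # vectorized path) count as ties rather than falling a ulp short
        eps = 1e-12 * max(1.0, abs(es))
        if es >= 0:
            same = pos_null
            tail = int((same >= es - eps).sum())
        else:
            same = neg_null
            tail = int((same <= es + eps).sum())
        if len(same) == 0:
            p_nominal, nes = 1.0, 0.0
        else:
            if was_exhaustive:
                p_nominal = tail / len(same)
            else:
                p_nominal = (1 + tail) / (1 + len(same))
            mean_same = float(np.abs(same).mean())
            nes = es / mean_same if mean_same > 0 else 0.0
        # Normalize the null the same way to build the pooled NES null.
        null_nes = np.zeros_like(null)
        if len(pos_null) and np.abs(pos_null).mean() > 0:
            null_nes[null >= 0] = pos_null / np.abs(pos_null).mean()
        if len(neg_null) and np.abs(neg_null).mean() > 0:
            null_nes[null < 0] = neg_null / np.abs(neg_null).mean()
        null_nes_pool.append(null_nes)
        records.append((set_id, size, es, nes, p_nominal, leading))

    if not records:
        return []
    pooled = np.concatenate(null_nes_pool)
    obs_nes = np.array([r[3] for r in records])
    results: list[GseaResult] = []
    q_values = np.ones(len(records))
    for i, (set_id, size, es, nes, p_nominal, leading) in enumerate(records):
        if nes >= 0:
            num_pool = pooled[pooled >= 0]
            obs_side = obs_nes[obs_nes >= 0]
            num = (num_pool >= nes).mean() if len(num_pool) else 0.0
            den = (obs_side >= nes).mean() if len(obs_side) else 1.0
        else:
            num_pool = pooled[pooled < 0]
            obs_side = obs_nes[obs_nes < 0]
            num = (num_pool <= nes).mean() if len(num_pool) else 0.0
            den = (obs_side <= nes).mean() if len(obs_side) else 1.0
        q_values[i] = min(1.0, num / den) if den > 0 else 0.0
    # Cumulative-minimum monotonization within each sign, weakest |NES| first.
    for sign_mask in (obs_nes >= 0, obs_nes < 0):
        idx = np.flatnonzero(sign_mask)
        order = idx[np.argsort(np.abs(obs_nes[idx]), kind="stable")]
        running_min = np.inf
        for i in order:
            running_min = min(running_min, q_values[i])
            q_values[i] = running_min
    for i, (set_id, size, es, nes, p_nominal, leading) in enumerate(records):
        results.append(
            GseaResult(set_id, size, es, nes, float(p_nominal),
                       float(q_values[i]), tuple(leading))
        )
    return results


def core_enrichment(result: GseaResult) -> list[str]:
    """The core enrichment (leading-edge) genes of one enrichment result."""
    return list(result.leading_edge)


def results_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p_nominal for r in results],
            "q": [r.q_fdr for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )


def write_results(results: list[GseaResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
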