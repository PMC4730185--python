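"""Integration logic: dual-program consensus, combined correlation x
prediction ranking metric, relevant-target selection, target-overlap counts,
and pathway-group consolidation and ranking.

A miRNA survives the consensus filter only when its predicted-target set is
significantly enriched (GSEA FDR below threshold, strict) against *both*
prediction programs.  The combined ranking metric multiplies the negative
Spearman correlation by the min-subtracted prediction score, promoting genes
that are both predicted and anti-correlated.  Pathway enrichments are
consolidated to pathway groups and categories through the hierarchy and
ranked by count with the stated tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .correlate import RankedGeneList
from .gsea import GseaResult
from .io_core import PathwayHierarchy, ValidationError


@dataclass(frozen=True)
class ConsensusDecision:
    mirna_id: str
    q_program1: float
    q_program2: float
    selected: bool


def consensus_filter(
    results_by_program: Mapping[str, Mapping[str, float]],
    threshold: float = 1e-3,
) -> list[ConsensusDecision]:
    """Keep miRNAs whose enrichment FDR is strictly below threshold in both programs.

    Both programs must report every candidate miRNA; a miRNA present in only
    one program is an input error, not a rejection.
    """
    programs = sorted(results_by_program)
    if len(programs) != 2:
        raise ValidationError(f"consensus needs exactly 2 programs, got {programs}")
    q1, q2 = (results_by_program[p] for p in programs)
    only = set(q1).symmetric_difference(q2)
    if only:
        raise ValidationError(
            f"miRNA(s) reported by one program only: {sorted(only)[:3]}"
        )
    decisions = []
    for mirna_id in sorted(q1):
        a, b = float(q1[mirna_id]), float(q2[mirna_id])
        decisions.append(
            ConsensusDecision(mirna_id, a, b, a < threshold and b < threshold)
        )
    return decisions


def normalize_scores(scores: Mapping[str, float]) -> dict[str, float]:
    """Shift prediction scores so the minimum over genes is exactly zero."""
    if not scores:
        raise ValidationError("cannot normalize an empty score map")
    m = min(scores.values())
    return {g: float(s) - m for g, s in scores.items()}


def combined_metric(
    neg_corr: Mapping[str, float],
    norm_score: Mapping[str, float],
    mirna_id: str = "",
) -> RankedGeneList:
    """Product of negative correlation and normalized prediction score.

    Genes missing a prediction score receive normalized score 0 (their raw
    score is taken as the table minimum), zeroing their metric.  The list
    covers every gene with a defined correlation.
    """
    if not neg_corr:
        raise ValidationError("empty correlation map")
    if not set(neg_corr) & set(norm_score):
        raise ValidationError("correlation and prediction domains do not overlap")
    metric = {g: float(c) * float(norm_score.get(g, 0.0)) for g, c in neg_corr.items()}
    # hashed tie-break: the metric's large zero block must not share a tie
    # order across different miRNAs' lists (see RankedGeneList.from_scores)
    return RankedGeneList.from_scores(mirna_id, metric, "combined_metric",
                                      tie_break="hashed")


def select_relevant_targets(
    mirna_direction: str,
    de_genes: pd.DataFrame,
    core_set: Iterable[str],
) -> list[str]:
    """Core-enrichment genes that are DE in the direction opposite the miRNA.

    An up-regulated miRNA represses its targets, so its relevant targets are
    the down-regulated DE genes of the core set, and vice versa.
    """
    if mirna_direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {mirna_direction!r}")
    want_sign = -1 if mirna_direction == "up" else 1
    out = []
    for gene in core_set:
        if gene not in de_genes.index:
            continue
        row = de_genes.loc[gene]
        if bool(row["is_de"]) and (1 if row["fold_change"] > 0 else -1) == want_sign:
            out.append(gene)
    return out


@dataclass
class OverlapResult:
    """Exact Venn-region counts: exclusive region sizes keyed by miRNA subset."""

    regions: dict[tuple[str, ...], int]
    union_size: int

    def count(self, *mirnas: str) -> int:
        return self.regions.get(tuple(sorted(mirnas)), 0)


def target_overlaps(target_lists: Mapping[str, Iterable[str]]) -> OverlapResult:
    """Exclusive Venn-region counts over every non-empty miRNA subset."""
    if not target_lists:
        raise ValidationError("need at least one target list")
    sets = {m: set(v) for m, v in target_lists.items()}
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for gene in union:
        signature = tuple(sorted(m for m, s in sets.items() if gene in s))
        regions[signature] = regions.get(signature, 0) + 1
    return OverlapResult(regions, len(union))


@dataclass
class PathwayGroupRow:
    """One pathway group's enrichment summary: per-miRNA count and FDR range."""

    group_id: str
    category_id: str
    per_mirna: dict[str, tuple[int, float, float]]  # mirna -> (count, qmin, qmax)
    rank: int | None = None

    def count(self, mirna_id: str) -> int:
        return self.per_mirna.get(mirna_id, (0, float("nan"), float("nan")))[0]

    def total(self, panel: Iterable[str]) -> int:
        return sum(self.count(m) for m in panel)

    def min_fdr(self, panel: Iterable[str]) -> float:
        qs = [self.per_mirna[m][1] for m in panel
              if m in self.per_mirna and self.per_mirna[m][0] > 0]
        return min(qs) if qs else float("inf")


def consolidate_pathways(
    gsea_by_mirna: Mapping[str, list[GseaResult]],
    hierarchy: PathwayHierarchy,
    fdr_threshold: float = 0.2,
) -> list[PathwayGroupRow]:
    """Count pathways with q <= threshold per (group, miRNA), with FDR ranges.

    Groups with zero enriched pathways across all miRNAs are omitted.  Every
    pathway id in the enrichment results must be present in the hierarchy.
    """
    known = hierarchy.pathway_ids
    rows: dict[str, PathwayGroupRow] = {}
    for mirna_id, results in gsea_by_mirna.items():
        for res in results:
            if res.set_id not in known:
                raise ValidationError(f"pathway {res.set_id!r} absent from hierarchy")
            if res.q_fdr > fdr_threshold:
                continue
            group = hierarchy.group_of(res.set_id)
            row = rows.get(group)
            if row is None:
                row = PathwayGroupRow(group, hierarchy.category_of_group(group), {})
                rows[group] = row
            count, qmin, qmax = row.per_mirna.get(mirna_id, (0, res.q_fdr, res.q_fdr))
            row.per_mirna[mirna_id] = (
                count + 1, min(qmin, res.q_fdr), max(qmax, res.q_fdr)
            )
    return sorted(rows.values(), key=lambda r: r.group_id)


def rank_pathway_groups(
    rows: list[PathwayGroupRow], panel: list[str]
) -> list[PathwayGroupRow]:
    """Total order over one direction's pathway groups.

    Primary key: total pathway count across the panel's miRNAs, descending.
    Ties: groups with at least one pathway enriched in *all* panel miRNAs
    first, then smaller minimum FDR, then lexicographic group id (the final
    determinism guarantee).  Returns new rows with 1-based ranks assigned.
    """
    def key(row: PathwayGroupRow):
        all_flag = all(row.count(m) > 0 for m in panel)
        return (-row.total(panel), not all_flag, row.min_fdr(panel), row.group_id)

    ranked = []
    for rank, row in enumerate(sorted(rows, key=key), start=1):
        ranked.append(
            PathwayGroupRow(row.group_id, row.category_id, dict(row.per_mirna), rank)
        )
    return ranked


def order_categories(ranked_rows: list[PathwayGroupRow]) -> list[str]:
    """Categories ordered by their best-ranked pathway group."""
    best: dict[str, int] = {}
    for row in ranked_rows:
        if row.rank is not None:
            best[row.category_id] = min(best.get(row.category_id, 10 ** 9), row.rank)
    return sorted(best, key=lambda c: best[c])


def pathway_groups_to_frame(
    ranked_rows: list[PathwayGroupRow], panel: list[str]
) -> pd.DataFrame:
    """Flat table of ranked pathway groups (one column triple per miRNA)."""
    records = []
    for row in ranked_rows:
        rec: dict[str, object] = {
            "category_id": row.category_id,
            "group_id": row.group_id,
            "rank": row.rank,
            "total": row.total(panel),
        }
        for m in panel:
            count, qmin, qmax = row.per_mirna.get(m, (0, float("nan"), float("nan")))
            rec[f"{m}_count"] = count
            rec[f"{m}_fdr_min"] = qmin
            rec[f"{m}_fdr_max"] = qmax
        records.append(rec)
    return pd.DataFrame(records)
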