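"""Spearman correlation between miRNAs and genes, and ranked gene lists.

For every differentially expressed miRNA the genes are ranked by their
negative Spearman correlation with the miRNA across all tumor and adjacent
columns pooled (a config switch allows tumor-only columns as a sensitivity
analysis).  Constant-expression genes have undefined rank correlation and
are dropped from the list rather than parked mid-list at rho = 0.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes ordered by a real-valued score, descending; ties broken by gene id."""

    mirna_id: str
    genes: np.ndarray
    scores: np.ndarray
    semantics: str = "neg_correlation"  # or "combined_metric"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")

    @classmethod
    def from_scores(
        cls,
        mirna_id: str,
        scores: dict[str, float],
        semantics: str,
        tie_break: str = "lexicographic",
    ) -> "RankedGeneList":
        """Sort descending by score with a deterministic tie-break.

        ``tie_break="lexicographic"`` orders tied genes by id -- fine for
        correlation scores, where ties are rare.  ``tie_break="hashed"``
        orders ties by a stable hash of (list id, gene id): still fully
        reproducible, but the tie order differs between lists and carries no
        shared structure.  This matters for the zero-inflated combined
        metric, where a lexicographic tie block identical across every
        miRNA's list would let gene sets skewed toward early ids mimic
        enrichment coherently across a whole panel.
        """
        if tie_break == "lexicographic":
            def token(gene: str) -> str:
                return gene
        elif tie_break == "hashed":
            def token(gene: str) -> str:
                return hashlib.blake2s(
                    f"{mirna_id}:{gene}".encode(), digest_size=8
                ).hexdigest()
        else:
            raise ValidationError(f"unknown tie_break {tie_break!r}")
        items = sorted(scores.items(), key=lambda kv: (-kv[1], token(kv[0])))
        genes = np.array([g for g, _ in items], dtype=object)
        vals = np.array([v for _, v in items], dtype=float)
        return cls(mirna_id, genes, vals, semantics)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, "score": self.scores})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, mirna_id: str, semantics: str = "neg_correlation"
    ) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        return cls(mirna_id, df["gene_id"].to_numpy(object),
                   df["score"].to_numpy(float), semantics)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on midranks).

    Rejects constant vectors, whose rank correlation is undefined; callers
    ranking whole matrices drop such features instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman_rho needs two equal-length vectors, n >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValidationError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1)


def neg_correlation_ranking(
    mirna_id: str,
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    samples: list[str] | None = None,
) -> RankedGeneList:
    """Rank all genes by -rho(miRNA, gene), most negatively correlated first.

    Sample columns of the two matrices are aligned by id; by default every
    shared column (tumor and adjacent pooled) is used.  Genes with constant
    expression are excluded with a logged count.
    """
    if samples is None:
        shared = set(mrna_matrix.sample_ids)
        samples = [s for s in mirna_matrix.sample_ids if s in shared]
    if not samples:
        raise ValidationError("no shared samples between the two matrices")
    if mirna_id not in mirna_matrix.data.index:
        raise ValidationError(f"unknown miRNA {mirna_id!r}")
    x = mirna_matrix.data.loc[mirna_id, samples].to_numpy(float)
    if len(np.unique(x)) < 2:
        raise ValidationError(f"miRNA {mirna_id!r} has constant expression")
    G = mrna_matrix.data[samples].to_numpy(float)
    variable = np.ptp(G, axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        log.info("neg_correlation_ranking(%s): dropped %d constant gene(s)",
                 mirna_id, n_dropped)
    gene_ids = np.asarray(mrna_matrix.feature_ids, dtype=object)[variable]
    R = _rank_rows(G[variable])
    rx = stats.rankdata(x)
    rx_c = rx - rx.mean()
    R_c = R - R.mean(axis=1, keepdims=True)
    denom = np.sqrt((R_c ** 2).sum(axis=1)) * np.sqrt((rx_c ** 2).sum())
    rho = (R_c @ rx_c) / denom
    scores = dict(zip(gene_ids, -rho))
    return RankedGeneList.from_scores(mirna_id, scores, "neg_correlation")


def mirna_pair_correlations(
    mirna_matrix: ExpressionMatrix, mirna_ids: list[str]
) -> pd.DataFrame:
    """Symmetric table of pairwise Spearman rho over all sample columns."""
    if len(mirna_ids) < 2:
        raise ValidationError("need >= 2 miRNAs for pairwise correlation")
    unknown = [m for m in mirna_ids if m not in mirna_matrix.data.index]
    if unknown:
        raise ValidationError(f"unknown miRNA id(s): {unknown}")
    X = mirna_matrix.data.loc[mirna_ids].to_numpy(float)
    R = _rank_rows(X)
    C = np.corrcoef(R)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=mirna_ids, columns=mirna_ids)
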