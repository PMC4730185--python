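"""End-to-end orchestration of the integrative miRNA-target analysis.

Stage order: preprocess (quantile normalization, optional batch adjustment,
PCA batch check) -> paired differential expression (miRNA and gene) ->
negative-correlation ranking for DE miRNAs -> target-set GSEA against two
prediction programs -> dual-program consensus -> combined metric + pathway
GSEA -> pathway-group consolidation and ranking -> relevant-target overlaps
-> clinical association.  Every stochastic stage draws its seed
deterministically from the single run seed, so re-running an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clinical as clinical_mod
from .correlate import RankedGeneList, neg_correlation_ranking
from .diffexpr import de_analysis
from .gsea import GseaResult, preranked_gsea, results_to_frame, write_results
from .integrate import (
    combined_metric,
    consensus_filter,
    consolidate_pathways,
    normalize_scores,
    pathway_groups_to_frame,
    rank_pathway_groups,
    select_relevant_targets,
    target_overlaps,
)
from .io_core import (
    GeneSetCollection,
    ValidationError,
    read_clinical,
    read_design,
    read_gmt,
    read_hierarchy,
    read_matrix,
    read_predictions,
    write_matrix,
)
from .preprocess import combat_adjust, pca_batch_check, quantile_normalize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat, auditable configuration of one pipeline run."""

    mirna_matrix: str = ""
    mrna_matrix: str = ""
    design: str = ""
    predictions_a: str = ""
    predictions_b: str = ""
    program_a: str = "programA"
    program_b: str = "programB"
    gene_sets: str = ""
    hierarchy: str = ""
    clinical: str = ""
    outdir: str = "run"
    fc_threshold: float = 1.5
    de_fdr: float = 0.05
    consensus_fdr: float = 1e-3
    pathway_fdr: float = 0.2
    clinical_fdr: float = 0.2
    n_perm: int = 1000
    weight_exponent: float = 1.0
    # The combined metric is zero-inflated (genes without a prediction score
    # have metric 0); with a weighted statistic any set containing a single
    # nonzero-weight gene walks to ES ~ 1, so the pathway stage defaults to
    # the unweighted statistic, where the signal lives in the ranks.
    pathway_weight_exponent: float = 0.0
    seed: int = 0
    run_quantile: bool = True
    combat_mirna: bool = True
    combat_mrna: bool = False
    run_clinical: bool = True

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "de_fdr", "consensus_fdr", "pathway_fdr",
                     "clinical_fdr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in dataclasses.asdict(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValidationError(f"unknown config key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = raw.lower() in ("true", "1", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(raw)
                elif isinstance(current, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def sha256(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage_seed(base_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage seed below 2**31, derived from the run seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}:{item}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.txt")
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "versions": {
            "mirnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    try:
        mirna = read_matrix(config.mirna_matrix)
        mrna = read_matrix(config.mrna_matrix)
        design = read_design(config.design)
        design.validate_against(mirna)
        design.validate_against(mrna)

        # --- preprocess ---------------------------------------------------
        if config.run_quantile:
            mirna = quantile_normalize(mirna)
            mrna = quantile_normalize(mrna)
        if config.combat_mirna:
            mirna, _ = combat_adjust(mirna, design.batch)
        if config.combat_mrna:
            mrna, _ = combat_adjust(mrna, design.batch)
        report = pca_batch_check(mirna, design.batch)
        write_matrix(mirna, outdir / "mirna_preprocessed.tsv")
        write_matrix(mrna, outdir / "mrna_preprocessed.tsv")
        with open(outdir / "pca_batch_report.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=1)
        record("preprocess", mirna_features=mirna.shape[0],
               mrna_features=mrna.shape[0],
               pca_flagged=int(sum(report.flagged)))

        # --- differential expression --------------------------------------
        de_mirna = de_analysis(mirna, design, config.fc_threshold, config.de_fdr)
        de_mrna = de_analysis(mrna, design, config.fc_threshold, config.de_fdr)
        de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t", index_label="feature_id")
        de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t", index_label="feature_id")
        de_mirna_ids = sorted(de_mirna.index[de_mirna["is_de"]])
        record("de", de_mirnas=len(de_mirna_ids),
               de_genes=int(de_mrna["is_de"].sum()))

        # --- correlation ranking ------------------------------------------
        ranked_dir = outdir / "ranked_lists"
        ranked_dir.mkdir(exist_ok=True)
        ranked: dict[str, RankedGeneList] = {}
        for mirna_id in de_mirna_ids:
            lst = neg_correlation_ranking(mirna_id, mirna, mrna)
            lst.write_tsv(ranked_dir / f"{mirna_id}.tsv")
            ranked[mirna_id] = lst
        record("correlate", ranked_lists=len(ranked))

        # --- target-set GSEA per program ----------------------------------
        preds = {
            config.program_a: read_predictions(config.predictions_a, config.program_a),
            config.program_b: read_predictions(config.predictions_b, config.program_b),
        }
        target_gsea: dict[str, dict[str, GseaResult]] = {}
        q_by_program: dict[str, dict[str, float]] = {}
        for program, table in preds.items():
            per_mirna: dict[str, GseaResult] = {}
            qmap: dict[str, float] = {}
            frames = []
            for mirna_id in de_mirna_ids:
                targets = list(table.targets_of(mirna_id)["gene_id"])
                targets = [g for g in targets if g in set(ranked[mirna_id].genes)]
                if len(targets) < 2:
                    qmap[mirna_id] = 1.0
                    continue
                res = preranked_gsea(
                    ranked[mirna_id],
                    GeneSetCollection({f"targets_{mirna_id}": targets}),
                    n_perm=config.n_perm,
                    weight_exponent=config.weight_exponent,
                    seed=_stage_seed(config.seed, f"gsea_{program}", mirna_id),
                )[0]
                per_mirna[mirna_id] = res
                qmap[mirna_id] = res.q_fdr
                frame = results_to_frame([res])
                frame.insert(0, "mirna_id", mirna_id)
                frames.append(frame)
            if frames:
                pd.concat(frames).to_csv(outdir / f"target_gsea_{program}.tsv",
                                         sep="\t", index=False)
            target_gsea[program] = per_mirna
            q_by_program[program] = qmap
        record("target_gsea", programs=2, tested=len(de_mirna_ids))

        # --- consensus ----------------------------------------------------
        decisions = consensus_filter(q_by_program, config.consensus_fdr)
        cons_frame = pd.DataFrame(
            [(d.mirna_id, d.q_program1, d.q_program2, d.selected) for d in decisions],
            columns=["mirna_id", "q_program1", "q_program2", "selected"],
        )
        cons_frame.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        selected = [d.mirna_id for d in decisions if d.selected]
        record("consensus", candidates=len(decisions), selected=len(selected))

        # --- combined metric + pathway GSEA -------------------------------
        collection = read_gmt(config.gene_sets) if config.gene_sets else None
        hierarchy = read_hierarchy(config.hierarchy) if config.hierarchy else None
        gsea_by_mirna: dict[str, list[GseaResult]] = {}
        direction = {
            m: ("up" if de_mirna.loc[m, "fold_change"] > 0 else "down")
            for m in selected
        }
        if collection is not None:
            table_a = preds[config.program_a]
            for mirna_id in selected:
                neg_corr = dict(zip(ranked[mirna_id].genes, ranked[mirna_id].scores))
                raw = table_a.scores_of(mirna_id)
                raw_in = {g: s for g, s in raw.items() if g in neg_corr}
                if not raw_in:
                    continue
                floor = min(raw_in.values())
                full = {g: raw_in.get(g, floor) for g in neg_corr}
                metric = combined_metric(neg_corr, normalize_scores(full), mirna_id)
                results = preranked_gsea(
                    metric, collection, n_perm=config.n_perm,
                    weight_exponent=config.pathway_weight_exponent,
                    seed=_stage_seed(config.seed, "pathway_gsea", mirna_id),
                )
                gsea_by_mirna[mirna_id] = results
                write_results(results, outdir / f"pathway_gsea_{mirna_id}.tsv")
        record("pathway_gsea", mirnas=len(gsea_by_mirna))

        if hierarchy is not None and gsea_by_mirna:
            rows = consolidate_pathways(gsea_by_mirna, hierarchy, config.pathway_fdr)
            for dir_label in ("up", "down"):
                panel = sorted(m for m in gsea_by_mirna if direction[m] == dir_label)
                if not panel:
                    continue
                panel_rows = [
                    r for r in rows if any(r.count(m) > 0 for m in panel)
                ]
                ranked_rows = rank_pathway_groups(panel_rows, panel)
                pathway_groups_to_frame(ranked_rows, panel).to_csv(
                    outdir / f"pathway_groups_{dir_label}.tsv", sep="\t", index=False
                )
            record("consolidate", groups=len(rows))
        else:
            record("consolidate", skipped=True)

        # --- relevant targets and overlaps --------------------------------
        relevant: dict[str, list[str]] = {}
        for mirna_id in selected:
            res = target_gsea[config.program_a].get(mirna_id)
            if res is None:
                continue
            relevant[mirna_id] = select_relevant_targets(
                direction[mirna_id], de_mrna, res.leading_edge
            )
        for mirna_id, targets in relevant.items():
            pd.DataFrame({"gene_id": targets}).to_csv(
                outdir / f"relevant_targets_{mirna_id}.tsv", sep="\t", index=False
            )
        if relevant:
            overlaps = target_overlaps(relevant)
            pd.DataFrame(
                [(";".join(k), v) for k, v in sorted(overlaps.regions.items())],
                columns=["mirna_subset", "exclusive_count"],
            ).to_csv(outdir / "target_overlaps.tsv", sep="\t", index=False)
            record("overlaps", union=overlaps.union_size,
                   regions=len(overlaps.regions))
        else:
            record("overlaps", skipped=True)

        # --- clinical -----------------------------------------------------
        if config.run_clinical and config.clinical:
            ctab = read_clinical(config.clinical)
            features = list(selected)
            for targets in relevant.values():
                features += targets
            assoc = clinical_mod.associate_features(
                _concat_feature_matrix(mirna, mrna), design, ctab,
                sorted(set(features)), config.clinical_fdr,
            )
            assoc.to_csv(outdir / "clinical_associations.tsv", sep="\t", index=False)
            record("clinical", tests=len(assoc),
                   significant=int(assoc["significant"].sum()) if len(assoc) else 0)
        else:
            record("clinical", skipped=True)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _concat_feature_matrix(mirna, mrna):
    from .io_core import ExpressionMatrix

    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    data = pd.concat([mirna.data[shared], mrna.data[shared]])
    return ExpressionMatrix(data)
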