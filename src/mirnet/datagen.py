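"""Synthetic paired tumor/adjacent cohorts with planted miRNA regulation.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of patients with paired tumor and adjacent-tissue log2
expression for miRNAs and genes; a handful of planted regulator miRNAs that
are shifted in tumor tissue and negatively coupled to a dedicated block of
target genes; additional "decoy" miRNAs that are differentially expressed but
regulate nothing; two overlapping-but-noisy target-prediction programs;
pathway gene sets (planted, built from true targets, plus random decoy sets)
with a pathway -> group -> category hierarchy; and a clinical covariate table
optionally associated with one planted miRNA.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_core import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    PairedDesign,
    PathwayHierarchy,
    PredictionTable,
    ValidationError,
)

# Marginal frequencies of the categorical covariates, renormalized over the
# known (non-missing) entries of the cohort the generator emulates.
_CLINICAL_MARGINALS: dict[str, dict[str, float]] = {
    "gender": {"male": 0.84, "female": 0.16},
    "age_group": {">60": 0.56, "<=60": 0.44},
    "hepatitis": {"HBV": 0.62, "HCV": 0.09, "none": 0.29},
    "cirrhosis": {"yes": 0.49, "no": 0.51},
    "stage": {"low": 0.73, "high": 0.27},
    "grade": {"low": 0.46, "high": 0.54},
    "tumor_size": {">5cm": 0.58, "<=5cm": 0.42},
    "encapsulation": {"complete": 0.43, "incomplete": 0.57},
    "afp": {">400": 0.42, "<=400": 0.58},
}

#: Fraction of clinical entries masked as "unknown" to force missing-data
#: handling downstream.
UNKNOWN_FRACTION = 0.10


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions the pipeline is exercised under:
    100 patient pairs, 300 miRNAs, 2,000 genes, 6 planted regulators with 50
    targets each, plus 20 differentially expressed but uncoupled decoy miRNAs.
    ``regulator_log2fc`` is the mean tumor-vs-adjacent shift of a planted
    regulator on the log2 scale (default 1.0, i.e. fold change 2.0, within
    the 1.5-2.3 range typical of consensus-grade liver-tumor miRNAs);
    ``coupling_strength`` is the fraction of a target gene's variance
    explained by its regulator.
    """

    n_patients: int = 100
    n_mirna: int = 300
    n_gene: int = 2000
    n_regulators: int = 6
    targets_per_regulator: int = 50
    regulator_log2fc: float = 1.0
    coupling_strength: float = 0.5
    noise_sd: float = 1.0
    n_batches: int = 4
    batch_shift_sd: float = 0.3
    n_de_decoys: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_mirna, self.n_gene,
               self.targets_per_regulator, self.n_batches) <= 0:
            raise ValidationError("cohort sizes must be positive")
        if self.n_regulators < 0 or self.n_de_decoys < 0:
            raise ValidationError("regulator/decoy counts must be non-negative")
        if self.n_regulators * self.targets_per_regulator > self.n_gene:
            raise ValidationError(
                f"{self.n_regulators} regulators x {self.targets_per_regulator} "
                f"targets exceed the {self.n_gene}-gene universe"
            )
        if self.n_regulators + self.n_de_decoys > self.n_mirna:
            raise ValidationError("regulators plus decoys exceed miRNA count")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValidationError("coupling_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.batch_shift_sd < 0:
            raise ValidationError("batch_shift_sd must be non-negative")


@dataclass(frozen=True)
class Regulator:
    mirna_id: str
    direction: str  # "up" or "down" in tumor
    targets: tuple[str, ...]


@dataclass
class TruthTable:
    """Machine-readable ground truth of a generated cohort."""

    regulators: list[Regulator]
    decoy_de: list[str]
    planted_pathways: dict[str, tuple[str, ...]]
    config: CohortConfig
    seed: int = field(init=False)

    def __post_init__(self) -> None:
        self.seed = self.config.seed
        seen: set[str] = set()
        for reg in self.regulators:
            overlap = seen & set(reg.targets)
            if overlap:
                raise ValidationError(
                    f"target {sorted(overlap)[0]!r} planted under two regulators"
                )
            seen |= set(reg.targets)
        for pid, genes in self.planted_pathways.items():
            if not genes:
                raise ValidationError(f"planted pathway {pid!r} is empty")

    @property
    def regulator_ids(self) -> list[str]:
        return [r.mirna_id for r in self.regulators]

    def targets_of(self, mirna_id: str) -> tuple[str, ...]:
        for reg in self.regulators:
            if reg.mirna_id == mirna_id:
                return reg.targets
        raise KeyError(mirna_id)


def _mirna_ids(n: int) -> list[str]:
    return [f"mir{i:04d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:04d}" for i in range(n)]


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PairedDesign, TruthTable]:
    """Draw one synthetic cohort.

    Matrices have ``2 * n_patients`` columns (all tumor columns, then all
    adjacent columns).  Regulator miRNAs carry a ``regulator_log2fc`` mean
    shift in the tumor columns; each true target equals its baseline minus
    ``sqrt(coupling_strength)`` times the standardized regulator expression
    plus independent noise, so the regulator-target Spearman correlation is
    negative across all columns.  Both tissues of a patient share a batch
    (round-robin assignment) and receive the same additive per-feature batch
    shift.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, two_n = cfg.n_patients, 2 * cfg.n_patients

    patients = [f"P{i:03d}" for i in range(n)]
    tumor_samples = [f"{p}_T" for p in patients]
    adj_samples = [f"{p}_N" for p in patients]
    samples = tumor_samples + adj_samples
    mirnas = _mirna_ids(cfg.n_mirna)
    genes = _gene_ids(cfg.n_gene)

    n_planted = cfg.n_regulators + cfg.n_de_decoys
    planted_idx = rng.choice(cfg.n_mirna, size=n_planted, replace=False)
    reg_idx = planted_idx[: cfg.n_regulators]
    decoy_idx = planted_idx[cfg.n_regulators:]
    reg_dirs = ["up" if j % 2 == 0 else "down" for j in range(cfg.n_regulators)]
    decoy_signs = rng.choice([-1.0, 1.0], size=cfg.n_de_decoys)

    target_pool = rng.choice(cfg.n_gene,
                             size=cfg.n_regulators * cfg.targets_per_regulator,
                             replace=False)

    # Biological miRNA expression: baseline + noise + tumor shift for planted.
    mirna_base = rng.normal(8.0, 2.0, size=cfg.n_mirna)
    M = mirna_base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirna, two_n))
    tumor_mask = np.zeros(two_n)
    tumor_mask[:n] = 1.0
    for j, idx in enumerate(reg_idx):
        sign = 1.0 if reg_dirs[j] == "up" else -1.0
        M[idx] += sign * cfg.regulator_log2fc * tumor_mask
    for j, idx in enumerate(decoy_idx):
        M[idx] += decoy_signs[j] * cfg.regulator_log2fc * tumor_mask

    # Gene expression: independent noise, then overwrite planted targets with
    # the coupled model  baseline + noise_sd * (-sqrt(c) z_reg + sqrt(1-c) eps).
    gene_base = rng.normal(8.0, 2.0, size=cfg.n_gene)
    E = gene_base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_gene, two_n))
    c = cfg.coupling_strength
    regulators: list[Regulator] = []
    for j, idx in enumerate(reg_idx):
        lo = j * cfg.targets_per_regulator
        t_idx = target_pool[lo: lo + cfg.targets_per_regulator]
        reg_expr = M[idx]
        z = (reg_expr - reg_expr.mean()) / reg_expr.std()
        eps = rng.normal(0.0, 1.0, size=(cfg.targets_per_regulator, two_n))
        E[t_idx] = (
            gene_base[t_idx][:, None]
            + cfg.noise_sd * (-math.sqrt(c) * z[None, :] + math.sqrt(1.0 - c) * eps)
        )
        regulators.append(
            Regulator(mirnas[idx], reg_dirs[j], tuple(genes[g] for g in t_idx))
        )

    # Batch structure: patients round-robin over batches, both tissues shared.
    patient_batch = np.arange(n) % cfg.n_batches
    sample_batch = np.concatenate([patient_batch, patient_batch])
    if cfg.batch_shift_sd > 0:
        for mat, n_feat in ((M, cfg.n_mirna), (E, cfg.n_gene)):
            shifts = rng.normal(0.0, cfg.batch_shift_sd, size=(n_feat, cfg.n_batches))
            mat += shifts[:, sample_batch]

    mirna_matrix = ExpressionMatrix(pd.DataFrame(M, index=mirnas, columns=samples))
    mrna_matrix = ExpressionMatrix(pd.DataFrame(E, index=genes, columns=samples))
    design = PairedDesign(
        patient_ids=patients,
        tumor_col=dict(zip(patients, tumor_samples)),
        adjacent_col=dict(zip(patients, adj_samples)),
        batch={s: f"batch{b}" for s, b in zip(samples, sample_batch)},
    )

    # Planted pathways: each regulator's targets split into two gene sets.
    pathways: dict[str, tuple[str, ...]] = {}
    for reg in regulators:
        half = len(reg.targets) // 2
        pathways[f"path_{reg.mirna_id}_a"] = reg.targets[:half]
        pathways[f"path_{reg.mirna_id}_b"] = reg.targets[half:]
    truth = TruthTable(
        regulators=regulators,
        decoy_de=[mirnas[i] for i in decoy_idx],
        planted_pathways=pathways,
        config=cfg,
    )
    return mirna_matrix, mrna_matrix, design, truth


def generate_predictions(
    truth: TruthTable,
    program_id: str,
    sensitivity: float = 0.8,
    fp_per_mirna: int = 17,
    seed: int = 0,
) -> PredictionTable:
    """Emulate one in-silico target-prediction program's score table.

    For each planted regulator, every true target is reported with
    probability ``sensitivity`` and ``fp_per_mirna`` random non-target genes
    are added; true targets draw stochastically higher scores than false
    positives.  Decoy miRNAs (differentially expressed but uncoupled) receive
    a random gene set of comparable size so the consensus filter has
    something to reject.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValidationError("sensitivity must lie in [0, 1]")
    if fp_per_mirna < 0:
        raise ValidationError("fp_per_mirna must be non-negative")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_ids(truth.config.n_gene))
    rows: list[tuple[str, str, float]] = []
    for reg in truth.regulators:
        keep = rng.random(len(reg.targets)) < sensitivity
        true_hits = [t for t, k in zip(reg.targets, keep) if k]
        rows += [
            (reg.mirna_id, t, float(s))
            for t, s in zip(true_hits, rng.normal(160.0, 20.0, size=len(true_hits)))
        ]
        if fp_per_mirna:
            non_targets = genes[~np.isin(genes, reg.targets)]
            fps = rng.choice(non_targets, size=fp_per_mirna, replace=False)
            rows += [
                (reg.mirna_id, g, float(s))
                for g, s in zip(fps, rng.normal(140.0, 20.0, size=fp_per_mirna))
            ]
    decoy_size = round(sensitivity * truth.config.targets_per_regulator) + fp_per_mirna
    for mirna_id in truth.decoy_de:
        if decoy_size == 0:
            continue
        picks = rng.choice(genes, size=decoy_size, replace=False)
        rows += [
            (mirna_id, g, float(s))
            for g, s in zip(picks, rng.normal(140.0, 20.0, size=decoy_size))
        ]
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"])
    return PredictionTable(program_id, table)


def generate_pathway_db(
    truth: TruthTable,
    n_decoy_sets: int = 40,
    set_size_range: tuple[int, int] = (20, 60),
    seed: int = 0,
) -> tuple[GeneSetCollection, PathwayHierarchy]:
    """Planted pathways plus random decoy gene sets, with a group/category hierarchy.

    Each regulator's two planted pathways share a group; up- and
    down-regulator groups fall under two different categories, so planted
    pathways are spread across several groups.  Decoy sets pair up into decoy
    groups under decoy categories.
    """
    lo, hi = set_size_range
    if lo < 2:
        raise ValidationError("gene-set sizes must be >= 2")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_ids(truth.config.n_gene))

    sets: dict[str, list[str]] = {
        pid: list(members) for pid, members in truth.planted_pathways.items()
    }
    descriptions = {pid: "planted" for pid in sets}
    rows: list[tuple[str, str, str]] = []
    direction = {r.mirna_id: r.direction for r in truth.regulators}
    for pid in truth.planted_pathways:
        mirna_id = pid[len("path_"):-2]
        rows.append((pid, f"grp_{mirna_id}", f"planted_{direction[mirna_id]}"))

    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        pid = f"decoy{i:03d}"
        sets[pid] = list(rng.choice(genes, size=size, replace=False))
        descriptions[pid] = "decoy"
        rows.append((pid, f"decoygrp{i // 2:03d}", f"decoycat{i // 8}"))

    collection = GeneSetCollection(sets, descriptions)
    hierarchy = PathwayHierarchy(
        pd.DataFrame(rows, columns=["pathway_id", "group_id", "category_id"])
    )
    return collection, hierarchy


def generate_clinical(
    truth: TruthTable,
    design: PairedDesign,
    assoc_mirna: str | None = None,
    seed: int = 0,
    mirna_matrix: ExpressionMatrix | None = None,
    assoc_covariate: str = "afp",
    assoc_effect: float = 1.5,
) -> ClinicalTable:
    """Clinical covariates with optional planted miRNA association.

    With ``assoc_mirna`` given (requires ``mirna_matrix``), the chosen
    categorical covariate's group assignment follows a logistic model on the
    miRNA's standardized tumor expression with slope ``assoc_effect``;
    otherwise every covariate is drawn independently of expression.  Relapse
    is a (time, event) pair from an exponential event-time model with uniform
    censoring.  A fixed 10% of entries are masked as unknown.
    """
    rng = np.random.default_rng(seed)
    patients = design.patient_ids
    n = len(patients)
    table = pd.DataFrame(index=pd.Index(patients, name="patient_id"),
                         columns=list(CLINICAL_COLUMNS), dtype=object)

    assoc_z = None
    if assoc_mirna is not None:
        if mirna_matrix is None:
            raise ValidationError("assoc_mirna requires mirna_matrix")
        tumor_cols = [design.tumor_col[p] for p in patients]
        expr = mirna_matrix.data.loc[assoc_mirna, tumor_cols].to_numpy(float)
        assoc_z = (expr - expr.mean()) / expr.std()

    for col, marginal in _CLINICAL_MARGINALS.items():
        levels = list(marginal)
        probs = np.array([marginal[l] for l in levels])
        if assoc_z is not None and col == assoc_covariate:
            # Two-level covariate: first level's log-odds shift by expression.
            base_logit = math.log(probs[0] / (1.0 - probs[0]))
            p_first = expit(base_logit + assoc_effect * assoc_z)
            draws = np.where(rng.random(n) < p_first, levels[0], levels[1])
        else:
            draws = rng.choice(levels, size=n, p=probs / probs.sum())
        table[col] = draws

    event = rng.random(n) < 0.38
    event_time = rng.exponential(24.0, size=n)
    censor_time = rng.uniform(6.0, 60.0, size=n)
    time = np.where(event, np.minimum(event_time, 60.0), censor_time)
    table["relapse_time"] = np.round(time, 2)
    table["relapse_event"] = event.astype(float)

    # Fixed 10% unknown entries; relapse time/event masked jointly.
    for col in _CLINICAL_MARGINALS:
        mask = rng.random(n) < UNKNOWN_FRACTION
        table.loc[mask, col] = np.nan
    mask = rng.random(n) < UNKNOWN_FRACTION
    table.loc[mask, ["relapse_time", "relapse_event"]] = np.nan
    table["relapse_time"] = pd.to_numeric(table["relapse_time"])
    table["relapse_event"] = pd.to_numeric(table["relapse_event"])
    return ClinicalTable(table)


def write_truth(truth: TruthTable, outdir: str | Path) -> None:
    """Serialize the ground truth as TSVs plus a plain-text config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg_rows = [
        (r.mirna_id, r.direction, ",".join(r.targets)) for r in truth.regulators
    ]
    pd.DataFrame(reg_rows, columns=["mirna_id", "direction", "targets"]).to_csv(
        outdir / "truth_regulators.tsv", sep="\t", index=False
    )
    pd.DataFrame({"mirna_id": truth.decoy_de}).to_csv(
        outdir / "truth_decoys.tsv", sep="\t", index=False
    )
    path_rows = [
        (pid, ",".join(genes)) for pid, genes in truth.planted_pathways.items()
    ]
    pd.DataFrame(path_rows, columns=["pathway_id", "genes"]).to_csv(
        outdir / "truth_pathways.tsv", sep="\t", index=False
    )
    with open(outdir / "truth_config.txt", "w", encoding="utf-8") as fh:
        for key, value in asdict(truth.config).items():
            fh.write(f"{key} = {value}\n")
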