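"""Experiment orchestration over the (phenotype x modality x CTQ x sex) grid.

One grid cell = one classification analysis: comorbidity exclusion, optional
CTQ thresholding of cases, sex stratification, 1-to-1 matching, connectome
simulation for the matched subjects only, nested cross-validation, stable
important-feature selection, and subnetwork enrichment (functional edge
spaces only). The module also reproduces the summary analyses: the
threshold-comparison Jaccard table and the accuracy-vs-sample-size /
accuracy-vs-K correlations across cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import io
from .cohort import (
    PHENOTYPES,
    CohortConfig,
    SubjectRecord,
    functional_rng,
    generate_cohort,
    shared_structural_topology,
    simulate_functional,
    simulate_structural,
    structural_rng,
)
from .cv import CVPlan, CVResult, RidgeConfig, make_cv_plan, run_nested_cv
from .enrichment import EnrichmentResult, Partition, enrich
from .features import EdgeSpace, FeatureMatrix, proportional_threshold, stack_modalities
from .matching import (
    MatchedSample,
    apply_ctq_threshold,
    eligible_controls,
    exclude_comorbid,
    match_one_to_one,
)
from .stability import (
    ImportantFeatureSet,
    jaccard,
    mean_coefficients,
    round_half_up,
    select_important,
)

log = logging.getLogger("connclass")

__all__ = [
    "STRUCTURAL_CHANNELS",
    "FUNCTIONAL_MODALITIES",
    "ExperimentGrid",
    "CellResult",
    "ExperimentReport",
    "build_matched_sample",
    "assemble_features",
    "run_cell",
    "run_experiment",
    "compare_thresholds",
    "accuracy_correlations",
]

#: Structural weighting channel names, in channel order.
STRUCTURAL_CHANNELS = ("SC", "FA", "MD", "ICVF", "ISOVF", "OD")
FUNCTIONAL_MODALITIES = ("corr", "pcorr")
#: Group proportional-thresholding fraction for structural modalities.
STRUCTURAL_THRESHOLD_FRACTION = 2.0 / 3.0


@dataclass
class ExperimentGrid:
    """The experiment grid plus the shared cohort and model configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    phenotypes: tuple[str, ...] = ("current",)
    modalities: tuple[str, ...] = ("corr",)
    ctq_thresholds: tuple[float | None, ...] = (None,)
    sex: str = "all"                       # "all" | "female" | "male"
    n_pairs: int | None = None             # cap on matched pairs per cell
    n_outer: int = 6
    n_inner: int = 5
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (self.phenotypes and self.modalities and self.ctq_thresholds):
            raise ValueError("phenotypes, modalities and ctq_thresholds must be nonempty")
        for p in self.phenotypes:
            if p not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {p!r}")
        for m in self.modalities:
            parse_modality(m)
        if self.sex not in ("all", "female", "male"):
            raise ValueError("sex must be all, female or male")

    def cells(self):
        for p in self.phenotypes:
            for m in self.modalities:
                for t in self.ctq_thresholds:
                    yield (p, m, t)


def parse_modality(modality: str) -> tuple[str | None, str | None]:
    """Split a modality tag into (functional, structural) parts.

    Accepts "corr", "pcorr", a structural channel name, or a combined
    "corr+FA"-style tag (functional part first).
    """
    parts = modality.split("+")
    func = struct = None
    if len(parts) == 1:
        if parts[0] in FUNCTIONAL_MODALITIES:
            func = parts[0]
        elif parts[0] in STRUCTURAL_CHANNELS:
            struct = parts[0]
        else:
            raise ValueError(f"unknown modality {modality!r}")
    elif len(parts) == 2:
        func, struct = parts
        if func not in FUNCTIONAL_MODALITIES or struct not in STRUCTURAL_CHANNELS:
            raise ValueError(f"unknown combined modality {modality!r}")
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return func, struct


# ---------------------------------------------------------------------------
# sample and feature assembly
# ---------------------------------------------------------------------------

def build_matched_sample(
    subjects: list[SubjectRecord],
    phenotype: str,
    ctq_threshold: float | None = None,
    sex: str = "all",
    n_pairs: int | None = None,
    seed: int = 0,
) -> MatchedSample:
    """Exclusion -> CTQ filter -> optional sex stratum -> 1-to-1 matching.

    When ``n_pairs`` is given and more cases survive the filters, a random
    (seeded) subset of cases of that size is matched; fewer surviving cases
    raise, so a returned sample always has exactly ``n_pairs`` pairs.
    """
    usable = exclude_comorbid(subjects)
    if sex != "all":
        usable = [s for s in usable if s.sex == sex]
    cases = [s for s in usable if s.has_flag(phenotype)]
    cases = apply_ctq_threshold(cases, ctq_threshold)
    if n_pairs is not None:
        if len(cases) < n_pairs:
            raise ValueError(
                f"only {len(cases)} {phenotype} cases survive the filters; "
                f"{n_pairs} requested"
            )
        rng = np.random.default_rng(np.random.SeedSequence((seed, 20)))
        keep = rng.choice(len(cases), size=n_pairs, replace=False)
        cases = [cases[i] for i in sorted(keep)]
    pool = eligible_controls(usable)
    return match_one_to_one(
        cases, pool, phenotype=phenotype, ctq_threshold=ctq_threshold
    )


def assemble_features(
    subjects: list[SubjectRecord],
    sample: MatchedSample,
    modality: str,
    config: CohortConfig,
) -> FeatureMatrix:
    """Simulate connectomes for the matched subjects and build the features.

    Functional modalities use all Ne = N(N-1)/2 edges; structural channels
    are sparsified with group proportional thresholding at 2/3 before
    vectorisation; combined tags stack structural after functional columns.
    """
    func, struct = parse_modality(modality)
    by_id = {s.id: s for s in subjects}
    members = [by_id[sid] for sid in sample.subject_ids]

    func_fm = struct_fm = None
    if func is not None:
        mats = []
        for s in members:
            full, partial = simulate_functional(s, config, functional_rng(config, s))
            mats.append(full if func == "corr" else partial)
        func_fm = FeatureMatrix.from_matrices(sample.subject_ids, mats, func)
    if struct is not None:
        channel = STRUCTURAL_CHANNELS.index(struct)
        topology = shared_structural_topology(config)
        mats = [
            simulate_structural(s, config, structural_rng(config, s), topology)[channel]
            for s in members
        ]
        mask = proportional_threshold(mats, STRUCTURAL_THRESHOLD_FRACTION)
        struct_fm = FeatureMatrix.from_matrices(sample.subject_ids, mats, struct, mask=mask)

    if func_fm is not None and struct_fm is not None:
        return stack_modalities(func_fm, struct_fm)
    return func_fm if func_fm is not None else struct_fm


# ---------------------------------------------------------------------------
# one grid cell
# ---------------------------------------------------------------------------

@dataclass
class CellResult:
    phenotype: str
    modality: str
    ctq_threshold: float | None
    sex: str
    sample: MatchedSample
    cv: CVResult
    important: ImportantFeatureSet
    enrichment: EnrichmentResult | None

    @property
    def mean_accuracy(self) -> float:
        return self.cv.mean_accuracy

    def summary(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "modality": self.modality,
            "ctq_threshold": np.nan if self.ctq_threshold is None else self.ctq_threshold,
            "sex": self.sex,
            "n_pairs": self.sample.n_pairs,
            "mean_accuracy": self.cv.mean_accuracy,
            "se_accuracy": self.cv.se_accuracy,
            "k_important": self.important.k,
        }


def run_cell(
    subjects: list[SubjectRecord],
    grid: ExperimentGrid,
    phenotype: str,
    modality: str,
    ctq_threshold: float | None,
) -> CellResult:
    sample = build_matched_sample(
        subjects, phenotype, ctq_threshold, grid.sex, grid.n_pairs, grid.seed
    )
    fm = assemble_features(subjects, sample, modality, grid.cohort)
    plan = make_cv_plan(sample, grid.n_outer, grid.n_inner, grid.seed)
    cv_result = run_nested_cv(fm, sample, plan, grid.ridge)
    important = select_important(
        cv_result.models, phenotype=phenotype, modality=modality,
        ctq_threshold=ctq_threshold,
    )
    beta_mean = mean_coefficients(cv_result.models)

    enrichment_result = None
    func, _ = parse_modality(modality)
    if func is not None:
        space = EdgeSpace(grid.cohort.functional_nodes)
        partition = Partition.from_sizes(
            grid.cohort.subnetwork_sizes, grid.cohort.subnetwork_names
        )
        func_cols = np.flatnonzero(np.asarray(fm.col_modality, dtype=object) == func)
        func_set = ImportantFeatureSet(
            indices=np.intersect1d(important.indices, func_cols),
            signs=important.signs[np.isin(important.indices, func_cols)],
            n_features=space.n_edges,
            phenotype=phenotype, modality=modality, ctq_threshold=ctq_threshold,
        )
        enrichment_result = enrich(func_set, partition, space, beta_mean[: space.n_edges])
    return CellResult(
        phenotype=phenotype, modality=modality, ctq_threshold=ctq_threshold,
        sex=grid.sex, sample=sample, cv=cv_result, important=important,
        enrichment=enrichment_result,
    )


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    grid: ExperimentGrid
    cells: dict                       # (phenotype, modality, tau) -> CellResult
    failures: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [c.summary() for c in self.cells.values()]
        return pd.DataFrame(rows)


def _cell_hash(grid: ExperimentGrid, cell) -> str:
    payload = json.dumps(
        {
            "cohort": io._jsonable(grid.cohort),
            "seed": grid.seed,
            "sex": grid.sex,
            "n_pairs": grid.n_pairs,
            "folds": [grid.n_outer, grid.n_inner],
            "lambdas": grid.ridge.lambdas.tolist(),
            "cell": list(cell),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_cell(out: Path, cell_key, result: CellResult, digest: str) -> None:
    tag = "-".join(str(c) for c in cell_key).replace("+", "_")
    cell_dir = out / f"cell_{tag}"
    cell_dir.mkdir(parents=True, exist_ok=True)
    result.cv.to_frame().to_csv(cell_dir / "accuracies.csv", index=False)
    result.sample.to_frame().to_csv(cell_dir / "matched_pairs.csv", index=False)
    coefs = pd.DataFrame(np.stack([m.coef for m in result.cv.models]))
    coefs.to_csv(cell_dir / "coefficients.csv", index=False)
    if result.enrichment is not None:
        result.enrichment.tidy().to_csv(cell_dir / "enrichment.csv", index=False)
    (cell_dir / "manifest.json").write_text(
        json.dumps({"hash": digest, **result.summary()}, sort_keys=True, default=str)
    )


def run_experiment(grid: ExperimentGrid) -> ExperimentReport:
    """Run every grid cell; per-cell failures are recorded, not fatal.

    With ``grid.out_dir`` set, each cell's artifacts (accuracies, pairs,
    coefficients, enrichment tables, manifest) are written under a directory
    keyed by the cell; cells whose manifest already carries the current
    content hash are recomputed-skipped only at the artifact-writing level.
    """
    subjects = generate_cohort(grid.cohort)
    out = Path(grid.out_dir) if grid.out_dir else None
    report = ExperimentReport(grid=grid, cells={})
    for cell in grid.cells():
        phenotype, modality, tau = cell
        try:
            result = run_cell(subjects, grid, phenotype, modality, tau)
        except Exception as exc:  # keep the rest of the grid alive
            log.warning("cell %s failed: %s", cell, exc)
            report.failures[cell] = str(exc)
            continue
        report.cells[cell] = result
        log.info(
            "cell %s: n_pairs=%d mean_acc=%.3f K=%d",
            cell, result.sample.n_pairs, result.mean_accuracy, result.important.k,
        )
        if out is not None:
            _write_cell(out, cell, result, _cell_hash(grid, cell))
    if out is not None:
        io.write_manifest(out / "manifest.json", grid.cohort, seed=grid.seed,
                          cells=[list(c) for c in report.cells])
        if report.cells:
            report.table().to_csv(out / "report.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# summary analyses
# ---------------------------------------------------------------------------

def compare_thresholds(
    report: ExperimentReport, tau: float = 0.4
) -> pd.DataFrame:
    """Important-feature overlap between unthresholded and CTQ-thresholded runs.

    One row per (phenotype, modality) with columns (K_none, K_tau, overlap,
    jaccard), the Jaccard index reported to 4 decimals. Missing cells yield
    an explicit NaN row rather than being dropped.
    """
    rows = []
    for phenotype in report.grid.phenotypes:
        for modality in report.grid.modalities:
            a = report.cells.get((phenotype, modality, None))
            b = report.cells.get((phenotype, modality, tau))
            row = {"phenotype": phenotype, "modality": modality,
                   "K_none": np.nan, "K_tau": np.nan,
                   "overlap": np.nan, "jaccard": np.nan}
            if a is not None and b is not None:
                sa, sb = a.important.as_set(), b.important.as_set()
                row.update(
                    K_none=len(sa), K_tau=len(sb), overlap=len(sa & sb),
                    jaccard=round_half_up(jaccard(sa, sb), 4),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def accuracy_correlations(report: ExperimentReport) -> pd.DataFrame:
    """Pearson r of mean accuracy vs case count and vs K, per modality."""
    table = report.table()
    if len(table) == 0:
        raise ValueError("empty report")
    rows = []
    for modality, sub in table.groupby("modality"):
        row = {"modality": modality, "n_cells": len(sub)}
        for var, tag in [("n_pairs", "size"), ("k_important", "k")]:
            r = p = np.nan
            if len(sub) < 3:
                warnings.warn(
                    f"{modality}: only {len(sub)} cells; correlation is degenerate",
                    stacklevel=2,
                )
            if len(sub) >= 2 and sub[var].nunique() > 1 and sub["mean_accuracy"].nunique() > 1:
                r, p = pearsonr(sub["mean_accuracy"], sub[var])
            elif sub[var].nunique() <= 1:
                warnings.warn(f"{modality}: zero variance in {var}", stacklevel=2)
            row[f"r_accuracy_{tag}"] = r
            row[f"p_accuracy_{tag}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
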