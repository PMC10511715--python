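"""End-to-end pharmacophenotyping pipeline.

simulate -> preprocess -> PCA profile -> RBM fit -> medication cluster
assignment -> patient features -> hierarchical phenotypes -> outcome
validation, as one reproducible run driven by a single config and master
seed.  Every intermediate artifact is written as delimited text or JSON so
stages are individually inspectable and re-runnable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import PatientFeatureMatrix, PhenotypeModel, PhenotypeResults, compute_cluster_distribution
from .preprocess import BinaryMedicationMatrix, preprocess_records, recode_outcomes
from .rbm import (
    MedicationClusterAssignment,
    MedicationRBM,
    MedicationRBMResults,
    PCAProfile,
    fit_pca,
)
from .synthetic import CohortSpec, generate_cohort
from .validation import (
    ClusterSummary,
    PairwiseTestTable,
    PermanovaResult,
    pairwise_outcome_tests,
    permutation_manova,
    summarize_clusters,
)
from .preprocess import _normalize_name

logger = logging.getLogger(__name__)

_PKG_VERSION = "0.1.0"

__all__ = ["RunConfig", "PhenotypeSolution", "PipelineError", "run_pipeline", "classify_new_patient"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline knobs with documented defaults.

    Defaults mirror the reference analysis: 5 hidden units (medication
    clusters), ~75% PCA target variance, Ward linkage with silhouette-based
    k selection, alpha 0.05, z-scored permutation MANOVA.
    """

    # inputs: either simulate, or read MAR/outcome delimited files
    simulate: bool = True
    mar_path: str | None = None
    outcomes_path: str | None = None
    out_dir: str | None = None
    # simulation scale (only used when simulate=True)
    n_patients: int = 1000
    n_medications: int = 440
    n_blocks: int = 5
    n_archetypes: int = 5
    block_size: int | None = 20
    block_on: float = 0.4
    block_off: float = 0.02
    background_rate: float = 0.025
    # preprocessing
    keep_actions: tuple = ("Given", "New Bag", "Restarted", "Rate Change")
    # PCA / RBM
    pca_target_variance: float = 0.75
    rbm_input: str = "binary"  # "binary" (canonical) or "pca"
    n_hidden: int = 5
    learning_rate: float = 0.1
    batch_size: int = 10
    n_epochs: int = 10
    cd_steps: int = 1
    tau: float = 0.5
    # patient clustering
    normalization: str = "by_total_meds"
    linkage: str = "ward"
    k: int | None = None
    k_min: int = 2
    k_max: int = 8
    # validation
    alpha: float = 0.05
    n_permutations: int = 9999
    manova_standardize: str = "zscore"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rbm_input not in ("binary", "pca"):
            raise ValueError("rbm_input must be 'binary' or 'pca'")
        if not self.simulate and (self.mar_path is None or self.outcomes_path is None):
            raise ValueError("mar_path and outcomes_path are required when simulate=False")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "keep_actions" in d and isinstance(d["keep_actions"], list):
            d = {**d, "keep_actions": tuple(d["keep_actions"])}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat ``key: value`` config file (YAML subset)."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain flat key: value pairs")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["keep_actions"] = list(self.keep_actions)
        return d


@dataclass
class PhenotypeSolution:
    """Everything a pipeline run produces."""

    config: RunConfig
    matrix: BinaryMedicationMatrix
    outcomes: pd.DataFrame
    pca_profile: PCAProfile
    rbm: MedicationRBMResults
    assignment: MedicationClusterAssignment
    features: PatientFeatureMatrix
    phenotypes: PhenotypeResults
    pairwise: PairwiseTestTable
    permanova: PermanovaResult
    cluster_summary: ClusterSummary
    manifest: dict = field(default_factory=dict)
    truth: object | None = None

    def summary(self) -> str:
        parts = [
            self.phenotypes.summary(),
            "",
            str(self.permanova),
            "",
            "Per-cluster outcome summary",
            "=" * 40,
            self.cluster_summary.table.to_string(),
            "",
            f"Significant pairwise contrasts (Holm-adjusted p < {self.pairwise.alpha}): "
            f"{len(self.pairwise.significant())} of {len(self.pairwise.long)}",
        ]
        return "\n".join(parts)


def _rescale_pca_scores(matrix: BinaryMedicationMatrix, n_components: int) -> np.ndarray:
    """PCA scores linearly rescaled to [0, 1] then stochastically binarized
    is NOT used; the alternative 'pca' pathway feeds thresholded rescaled
    scores, keeping the RBM input binary."""
    from sklearn.decomposition import PCA

    X = matrix.values.to_numpy(dtype=float)
    k = min(n_components, min(X.shape) - 1)
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    rescaled = (scores - lo) / span
    return (rescaled >= 0.5).astype(float)


def run_pipeline(config: RunConfig) -> PhenotypeSolution:
    """Execute every stage in order; see module docstring.

    Artifacts are written under ``config.out_dir`` when set.  Any stage
    error is re-raised as :class:`PipelineError` naming the stage; partial
    artifacts already written are marked with an empty ``<stage>.failed``
    file next to them.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": config.to_dict(),
        "versions": {"medpheno": _PKG_VERSION, "python": sys.version.split()[0]},
        "stages": {},
    }
    stage = "input"
    truth = None
    try:
        if config.simulate:
            spec = CohortSpec(
                n_patients=config.n_patients,
                n_medications=config.n_medications,
                n_blocks=config.n_blocks,
                n_archetypes=config.n_archetypes,
                block_size=config.block_size,
                block_usage=_block_usage(config),
                background_rate=config.background_rate,
                seed=config.seed,
            )
            records, raw_outcomes, truth = generate_cohort(spec)
        else:
            records = pd.read_csv(config.mar_path, dtype={"medication_name": str, "action": str},
                                  keep_default_na=False)
            raw_outcomes = pd.read_csv(config.outcomes_path, keep_default_na=False)
        manifest["stages"]["input"] = {"mar_rows": len(records), "outcome_rows": len(raw_outcomes)}
        if out_dir and config.simulate:
            records.to_csv(out_dir / "mar_records.csv", index=False)
            raw_outcomes.to_csv(out_dir / "outcomes_raw.csv", index=False)
            truth.to_frame().to_csv(out_dir / "truth.csv", index=False)

        stage = "preprocess"
        clean, matrix = preprocess_records(records, config.keep_actions)
        outcomes = recode_outcomes(raw_outcomes)
        if "patient_id" in outcomes.columns:
            outcomes = outcomes.set_index("patient_id")
        outcomes = outcomes.loc[matrix.patient_ids]
        manifest["stages"]["preprocess"] = {
            "clean_rows": len(clean),
            "patients": matrix.shape[0],
            "medications": matrix.shape[1],
        }
        if out_dir:
            matrix.to_tsv(out_dir / "binary_matrix.tsv")
            outcomes.to_csv(out_dir / "outcomes_recoded.csv")

        stage = "pca"
        pca_profile = fit_pca(matrix, config.pca_target_variance)
        manifest["stages"]["pca"] = {"selected_components": pca_profile.selected_components}
        if out_dir:
            pca_profile.to_frame().to_csv(out_dir / "pca_profile.tsv", sep="\t", index=False)

        stage = "rbm"
        V = None
        if config.rbm_input == "binary":
            model = MedicationRBM(matrix, n_hidden=config.n_hidden)
        else:
            # alternative reading: RBM on binarized rescaled PCA scores
            V = _rescale_pca_scores(matrix, pca_profile.selected_components)
            model = MedicationRBM(V, n_hidden=config.n_hidden)
        rbm = model.fit(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            n_epochs=config.n_epochs,
            cd_steps=config.cd_steps,
            seed=config.seed,
        )
        if config.rbm_input == "binary":
            rbm.medication_names = matrix.medication_names
        manifest["stages"]["rbm"] = {
            "n_visible": rbm.n_visible,
            "n_hidden": rbm.n_hidden,
            "final_reconstruction_error": rbm.reconstruction_trace[-1],
        }
        if out_dir:
            rbm.to_json(out_dir / "rbm_model.json")

        stage = "assign"
        if config.rbm_input == "binary":
            assignment = rbm.assign_clusters(tau=config.tau)
        else:
            # PCA pathway has no per-medication visible units; assign every
            # medication to the residual cluster and warn.
            logger.warning("rbm_input='pca': medication-level assignment undefined; all residual")
            assignment = MedicationClusterAssignment(
                {m: frozenset() for m in matrix.medication_names}, n_hidden=config.n_hidden, tau=config.tau
            )
        sizes = {k: len(assignment.cluster_members(k)) for k in range(1, assignment.n_clusters + 1)}
        manifest["stages"]["assign"] = {"cluster_sizes": sizes}
        if out_dir:
            assignment.to_frame().to_csv(out_dir / "medication_clusters.tsv", sep="\t", index=False)

        stage = "featurize"
        if config.rbm_input == "binary":
            features = compute_cluster_distribution(matrix, assignment, config.normalization)
        else:
            # PCA pathway: no per-medication visible units, so patients are
            # featurized by their hidden-unit activation probabilities
            act = rbm.hidden_activation(V)
            features = PatientFeatureMatrix(
                pd.DataFrame(
                    act,
                    index=pd.Index(matrix.patient_ids, name="patient_id"),
                    columns=[f"hidden_{k}" for k in range(1, config.n_hidden + 1)],
                )
            )
        manifest["stages"]["featurize"] = {"patients": len(features.patient_ids)}
        if out_dir:
            features.to_tsv(out_dir / "patient_features.tsv")

        stage = "cluster"
        phenotypes = PhenotypeModel(features, linkage_method=config.linkage).fit(
            k=config.k, k_range=range(config.k_min, config.k_max + 1)
        )
        manifest["stages"]["cluster"] = {
            "k": phenotypes.k,
            "rule": phenotypes.selection_rule,
            "sizes": phenotypes.labels.value_counts().sort_index().to_dict(),
        }
        if out_dir:
            phenotypes.labels.to_frame().to_csv(out_dir / "patient_clusters.tsv", sep="\t")
            phenotypes.merge_tree_frame().to_csv(out_dir / "merge_tree.tsv", sep="\t", index=False)
            phenotypes.silhouette_frame().to_csv(out_dir / "silhouette.tsv", sep="\t", index=False)

        stage = "validate"
        pairwise = pairwise_outcome_tests(phenotypes.labels, outcomes, alpha=config.alpha)
        manova = permutation_manova(
            outcomes, phenotypes.labels.values,
            n_permutations=config.n_permutations, seed=config.seed,
            standardize=config.manova_standardize,
        )
        summary = summarize_clusters(phenotypes.labels, outcomes, features=features.values)
        manifest["stages"]["validate"] = {
            "pairwise_tests": len(pairwise.long),
            "significant": len(pairwise.significant()),
            "permanova_p": manova.p_value,
        }
        if out_dir:
            pairwise.to_tsv(out_dir / "pairwise_long.tsv")
            pairwise.wide().to_csv(out_dir / "pairwise_holm.tsv", sep="\t")
            (out_dir / "permanova.txt").write_text(str(manova) + "\n", encoding="utf-8")
            summary.to_tsv(out_dir / "cluster_summary.tsv")
    except Exception as exc:
        if out_dir:
            (out_dir / f"{stage}.failed").write_text(str(exc), encoding="utf-8")
        raise PipelineError(stage, exc) from exc

    solution = PhenotypeSolution(
        config=config, matrix=matrix, outcomes=outcomes, pca_profile=pca_profile,
        rbm=rbm, assignment=assignment, features=features, phenotypes=phenotypes,
        pairwise=pairwise, permanova=manova, cluster_summary=summary,
        manifest=manifest, truth=truth,
    )
    if out_dir:
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        (out_dir / "report.md").write_text(
            "# Pharmacophenotype run report\n\n```\n" + solution.summary() + "\n```\n",
            encoding="utf-8",
        )
    return solution


def _block_usage(config: RunConfig) -> np.ndarray:
    usage = np.full((config.n_archetypes, config.n_blocks), config.block_off, dtype=float)
    for a in range(config.n_archetypes):
        usage[a, a % config.n_blocks] = config.block_on
    return usage


def classify_new_patient(
    assignment: MedicationClusterAssignment,
    centroids: pd.DataFrame,
    medications: list[str],
    normalization: str = "by_total_meds",
) -> dict:
    """Assign a new patient to the nearest phenotype centroid.

    The patient's medication list is name-normalized and converted to the
    frozen cluster-distribution feature; medications unseen in training are
    routed to the residual cluster and counted.  Returns the feature
    vector, the nearest centroid's label and the Euclidean distance.
    """
    if not medications:
        raise ValueError("medication list is empty")
    names = [_normalize_name(m) for m in medications]
    distinct = sorted(set(names))
    n_clusters = assignment.n_clusters
    counts = np.zeros(n_clusters)
    n_unseen = 0
    for name in distinct:
        if name in assignment.membership:
            mem = assignment.effective_membership(name)
        else:
            n_unseen += 1
            mem = frozenset({assignment.residual_index})
        for k in mem:
            counts[k - 1] += 1
    if n_unseen:
        logger.warning("classify_new_patient: %d unseen medications routed to residual cluster", n_unseen)
    if normalization == "by_total_meds":
        feats = counts / len(distinct)
    else:
        feats = counts / counts.sum()
    C = centroids.to_numpy(dtype=float)
    dists = np.sqrt(((C - feats[None, :]) ** 2).sum(axis=1))
    best = int(np.argmin(dists))
    return {
        "features": feats,
        "cluster": centroids.index[best],
        "distance": float(dists[best]),
        "n_unseen_medications": n_unseen,
    }
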