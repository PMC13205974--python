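"""End-to-end orchestration: cohort -> poses -> features -> phenotypes -> stats.

This is the programmatic equivalent of running every stage in order on one
cohort.  Each stage is the public function from its module; the pipeline only
wires them together and collects the artifacts a study report needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import canonical_frame
from .group_stats import OmnibusResult, comparisons_table, omnibus_and_posthoc
from .phenotype import (
    ClusterModel,
    LatentEmbedding,
    kmeans_fit,
    order_by_gamma,
    pca_project,
    select_k,
    validity_indices,
)
from .registration import (
    OptimizerConfig,
    PoseSequence,
    center_series,
    estimate_pose_sequence,
    poses_to_dof,
    qc_filter,
)
from .standardize import (
    KinematicSummary,
    StandardizedTrajectory,
    biphasic_resample,
    build_feature_matrix,
    find_peak_frame,
    mirror_if_left,
    smooth_standardized,
    summarize_dof,
)
from .synthetic import CohortConfig, FrameSeries, PhenotypeTemplate, generate_cohort

#: Kinematic variables compared between phenotypes in the standard report.
REPORT_VARIABLES = (
    "max_lateral_displacement",
    "lateral_range_of_motion",
    "max_longitudinal_displacement",
)


@dataclass
class PipelineResult:
    truth: pd.DataFrame
    pose_sequences: list[PoseSequence]
    qc_report: pd.DataFrame
    standardized: list[StandardizedTrajectory]
    summaries: list[KinematicSummary]
    features: pd.DataFrame
    embedding: LatentEmbedding
    selected_k: int
    selection_diagnostics: pd.DataFrame
    cluster: ClusterModel
    stats: list[OmnibusResult] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.cluster.labels, index=self.features.index, name="type")

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.summaries],
                "max_lateral_displacement": [s.max_lateral_displacement for s in self.summaries],
                "lateral_range_of_motion": [s.lateral_range_of_motion for s in self.summaries],
                "max_longitudinal_displacement": [
                    s.max_longitudinal_displacement for s in self.summaries
                ],
            }
        ).set_index("subject_id")

    def comparisons(self) -> pd.DataFrame:
        return comparisons_table(self.stats)


def standardize_trajectories(
    sequences: list[PoseSequence],
    sg_window: int = 7,
    sg_order: int = 2,
    points_per_phase: int = 25,
) -> tuple[list[StandardizedTrajectory], list[KinematicSummary]]:
    """Mirror, locate peak flexion, resample biphasically, smooth, summarize."""
    frame = canonical_frame()
    standardized, summaries = [], []
    for seq in sequences:
        traj = mirror_if_left(poses_to_dof(seq, frame))
        kpeak = find_peak_frame(traj)
        std = smooth_standardized(
            biphasic_resample(traj, kpeak, points_per_phase), sg_window, sg_order
        )
        standardized.append(std)
        summaries.append(summarize_dof(std))
    return standardized, summaries


def run_pipeline(
    cohort_config: CohortConfig | None = None,
    templates: tuple[PhenotypeTemplate, ...] | None = None,
    optimizer_config: OptimizerConfig | None = None,
    k_range: tuple[int, int] = (2, 6),
    fixed_k: int | None = None,
    seed: int | None = None,
    series_list: list[FrameSeries] | None = None,
    truth: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic (or pre-generated) cohort.

    ``seed`` drives clustering restarts and any permutation fallbacks; it
    defaults to the cohort seed.  Pass ``series_list`` (and optionally
    ``truth``) to analyze an existing cohort instead of generating one.
    """
    cohort_config = cohort_config or CohortConfig()
    optimizer_config = optimizer_config or OptimizerConfig()
    seed = cohort_config.seed if seed is None else seed

    if series_list is None:
        series_list, truth = generate_cohort(cohort_config, templates)
    if truth is None:
        truth = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in series_list],
                "label": [s.truth_label for s in series_list],
                "laterality": [s.laterality for s in series_list],
                "n_frames": [s.n_frames for s in series_list],
            }
        )

    sequences = [
        estimate_pose_sequence(center_series(series), optimizer_config)
        for series in series_list
    ]
    kept, qc_report = qc_filter(sequences, optimizer_config)

    standardized, summaries = standardize_trajectories(kept)
    features = build_feature_matrix(standardized)

    embedding = pca_project(features)
    if fixed_k is None:
        selected_k, diagnostics = select_k(embedding.projection, k_range, seed=seed)
    else:
        selected_k = fixed_k
        _, diagnostics = select_k(embedding.projection, k_range, seed=seed)
    model = kmeans_fit(
        embedding.projection, selected_k, seed=seed, subject_ids=list(features.index)
    )
    model.validity = validity_indices(embedding.projection, model.labels)
    ordered = order_by_gamma(model, summaries)

    metrics = pd.DataFrame(
        {
            "max_lateral_displacement": [s.max_lateral_displacement for s in summaries],
            "lateral_range_of_motion": [s.lateral_range_of_motion for s in summaries],
            "max_longitudinal_displacement": [s.max_longitudinal_displacement for s in summaries],
        },
        index=[s.subject_id for s in summaries],
    )
    stats_results = [
        omnibus_and_posthoc(metrics[var].to_numpy(), ordered.labels, family=var, seed=seed)
        for var in REPORT_VARIABLES
    ]

    return PipelineResult(
        truth=truth,
        pose_sequences=sequences,
        qc_report=qc_report,
        standardized=standardized,
        summaries=summaries,
        features=features,
        embedding=embedding,
        selected_k=selected_k,
        selection_diagnostics=diagnostics,
        cluster=ordered,
        stats=stats_results,
    )


def phenotype_shares(result: PipelineResult) -> pd.Series:
    """Percentage of subjects per gamma-ordered type."""
    counts = pd.Series(result.cluster.labels).value_counts().sort_index()
    return 100.0 * counts / counts.sum()
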