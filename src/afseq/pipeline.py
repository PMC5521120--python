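"""End-to-end orchestration: featurize -> select -> cross-validate.

This is the library-level composition used by the command-line interface
and by reproduction scripts.  A zero-feature final subset (possible on
uninformative data, where no descriptor clears the information-gain
threshold) degrades to the majority-class baseline rather than failing, and
the report says so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .descriptor_engine import FeaturizeConfig, featurize
from .feature_selection import (
    FeatureSubset,
    GAParams,
    ga_wrapper_select,
    ig_filter,
    redundancy_reduce,
)
from .matrix import DescriptorMatrix
from .seq_io import LabeledDataset
from .svm_model import CVReport, SVMParams, crossvalidate

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Selection provenance and cross-validated performance of one run."""

    stage_sizes: dict[str, int]          # all -> ig -> redundancy -> wrapper
    ig_subset: FeatureSubset
    redundancy_subset: FeatureSubset
    wrapper_subset: FeatureSubset
    cv_report: CVReport
    majority_baseline: bool = False      # true when the final subset was empty


def _majority_report(labels: np.ndarray, folds: int, n_runs: int, base_seed: int) -> CVReport:
    """CV report of the majority-class predictor (prior-only model)."""
    counts = np.bincount(labels, minlength=2)
    majority = int(np.argmax(counts))
    acc = 100.0 * counts[majority] / labels.size
    f1 = 0.0
    if majority == 1:
        precision = counts[1] / labels.size
        f1 = 2 * precision / (precision + 1.0)
    return CVReport(
        run_accuracies=[acc] * n_runs,
        run_f1=[f1] * n_runs,
        folds=folds,
        n_runs=n_runs,
        seeds=[base_seed + r for r in range(n_runs)],
    )


def run_pipeline(
    dataset: LabeledDataset | None = None,
    matrix: DescriptorMatrix | None = None,
    featurize_config: FeaturizeConfig | None = None,
    ig_fraction: float = 0.15,
    ig_bins: int = 10,
    rho: float = 0.95,
    ga: GAParams | None = None,
    wrapper_svm: SVMParams | None = None,
    cv_svm: SVMParams | None = None,
    folds: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    skip_wrapper: bool = False,
) -> PipelineResult:
    """Run the full selection + evaluation pipeline.

    Provide either a sequence ``dataset`` (featurized here) or a
    pre-computed labeled ``matrix``.  All randomness derives from ``seed``.
    """
    if (dataset is None) == (matrix is None):
        raise ValueError("provide exactly one of dataset or matrix")
    if matrix is None:
        matrix = featurize(dataset, featurize_config)
    if matrix.labels is None:
        raise ValueError("pipeline requires labels")

    ig_subset = ig_filter(matrix, fraction=ig_fraction, n_bins=ig_bins)
    red_subset = redundancy_reduce(matrix, ig_subset, rho=rho)
    if skip_wrapper or len(red_subset) == 0:
        wrapper_subset = FeatureSubset(names=list(red_subset.names), stage="wrapper")
    else:
        wrapper_subset = ga_wrapper_select(
            matrix, red_subset, ga=ga, svm=wrapper_svm, seed=seed
        )

    stage_sizes = {
        "all": matrix.n_features,
        "ig": len(ig_subset),
        "redundancy": len(red_subset),
        "wrapper": len(wrapper_subset),
    }
    logger.info(
        "selection stages: %s",
        " -> ".join(f"{k}={v}" for k, v in stage_sizes.items()),
    )

    majority_baseline = len(wrapper_subset) == 0
    if majority_baseline:
        logger.warning(
            "no feature survived selection; reporting the majority-class baseline"
        )
        report = _majority_report(matrix.labels, folds, n_runs, seed)
    else:
        report = crossvalidate(
            matrix.select(wrapper_subset.names).with_labels(matrix.labels),
            cv_svm,
            folds=folds,
            n_runs=n_runs,
            base_seed=seed,
        )
    return PipelineResult(
        stage_sizes=stage_sizes,
        ig_subset=ig_subset,
        redundancy_subset=red_subset,
        wrapper_subset=wrapper_subset,
        cv_report=report,
        majority_baseline=majority_baseline,
    )
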