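"""Quality control and centering for expression-difference matrices.

The corpus-level filters mirror standard practice for heterogeneous
compendia of log-ratio experiments: drop genes measured too rarely, drop
experiments covering too few genes, and drop experiments whose overall
magnitude suggests a normalisation problem.  All three thresholds are strict
inequalities.  The canonical pipeline order is genes -> coverage -> mean-abs,
and :func:`qc_pipeline` records how many rows/columns each rule removed.
"""

from __future__ import annotations

import logging

import numpy as np

from .expression import EmptyMatrixError, ExpressionDeltaMatrix

__all__ = [
    "filter_genes_by_missingness",
    "filter_experiments_by_coverage",
    "filter_experiments_by_mean_abs",
    "center_and_impute",
    "qc_pipeline",
]

logger = logging.getLogger(__name__)

#: Default thresholds: a gene is dropped when unobserved in more than 250
#: experiments; an experiment is dropped when it observes fewer than 4,000
#: genes or its mean absolute log difference exceeds 0.5.
DEFAULT_MAX_MISSING = 250
DEFAULT_MIN_GENES = 4000
DEFAULT_MAX_MEAN_ABS = 0.5


def filter_genes_by_missingness(
    matrix: ExpressionDeltaMatrix, max_missing: int = DEFAULT_MAX_MISSING
) -> ExpressionDeltaMatrix:
    """Remove genes unobserved in strictly more than ``max_missing`` experiments."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    keep = np.flatnonzero(matrix.missing_per_gene() <= max_missing)
    if keep.size == 0:
        raise EmptyMatrixError("all genes removed by missingness filter")
    return matrix.subset(gene_index=keep)


def filter_experiments_by_coverage(
    matrix: ExpressionDeltaMatrix, min_genes: int = DEFAULT_MIN_GENES
) -> ExpressionDeltaMatrix:
    """Remove experiments observing strictly fewer than ``min_genes`` genes."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    keep = np.flatnonzero(matrix.observed_per_experiment() >= min_genes)
    if keep.size == 0:
        raise EmptyMatrixError("all experiments removed by coverage filter")
    return matrix.subset(experiment_index=keep)


def filter_experiments_by_mean_abs(
    matrix: ExpressionDeltaMatrix, threshold: float = DEFAULT_MAX_MEAN_ABS
) -> ExpressionDeltaMatrix:
    """Remove experiments whose mean absolute observed value exceeds ``threshold``.

    Experiments with zero observed entries are removed as well (their mean is
    undefined) and logged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n_obs = matrix.observed_per_experiment()
    abs_vals = np.where(matrix.observed, np.abs(matrix.values), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs = abs_vals.sum(axis=0) / n_obs
    empty = n_obs == 0
    if empty.any():
        logger.warning(
            "removing %d experiment(s) with zero observed entries", int(empty.sum())
        )
    keep = np.flatnonzero(~empty & (mean_abs <= threshold))
    if keep.size == 0:
        raise EmptyMatrixError("all experiments removed by mean-abs filter")
    return matrix.subset(experiment_index=keep)


def center_and_impute(matrix: ExpressionDeltaMatrix) -> ExpressionDeltaMatrix:
    """Subtract each experiment's observed mean; impute missing entries to 0.

    Centering is per experiment (column) across genes, so every experiment
    becomes a contrast among genes.  Zero is the post-centering column mean,
    making the fill rank-neutral.
    """
    n_obs = matrix.observed_per_experiment()
    if np.any(n_obs == 0):
        raise ValueError("every experiment needs at least one observed entry")
    sums = np.where(matrix.observed, matrix.values, 0.0).sum(axis=0)
    means = sums / n_obs
    values = np.where(matrix.observed, matrix.values - means, 0.0)
    return ExpressionDeltaMatrix(
        values=values,
        observed=matrix.observed.copy(),
        gene_ids=list(matrix.gene_ids),
        experiment_ids=list(matrix.experiment_ids),
        centered=True,
    )


def qc_pipeline(
    matrix: ExpressionDeltaMatrix,
    max_missing: int = DEFAULT_MAX_MISSING,
    min_genes: int = DEFAULT_MIN_GENES,
    max_mean_abs: float = DEFAULT_MAX_MEAN_ABS,
) -> tuple[ExpressionDeltaMatrix, dict]:
    """Apply the three filters in canonical order and report removals."""
    report: dict = {
        "input": {"genes": matrix.n_genes, "experiments": matrix.n_experiments}
    }
    m1 = filter_genes_by_missingness(matrix, max_missing)
    report["genes_removed_missingness"] = matrix.n_genes - m1.n_genes
    m2 = filter_experiments_by_coverage(m1, min_genes)
    report["experiments_removed_coverage"] = m1.n_experiments - m2.n_experiments
    m3 = filter_experiments_by_mean_abs(m2, max_mean_abs)
    report["experiments_removed_mean_abs"] = m2.n_experiments - m3.n_experiments
    report["output"] = {"genes": m3.n_genes, "experiments": m3.n_experiments}
    return m3, report
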