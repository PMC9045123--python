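"""Gene x experiment matrices of log expression differences.

The central in-memory container is :class:`ExpressionDeltaMatrix`: a dense
``genes x experiments`` array of log-scale expression differences
(treated minus control) together with an observation mask.  Missing entries
are stored as NaN until :func:`tcsy.qc.center_and_impute` replaces them with
the post-centering column mean (zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDeltaMatrix",
    "EmptyMatrixError",
    "read_expression_tsv",
    "write_expression_tsv",
]


class EmptyMatrixError(ValueError):
    """Raised when a filter removes every gene or every experiment."""


@dataclass
class ExpressionDeltaMatrix:
    """Log expression differences with an explicit missing-value mask.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_experiments)``.  Entries where
        ``observed`` is False may be NaN.
    observed
        Boolean mask, same shape as ``values``; True where a measurement
        exists.
    gene_ids, experiment_ids
        Unique row / column identifiers.
    centered
        True once experiment means have been subtracted and missing entries
        imputed to zero.
    """

    values: np.ndarray
    observed: np.ndarray
    gene_ids: list[str]
    experiment_ids: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.experiment_ids = [str(e) for e in self.experiment_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must have the same shape")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match row count")
        if len(self.experiment_ids) != self.values.shape[1]:
            raise ValueError("experiment_ids length must match column count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.experiment_ids)) != len(self.experiment_ids):
            raise ValueError("duplicate experiment_ids")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed entries must be finite")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_per_gene(self) -> np.ndarray:
        """Number of unobserved experiments for each gene."""
        return (~self.observed).sum(axis=1)

    def observed_per_experiment(self) -> np.ndarray:
        """Number of observed gene values in each experiment."""
        return self.observed.sum(axis=0)

    # ------------------------------------------------------------------
    def subset(self, gene_index=None, experiment_index=None) -> "ExpressionDeltaMatrix":
        """Return a copy restricted to the given positional indices."""
        gi = np.arange(self.n_genes) if gene_index is None else np.asarray(gene_index)
        ei = (
            np.arange(self.n_experiments)
            if experiment_index is None
            else np.asarray(experiment_index)
        )
        return ExpressionDeltaMatrix(
            values=self.values[np.ix_(gi, ei)].copy(),
            observed=self.observed[np.ix_(gi, ei)].copy(),
            gene_ids=[self.gene_ids[i] for i in gi],
            experiment_ids=[self.experiment_ids[i] for i in ei],
            centered=self.centered,
        )

    def copy(self) -> "ExpressionDeltaMatrix":
        return replace(
            self, values=self.values.copy(), observed=self.observed.copy()
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, centered: bool = False):
        values = frame.to_numpy(dtype=float)
        return cls(
            values=values,
            observed=np.isfinite(values),
            gene_ids=[str(i) for i in frame.index],
            experiment_ids=[str(c) for c in frame.columns],
            centered=centered,
        )

    def to_dataframe(self) -> pd.DataFrame:
        values = self.values.copy()
        values[~self.observed] = np.nan
        return pd.DataFrame(values, index=self.gene_ids, columns=self.experiment_ids)


def read_expression_tsv(path) -> ExpressionDeltaMatrix:
    """Read a genes x experiments TSV with ``NA`` missing markers."""
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionDeltaMatrix.from_dataframe(frame)


def write_expression_tsv(matrix: ExpressionDeltaMatrix, path) -> None:
    """Write a genes x experiments TSV, missing entries as ``NA``."""
    matrix.to_dataframe().to_csv(path, sep="\t", na_rep="NA")
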