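"""Model/Results interface for the expression degree-of-freedom analysis.

:class:`ExpressionDofModel` wraps a QC'd expression-difference matrix;
``fit()`` runs the repeated cross-validated rank selection and returns a
:class:`DofResults` carrying the per-repeat selections, their spread, a
``summary()`` table, and constructors for the state basis and the universal
coordinate system derived from the fitted dimension.
"""

from __future__ import annotations

import numpy as np

from . import qc as _qc
from .coordinates import TcsyBasis, build_tcsy
from .dof import DofEstimate, StateBasis, estimate_dof, svd_decompose
from .expression import ExpressionDeltaMatrix, read_expression_tsv

__all__ = ["ExpressionDofModel", "DofResults"]


class ExpressionDofModel:
    """Degree-of-freedom model for a gene x experiment log-difference matrix.

    Parameters
    ----------
    delta
        Expression-difference matrix.  If it has not been centered, QC and
        centering behaviour are controlled by ``apply_qc``.
    n_train
        Training genes per cross-validation split (default 4,000).
    bracket
        Integer search interval for the candidate rank; default
        ``[1, min(800, rank bound) - 1]``.
    apply_qc
        Run the canonical QC filters before fitting (uses the thresholds in
        ``qc_params``).
    """

    def __init__(
        self,
        delta: ExpressionDeltaMatrix,
        n_train: int = 4000,
        bracket: tuple[int, int] | None = None,
        apply_qc: bool = False,
        qc_params: dict | None = None,
    ):
        self.qc_report: dict | None = None
        if apply_qc:
            delta, self.qc_report = _qc.qc_pipeline(delta, **(qc_params or {}))
        self.delta = delta
        self.n_train = n_train
        self.bracket = bracket

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ExpressionDofModel":
        """Build a model from a genes x experiments TSV (``NA`` = missing)."""
        return cls(read_expression_tsv(path), **kwargs)

    def fit(self, n_repeats: int = 15, seed: int = 0) -> "DofResults":
        estimate = estimate_dof(
            self.delta,
            n_train=self.n_train,
            n_repeats=n_repeats,
            seed=seed,
            bracket=self.bracket,
        )
        return DofResults(self, estimate, seed=seed)


class DofResults:
    """Fitted degree-of-freedom estimate and derived artefacts."""

    def __init__(self, model: ExpressionDofModel, estimate: DofEstimate, seed: int):
        self.model = model
        self.estimate = estimate
        self.seed = seed
        self._basis: StateBasis | None = None

    # -- estimates ------------------------------------------------------
    @property
    def runs(self) -> list[int]:
        return self.estimate.runs

    @property
    def dof(self) -> float:
        """Mean selected rank over repeats (the DOF point estimate)."""
        return self.estimate.mean

    @property
    def sd(self) -> float:
        return self.estimate.sd

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Expression degree-of-freedom estimate",
            "=" * 45,
            f"{'Genes':<28}{self.model.delta.n_genes:>17}",
            f"{'Experiments':<28}{self.model.delta.n_experiments:>17}",
            f"{'Training genes per split':<28}{self.model.n_train:>17}",
            f"{'Cross-validation repeats':<28}{e.n_repeats:>17}",
            "-" * 45,
            f"{'DOF (mean over repeats)':<28}{e.mean:>17.2f}",
            f"{'Standard deviation':<28}{e.sd:>17.2f}",
            f"{'Minimum':<28}{e.min:>17d}",
            f"{'Maximum':<28}{e.max:>17d}",
            "=" * 45,
        ]
        return "\n".join(lines)

    # -- derived artefacts ---------------------------------------------
    def state_basis(self) -> StateBasis:
        """SVD basis of the full centered matrix, `m` = rounded DOF estimate."""
        if self._basis is None:
            delta = self.model.delta
            if not delta.centered:
                delta = _qc.center_and_impute(delta)
            m = int(round(self.dof))
            basis = svd_decompose(delta)
            basis.m = min(m, basis.rank)
            self._basis = basis
        return self._basis

    def tcsy(self, m: int | None = None, **kwargs) -> TcsyBasis:
        """Universal coordinate basis truncated to ``m`` dimensions."""
        basis = self.state_basis()
        if m is None:
            m = basis.m
        return build_tcsy(basis, m=m, seed=self.seed, **kwargs)
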