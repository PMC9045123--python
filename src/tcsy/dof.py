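"""Degree-of-freedom estimation by cross-validated SVD rank selection.

The number of independent state variables needed to represent genome-wide
expression changes is estimated by gene-split cross-validation: the SVD of a
training block of genes supplies right singular vectors in experiment space,
and held-out genes are scored through the corrected projector

    E_approx(k) = sum_i || row_i [I - P P' + diag(P P')] ||^2

where ``P`` holds the top-``k`` right singular vectors.  The ``diag(P P')``
term is the leave-out correction of cross-validatory component-number
selection; without it the error would decrease monotonically in ``k``.  The
minimising ``k`` is located by an integer golden-section search and the whole
procedure is repeated over random gene splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionDeltaMatrix

__all__ = [
    "StateBasis",
    "CvRun",
    "DofEstimate",
    "svd_decompose",
    "cv_error",
    "golden_section_min",
    "estimate_dof",
    "dof_vs_datasize",
    "extrapolate_quadric",
    "extrapolate_linear_increments",
]

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


# ----------------------------------------------------------------------
@dataclass
class StateBasis:
    """SVD factorisation ``delta = U diag(sigma) V'`` plus a retained dimension.

    ``X = U[:, :m] * sigma[:m]`` is the gene-side coordinate basis spanned by
    the first ``m`` state variables.
    """

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    m: int
    gene_ids: list[str] | None = None
    experiment_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        r = self.sigma.shape[0]
        if self.U.shape[1] != r or self.V.shape[1] != r:
            raise ValueError("U/V column count must match number of singular values")
        if np.any(np.diff(self.sigma) > 1e-9 * max(1.0, self.sigma[0] if r else 1.0)):
            raise ValueError("singular values must be non-increasing")
        if not 0 <= self.m <= r:
            raise ValueError("retained dimension m out of range")

    @property
    def rank(self) -> int:
        return int(self.sigma.shape[0])

    @property
    def X(self) -> np.ndarray:
        """Coordinate basis: first ``m`` left singular vectors scaled by sigma."""
        return self.U[:, : self.m] * self.sigma[: self.m]

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.sigma) @ self.V.T


@dataclass
class CvRun:
    """One cross-validation evaluation: projector, candidate rank and error."""

    k: int
    e_approx: float
    n_train_genes: int
    n_test_genes: int
    seed: int


@dataclass
class DofEstimate:
    """Selected ranks over repeated random gene splits, with summaries."""

    runs: list[int]
    n_repeats: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.runs))

    @property
    def sd(self) -> float:
        return float(np.std(self.runs, ddof=1)) if len(self.runs) > 1 else 0.0

    @property
    def min(self) -> int:
        return int(np.min(self.runs))

    @property
    def max(self) -> int:
        return int(np.max(self.runs))

    def as_dict(self) -> dict:
        return {
            "runs": [int(k) for k in self.runs],
            "n_repeats": self.n_repeats,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
        }


# ----------------------------------------------------------------------
def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|entry| of each U column positive."""
    if U.shape[1] == 0:
        return U, V
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def svd_decompose(matrix: ExpressionDeltaMatrix, m: int | None = None) -> StateBasis:
    """Thin SVD of a centered, imputed expression-difference matrix."""
    if not matrix.centered:
        raise ValueError("matrix must be centered and imputed before SVD")
    values = matrix.values
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    U, sigma, Vt = np.linalg.svd(values, full_matrices=False)
    U, V = _fix_signs(U, Vt.T)
    r = sigma.shape[0]
    return StateBasis(
        U=U,
        sigma=sigma,
        V=V,
        m=r if m is None else m,
        gene_ids=list(matrix.gene_ids),
        experiment_ids=list(matrix.experiment_ids),
    )


# ----------------------------------------------------------------------
def cv_error(test_block: np.ndarray, P: np.ndarray) -> float:
    """Corrected cross-validation error of held-out genes.

    ``test_block`` is the held-out genes x experiments sub-matrix (centered
    with training column means); ``P`` has orthonormal columns in experiment
    space.  Returns ``sum_i || row_i @ (I - P P' + diag(P P')) ||^2``.
    """
    T = np.asarray(test_block, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[0] != T.shape[1]:
        raise ValueError(
            f"P has {P.shape[0]} rows but test block has {T.shape[1]} experiments"
        )
    if P.shape[1] == 0:
        return float(np.sum(T * T))
    d = np.sum(P * P, axis=1)  # diag(P P')
    R = T - (T @ P) @ P.T + T * d
    return float(np.sum(R * R))


# ----------------------------------------------------------------------
def golden_section_min(f, lo: int, hi: int) -> int:
    """Minimise an integer-argument function assumed unimodal on [lo, hi].

    Golden-ratio bracket shrinking on the integer lattice with memoised
    evaluations; probe points are rounded to the nearest integer and nudged
    by one when they collide.  Once the bracket width is <= 3 every remaining
    integer is evaluated.  Ties break toward smaller arguments.
    """
    lo, hi = int(lo), int(hi)
    if lo >= hi:
        raise ValueError("need lo < hi")
    cache: dict[int, float] = {}

    def g(k: int) -> float:
        if k not in cache:
            cache[k] = float(f(k))
        return cache[k]

    a, b = lo, hi
    while b - a > 3:
        span = b - a
        x1 = int(round(b - _INVPHI * span))
        x2 = int(round(a + _INVPHI * span))
        x1 = min(max(x1, a + 1), b - 1)
        x2 = min(max(x2, a + 1), b - 1)
        if x1 == x2:
            if x2 < b - 1:
                x2 += 1
            else:
                x1 -= 1
        if x1 > x2:
            x1, x2 = x2, x1
        if g(x1) <= g(x2):
            b = x2
        else:
            a = x1
    for k in range(a, b + 1):
        g(k)
    best = min((v, k) for k, v in cache.items() if lo <= k <= hi)
    return best[1]


# ----------------------------------------------------------------------
def _train_column_stats(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Column means over observed entries; all-missing columns fall back to 0."""
    n_obs = observed.sum(axis=0)
    sums = np.where(observed, values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), 0.0)
    return means


def _center_block(values, observed, means):
    return np.where(observed, values - means, 0.0)


def estimate_dof(
    matrix: ExpressionDeltaMatrix,
    n_train: int = 4000,
    n_repeats: int = 15,
    seed: int = 0,
    bracket: tuple[int, int] | None = None,
    splits=None,
) -> DofEstimate:
    """Estimate the expression degree of freedom over repeated gene splits.

    For each repeat: a seeded random split into ``n_train`` training genes and
    the remainder; centering/imputation with training column means (no
    information leaks from held-out genes); SVD of the training block; a
    golden-section search over candidate rank ``k`` of the corrected CV error
    on the held-out genes.

    Parameters
    ----------
    bracket
        Integer search interval for ``k``; defaults to
        ``[1, min(800, rank bound) - 1]`` where the rank bound is
        ``min(n_train, n_experiments)``.
    splits
        Optional explicit list of ``(train_index, test_index)`` positional
        index pairs overriding the random splits (length must be
        ``n_repeats``); useful for reproducing a specific partition.
    """
    G, E = matrix.shape
    if n_train >= G:
        raise ValueError("n_train must be smaller than the gene count")
    if E < 2:
        raise ValueError("need at least 2 experiments")
    rank_bound = min(n_train, E)
    if bracket is None:
        bracket = (1, min(800, rank_bound) - 1 if rank_bound <= 800 else 800)
    lo, hi = int(bracket[0]), int(bracket[1])
    if not (1 <= lo < hi <= rank_bound):
        raise ValueError(f"bracket {bracket} outside valid rank range [1, {rank_bound}]")

    ks: list[int] = []
    for r in range(n_repeats):
        if splits is None:
            rng = np.random.default_rng(seed + r)
            perm = rng.permutation(G)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
        else:
            train_idx, test_idx = (np.asarray(ix) for ix in splits[r])
        means = _train_column_stats(
            matrix.values[train_idx], matrix.observed[train_idx]
        )
        Tr = _center_block(matrix.values[train_idx], matrix.observed[train_idx], means)
        Te = _center_block(matrix.values[test_idx], matrix.observed[test_idx], means)
        _, _, Vt = np.linalg.svd(Tr, full_matrices=False)
        V = Vt.T  # experiments x rank
        TV = Te @ V
        dcum = np.cumsum(V * V, axis=1)  # experiments x rank
        frob2 = float(np.sum(Te * Te))

        def f(k: int) -> float:
            if k == 0:
                return frob2
            R = Te - TV[:, :k] @ V[:, :k].T + Te * dcum[:, k - 1]
            return float(np.sum(R * R))

        ks.append(golden_section_min(f, lo, min(hi, V.shape[1] - 1)))
    return DofEstimate(runs=ks, n_repeats=n_repeats)


# ----------------------------------------------------------------------
def dof_vs_datasize(
    matrix: ExpressionDeltaMatrix,
    axis: str,
    sizes,
    n_repeats: int = 15,
    seed: int = 0,
    n_train: int | None = None,
    train_fraction: float = 0.8,
    inner_repeats: int = 1,
    bracket: tuple[int, int] | None = None,
):
    """Resample one axis at several sizes and re-estimate the DOF at each.

    For each requested size, ``n_repeats`` seeded subsamples (without
    replacement) are drawn along ``axis`` ('experiments' or 'genes') and the
    DOF re-estimated on each (a single cross-validation per subsample by
    default).  Returns a long-format table of per-repeat selections, a
    per-size summary (mean, sd), and the successive increments of the mean.
    """
    if axis not in ("experiments", "genes"):
        raise ValueError("axis must be 'experiments' or 'genes'")
    G, E = matrix.shape
    limit = E if axis == "experiments" else G
    sizes = [int(s) for s in sizes]
    for s in sizes:
        if s > limit:
            raise ValueError(f"requested size {s} exceeds available {axis} ({limit})")

    records = []
    for si, size in enumerate(sizes):
        for rep in range(n_repeats):
            rng = np.random.default_rng([seed, si, rep])
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if axis == "experiments":
                idx = rng.choice(E, size=size, replace=False)
                sub = matrix.subset(experiment_index=idx)
                nt = n_train if n_train is not None else int(train_fraction * G)
            else:
                idx = rng.choice(G, size=size, replace=False)
                sub = matrix.subset(gene_index=idx)
                nt = int(train_fraction * size)
            est = estimate_dof(
                sub,
                n_train=nt,
                n_repeats=inner_repeats,
                seed=sub_seed,
                bracket=bracket,
            )
            for k in est.runs:
                records.append({"axis": axis, "size": size, "repeat": rep, "k": k})
    table = pd.DataFrame.from_records(records)
    summary = (
        table.groupby("size")["k"].agg(mean_dof="mean", sd_dof="std").reset_index()
    )
    summary["sd_dof"] = summary["sd_dof"].fillna(0.0)
    increments = summary["mean_dof"].diff().dropna().to_numpy()
    return table, summary, increments


def extrapolate_quadric(sizes, mean_dofs) -> tuple[float, float]:
    """OLS quadratic fit ``y = a x^2 + b x + c``; returns the vertex (size, dof).

    Requires a negative leading coefficient (a maximum); raises otherwise.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(mean_dofs, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a quadratic fit")
    if np.unique(x).size < 3:
        raise ValueError("degenerate design: need 3 distinct x values")
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:
        raise ValueError("quadratic opens upward; no interior maximum")
    vx = -b / (2.0 * a)
    vy = c - b * b / (4.0 * a)
    return float(vx), float(vy)


def extrapolate_linear_increments(sizes, increments) -> float:
    """Line fit of DOF increments vs size; returns the zero-crossing size."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(increments, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points for a linear fit")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: need 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise ValueError("flat increments: no zero crossing")
    return float(-intercept / slope)
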