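"""The universal transcriptional coordinate system.

A fixed basis ``X = U(m) Sigma(m)`` built from one reference corpus lets any
expression-change vector be represented by an m-dimensional coordinate
vector ``v_hat = (X'X)^{-1} X' delta`` — a least-squares projection that is
robust to missing genes because the gene count far exceeds ``m``.  States
from different studies become directly comparable once projected into the
shared basis.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .dof import StateBasis
from .expression import ExpressionDeltaMatrix

__all__ = [
    "TcsyBasis",
    "TcsyCoordinates",
    "build_tcsy",
    "save_basis",
    "load_basis",
    "project",
    "variance_explained",
    "compare_states",
    "export_parallel_coordinates",
]

DEFAULT_DIMENSIONS = 450


@dataclass
class TcsyCoordinates:
    """Coordinates of one transcriptional state in the shared basis."""

    v_hat: np.ndarray
    n_genes_used: int
    residual_fraction: float

    def __post_init__(self) -> None:
        self.v_hat = np.asarray(self.v_hat, dtype=float)
        if not np.all(np.isfinite(self.v_hat)):
            raise ValueError("coordinates must be finite")
        if not -1e-9 <= self.residual_fraction <= 1 + 1e-9:
            raise ValueError("residual_fraction outside [0, 1]")


@dataclass
class TcsyBasis:
    """Serialized coordinate basis with provenance.

    ``X`` is genes x m with mutually orthogonal columns (left singular
    vectors scaled by singular values).  ``fingerprint`` hashes the gene
    list and build parameters so that projections against a mismatched
    basis fail loudly.
    """

    X: np.ndarray
    gene_ids: list[str]
    m: int
    sigma: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.gene_ids), self.m):
            raise ValueError("X shape must be (n_genes, m)")

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\n".join(self.gene_ids).encode())
        h.update(json.dumps(self.provenance, sort_keys=True).encode())
        h.update(str(self.m).encode())
        return h.hexdigest()[:16]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        save_basis(self, path)

    def export_tsv(self, path) -> None:
        cols = [f"sv{j + 1}" for j in range(self.m)]
        pd.DataFrame(self.X, index=self.gene_ids, columns=cols).to_csv(
            path, sep="\t", index_label="gene_id"
        )


def build_tcsy(
    basis: StateBasis, m: int = DEFAULT_DIMENSIONS, seed: int | None = None, **extra
) -> TcsyBasis:
    """Truncate a state basis to its top ``m`` dimensions as a coordinate system."""
    if m > basis.rank:
        raise ValueError(f"m={m} exceeds available rank {basis.rank}")
    if basis.gene_ids is None:
        raise ValueError("state basis carries no gene identifiers")
    X = basis.U[:, :m] * basis.sigma[:m]
    provenance = {"m": int(m), "seed": seed, **extra}
    return TcsyBasis(
        X=X,
        gene_ids=list(basis.gene_ids),
        m=int(m),
        sigma=basis.sigma[:m].copy(),
        provenance=provenance,
    )


def save_basis(basis: TcsyBasis, path) -> None:
    """Write the basis to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=basis.X)
        if basis.sigma is not None:
            fh.create_dataset("sigma", data=basis.sigma)
        fh.create_dataset(
            "gene_ids", data=np.array(basis.gene_ids, dtype=h5py.string_dtype())
        )
        fh.attrs["m"] = basis.m
        fh.attrs["provenance"] = json.dumps(basis.provenance, sort_keys=True)
        fh.attrs["fingerprint"] = basis.fingerprint


def load_basis(path) -> TcsyBasis:
    with h5py.File(path, "r") as fh:
        basis = TcsyBasis(
            X=fh["X"][:],
            gene_ids=[g.decode() for g in fh["gene_ids"][:]],
            m=int(fh.attrs["m"]),
            sigma=fh["sigma"][:] if "sigma" in fh else None,
            provenance=json.loads(fh.attrs["provenance"]),
        )
    return basis


# ----------------------------------------------------------------------
def _as_series(delta, gene_ids) -> pd.Series:
    if isinstance(delta, pd.Series):
        return delta
    if isinstance(delta, dict):
        return pd.Series(delta)
    arr = np.asarray(delta, dtype=float)
    if arr.shape[0] != len(gene_ids):
        raise ValueError("positional delta vector must match basis gene count")
    return pd.Series(arr, index=gene_ids)


def project(basis: TcsyBasis, delta) -> TcsyCoordinates:
    """Project one expression-change vector into the coordinate system.

    ``delta`` may be a mapping/Series keyed by gene id (missing genes simply
    absent or NaN) or a positional vector aligned to the basis genes.  The
    normal equations are solved on the observed overlap; at least ``m``
    observed genes are required.
    """
    s = _as_series(delta, basis.gene_ids)
    index = basis.gene_index()
    rows, vals = [], []
    for g, v in s.items():
        i = index.get(str(g))
        if i is not None and np.isfinite(v):
            rows.append(i)
            vals.append(float(v))
    n_used = len(rows)
    if n_used < basis.m:
        n_missing = len(basis.gene_ids) - n_used
        raise ValueError(
            f"only {n_used} observed genes overlap the basis (need >= {basis.m}; "
            f"{n_missing} basis genes unobserved)"
        )
    dropped = s.index.difference([basis.gene_ids[i] for i in rows]).size - int(
        (~np.isfinite(s.to_numpy(dtype=float))).sum()
    )
    if dropped > 0:
        warnings.warn(f"{dropped} query gene(s) absent from the basis; dropped")
    Xo = basis.X[rows]
    f = np.asarray(vals)
    A = Xo.T @ Xo
    ridge = 1e-10 * np.trace(A) / max(basis.m, 1)
    v_hat = np.linalg.solve(A + ridge * np.eye(basis.m), Xo.T @ f)
    total = float(f @ f)
    if total == 0.0:
        resid_frac = 0.0
    else:
        resid = f - Xo @ v_hat
        resid_frac = min(max(float(resid @ resid) / total, 0.0), 1.0)
    return TcsyCoordinates(
        v_hat=v_hat, n_genes_used=n_used, residual_fraction=resid_frac
    )


def variance_explained(basis: TcsyBasis, data: ExpressionDeltaMatrix) -> pd.DataFrame:
    """Per-dimension and cumulative fractions of total variance captured.

    The fraction for dimension ``j`` is the squared magnitude of the data's
    orthogonal projection onto that basis direction divided by the data's
    total sum of squares.
    """
    if not data.centered:
        raise ValueError("data must be centered")
    if list(data.gene_ids) != list(basis.gene_ids):
        index = basis.gene_index()
        try:
            order = [index[g] for g in data.gene_ids]
        except KeyError as exc:
            raise ValueError(f"data gene {exc} absent from basis") from exc
        X = basis.X[order]
    else:
        X = basis.X
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("basis contains a zero column")
    Q = X / norms
    D = data.values
    total = float(np.sum(D * D))
    if total == 0:
        raise ValueError("data has zero total variance")
    per_dim = np.sum((Q.T @ D) ** 2, axis=1) / total
    return pd.DataFrame(
        {
            "dimension": np.arange(1, basis.m + 1),
            "fraction": per_dim,
            "cumulative": np.cumsum(per_dim),
        }
    )


# ----------------------------------------------------------------------
def compare_states(states, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation matrix of transcriptional states.

    ``states`` is a DataFrame (rows = shared index of genes or dimensions,
    columns = conditions) or a mapping of condition -> vector.  Pairwise
    complete observations are used; a zero-variance vector yields NaN for
    its pairs (reported as missing rather than raising).
    """
    if not isinstance(states, pd.DataFrame):
        states = pd.DataFrame({k: pd.Series(v) for k, v in dict(states).items()})
    if states.shape[1] < 2:
        raise ValueError("need at least 2 conditions to compare")
    corr = states.corr(method=method, min_periods=2)
    sd = states.std(ddof=0)
    ok = sd > 0
    np.fill_diagonal(corr.values, np.where(ok.to_numpy(), 1.0, np.nan))
    return corr


def export_parallel_coordinates(coords, path, groups=None) -> pd.DataFrame:
    """Long-format export of coordinate vectors for parallel-coordinate plots.

    ``coords`` maps condition name -> coordinate vector (all the same length
    ``m``); ``groups`` optionally maps condition -> replicate group.  Writes a
    TSV with columns (condition, dimension, value, group, group_sd) where
    ``group_sd`` is the per-dimension standard deviation across the members
    of the condition's group.
    """
    coords = {str(k): np.asarray(v, dtype=float) for k, v in dict(coords).items()}
    lengths = {v.shape[0] for v in coords.values()}
    if len(lengths) != 1:
        raise ValueError("all coordinate vectors must have the same dimension")
    (m,) = lengths
    groups = {c: (groups or {}).get(c, c) for c in coords}
    group_members: dict[str, list[str]] = {}
    for c, g in groups.items():
        group_members.setdefault(g, []).append(c)
    group_sd = {
        g: np.std(np.stack([coords[c] for c in members]), axis=0, ddof=0)
        for g, members in group_members.items()
    }
    rows = []
    for c, vec in coords.items():
        g = groups[c]
        for j in range(m):
            rows.append(
                {
                    "condition": c,
                    "dimension": j + 1,
                    "value": vec[j],
                    "group": g,
                    "group_sd": group_sd[g][j],
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
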