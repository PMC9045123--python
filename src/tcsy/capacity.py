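"""Shannon information capacity of extreme-weight regulatory motifs.

Per state variable, the motifs ranked in the top 1% by positive weight get
+1 and the top 1% by negative weight get -1 in a 65,536 x m selection
matrix (1,311 selected motifs per variable at the default fraction).  The
capacity of the whole configuration is the entropy of the partition of
motifs into identical-row groups,

    H = -sum_i p_i log2(p_i),

bounded by 16 bits for 8-mers.  Per promoter, with k selected motifs
present and q_i the fraction of variables selecting motif i,

    H(j) = -(1/k) sum_i q_i log2(q_i),

low values marking promoters dominated by motifs shared across many state
variables.  Genes ranked by H(j) feed preranked enrichment tools via a
two-column .rnk file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import MotifPresence, MotifWeightTable, N_MOTIFS, decode_motif

__all__ = [
    "SelectionMatrix",
    "PromoterCapacity",
    "select_extreme_motifs",
    "group_entropy",
    "overlap_counts",
    "promoter_capacity",
    "rank_genes_by_capacity",
    "write_rnk",
    "read_rnk",
    "binary_configuration_count",
]

DEFAULT_FRACTION = 0.01
MAX_GROUP_ENTROPY_BITS = math.log2(N_MOTIFS)  # 16 bits for 8-mers


@dataclass
class SelectionMatrix:
    """{-1, 0, +1} extreme-weight selection of motifs per state variable."""

    config: np.ndarray  # n_motifs x m, int8 (n_motifs = 65,536 for 8-mers)

    def __post_init__(self) -> None:
        self.config = np.asarray(self.config, dtype=np.int8)
        if self.config.ndim != 2 or self.config.shape[0] < 1:
            raise ValueError("config must be n_motifs x m")
        if not np.isin(self.config, (-1, 0, 1)).all():
            raise ValueError("config entries must be in {-1, 0, +1}")

    @property
    def n_motifs(self) -> int:
        return self.config.shape[0]

    @property
    def n_variables(self) -> int:
        return self.config.shape[1]

    def selected_per_variable(self) -> np.ndarray:
        return (self.config != 0).sum(axis=0)

    def selection_frequency(self) -> np.ndarray:
        """q_i: fraction of variables whose selected set contains motif i."""
        return (self.config != 0).sum(axis=1) / self.n_variables

    def to_sparse_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.config)
        labels = (
            [decode_motif(int(i)) for i in rows]
            if self.n_motifs == N_MOTIFS
            else [str(int(i)) for i in rows]
        )
        return pd.DataFrame(
            {
                "motif": labels,
                "variable": cols + 1,
                "sign": self.config[rows, cols].astype(int),
            }
        )


@dataclass
class PromoterCapacity:
    gene_id: str
    k: int
    q_values: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        if self.k != self.q_values.shape[0]:
            raise ValueError("k must equal the number of q values")
        if np.any((self.q_values <= 0) | (self.q_values > 1)):
            raise ValueError("q values must lie in (0, 1]")
        if self.h < -1e-12:
            raise ValueError("capacity must be non-negative")


def select_extreme_motifs(
    weights: MotifWeightTable | np.ndarray, fraction: float = DEFAULT_FRACTION
) -> SelectionMatrix:
    """Select the extreme tails of each variable's weight column.

    Per variable the ``ceil(fraction * N)`` largest weights get +1 and the
    ``floor(fraction * N)`` smallest get -1 (656 + 655 = 1,311 at the default
    1% of 65,536); ties break toward the lexicographically smaller motif
    string, which coincides with the row-index order of the encoding.  Toy
    weight tables with fewer rows are accepted (N = row count).  Under
    pathological mass ties the two tails can touch; the negative assignment
    then wins.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    W = weights.weights if isinstance(weights, MotifWeightTable) else np.asarray(weights)
    N, m = W.shape
    n_pos = int(math.ceil(fraction * N))
    n_neg = int(math.floor(fraction * N))
    config = np.zeros((N, m), dtype=np.int8)
    for j in range(m):
        asc = np.argsort(W[:, j], kind="stable")  # ties -> smaller motif index
        desc = np.argsort(-W[:, j], kind="stable")
        config[desc[:n_pos], j] = 1
        config[asc[:n_neg], j] = -1
    return SelectionMatrix(config=config)


def group_entropy(selection: SelectionMatrix) -> float:
    """Entropy (bits) of the partition of motifs into identical-row groups."""
    _, counts = np.unique(selection.config, axis=0, return_counts=True)
    p = counts / selection.config.shape[0]
    return float(-(p * np.log2(p)).sum())


def overlap_counts(selection: SelectionMatrix, variables) -> tuple[dict[int, int], int]:
    """How many motifs are selected in exactly 1, 2, ... of the given sets.

    Returns the exact-count histogram and the union size.
    """
    variables = np.asarray(list(variables), dtype=int)
    if variables.size == 0:
        raise ValueError("variable subset must be nonempty")
    if variables.min() < 0 or variables.max() >= selection.n_variables:
        raise ValueError("variable index out of range")
    member = selection.config[:, variables] != 0
    counts = member.sum(axis=1)
    hist = {
        c: int((counts == c).sum()) for c in range(1, variables.size + 1)
    }
    return hist, int((counts > 0).sum())


def promoter_capacity(
    selection: SelectionMatrix, presence: MotifPresence, gene_id: str
) -> PromoterCapacity | None:
    """Capacity H(j) of one promoter; None when no selected motif is present."""
    q_all = selection.selection_frequency()
    present = presence.present_motifs(gene_id)
    q = q_all[present]
    q = q[q > 0]
    k = q.shape[0]
    if k == 0:
        return None
    h = float(-(q * np.log2(q)).sum() / k)
    return PromoterCapacity(gene_id=gene_id, k=k, q_values=q, h=h)


def rank_genes_by_capacity(
    selection: SelectionMatrix, presence: MotifPresence
) -> pd.DataFrame:
    """All eligible genes sorted by ascending promoter capacity H(j).

    Genes whose promoters contain no selected motif have undefined capacity
    and are excluded (their count is available as the difference from the
    presence matrix's gene count).
    """
    q_all = selection.selection_frequency()
    selected = q_all > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(selected, -q_all * np.log2(np.where(selected, q_all, 1.0)), 0.0)
    M = presence.matrix.astype(float)
    k = M @ selected.astype(float)
    s = M @ contrib
    eligible = k > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(eligible, s / np.maximum(k, 1), np.nan)
    frame = pd.DataFrame(
        {
            "gene_id": presence.gene_ids,
            "k": k.astype(int),
            "h": h,
        }
    )
    frame = frame[eligible].sort_values(
        ["h", "gene_id"], ascending=[True, True], kind="stable"
    )
    return frame.reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    """Two-column, header-free gene/score file for preranked enrichment tools."""
    if ranked.empty:
        raise ValueError("ranked list is empty")
    try:
        ranked[["gene_id", "h"]].to_csv(
            path, sep="\t", header=False, index=False, float_format="%.10g"
        )
    except OSError as exc:
        raise OSError(f"failed to write rnk file {path}: {exc}") from exc


def read_rnk(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene_id", "h"])


def binary_configuration_count(m: int = 450) -> tuple[float, int]:
    """Significand and decimal exponent of 2**m (binary on/off state counts).

    ``binary_configuration_count(450)`` -> ``(2.91..., 125)``: the number of
    configurations available to 450 two-state variables.
    """
    digits = str(1 << m)
    exponent = len(digits) - 1
    significand = float(digits[0] + "." + digits[1:17])
    return significand, exponent
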