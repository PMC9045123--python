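"""Promoter extraction, 8-mer motif scanning and least-squares feature mapping.

Any per-gene feature vector f (binary motif presence, GO-term membership,
or an expression change) is mapped onto the state variables by the ordinary
least-squares solution of the normal equations

    v_hat = (X'X)^{-1} X' f,      X = U(m) Sigma(m),

restricted to the genes with an observed feature value.  Features are
mean-centered over the observed genes by default (``center=False`` is
available since the absolute weight scale depends on this choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .dof import StateBasis

__all__ = [
    "MOTIF_LENGTH",
    "N_MOTIFS",
    "PromoterRecord",
    "PromoterSet",
    "MotifPresence",
    "MotifWeightTable",
    "encode_motif",
    "decode_motif",
    "extract_promoters",
    "motif_presence",
    "map_feature",
    "map_all_motifs",
    "summarize_weights",
    "map_go_terms",
]

MOTIF_LENGTH = 8
ALPHABET = "ACGT"
N_MOTIFS = len(ALPHABET) ** MOTIF_LENGTH  # 4^8 = 65,536

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_POWERS = (len(ALPHABET) ** np.arange(MOTIF_LENGTH - 1, -1, -1)).astype(np.int64)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_motif(motif: str) -> int:
    """Base-4 big-endian index of an 8-mer (A=0, C=1, G=2, T=3)."""
    if len(motif) != MOTIF_LENGTH:
        raise ValueError(f"motif must have length {MOTIF_LENGTH}")
    code = 0
    for base in motif.upper():
        if base not in _BASE_INDEX:
            raise ValueError(f"invalid base {base!r} in motif")
        code = code * 4 + _BASE_INDEX[base]
    return code


def decode_motif(index: int) -> str:
    if not 0 <= index < N_MOTIFS:
        raise ValueError(f"motif index {index} out of range")
    bases = []
    for _ in range(MOTIF_LENGTH):
        bases.append(ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(bases))


# ----------------------------------------------------------------------
@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str  # uppercase, 5'->3' toward the gene (minus strand already revcomp'd)
    strand: str
    contig: str | None = None
    start: int | None = None  # 1-based inclusive genome coords of the region
    end: int | None = None


@dataclass
class PromoterSet:
    """Per-gene upstream sequences, strand-resolved."""

    records: dict[str, PromoterRecord]

    def __post_init__(self) -> None:
        for gid, rec in self.records.items():
            rec.sequence = rec.sequence.upper()
            if set(rec.sequence) - set("ACGTN"):
                raise ValueError(f"promoter of {gid} has non-ACGTN characters")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def sequences(self) -> dict[str, str]:
        return {g: r.sequence for g, r in self.records.items()}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self.records[gene_id]


# ----------------------------------------------------------------------
def _read_bed(path) -> list[tuple[str, str, int, int, str]]:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    # BED is 0-based half-open; convert to 1-based inclusive.
    return [
        (str(r.name_), str(r.contig), int(r.start) + 1, int(r.end), str(r.strand))
        for r in frame.rename(columns={"name": "name_"}).itertuples()
    ]


def _read_gff3(path) -> list[tuple[str, str, int, int, str]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append((feat.id, feat.seqid, int(feat.start), int(feat.end), feat.strand))
    return genes


def extract_promoters(genome_fasta, annotation, upstream: int = 500) -> PromoterSet:
    """Extract the ``upstream``-bp region 5' of each annotated gene start.

    Plus strand: the bases immediately upstream of the annotated start.
    Minus strand: the bases 3' of the annotated end in genome coordinates,
    reverse-complemented so every promoter reads 5'->3' toward the gene.
    Regions are truncated (never padded) at contig boundaries; a gene flush
    against the contig edge yields an empty sequence and a warning.
    """
    import pyfaidx

    fasta = pyfaidx.Fasta(str(genome_fasta))
    path = Path(str(annotation))
    if path.suffix.lower() == ".bed":
        genes = _read_bed(path)
    elif path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unrecognised annotation format: {path.suffix}")

    records: dict[str, PromoterRecord] = {}
    for gene_id, contig, start, end, strand in genes:
        if contig not in fasta:
            raise KeyError(f"gene {gene_id}: contig {contig!r} absent from FASTA")
        contig_len = len(fasta[contig])
        if strand == "+":
            lo = max(1, start - upstream)
            hi = start - 1
            seq = str(fasta[contig][lo - 1 : hi]).upper() if hi >= lo else ""
        else:
            lo = end + 1
            hi = min(contig_len, end + upstream)
            raw = str(fasta[contig][lo - 1 : hi]).upper() if hi >= lo else ""
            seq = reverse_complement(raw)
        if not seq:
            warnings.warn(f"gene {gene_id}: zero-length promoter at contig edge")
        records[gene_id] = PromoterRecord(
            gene_id=gene_id,
            sequence=seq,
            strand=strand,
            contig=contig,
            start=lo if seq else None,
            end=hi if seq else None,
        )
    return PromoterSet(records=records)


# ----------------------------------------------------------------------
@dataclass
class MotifPresence:
    """Binary gene x 65,536 presence of 8-mers (sparse, multiplicity ignored)."""

    matrix: sparse.csr_matrix
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), N_MOTIFS):
            raise ValueError("presence matrix must be n_genes x 65,536")

    def present_motifs(self, gene_id: str) -> np.ndarray:
        row = self.gene_ids.index(gene_id)
        return self.matrix.indices[
            self.matrix.indptr[row] : self.matrix.indptr[row + 1]
        ]


def _window_codes(seq: str) -> np.ndarray:
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.shape[0] < MOTIF_LENGTH:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, MOTIF_LENGTH)
    valid = (windows >= 0).all(axis=1)  # windows containing N contribute nothing
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    return np.unique(windows[valid].astype(np.int64) @ _POWERS)


def motif_presence(promoters) -> MotifPresence:
    """Scan promoters for forward-orientation 8-mer occurrences."""
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else dict(promoters)
    indptr = [0]
    indices: list[np.ndarray] = []
    for seq in seqs.values():
        hits = _window_codes(seq)
        indices.append(hits)
        indptr.append(indptr[-1] + hits.shape[0])
    data = np.ones(indptr[-1], dtype=np.int8)
    matrix = sparse.csr_matrix(
        (data, np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
         np.asarray(indptr)),
        shape=(len(seqs), N_MOTIFS),
    )
    return MotifPresence(matrix=matrix, gene_ids=list(seqs))


# ----------------------------------------------------------------------
def _basis_X(basis) -> tuple[np.ndarray, list[str]]:
    if hasattr(basis, "gene_ids") and hasattr(basis, "X"):
        if basis.gene_ids is None:
            raise ValueError("basis carries no gene identifiers")
        return np.asarray(basis.X, dtype=float), list(basis.gene_ids)
    raise TypeError("basis must expose .X and .gene_ids")


def _solve_normal(X: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (X'X + ridge I) w = rhs with a tiny SPD-stabilising ridge."""
    from scipy import linalg

    m = X.shape[1]
    A = X.T @ X
    ridge = 1e-10 * np.trace(A) / max(m, 1)
    return linalg.solve(A + ridge * np.eye(m), rhs, assume_a="pos")


def map_feature(basis, gene_indicator, center: bool = True) -> np.ndarray:
    """Map one per-gene feature vector onto the state variables.

    ``gene_indicator`` may be a Series/dict keyed by gene id or a positional
    vector aligned with the basis genes; NaN marks missing genes.  Requires
    at least ``m`` observed genes (the fit is underdetermined otherwise).
    """
    X, gene_ids = _basis_X(basis)
    m = X.shape[1]
    if isinstance(gene_indicator, dict):
        gene_indicator = pd.Series(gene_indicator)
    if isinstance(gene_indicator, pd.Series):
        f = gene_indicator.reindex(gene_ids).to_numpy(dtype=float)
    else:
        f = np.asarray(gene_indicator, dtype=float)
        if f.shape[0] != len(gene_ids):
            raise ValueError("positional indicator must match basis gene count")
    obs = np.isfinite(f)
    n_obs = int(obs.sum())
    if n_obs < m:
        raise ValueError(f"only {n_obs} observed genes; need >= m = {m}")
    fo = f[obs]
    if center:
        fo = fo - fo.mean()
    Xo = X[obs]
    return _solve_normal(Xo, Xo.T @ fo)


@dataclass
class MotifWeightTable:
    """Least-squares weights of all 65,536 motifs on the state variables."""

    weights: np.ndarray  # N_MOTIFS x m

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != N_MOTIFS:
            raise ValueError(f"weight table must have {N_MOTIFS} rows")

    @property
    def n_variables(self) -> int:
        return self.weights.shape[1]

    def column(self, variable: int) -> np.ndarray:
        return self.weights[:, variable]

    def to_frame(self) -> pd.DataFrame:
        motifs = [decode_motif(i) for i in range(N_MOTIFS)]
        cols = [f"sv{j + 1}" for j in range(self.n_variables)]
        return pd.DataFrame(self.weights, index=motifs, columns=cols)


def map_all_motifs(basis, presence: MotifPresence, center: bool = True) -> MotifWeightTable:
    """Map every motif's presence vector onto the state variables at once."""
    X, gene_ids = _basis_X(basis)
    if presence.gene_ids != gene_ids:
        order = {g: i for i, g in enumerate(presence.gene_ids)}
        try:
            rows = [order[g] for g in gene_ids]
        except KeyError as exc:
            raise ValueError(f"basis gene {exc} missing from presence matrix") from exc
        F = presence.matrix[rows].astype(float)
    else:
        F = presence.matrix.astype(float)
    XtF = (F.T @ X).T  # m x N_MOTIFS
    if center:
        mu = np.asarray(F.mean(axis=0)).ravel()
        XtF = XtF - np.outer(X.sum(axis=0), mu)
    W = _solve_normal(X, XtF)
    return MotifWeightTable(weights=W.T)


def summarize_weights(
    table: MotifWeightTable, variable: int = 0, threshold: float = 0.5, top_n: int = 10
) -> dict:
    """Distribution summary of one variable's motif weights.

    Reports the counts of motifs below ``-threshold`` and above ``threshold``,
    the mean and SD of the column, and the ``top_n`` most extreme motifs on
    each tail.
    """
    w = table.column(variable)
    order = np.argsort(w, kind="stable")
    neg = [(decode_motif(int(i)), float(w[i])) for i in order[:top_n]]
    pos = [(decode_motif(int(i)), float(w[i])) for i in order[::-1][:top_n]]
    return {
        "variable": variable,
        "n_below": int((w < -threshold).sum()),
        "n_above": int((w > threshold).sum()),
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=0)),
        "top_negative": neg,
        "top_positive": pos,
    }


def map_go_terms(basis, go_table: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Map each GO term's binary membership vector onto the state variables.

    ``go_table`` needs columns ``gene_id`` and ``term_id`` (``term_name``
    carried through when present).  Terms with no member gene in the basis
    are skipped with a warning.  Rows of the result are sortable by any
    ``sv*`` column to rank terms by signed weight per variable.
    """
    X, gene_ids = _basis_X(basis)
    index = {g: i for i, g in enumerate(gene_ids)}
    names = {}
    if "term_name" in go_table.columns:
        names = dict(zip(go_table["term_id"], go_table["term_name"]))
    rows = []
    for term_id, members in go_table.groupby("term_id")["gene_id"]:
        hit = [index[g] for g in members if g in index]
        if not hit:
            warnings.warn(f"GO term {term_id}: no member genes in basis; skipped")
            continue
        indicator = np.zeros(len(gene_ids))
        indicator[hit] = 1.0
        v_hat = map_feature(basis, indicator, center=center)
        rows.append({"term_id": term_id, "term_name": names.get(term_id, ""),
                     "n_genes": len(hit),
                     **{f"sv{j + 1}": v_hat[j] for j in range(X.shape[1])}})
    columns = ["term_id", "term_name", "n_genes"] + [
        f"sv{j + 1}" for j in range(X.shape[1])
    ]
    return pd.DataFrame(rows, columns=columns).set_index("term_id")
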