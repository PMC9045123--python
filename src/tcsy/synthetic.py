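"""Synthetic data with the statistical structure the analysis assumes.

Three generators stand in for a real expression corpus, genome and GO
annotation so every downstream stage is testable without downloads:

* a low-rank-plus-noise expression-difference matrix with a known singular
  value profile and missing-at-random entries;
* a linear state-space simulator ``x(t+1) = A x(t) + B u(t)``,
  ``y(t) = C x(t) + D u(t)`` whose treatment/control output differences have
  rank bounded by the state dimension;
* 500-bp promoter sequences with 8-mer motifs planted preferentially into
  high-loading genes, embedded in a toy genome (FASTA + BED/GFF3) laid out so
  that promoter extraction inverts the generator exactly;
* GO-like gene sets whose membership probability couples to a designated
  state variable's loadings.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dof import StateBasis, _fix_signs
from .expression import ExpressionDeltaMatrix
from .features import (
    MOTIF_LENGTH,
    PromoterRecord,
    PromoterSet,
    reverse_complement,
)

__all__ = [
    "PlantedMotif",
    "SyntheticTruth",
    "StateSpaceSystem",
    "GoAnnotations",
    "simulate_low_rank_delta",
    "simulate_state_space",
    "simulate_promoters",
    "simulate_go_annotations",
    "write_genome_fasta",
    "write_bed",
    "write_gff3",
]

GENE_BODY_LENGTH = 60
GENES_PER_CONTIG = 1000
#: Genes in this top fraction of the loading ranking receive the full
#: enrichment probability; insertion probability declines linearly to zero
#: across the remaining ranks.
TOP_LOADING_FRACTION = 0.1


@dataclass
class PlantedMotif:
    motif: str
    variable: int
    enrichment: float

    def __post_init__(self) -> None:
        self.motif = self.motif.upper()
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"planted motif {self.motif!r} has non-ACGT characters")
        if len(self.motif) != MOTIF_LENGTH:
            raise ValueError("planted motifs must be 8-mers")
        if not 0 <= self.enrichment <= 1:
            raise ValueError("enrichment probability must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests."""

    rank: int
    singular_values: np.ndarray
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    planted_motifs: list[PlantedMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.singular_values.shape != (self.rank,):
            raise ValueError("singular_values length must equal rank")
        if np.any(self.singular_values <= 0):
            raise ValueError("singular values must be strictly positive")
        if np.any(np.diff(self.singular_values) > 0):
            raise ValueError("singular values must be non-increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        self.planted_motifs = [
            m if isinstance(m, PlantedMotif) else PlantedMotif(*m)
            for m in self.planted_motifs
        ]

    @classmethod
    def linear_profile(cls, rank: int, top: float, bottom: float, **kwargs):
        """Singular values declining linearly from ``top`` to ``bottom``."""
        return cls(
            rank=rank, singular_values=np.linspace(top, bottom, rank), **kwargs
        )


def _haar_frame(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random orthonormal n x k frame (QR of a Gaussian matrix, signs fixed)."""
    Q, R = np.linalg.qr(rng.standard_normal((n, k)))
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def simulate_low_rank_delta(
    n_genes: int, n_experiments: int, truth: SyntheticTruth
) -> tuple[ExpressionDeltaMatrix, StateBasis]:
    """Generate ``delta = U diag(s) V' + noise`` with a missing-at-random mask.

    Returns the matrix and the ground-truth factors as a :class:`StateBasis`.
    """
    if n_genes <= truth.rank or n_experiments <= truth.rank:
        raise ValueError("both dimensions must exceed the true rank")
    rng = np.random.default_rng(truth.seed)
    U = _haar_frame(rng, n_genes, truth.rank)
    V = _haar_frame(rng, n_experiments, truth.rank)
    U, V = _fix_signs(U, V)
    values = (U * truth.singular_values) @ V.T
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    observed = np.ones(values.shape, dtype=bool)
    if truth.missing_rate > 0:
        observed = rng.random(values.shape) >= truth.missing_rate
        values = np.where(observed, values, np.nan)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    experiment_ids = [f"exp{j + 1:05d}" for j in range(n_experiments)]
    matrix = ExpressionDeltaMatrix(
        values=values,
        observed=observed,
        gene_ids=gene_ids,
        experiment_ids=experiment_ids,
    )
    basis = StateBasis(
        U=U,
        sigma=truth.singular_values.copy(),
        V=V,
        m=truth.rank,
        gene_ids=gene_ids,
        experiment_ids=experiment_ids,
    )
    return matrix, basis


# ----------------------------------------------------------------------
@dataclass
class StateSpaceSystem:
    """Discrete-time linear system x(t+1) = A x(t) + B u(t), y = C x + D u."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray | None = None
    x0: np.ndarray | None = None
    treatment_time: int = 0

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        r = self.A.shape[0]
        if r < 1 or self.A.shape != (r, r):
            raise ValueError("A must be square with r >= 1")
        if self.B.shape[0] != r:
            raise ValueError("B must have r rows")
        if self.C.shape[1] != r:
            raise ValueError("C must have r columns")
        if self.D is None:
            self.D = np.zeros((self.C.shape[0], self.B.shape[1]))
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ValueError("D must be (n_genes, n_inputs)")
        if self.x0 is None:
            self.x0 = np.zeros(r)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (r,):
            raise ValueError("x0 must have length r")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_genes(self) -> int:
        return self.C.shape[0]


def _propagate(system: StateSpaceSystem, inputs: list[np.ndarray]) -> np.ndarray:
    x = system.x0.copy()
    for u in inputs:
        x = system.A @ x + system.B @ u
    return system.C @ x + system.D @ inputs[-1]


def simulate_state_space(
    system: StateSpaceSystem,
    input_contrasts,
    horizon_t: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionDeltaMatrix:
    """Expression differences between treated and control trajectories.

    Each contrast is a pair ``(u_star, u)`` of constant input vectors; the
    treated trajectory switches from ``u`` to ``u_star`` at
    ``system.treatment_time`` while the control keeps ``u`` throughout.  The
    column for a contrast is ``y*(horizon) - y(horizon)`` plus observation
    noise.
    """
    j = system.treatment_time
    if horizon_t <= j:
        raise ValueError("horizon_t must exceed treatment_time")
    rng = np.random.default_rng(seed)
    columns = []
    for u_star, u in input_contrasts:
        u_star = np.asarray(u_star, dtype=float)
        u = np.asarray(u, dtype=float)
        if u_star.shape != (system.n_inputs,) or u.shape != (system.n_inputs,):
            raise ValueError("input vectors must have length n_inputs")
        treated = [u] * j + [u_star] * (horizon_t - j)
        control = [u] * horizon_t
        delta = _propagate(system, treated) - _propagate(system, control)
        if noise_sd > 0:
            delta = delta + rng.normal(0.0, noise_sd, size=delta.shape)
        columns.append(delta)
    values = np.column_stack(columns)
    return ExpressionDeltaMatrix(
        values=values,
        observed=np.ones(values.shape, dtype=bool),
        gene_ids=[f"gene{i + 1:05d}" for i in range(system.n_genes)],
        experiment_ids=[f"contrast{j + 1:04d}" for j in range(values.shape[1])],
    )


# ----------------------------------------------------------------------
@dataclass
class ToyGenome:
    """Contig sequences plus gene coordinates for the synthetic world."""

    contigs: dict[str, str]
    genes: list[tuple[str, str, int, int, str]]  # (gene_id, contig, start, end, strand)


def _loading_scale(loadings_col: np.ndarray) -> np.ndarray:
    """Per-gene insertion scale from the loading ranking on one variable.

    Top-decile genes get scale 1; the rest decline linearly to ~0 with rank.
    """
    G = loadings_col.shape[0]
    order = np.argsort(-loadings_col, kind="stable")
    ranks = np.empty(G, dtype=int)
    ranks[order] = np.arange(G)
    n_top = max(1, int(np.ceil(TOP_LOADING_FRACTION * G)))
    scale = np.where(
        ranks < n_top, 1.0, (G - ranks) / max(G - n_top, 1)
    )
    return scale


def simulate_promoters(
    gene_ids,
    loadings,
    truth: SyntheticTruth,
    length: int = 500,
    out_dir=None,
) -> tuple[PromoterSet, ToyGenome]:
    """Generate promoters with motifs planted in proportion to loadings.

    Background sequence is uniform over ACGT.  Each planted motif is inserted
    (overwriting the background at a seeded uniform position) with
    probability = enrichment_probability x loading-rank scale on the target
    variable.  The promoters are embedded in a toy genome — one contig per
    1,000 genes, genes on alternating strands — such that
    :func:`tcsy.features.extract_promoters` recovers the same sequences.
    When ``out_dir`` is given, writes ``genome.fa``, ``genes.bed`` and
    ``genes.gff3`` there.
    """
    gene_ids = [str(g) for g in gene_ids]
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] != len(gene_ids):
        raise ValueError("loadings must be indexed by gene")
    if length < MOTIF_LENGTH:
        raise ValueError("promoter length shorter than the motif length")
    rng = np.random.default_rng([truth.seed, 1])
    G = len(gene_ids)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    promoters = [
        b"".join(bases[rng.integers(0, 4, size=length)]).decode() for _ in range(G)
    ]

    for planted in truth.planted_motifs:
        if planted.variable >= loadings.shape[1]:
            raise ValueError(
                f"planted motif targets variable {planted.variable} but loadings "
                f"have only {loadings.shape[1]} columns"
            )
        scale = _loading_scale(loadings[:, planted.variable])
        insert = rng.random(G) < planted.enrichment * scale
        positions = rng.integers(0, length - MOTIF_LENGTH + 1, size=G)
        for g in np.flatnonzero(insert):
            p = int(positions[g])
            promoters[g] = (
                promoters[g][:p] + planted.motif + promoters[g][p + MOTIF_LENGTH :]
            )

    # Lay the promoters into a toy genome (round-trip with extract_promoters).
    contigs: dict[str, list[str]] = {}
    offsets: dict[str, int] = {}
    genes: list[tuple[str, str, int, int, str]] = []
    records: dict[str, PromoterRecord] = {}
    for g, gene_id in enumerate(gene_ids):
        contig = f"contig{g // GENES_PER_CONTIG + 1:03d}"
        parts = contigs.setdefault(contig, [])
        offset = offsets.setdefault(contig, 0)
        body = b"".join(bases[rng.integers(0, 4, size=GENE_BODY_LENGTH)]).decode()
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            parts.append(promoters[g] + body)
            start = offset + length + 1
            end = offset + length + GENE_BODY_LENGTH
            p_lo, p_hi = offset + 1, offset + length
        else:
            parts.append(body + reverse_complement(promoters[g]))
            start = offset + 1
            end = offset + GENE_BODY_LENGTH
            p_lo, p_hi = end + 1, end + length
        offsets[contig] = offset + length + GENE_BODY_LENGTH
        genes.append((gene_id, contig, start, end, strand))
        records[gene_id] = PromoterRecord(
            gene_id=gene_id,
            sequence=promoters[g],
            strand=strand,
            contig=contig,
            start=p_lo,
            end=p_hi,
        )
    genome = ToyGenome(
        contigs={c: "".join(parts) for c, parts in contigs.items()}, genes=genes
    )
    pset = PromoterSet(records=records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_genome_fasta(genome, out_dir / "genome.fa")
        write_bed(genome, out_dir / "genes.bed")
        write_gff3(genome, out_dir / "genes.gff3")
    return pset, genome


def write_genome_fasta(genome: ToyGenome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=contig, description="")
        for contig, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(genome: ToyGenome, path) -> None:
    """BED6 (0-based half-open) gene annotation."""
    with open(path, "w") as fh:
        for gene_id, contig, start, end, strand in genome.genes:
            fh.write(f"{contig}\t{start - 1}\t{end}\t{gene_id}\t0\t{strand}\n")


def write_gff3(genome: ToyGenome, path) -> None:
    """GFF3 (1-based inclusive) gene annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, contig, start, end, strand in genome.genes:
            fh.write(
                f"{contig}\ttcsy\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )


# ----------------------------------------------------------------------
@dataclass
class GoAnnotations:
    """Synthetic gene/term table plus the ground-truth term -> variable map."""

    table: pd.DataFrame
    term_variables: dict[str, int]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


GO_BASE_RATE = 0.15
_ASPECTS = ("P", "F", "C")


def simulate_go_annotations(
    gene_ids, n_terms: int, coupling: float, seed: int = 0, loadings=None
) -> GoAnnotations:
    """Gene sets whose membership couples to state-variable loadings.

    Membership probability follows a logistic model
    ``p = sigmoid(logit(0.15) + coupling * z)`` where ``z`` is the gene's
    standardized loading on the term's designated variable (term ``t``
    targets variable ``t mod n_variables``).  ``coupling = 0`` gives
    loading-independent membership at the base rate.
    """
    from scipy.special import expit, logit

    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    gene_ids = [str(g) for g in gene_ids]
    G = len(gene_ids)
    rng = np.random.default_rng(seed)
    if loadings is None:
        loadings = np.zeros((G, 1))
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    if loadings.shape[0] != G:
        raise ValueError("loadings must be indexed by gene")
    n_vars = loadings.shape[1]
    rows = []
    term_variables = {}
    base = logit(GO_BASE_RATE)
    for t in range(n_terms):
        var = t % n_vars
        term_id = f"GO:{7000000 + t}"
        term_variables[term_id] = var
        col = loadings[:, var]
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(G)
        p = expit(base + coupling * z)
        members = np.flatnonzero(rng.random(G) < p)
        for g in members:
            rows.append(
                {
                    "gene_id": gene_ids[g],
                    "term_id": term_id,
                    "term_name": f"synthetic process {t + 1}",
                    "aspect": _ASPECTS[t % 3],
                }
            )
    table = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name", "aspect"])
    return GoAnnotations(table=table, term_variables=term_variables)
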