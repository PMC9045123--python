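import numpy as np
import pytest

import tcsy
from tcsy import synthetic


def make_matrix(values, observed=None, centered=False):
    """Wrap a raw array as an ExpressionDeltaMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    if observed is None:
        observed = np.isfinite(values)
    return tcsy.ExpressionDeltaMatrix(
        values=values,
        observed=observed,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        experiment_ids=[f"e{j}" for j in range(values.shape[1])],
        centered=centered,
    )


@pytest.fixture
def rank3_world():
    """Noiseless rank-3 matrix with its ground-truth factors."""
    truth = tcsy.SyntheticTruth.linear_profile(rank=3, top=10.0, bottom=4.0, seed=42)
    delta, basis = tcsy.simulate_low_rank_delta(50, 20, truth)
    return delta, basis, truth


@pytest.fixture
def promoter_world(tmp_path):
    """120 genes with one strongly planted motif, written to FASTA/BED/GFF3."""
    truth = tcsy.SyntheticTruth.linear_profile(
        rank=4,
        top=20.0,
        bottom=8.0,
        seed=7,
        planted_motifs=[("TATATAAA", 0, 1.0)],
    )
    delta, basis = tcsy.simulate_low_rank_delta(120, 40, truth)
    promoters, genome = synthetic.simulate_promoters(
        delta.gene_ids, basis.U, truth, out_dir=tmp_path
    )
    return {
        "truth": truth,
        "delta": delta,
        "basis": basis,
        "promoters": promoters,
        "genome": genome,
        "dir": tmp_path,
    }
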