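"""End-to-end orchestration: simulate/ingest -> QC -> DOF -> basis -> features
-> capacity, with a machine-readable run manifest.

Each stage writes its artefacts under the output directory and records a
SHA-256 checksum in ``manifest.json``; identical configuration + seed yields
identical checksums.  A stage failure raises :class:`PipelineStageError`
naming the stage, leaving earlier artefacts in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import capacity as _capacity
from . import coordinates as _coordinates
from . import features as _features
from . import qc as _qc
from . import synthetic as _synthetic
from .expression import read_expression_tsv, write_expression_tsv
from .model import ExpressionDofModel

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration mirrored 1:1 by the CLI flags (CLI wins on conflict)."""

    out_dir: str
    seed: int
    expression_tsv: str | None = None
    genome_fasta: str | None = None
    annotation: str | None = None
    go_table: str | None = None
    # simulation (used when expression_tsv is absent)
    simulate: bool = False
    sim_genes: int = 500
    sim_experiments: int = 200
    sim_rank: int = 10
    sim_noise_sd: float = 0.1
    sim_missing_rate: float = 0.05
    # QC thresholds
    max_missing: int = _qc.DEFAULT_MAX_MISSING
    min_genes: int = _qc.DEFAULT_MIN_GENES
    max_mean_abs: float = _qc.DEFAULT_MAX_MEAN_ABS
    # DOF settings
    n_train: int = 4000
    n_repeats: int = 15
    bracket_hi: int | None = None
    # coordinate system / selection
    m: int = 450
    selection_fraction: float = _capacity.DEFAULT_FRACTION

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("max_missing", "min_genes", "n_train", "n_repeats", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in canonical order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}

    def record(name: str, *paths: Path) -> None:
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)
        manifest["stages"][name]["artifacts"] = [p.name for p in paths]

    def stage(name: str):
        manifest["stages"][name] = {"started": time.time()}
        logger.info("stage %s", name)
        return name

    genome_fasta = config.genome_fasta
    annotation = config.annotation
    go_table_path = config.go_table

    # -- simulate / ingest ---------------------------------------------
    name = stage("input")
    try:
        if config.expression_tsv is not None:
            delta = read_expression_tsv(config.expression_tsv)
            manifest["stages"][name]["source"] = str(config.expression_tsv)
            record(name)
        elif config.simulate:
            truth = _synthetic.SyntheticTruth.linear_profile(
                rank=config.sim_rank,
                top=2.0 * np.sqrt(config.sim_genes),
                bottom=0.5 * np.sqrt(config.sim_genes),
                noise_sd=config.sim_noise_sd,
                missing_rate=config.sim_missing_rate,
                seed=config.seed,
                planted_motifs=[("TATATAAA", 0, 0.9)],
            )
            delta, true_basis = _synthetic.simulate_low_rank_delta(
                config.sim_genes, config.sim_experiments, truth
            )
            expr_path = out / "expression.tsv"
            write_expression_tsv(delta, expr_path)
            _, genome = _synthetic.simulate_promoters(
                delta.gene_ids, true_basis.U, truth, out_dir=out
            )
            go = _synthetic.simulate_go_annotations(
                delta.gene_ids,
                n_terms=20,
                coupling=2.0,
                seed=config.seed,
                loadings=true_basis.U,
            )
            go_path = out / "go.tsv"
            go.write_tsv(go_path)
            genome_fasta = str(out / "genome.fa")
            annotation = str(out / "genes.bed")
            go_table_path = str(go_path)
            record(
                name, expr_path, out / "genome.fa", out / "genes.bed",
                out / "genes.gff3", go_path,
            )
        else:
            raise FileNotFoundError(
                "no expression TSV given and --simulate not requested"
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(name, exc) from exc

    # -- qc -------------------------------------------------------------
    name = stage("qc")
    try:
        # On simulated worlds much smaller than a real corpus, cap the
        # coverage threshold at half the gene count so it stays meaningful.
        min_genes = config.min_genes
        if config.expression_tsv is None and config.simulate:
            min_genes = min(min_genes, max(1, delta.n_genes // 2))
        filtered, report = _qc.qc_pipeline(
            delta,
            max_missing=config.max_missing,
            min_genes=min_genes,
            max_mean_abs=config.max_mean_abs,
        )
        qc_path = out / "qc_report.json"
        qc_path.write_text(json.dumps(report, indent=2))
        record(name, qc_path)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc

    # -- dof -------------------------------------------------------------
    name = stage("dof")
    try:
        n_train = config.n_train
        if n_train >= filtered.n_genes:
            # 80/20 split fallback for matrices smaller than the default
            n_train = max(1, int(0.8 * filtered.n_genes))
        bracket = None
        if config.bracket_hi is not None:
            bracket = (1, config.bracket_hi)
        model = ExpressionDofModel(filtered, n_train=n_train, bracket=bracket)
        results = model.fit(n_repeats=config.n_repeats, seed=config.seed)
        dof_path = out / "dof.json"
        dof_path.write_text(json.dumps(results.estimate.as_dict(), indent=2))
        manifest["stages"][name]["dof"] = results.estimate.as_dict()
        record(name, dof_path)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc

    # -- basis ------------------------------------------------------------
    name = stage("basis")
    try:
        basis = results.state_basis()
        m_eff = min(config.m, int(round(results.dof)), basis.rank)
        tcsy_basis = results.tcsy(m=m_eff)
        basis_path = out / "basis.h5"
        tcsy_basis.save(basis_path)
        tsv_path = out / "basis.tsv"
        tcsy_basis.export_tsv(tsv_path)
        record(name, basis_path, tsv_path)
        manifest["stages"][name]["m"] = m_eff
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc

    # -- features ----------------------------------------------------------
    selection = None
    presence = None
    if genome_fasta is not None:
        name = stage("features")
        try:
            if annotation is None:
                raise FileNotFoundError("feature mapping requested without annotation")
            promoters = _features.extract_promoters(genome_fasta, annotation)
            presence_all = _features.motif_presence(promoters)
            keep = [
                i for i, g in enumerate(presence_all.gene_ids)
                if g in set(tcsy_basis.gene_ids)
            ]
            presence = _features.MotifPresence(
                matrix=presence_all.matrix[keep],
                gene_ids=[presence_all.gene_ids[i] for i in keep],
            )
            weights = _features.map_all_motifs(tcsy_basis, presence)
            summary = _features.summarize_weights(weights, variable=0)
            feat_path = out / "motif_weight_summary.json"
            feat_path.write_text(json.dumps(summary, indent=2))
            paths = [feat_path]
            if go_table_path is not None:
                import pandas as pd

                go_weights = _features.map_go_terms(
                    tcsy_basis, pd.read_csv(go_table_path, sep="\t")
                )
                go_w_path = out / "go_weights.tsv"
                go_weights.to_csv(go_w_path, sep="\t")
                paths.append(go_w_path)
            record(name, *paths)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

        # -- capacity ------------------------------------------------------
        name = stage("capacity")
        try:
            selection = _capacity.select_extreme_motifs(
                weights, fraction=config.selection_fraction
            )
            sel_path = out / "selection.tsv"
            selection.to_sparse_frame().to_csv(sel_path, sep="\t", index=False)
            ranked = _capacity.rank_genes_by_capacity(selection, presence)
            rnk_path = out / "ranked.rnk"
            _capacity.write_rnk(ranked, rnk_path)
            cap_report = {
                "group_entropy_bits": _capacity.group_entropy(selection),
                "selected_per_variable": selection.selected_per_variable().tolist(),
                "promoter_capacity_mean": float(ranked["h"].mean()),
                "promoter_capacity_sd": float(ranked["h"].std(ddof=1)),
                "n_ranked_genes": int(len(ranked)),
            }
            cap_path = out / "capacity.json"
            cap_path.write_text(json.dumps(cap_report, indent=2))
            record(name, sel_path, rnk_path, cap_path)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    # -- variance accounting ------------------------------------------------
    name = stage("variance")
    try:
        centered = _qc.center_and_impute(filtered)
        var_table = _coordinates.variance_explained(tcsy_basis, centered)
        var_path = out / "variance_explained.tsv"
        var_table.to_csv(var_path, sep="\t", index=False)
        manifest["stages"][name]["total_fraction"] = float(
            var_table["cumulative"].iloc[-1]
        )
        record(name, var_path)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
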