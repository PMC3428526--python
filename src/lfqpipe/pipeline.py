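"""End-to-end orchestration: preprocess → QC → both DE branches → clustering.

``run_full`` executes the whole pipeline from a :class:`PipelineConfig`,
writes every intermediate table under the output directory, and emits a run
manifest (config echo, package version, seed, per-stage row counts) that
suffices to re-run the pipeline bit-identically.  Identical configuration and
inputs produce byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abundance import run_abundance_branch
from .cluster import cluster_bidirectional, write_cluster3
from .preprocess import FilterCriteria, drop_reverse_proteins, filter_peptides
from .presence import (
    ImputationSpec,
    branch_overlap,
    impute_downshifted_normal,
    run_presence_branch,
)
from .qc import build_qc_report
from .rollup import rollup_protein_table
from .tables import (
    check_sample_axes,
    read_design,
    read_peptide_table,
    read_protein_table,
    write_results_table,
)

log = logging.getLogger("lfqpipe")

__all__ = ["PipelineConfig", "PipelineResult", "run_full"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and the mandatory seed for a full run."""

    peptide_table: str
    design: str
    output_dir: str
    protein_table: str | None = None      # when absent, rollup from peptides
    min_obs_fraction: float = 0.5
    require_unique: bool = True
    drop_reverse: bool = True
    min_shared: int = 1                   # rollup ratio-edge support floor
    top_k: int = 10
    alpha_pre: float = 0.05
    alpha_refine: float = 0.05
    fdr: float = 0.05
    n_perm: int = 250
    alpha_fisher: float = 0.05
    fisher_mode: str = "counts"
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_pre", "alpha_refine", "fdr", "alpha_fisher"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    qc: object
    abundance: object
    presence: object
    overlap: object
    clustering: object
    manifest: dict


def run_full(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "lfqpipe_version": __version__,
        "stages": {},
    }

    log.info("reading inputs")
    design = read_design(config.design)
    peptides = read_peptide_table(config.peptide_table)
    proteins = (
        read_protein_table(config.protein_table)
        if config.protein_table
        else None
    )
    check_sample_axes(design, peptides, proteins)
    if proteins is None:
        log.info("no protein table supplied; rolling up from peptides")
        proteins = rollup_protein_table(peptides, min_shared=config.min_shared)
    manifest["stages"]["input"] = {
        "n_peptides": int(len(peptides.peptide_keys)),
        "n_proteins": int(len(proteins.protein_group_ids)),
        "n_samples": len(peptides.samples),
    }

    log.info("QC battery")
    qc = build_qc_report(peptides, proteins, design)
    qc.write(out_dir / "qc_report.tsv")

    log.info("filtering peptides")
    criteria = FilterCriteria(
        require_unique=config.require_unique,
        drop_reverse=config.drop_reverse,
        min_obs_fraction=config.min_obs_fraction,
    )
    filtered, report = filter_peptides(peptides, design, criteria)
    write_results_table(report.to_frame(), out_dir / "filter_report.tsv")
    manifest["stages"]["filter"] = {
        "n_input": report.n_input,
        "n_output": report.n_output,
        "min_obs_count": report.min_obs_count,
    }

    forward_proteins = (
        drop_reverse_proteins(proteins) if proteins.is_reverse.any() else proteins
    )

    log.info("abundance branch (peptide-level model + t-test refinement)")
    res_a = run_abundance_branch(
        filtered,
        forward_proteins,
        design,
        top_k=config.top_k,
        alpha_pre=config.alpha_pre,
        alpha_refine=config.alpha_refine,
        fdr=config.fdr,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    write_results_table(res_a.table, out_dir / "abundance_results.tsv")
    manifest["stages"]["abundance"] = {
        "n_tested": int(len(res_a.table)),
        "n_preselected": len(res_a.preselected_ids),
        "n_selected": len(res_a.selected_ids),
    }

    log.info("presence branch (Fisher on spectral counts + imputed t-test)")
    res_p = run_presence_branch(
        forward_proteins,
        design,
        spec=ImputationSpec(
            width=config.impute_width,
            downshift=config.impute_downshift,
            seed=config.seed,
        ),
        alpha_fisher=config.alpha_fisher,
        alpha_refine=config.alpha_refine,
        fdr=config.fdr,
        n_perm=config.n_perm,
        seed=config.seed,
        mode=config.fisher_mode,
    )
    write_results_table(res_p.table, out_dir / "presence_results.tsv")
    manifest["stages"]["presence"] = {
        "n_tested": int(len(res_p.table)),
        "n_preselected": len(res_p.preselected_ids),
        "n_selected": len(res_p.selected_ids),
    }

    overlap = branch_overlap(res_a, res_p)
    if len(overlap.to_frame()):
        write_results_table(overlap.to_frame(), out_dir / "branch_overlap.tsv")
    manifest["stages"]["overlap"] = {
        "shared": len(overlap.shared),
        "concordant": len(overlap.concordant),
        "abundance_only": len(overlap.only_abundance),
        "presence_only": len(overlap.only_presence),
    }

    log.info("hierarchical clustering of selected proteins")
    clustering = None
    de_ids = [
        pid
        for pid in sorted(set(res_a.selected_ids) | set(res_p.selected_ids))
        if pid in forward_proteins.protein_group_ids
    ]
    exp = design.experimental
    if len(de_ids) >= 1 and len(exp) >= 2:
        mat = np.log2(forward_proteins.abundance.loc[de_ids, exp])
        mat = mat[mat.notna().any(axis=1)]
        if mat.isna().to_numpy().any():
            # presence-branch proteins can be absent from a whole group; complete
            # the matrix with the same downshifted imputation used for testing
            try:
                mat = impute_downshifted_normal(
                    mat,
                    ImputationSpec(
                        width=config.impute_width,
                        downshift=config.impute_downshift,
                        seed=config.seed,
                    ),
                )
            except ValueError:
                mat = mat.dropna()
        if len(mat) >= 1:
            clustering = cluster_bidirectional(mat, design)
            write_cluster3(clustering, out_dir / "de_clusters")
            manifest["stages"]["clustering"] = {
                "n_proteins": int(len(mat)),
                "sample_purity": clustering.sample_purity,
            }
    if clustering is None:
        manifest["stages"]["clustering"] = {"n_proteins": 0}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        qc=qc,
        abundance=res_a,
        presence=res_p,
        overlap=overlap,
        clustering=clustering,
        manifest=manifest,
    )
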