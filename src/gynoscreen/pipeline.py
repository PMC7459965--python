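"""End-to-end orchestration: simulate or load, normalize, screen, structure.

``run_pipeline`` sequences the stages, writes every intermediate artifact as
TSV/Newick/JSON into the output directory, and records all result-affecting
choices in a ``manifest.json``.  On a stage failure the partially written
outputs are removed and the error is re-raised annotated with the stage
name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import GynoscreenError, UsageError
from .io import CountMatrix, GeneMap, read_count_matrix, read_gene_map, write_count_matrix
from .normalization import normalize
from .screen import TranscriptSurvivalScreen
from .simulate import SimulationConfig, simulate_counts, simulate_survival
from .survival import SurvivalTable, kruskal_wallis, read_survival_table, GYNOGENETIC

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of (``counts_path`` + ``meta_path`` + ``survival_path``) or
    ``simulation`` must be provided.
    """

    out_dir: str | Path = "gynoscreen_out"
    counts_path: str | Path | None = None
    meta_path: str | Path | None = None
    survival_path: str | Path | None = None
    gene_map_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    stage: str = "eyed"
    method: str = "pearson"
    base_mean_threshold: float = 1.0
    score_threshold: float = 1.99
    log2: bool = False
    scaling: str = "unit_variance"
    linkage: str = "average"
    seed: int | None = None

    def validate(self) -> None:
        have_files = all(p is not None for p in
                         (self.counts_path, self.meta_path, self.survival_path))
        if not have_files and self.simulation is None:
            raise UsageError("provide input files or a simulation config")
        if have_files and self.simulation is not None:
            raise UsageError("provide either input files or a simulation config, not both")


def _load_inputs(cfg: PipelineConfig, out: Path
                 ) -> tuple[CountMatrix, SurvivalTable, GeneMap | None, dict]:
    extra: dict = {}
    if cfg.simulation is not None:
        sim = cfg.simulation
        if cfg.seed is not None:
            sim.seed = cfg.seed
        counts, truth = simulate_counts(sim)
        survival = simulate_survival(sim)
        write_count_matrix(counts, out / "counts.tsv", out / "samples.tsv")
        survival.write(out / "survival.tsv")
        truth.write(out / "truth.tsv")
        extra["simulation"] = sim.to_dict()
        extra["n_planted"] = len(truth.planted_ids)
        return counts, survival, None, extra
    counts = read_count_matrix(cfg.counts_path, cfg.meta_path)
    survival = read_survival_table(cfg.survival_path)
    gm = read_gene_map(cfg.gene_map_path) if cfg.gene_map_path else None
    return counts, survival, gm, extra


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(*names: str) -> None:
        written.extend(out / n for n in names)

    stage_name = "setup"
    try:
        stage_name = "input"
        counts, survival, gm, manifest_extra = _load_inputs(cfg, out)
        if cfg.simulation is not None:
            track("counts.tsv", "samples.tsv", "survival.tsv", "truth.tsv")

        stage_name = "survival"
        model = TranscriptSurvivalScreen(counts, survival, gene_map=gm, stage=cfg.stage)
        model.summary_table.write(out / "survival_summary.tsv")
        track("survival_summary.tsv")
        gyn = model.summary_table.groups
        gyn = gyn[gyn["condition"] == GYNOGENETIC]
        kw_groups = [model.summary_table.rates_for(g, cfg.stage) for g in gyn.index]
        kw_h, kw_p = kruskal_wallis(kw_groups) if len(kw_groups) >= 2 else (float("nan"),) * 2

        stage_name = "normalize"
        nm = normalize(counts)
        nm.write(out / "normalized.tsv", out / "size_factors.tsv", out / "base_means.tsv")
        track("normalized.tsv", "size_factors.tsv", "base_means.tsv")

        stage_name = "screen"
        results = model.fit(method=cfg.method,
                            base_mean_threshold=cfg.base_mean_threshold,
                            score_threshold=cfg.score_threshold, log2=cfg.log2)
        results.to_file(out / "screen.tsv")
        track("screen.tsv")
        n_transcripts_passing, n_genes = results.gene_tally()

        stage_name = "structure"
        structure_meta: dict = {}
        if results.n_passing >= 2:
            st = results.structure(scaling=cfg.scaling, linkage=cfg.linkage)
            (out / "samples_dendrogram.nwk").write_text(
                st.sample_dendrogram.to_newick() + "\n")
            if st.transcript_dendrogram is not None:
                (out / "transcripts_dendrogram.nwk").write_text(
                    st.transcript_dendrogram.to_newick() + "\n")
            st.pca.write(out / "pca_scores.tsv", out / "pca_loadings.tsv",
                         out / "pca_variance.tsv")
            track("samples_dendrogram.nwk", "transcripts_dendrogram.nwk",
                  "pca_scores.tsv", "pca_loadings.tsv", "pca_variance.tsv")
            structure_meta = st.metadata()
        else:
            logger.info("fewer than 2 passing transcripts; structure stage skipped")

        stage_name = "manifest"
        manifest = {
            "gynoscreen_version": __version__,
            "stage": cfg.stage,
            "method": cfg.method,
            "log2_expression": cfg.log2,
            "base_mean_threshold": cfg.base_mean_threshold,
            "score_threshold": cfg.score_threshold,
            "scaling": cfg.scaling,
            "linkage": cfg.linkage,
            "seed": cfg.seed,
            "efficiency_vector_pct": {k: float(v) for k, v in model.efficiency.items()},
            "kruskal_wallis": {"H": float(kw_h), "p": float(kw_p)},
            "n_transcripts": counts.n_transcripts,
            "n_samples": counts.n_samples,
            "n_passing_transcripts": n_transcripts_passing,
            "n_passing_genes": n_genes,
            "structure": structure_meta,
            **manifest_extra,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except GynoscreenError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(
            f"[stage: {stage_name}] {exc} "
            f"(fix the {stage_name} inputs/options and re-run)"
        ) from exc
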