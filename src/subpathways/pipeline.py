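"""End-to-end workflow: DE testing, enrichment, enumeration, scoring.

`run_pipeline` wires the stages in order — per-gene presence tests,
hypergeometric pathway enrichment, subpathway enumeration, perturbation/
impact scoring with a permutation null, BH FDR — and writes each stage's
output as TSV next to a JSON run manifest, so any stage can be reloaded
or re-run individually. All randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexp import ExpressionDataset, de_genes, gene_stats, load_dataset
from .enrichment import enrich_pathways
from .graph import EnumerationConfig, Subpathway, derive_subpathways, subpathways_to_tsv
from .impact import overlap_subpathways, score_subpathways
from .kgml import read_kgml_file

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and caps of one analysis run."""

    expression: str
    calls: str
    probe_map: str
    metadata: str
    pathways: list[str]
    outdir: str | None = None
    paired: bool | None = None
    alpha_de: float = 0.05
    alpha_subpathway: float = 0.05
    n_permutations: int = 100
    seed: int = 0
    max_path_length: int = 30
    max_paths_per_pathway: int = 50_000
    binding_subset_cap: int = 6
    start_policy: str = "entry_only"
    enrichment_direction: str = "all"
    marginal_present: bool = False
    expr_agg: str = "max"
    binding_agg: str = "max"
    de_scope: str = "subpathway"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for p in [self.expression, self.calls, self.probe_map, self.metadata, *self.pathways]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for name in ("alpha_de", "alpha_subpathway"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def enumeration_config(self) -> EnumerationConfig:
        return EnumerationConfig(
            max_path_length=self.max_path_length,
            max_paths_per_pathway=self.max_paths_per_pathway,
            binding_subset_cap=self.binding_subset_cap,
            start_policy=self.start_policy,
        )


@dataclass
class PipelineResult:
    gene_stats: pd.DataFrame
    enrichment: pd.DataFrame
    subpathways: list[Subpathway]
    scores: pd.DataFrame
    manifest: dict


def _load(config: RunConfig) -> ExpressionDataset:
    return load_dataset(config.expression, config.calls, config.probe_map, config.metadata)


def run_pipeline(config: RunConfig, dataset: ExpressionDataset | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Results are deterministic for identical config + seed. When
    ``config.outdir`` is set, stage outputs (gene_stats.tsv,
    enrichment.tsv, subpathways.tsv, scores.tsv, manifest.json) are
    written there.
    """
    if dataset is None:
        config.validate()
    ds = dataset if dataset is not None else _load(config)
    paired = ds.is_paired() if config.paired is None else config.paired

    graphs = [read_kgml_file(p) for p in config.pathways]
    pathway_genes = {g.pathway_id: g.gene_symbols() for g in graphs}

    subpathways: list[Subpathway] = []
    for g in graphs:
        subpathways.extend(derive_subpathways(g, config.enumeration_config()))
    logger.info("enumerated %d subpathways from %d pathways", len(subpathways), len(graphs))

    stats = gene_stats(
        ds,
        paired=paired,
        alpha=config.alpha_de,
        marginal_present=config.marginal_present,
        expr_agg=config.expr_agg,
    )
    universe = set(stats.index) & set().union(*pathway_genes.values())
    enrichment = enrich_pathways(
        de_genes(stats, config.enrichment_direction) & universe, pathway_genes, universe
    )

    scores = score_subpathways(
        ds,
        subpathways,
        pathway_genes,
        paired=paired,
        alpha=config.alpha_de,
        n_permutations=config.n_permutations,
        seed=config.seed,
        binding_agg=config.binding_agg,
        enrichment_direction=config.enrichment_direction,
        marginal_present=config.marginal_present,
        expr_agg=config.expr_agg,
        de_scope=config.de_scope,
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "paired": paired,
        "n_permutations": config.n_permutations,
        "alpha_de": config.alpha_de,
        "alpha_subpathway": config.alpha_subpathway,
        "n_subpathways": len(subpathways),
        "inputs": {
            "expression": str(config.expression),
            "calls": str(config.calls),
            "probe_map": str(config.probe_map),
            "metadata": str(config.metadata),
            "pathways": [str(p) for p in config.pathways],
        },
    }
    result = PipelineResult(stats, enrichment, subpathways, scores, manifest)
    if config.outdir:
        _write_outputs(result, config.outdir)
    return result


def _write_outputs(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.gene_stats.to_csv(out / "gene_stats.tsv", sep="\t", index_label="gene")
    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    (out / "subpathways.tsv").write_text(subpathways_to_tsv(result.subpathways))
    result.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def run_overlap(
    result_a: PipelineResult,
    result_b: PipelineResult,
    alpha: float = 0.05,
    outdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine two completed runs into the overlap report.

    Returns the per-subpathway overlap table (significant and positively
    directed in both cohorts) and the per-pathway summary.
    """
    overlap, summary = overlap_subpathways(result_a.scores, result_b.scores, alpha=alpha)
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        overlap.to_csv(out / "overlap_subpathways.tsv", sep="\t", index=False)
        summary.to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
    return overlap, summary
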