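"""Pipeline orchestration: configuration, stage execution, run manifest."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from micropat import bgc as bgc_mod
from micropat import io as mio
from micropat import maturation as mat_mod
from micropat import network as net_mod
from micropat import synthetic as syn_mod
from micropat.stats import bh_fdr  # noqa: F401  (re-exported for configs)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the study's printed values as defaults."""

    stages: list[str] = field(
        default_factory=lambda: ["simulate", "bgc", "maturation", "network"]
    )
    outdir: str = "micropat_out"
    seed: int = 0
    # simulate
    n_mice_per_cell: int = 6
    timepoints: list[int] = field(default_factory=lambda: [12, 42])
    n_taxa: int = 200
    n_genes: int = 547
    n_bgcs: int = 228
    # bgc
    min_ratio: float = 0.75
    q_threshold: float = 0.15
    cluster_threshold: float = 0.5
    # maturation
    t0: int = 12
    t1: int = 42
    alpha: float = 0.05
    # network
    min_rel_abund: float = 1e-4
    n_subsamples: int = 50
    beta: float = 0.05
    bootstraps: int = 5000
    network_taxa: int = 15
    network_genes: int = 43
    network_true_edges: int = 25
    network_mice_per_cell: int = 12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _simulate(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> None:
    meta = syn_mod.generate_metadata(
        cfg.n_mice_per_cell, cfg.timepoints, seed=int(rng.integers(2**31))
    )
    mio.write_metadata(meta, outdir / "metadata.tsv")
    taxa, taxa_truth = syn_mod.generate_taxa_counts(
        meta, n_taxa=cfg.n_taxa, seed=int(rng.integers(2**31))
    )
    mio.write_count_table(taxa, outdir / "taxa.tsv")
    mio.write_truth(taxa_truth, outdir / "taxa.truth.json")
    # planted class sizes scale with the gene panel (defaults sized for 547)
    frac = cfg.n_genes / 547
    class_counts = {
        "I_only": round(30 * frac),
        "III": round(30 * frac),
        "IV": round(20 * frac),
        "V": round(20 * frac),
    }
    expr, expr_truth = syn_mod.generate_expression(
        meta,
        n_genes=cfg.n_genes,
        class_counts=class_counts,
        seed=int(rng.integers(2**31)),
    )
    mio.write_count_table(expr, outdir / "expression.tsv")  # genes x samples on disk
    mio.write_truth(expr_truth, outdir / "expression.truth.json")
    bgcs = syn_mod.generate_bgc_reference(n_bgcs=cfg.n_bgcs, seed=int(rng.integers(2**31)))
    mio.write_bgc_reference(bgcs, outdir / "bgc_reference.tsv")
    obs = []
    day0 = meta[meta["day"] == cfg.timepoints[0]]
    for _, row in day0.iterrows():
        for b in bgcs[: min(len(bgcs), 40)]:
            n_reads = int(rng.poisson(2 * b.length_bp / 100 / 3))
            obs.append(
                syn_mod.simulate_read_coverage(
                    b, n_reads, 100, seed=int(rng.integers(2**31)), sample_id=row["sample_id"]
                )
            )
    mio.write_coverage_table(obs, outdir / "coverage.tsv")


def _run_bgc(cfg: PipelineConfig, outdir: Path) -> None:
    bgcs = mio.read_bgc_reference(outdir / "bgc_reference.tsv")
    obs = mio.read_coverage_table(outdir / "coverage.tsv")
    meta = mio.read_metadata(outdir / "metadata.tsv")
    presence = bgc_mod.call_presence(obs, bgcs, min_ratio=cfg.min_ratio)
    presence.astype(int).to_csv(outdir / "presence.tsv", sep="\t")
    results = bgc_mod.bgc_enrichment(presence, meta, q_threshold=cfg.q_threshold)
    pd.DataFrame(
        {
            "bgc_id": [r.bgc_id for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "enriched_in": [r.enriched_in for r in results],
        }
    ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    clusters = bgc_mod.cluster_bgcs(bgcs, threshold=cfg.cluster_threshold)
    pd.Series(clusters.assignments, name="cluster_id").rename_axis("bgc_id").to_csv(
        outdir / "bgc_clusters.tsv", sep="\t"
    )


def _run_maturation(cfg: PipelineConfig, outdir: Path) -> None:
    expr = mio.read_count_table(
        outdir / "expression.tsv", orientation="features_by_samples"
    ).T
    meta = mio.read_metadata(outdir / "metadata.tsv")
    ctl = mat_mod.maturation_test(expr, meta, "control", cfg.t0, cfg.t1, alpha=cfg.alpha)
    pat = mat_mod.maturation_test(expr, meta, "PAT", cfg.t0, cfg.t1, alpha=cfg.alpha)
    calls = [mat_mod.classify_maturation(ctl[g], pat[g]) for g in expr.index]
    pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "control_log2fc": [c.control.log2fc for c in calls],
            "control_q": [c.control.q for c in calls],
            "pat_log2fc": [c.pat.log2fc for c in calls],
            "pat_q": [c.pat.q for c in calls],
            "primary_class": [c.primary_class for c in calls],
            "marginal_I": [c.marginal_I for c in calls],
            "marginal_II": [c.marginal_II for c in calls],
        }
    ).to_csv(outdir / "maturation_calls.tsv", sep="\t", index=False)
    mat_mod.summarize_classes(calls).rename_axis("class").to_frame("count").to_csv(
        outdir / "maturation_summary.tsv", sep="\t"
    )


def _run_network(cfg: PipelineConfig, outdir: Path, rng: np.random.Generator) -> None:
    meta = syn_mod.generate_metadata(
        cfg.network_mice_per_cell, [23], seed=int(rng.integers(2**31))
    )
    taxa, expr, truth = syn_mod.generate_paired_taxa_gene(
        meta,
        n_taxa=cfg.network_taxa,
        n_genes=cfg.network_genes,
        n_true_edges=cfg.network_true_edges,
        seed=int(rng.integers(2**31)),
    )
    mio.write_metadata(meta, outdir / "network_metadata.tsv")
    mio.write_count_table(taxa, outdir / "network_taxa.tsv")
    mio.write_count_table(expr, outdir / "network_expression.tsv")
    mio.write_truth(truth, outdir / "network.truth.json")
    block = net_mod.prepare_features(taxa, expr, meta, min_rel_abund=cfg.min_rel_abund)
    stars = net_mod.stars_select(
        block,
        n_subsamples=cfg.n_subsamples,
        beta=cfg.beta,
        seed=int(rng.integers(2**31)),
    )
    stars.diagnostics().to_csv(outdir / "stars_diagnostics.tsv", sep="\t", index=False)
    model = net_mod.spls_fit(block, stars.selected_lambda)
    edges = net_mod.bootstrap_significance(
        block, model, B=cfg.bootstraps, alpha=cfg.alpha, seed=int(rng.integers(2**31))
    )
    pd.DataFrame(
        {
            "taxon": [e.taxon for e in edges],
            "gene": [e.gene for e in edges],
            "coefficient": [e.coefficient for e in edges],
            "sign": [e.sign for e in edges],
            "empirical_p": [e.empirical_p for e in edges],
            "q": [e.q for e in edges],
            "selected": [e.selected for e in edges],
        }
    ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    graph = net_mod.build_network(edges, taxa, genes=list(expr.index))
    mio.write_graphml(graph, outdir / "network.graphml")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a run manifest."""
    known = ("simulate", "bgc", "maturation", "network")
    if not cfg.stages:
        raise ValueError("nothing to do: no stages enabled")
    unknown = set(cfg.stages) - set(known)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "simulate" not in cfg.stages:
        needed = {
            "bgc": ["bgc_reference.tsv", "coverage.tsv", "metadata.tsv"],
            "maturation": ["expression.tsv", "metadata.tsv"],
        }
        for stage in cfg.stages:
            for fname in needed.get(stage, []):
                if not (outdir / fname).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {fname} (enable 'simulate' or provide it)"
                    )
    rng = np.random.default_rng(cfg.seed)
    from micropat import __version__

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }
    for stage in known:
        if stage not in cfg.stages:
            continue
        logger.info("stage %s starting (seed %d)", stage, cfg.seed)
        start = time.monotonic()
        if stage == "simulate":
            _simulate(cfg, outdir, rng)
        elif stage == "bgc":
            _run_bgc(cfg, outdir)
        elif stage == "maturation":
            _run_maturation(cfg, outdir)
        elif stage == "network":
            _run_network(cfg, outdir, rng)
        manifest["stages"][stage] = {"runtime_s": round(time.monotonic() - start, 3)}
    manifest["checksums"] = {
        p.name: mio.file_checksum(p) for p in sorted(outdir.glob("*.tsv"))
    }
    mio.write_manifest(manifest, outdir / "manifest.json")
    return manifest
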