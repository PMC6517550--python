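"""End-to-end pipeline: simulate -> kinetics -> cluster -> DE -> modulon -> enrichment.

A single YAML configuration drives one reproducible run.  Every stage writes
its outputs under the run directory and the run manifest records all
parameters, the seed, SHA-256 checksums of written files and per-stage row
counts; re-running an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from growthmodulon import io as gmio
from growthmodulon.counts import (
    cluster_samples,
    drop_all_zero_genes,
    poisson_dissimilarity,
    rle_size_factors,
)
from growthmodulon.de import DEFAULT_LFC_CUTOFFS, call_degs, fit_rate_course
from growthmodulon.enrichment import enrich_sets, export_network, regulons_from_edges
from growthmodulon.kinetics import mu_differential, select_samples
from growthmodulon.modulon import cluster_profiles, identify_modulon
from growthmodulon.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_gene_sets,
    simulate_growth_curve,
    simulate_network,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

#: measured inoculum viabilities (%) per pre-culture condition
DEFAULT_VIABILITIES = {"phosphate": 60.0, "nitrogen": 96.0, "carbon": 88.0}
DEFAULT_TARGET_RATES = (0.0, 0.1, 0.2, 0.3, 0.4)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValueError(
            f"unknown keys in config section '{section}': {sorted(unknown)}"
        )


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    outdir: str = "modulon_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    sample_clustering: dict = field(default_factory=dict)
    de: dict = field(default_factory=dict)
    modulon: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    _SECTIONS = {
        "inputs": {"counts", "meta", "network", "gene_sets"},
        "kinetics": {"targets", "viability", "mu_max", "noise_sd"},
        "sample_clustering": {"linkage", "n_clusters", "transform"},
        "de": {"alpha", "lfc_cutoffs", "family", "degree", "reference_mu"},
        "modulon": {"similarity_threshold", "k", "linkage"},
        "enrichment": {"alpha", "pathway_alpha", "min_set_size"},
    }

    def __post_init__(self) -> None:
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        _check_keys("simulation", self.simulation, sim_fields)
        for section, allowed in self._SECTIONS.items():
            _check_keys(section, getattr(self, section), allowed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        _check_keys("<top level>", raw, known)
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all pipeline stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.echo(),
        "seed": config.seed,
        "stages": [],
        "files": {},
        "counts": {},
    }

    def record(name: str, path: Path, n_rows: int | None = None) -> None:
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
        if n_rows is not None:
            manifest["counts"][name] = n_rows

    # stage 1: simulate or load --------------------------------------------
    stage = "simulate"
    try:
        if config.inputs.get("counts"):
            counts = gmio.read_counts(config.inputs["counts"])
            meta = gmio.read_sample_meta(config.inputs["meta"])
            network = gmio.read_network(config.inputs["network"])
            gene_sets = (
                gmio.read_gmt(config.inputs["gene_sets"])
                if config.inputs.get("gene_sets")
                else {}
            )
            truth = None
        else:
            sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
            counts, meta, truth = simulate_counts(sim)
            network = simulate_network(sim, truth)
            gene_sets = simulate_gene_sets(sim, truth)
            gmio.write_counts(counts, outdir / "counts.tsv")
            gmio.write_sample_meta(meta, outdir / "sample_meta.tsv")
            gmio.write_network(network, outdir / "network.tsv")
            gmio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
            gmio.write_ground_truth(truth, outdir / "ground_truth.json")
            for name in ("counts.tsv", "sample_meta.tsv", "network.tsv",
                         "gene_sets.gmt", "ground_truth.json"):
                record(name, outdir / name)
        manifest["counts"]["genes"] = int(counts.shape[0])
        manifest["counts"]["samples"] = int(counts.shape[1])
    except FileNotFoundError as exc:
        raise PipelineError(stage, f"missing input file: {exc.filename}") from exc
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    # stage 2: growth kinetics ---------------------------------------------
    stage = "kinetics"
    try:
        targets = list(config.kinetics.get("targets", DEFAULT_TARGET_RATES))
        viab = {**DEFAULT_VIABILITIES, **config.kinetics.get("viability", {})}
        mu_max = float(config.kinetics.get("mu_max", max(targets) or 0.4))
        noise_sd = float(config.kinetics.get("noise_sd", 0.0))
        selections = []
        for cond in meta["condition"].unique():
            curve = simulate_growth_curve(
                viability_percent=viab.get(cond, 100.0),
                mu_max=mu_max,
                noise_sd=noise_sd,
                condition=cond,
                seed=config.seed,
            )
            gmio.write_growth_curve(curve, outdir / f"growth_{cond}.tsv")
            record(f"growth_{cond}", outdir / f"growth_{cond}.tsv")
            series = mu_differential(curve)
            series.to_frame().to_csv(
                outdir / f"mu_{cond}.tsv", sep="\t", index=False
            )
            record(f"mu_{cond}", outdir / f"mu_{cond}.tsv")
            lo, hi = series.time_bounds
            cand_times = np.linspace(lo, hi, 121)
            candidates = [(f"{cond}-t{j}", t) for j, t in enumerate(cand_times)]
            cond_targets = [
                t for t in targets
                if t in set(meta.loc[meta["condition"] == cond, "mu"])
            ]
            sel = select_samples(candidates, series, cond_targets)
            sel.insert(0, "condition", cond)
            selections.append(sel)
        sel_table = pd.concat(selections, ignore_index=True)
        sel_table.to_csv(outdir / "sample_selection.tsv", sep="\t", index=False)
        record("sample_selection", outdir / "sample_selection.tsv", len(sel_table))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    # stage 3: normalization + sample clustering ---------------------------
    stage = "cluster"
    try:
        counts_nz = drop_all_zero_genes(counts)
        size_factors = rle_size_factors(counts_nz)
        size_factors.rename_axis("sample_id").to_csv(
            outdir / "size_factors.tsv", sep="\t"
        )
        record("size_factors", outdir / "size_factors.tsv", len(size_factors))
        d = poisson_dissimilarity(
            counts_nz, size_factors,
            transform=config.sample_clustering.get("transform"),
        )
        d.to_csv(outdir / "dissimilarity.tsv", sep="\t")
        record("dissimilarity", outdir / "dissimilarity.tsv", len(d))
        z, leaves, labels = cluster_samples(
            d,
            linkage_rule=config.sample_clustering.get("linkage", "complete"),
            n_clusters=int(config.sample_clustering.get("n_clusters", 3)),
        )
        (outdir / "sample_dendrogram.nwk").write_text(
            gmio.linkage_to_newick(z, list(d.index))
        )
        record("sample_dendrogram", outdir / "sample_dendrogram.nwk")
        labels.rename_axis("sample_id").to_csv(
            outdir / "sample_clusters.tsv", sep="\t"
        )
        record("sample_clusters", outdir / "sample_clusters.tsv", len(labels))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    # stage 4: differential expression per condition -----------------------
    stage = "de"
    try:
        alpha = float(config.de.get("alpha", 0.05))
        cutoffs = {**DEFAULT_LFC_CUTOFFS, **config.de.get("lfc_cutoffs", {})}
        family = config.de.get("family", "auto")
        degree = int(config.de.get("degree", 3))
        reference_mu = config.de.get("reference_mu")
        fits_by_condition = {}
        deg_sets = []
        for cond in meta["condition"].unique():
            sel = meta["condition"] == cond
            sample_ids = meta.loc[sel, "sample_id"].tolist()
            fits = fit_rate_course(
                counts_nz[sample_ids],
                meta.loc[sel, "mu"].to_numpy(dtype=float),
                size_factors[sample_ids],
                degree=degree, family=family,
                reference_mu=reference_mu, condition=cond,
            )
            fits.rename_axis("gene_id").to_csv(
                outdir / f"fits_{cond}.tsv", sep="\t"
            )
            record(f"fits_{cond}", outdir / f"fits_{cond}.tsv", len(fits))
            degs = call_degs(
                fits, alpha=alpha,
                log2fc_cutoff=float(cutoffs.get(cond, 0.73)),
            )
            (outdir / f"degs_{cond}.txt").write_text(
                "\n".join(sorted(degs.genes)) + "\n"
            )
            record(f"degs_{cond}", outdir / f"degs_{cond}.txt", len(degs.genes))
            fits_by_condition[cond] = fits
            deg_sets.append(degs)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    # stage 5: modulon -----------------------------------------------------
    stage = "modulon"
    try:
        result = identify_modulon(
            deg_sets, fits_by_condition,
            similarity_threshold=float(
                config.modulon.get("similarity_threshold", 0.7)
            ),
        )
        k = int(config.modulon.get("k", 4))
        if len(result.modulon_genes) >= k:
            result = cluster_profiles(
                result, fits_by_condition, k=k,
                linkage=config.modulon.get("linkage", "ward"),
            )
        mod_table = pd.DataFrame(
            {
                "gene_id": sorted(result.modulon_genes),
                "similarity_score": [
                    result.similarity_score[g]
                    for g in sorted(result.modulon_genes)
                ],
                "cluster": [
                    (result.cluster_of_gene or {}).get(g, "")
                    for g in sorted(result.modulon_genes)
                ],
            }
        )
        mod_table.to_csv(outdir / "modulon.tsv", sep="\t", index=False)
        record("modulon", outdir / "modulon.tsv", len(mod_table))
        if result.mean_cluster_profiles is not None:
            result.mean_cluster_profiles.to_csv(
                outdir / "cluster_profiles.tsv", sep="\t"
            )
            record("cluster_profiles", outdir / "cluster_profiles.tsv",
                   len(result.mean_cluster_profiles))
        overlap = pd.DataFrame(
            {
                "gene_id": sorted(
                    set.union(*(set(d.genes) for d in deg_sets))
                ),
            }
        )
        for d_set in deg_sets:
            overlap[d_set.condition] = overlap["gene_id"].isin(d_set.genes)
        overlap.to_csv(outdir / "deg_overlap.tsv", sep="\t", index=False)
        record("deg_overlap", outdir / "deg_overlap.tsv", len(overlap))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    # stage 6: enrichment --------------------------------------------------
    stage = "enrichment"
    try:
        universe = set(counts_nz.index)
        regulons = regulons_from_edges(network)
        enr = enrich_sets(
            result.modulon_genes, regulons, universe,
            alpha=float(config.enrichment.get("alpha", 0.05)),
            min_set_size=int(config.enrichment.get("min_set_size", 2)),
            cluster_of_gene=result.cluster_of_gene or {},
        )
        enr.drop(columns=["_overlap"]).to_csv(
            outdir / "regulon_enrichment.tsv", sep="\t", index=False
        )
        record("regulon_enrichment", outdir / "regulon_enrichment.tsv", len(enr))
        export_network(
            enr, network, result.cluster_of_gene or {},
            outdir / "network_significant.sif",
            outdir / "network_nodes.tsv",
        )
        record("network_significant", outdir / "network_significant.sif")
        record("network_nodes", outdir / "network_nodes.tsv")
        if gene_sets:
            gs = enrich_sets(
                result.modulon_genes, gene_sets, universe,
                alpha=float(config.enrichment.get("pathway_alpha", 0.025)),
                min_set_size=int(config.enrichment.get("min_set_size", 2)),
                cluster_of_gene=result.cluster_of_gene or {},
            )
            gs.drop(columns=["_overlap"]).to_csv(
                outdir / "gene_set_enrichment.tsv", sep="\t", index=False
            )
            record("gene_set_enrichment",
                   outdir / "gene_set_enrichment.tsv", len(gs))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    manifest["stages"].append(stage)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
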