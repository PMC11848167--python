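"""End-to-end orchestration of the sex-stratified analysis on synthetic data.

A single config drives the chain: simulate a cohort with planted effects ->
per-sex differential expression -> sex-pattern classification -> category
enrichment -> communication filtering -> GRN selection -> proteomics
cross-validation -> covariate correlation. Every output TSV carries a
provenance header (tool version, config hash, seed) and the run writes a
machine-readable manifest with per-file checksums, so a rerun with the same
config is byte-identical and the manifest suffices to verify any output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import comm as comm_mod
from . import covariates as cov_mod
from . import de as de_mod
from . import enrich as enrich_mod
from . import grn as grn_mod
from . import proteomics as prot_mod
from . import synthetic as syn
from .io import write_table
from .patterns import Thresholds, classify_all, category_counts, summarize_patterns

logger = logging.getLogger("sexdim")


@dataclass
class PipelineConfig:
    """Validated knobs of the full run; see field defaults for units."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    # thresholds
    fdr: float = 0.05
    min_lfc: float = 0.25
    nonsig_p: float = 0.1
    expr_frac: float = 0.10
    # simulation scale
    subjects_per_stratum: int = 12  # per (group, sex)
    cells_per_subject: int = 50
    n_genes: int = 500
    cell_types: tuple[str, ...] = ("astrocytes", "excitatory_neurons", "microglia")
    focal_cell_type: str = "astrocytes"
    planted_per_category: int = 10
    delta_logfc: float = 0.8
    dispersion: float = 0.15
    # network / GA
    n_prior_edges: int = 300
    frac_unknown_sign: float = 0.3
    ga_population: int = 100
    ga_generations: int = 120
    ga_stagnation: int = 25
    # proteomics
    n_proteins: int = 200
    n_shared_effects: int = 5
    proteomics_noise_sd: float = 0.5

    def validate(self) -> None:
        for name in ("fdr", "nonsig_p", "expr_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_lfc < 0:
            raise ValueError("min_lfc must be >= 0")
        if self.focal_cell_type not in self.cell_types:
            raise ValueError("focal_cell_type must be one of cell_types")
        for name in ("subjects_per_stratum", "cells_per_subject", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cell_types" in raw:
            raw["cell_types"] = tuple(raw["cell_types"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_study(cfg: PipelineConfig):
    """Cohort, counts, gene sets, prior network, LR pairs, proteomics."""
    spec = syn.CohortSpec(
        group_sizes={g: (cfg.subjects_per_stratum, cfg.subjects_per_stratum)
                     for g in syn.GROUPS}
    )
    subjects = syn.generate_cohort(spec, seed=cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    k = cfg.planted_per_category
    planted = {
        "neutral": genes[0:k],
        "male_specific": genes[k:2 * k],
        "female_specific": genes[2 * k:3 * k],
        "dimorphic": genes[3 * k:4 * k],
    }
    effects = syn.make_effects(planted, cfg.focal_cell_type, cfg.delta_logfc)
    counts, meta, truth = syn.generate_counts(
        subjects, cfg.cells_per_subject, genes, list(cfg.cell_types),
        effects, dispersion=cfg.dispersion, seed=cfg.seed + 1,
    )
    truth.planted_sets = {"PLANTED_MALE_SPECIFIC": planted["male_specific"]}
    gene_sets = syn.generate_gene_sets(
        genes, n_sets=50, planted=truth.planted_sets, seed=cfg.seed + 2
    )
    # a consistent chain among the male-specific planted genes (all up in AD,
    # so activating edges between them align with the Boolean states)
    chain_genes = planted["male_specific"]
    chain = pd.DataFrame(
        {
            "source": chain_genes[:-1],
            "target": chain_genes[1:],
            "sign": ["+"] * (len(chain_genes) - 1),
        }
    )
    truth.planted_edges = chain.to_dict("records")
    prior = syn.generate_prior_network(
        genes, cfg.n_prior_edges, cfg.frac_unknown_sign,
        planted_consistent=chain, seed=cfg.seed + 3,
    )
    lr = syn.generate_lr_pairs(genes, n_pairs=80, seed=cfg.seed + 4)
    # proteins share sex-specific/dimorphic effects (the categories the
    # cross-omics intersection is defined over)
    non_neutral = [e for e in effects if e.category != "neutral"]
    shared = non_neutral[:cfg.n_shared_effects] if cfg.n_shared_effects else []
    prot, samples = syn.generate_proteomics(
        subjects, genes[: cfg.n_proteins],
        shared_effects=[e for e in shared if e.gene in set(genes[: cfg.n_proteins])],
        noise_sd=cfg.proteomics_noise_sd, seed=cfg.seed + 5,
    )
    return subjects, counts, meta, truth, gene_sets, prior, lr, prot, samples


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"tool": "sexdim", "version": __version__,
            "config_hash": cfg.config_hash(), "seed": cfg.seed}
    th = Thresholds(cfg.fdr, cfg.min_lfc, cfg.nonsig_p)
    outputs: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        write_table(df, path, provenance=prov)
        outputs[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    logger.info("stage simulate")
    (subjects, counts, meta, truth, gene_sets, prior, lr, prot,
     samples) = simulate_study(cfg)
    emit(subjects, "subjects.tsv")
    truth.to_json(out / "ground_truth.json")
    outputs["ground_truth.json"] = hashlib.sha256(
        (out / "ground_truth.json").read_bytes()
    ).hexdigest()

    logger.info("stage de")
    ct = cfg.focal_cell_type
    de_m = de_mod.run_de(counts, meta, ct, "M", min_pct=cfg.expr_frac)
    de_f = de_mod.run_de(counts, meta, ct, "F", min_pct=cfg.expr_frac)
    emit(de_m, f"de_{ct}_M.tsv")
    emit(de_f, f"de_{ct}_F.tsv")

    logger.info("stage classify")
    patterns = classify_all(de_m, de_f, th)
    emit(patterns, f"patterns_{ct}.tsv")
    emit(category_counts(patterns).rename_axis("category").reset_index(name="n"),
         "category_counts.tsv")
    emit(summarize_patterns(patterns), "top_degs.tsv")

    logger.info("stage enrich")
    universe = sorted(set(de_m["gene"]) | set(de_f["gene"]))
    enr = {}
    for sex, label in (("M", "male_specific"), ("F", "female_specific")):
        query = set(patterns.loc[patterns["category"] == label, "feature"])
        enr[sex] = enrich_mod.enrich_collection(query, gene_sets, universe)
        emit(enr[sex], f"enrich_{label}.tsv")
    emit(enrich_mod.sex_specific_terms(enr["M"], enr["F"], cfg.fdr, cfg.nonsig_p),
         "enrich_sex_specific.tsv")

    logger.info("stage comm")
    sender = receiver = ct
    expressed = comm_mod.filter_expressed(counts, meta, ct, cfg.expr_frac)
    degs_m = set(patterns.loc[patterns["category"] == "male_specific", "feature"])
    pairs = comm_mod.intersect_degs_lr(degs_m, lr, expressed, expressed)
    emit(pairs, "comm_pairs.tsv")
    emit(comm_mod.rank_ligands(pairs, prior, degs_m), "comm_ligands.tsv")
    endpoint_genes = set(pairs["ligand"]) | set(pairs["receptor"])
    emit(comm_mod.comm_enrichment(endpoint_genes, gene_sets, universe),
         "comm_enrichment.tsv")

    logger.info("stage grn")
    filtered = grn_mod.filter_interactions(prior)
    grn_nodes = degs_m
    cand = filtered[
        filtered["source"].isin(grn_nodes) & filtered["target"].isin(grn_nodes)
    ].reset_index(drop=True)
    if len(cand):
        states = grn_mod.booleanize(patterns, sorted(set(cand["source"]) | set(cand["target"])),
                                    lfc_col="logfc_m")
        params = grn_mod.GAParams(
            population_size=cfg.ga_population, max_generations=cfg.ga_generations,
            stagnation_limit=cfg.ga_stagnation, seed=cfg.seed + 6,
        )
        result = grn_mod.run_ga(cand, states, params)
        emit(result.edges, "grn_selected_edges.tsv")
        emit(grn_mod.perturbagen_scores(result), "grn_perturbagens.tsv")
        emit(grn_mod.mediator_scores(result), "grn_mediators.tsv")
    else:
        logger.warning("no candidate edges among male-specific DEGs; GRN skipped")

    logger.info("stage proteomics")
    dep_m = prot_mod.run_dep(prot, samples, "M")
    dep_f = prot_mod.run_dep(prot, samples, "F")
    emit(dep_m, "dep_M.tsv")
    emit(dep_f, "dep_F.tsv")
    dep_patterns = prot_mod.classify_proteins(dep_m, dep_f)
    emit(dep_patterns, "dep_patterns.tsv")
    emit(prot_mod.intersect_omics({ct: patterns}, dep_patterns), "omics_overlap.tsv")

    logger.info("stage correlate")
    pb = cov_mod.pseudobulk(counts, meta, ct)
    planted_genes = [e.gene for e in truth.effects]
    corr = cov_mod.correlate_covariates(pb, subjects, genes=planted_genes)
    emit(corr, "covariate_correlations.tsv")

    manifest = {"version": __version__, "config": asdict(cfg),
                "config_hash": cfg.config_hash(), "outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
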