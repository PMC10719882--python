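"""Workflow orchestration and run configuration.

One declarative config drives the full workflow:

    simulate/load → filter → impute → prune/PCA/kinship → LMM scan
    → Gao thresholds → SNP subsets → BSLMM (genome-wide and per subset)
    → candidate pathway association → summary tables

Every stage writes tab-delimited artifacts into the run directory, each
with a header comment carrying the tool version, a hash of the config
and the seed, so a rerun with an identical config is bit-identical and
per-stage SNP counts can be reconstructed from the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bslmm import BslmmConfig, BslmmPosterior, bslmm_fit, classify_major
from .genotype_io import (
    GenotypeMatrix, PhenotypeVector, align_samples, filter_snps,
    impute_missing_mean, read_dosage_matrix, read_phenotype, read_vcf,
    write_dosage_matrix, write_phenotype, write_vcf,
)
from .lmm import (
    blocks_from_bed, blocks_from_dprime, estimate_h2, gao_meff,
    lmm_associate, results_frame, subset_by_rank, subset_union,
)
from .pathway import load_pathway_genes, read_pathway_table, run_cpa
from .relatedness import centered_kinship, pca_covariates, prune_by_dprime
from .report import manhattan_bslmm, manhattan_lmm, render_tables
from .simulate import (
    SimulationConfig, block_intervals, block_partition,
    simulate_genotypes, simulate_phenotype,
)

logger = logging.getLogger("pathgwa")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class FilterSettings:
    maf_min: float = 0.05
    het_max: float = 0.10
    miss_max: float = 1.0


@dataclass
class PruneSettings:
    window_snps: int = 50
    step_snps: int = 5
    threshold: float = 0.8


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    out_dir: str = "pathgwa_run"
    seed: int = 1
    # inputs; when vcf and dosage are both absent the simulator supplies data
    vcf: str | None = None
    dosage: str | None = None
    phenotype: str | None = None
    gff: str | None = None
    pathway_table: str | None = None
    blocks_bed: str | None = None
    multiallelic: str = "reject"
    filters: FilterSettings = field(default_factory=FilterSettings)
    prune: PruneSettings = field(default_factory=PruneSettings)
    n_pcs: int = 4
    alpha: float = 0.05
    meff_mode: str = "block-count"
    meff_variance_fraction: float = 0.995
    subset_fraction: float = 0.01
    subset_bslmm: bool = True
    pip_threshold: float = 0.10
    bslmm: BslmmConfig = field(default_factory=BslmmConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key, sub in (("filters", FilterSettings), ("prune", PruneSettings),
                         ("bslmm", BslmmConfig), ("simulation", SimulationConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**{
                    k: (tuple(v) if isinstance(v, list) else v) for k, v in raw[key].items()
                })
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not affect results and is excluded)."""
        raw = asdict(self)
        raw.pop("out_dir", None)
        return hashlib.sha256(yaml.safe_dump(raw, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _header(config: RunConfig) -> list[str]:
    return [
        f"pathgwa v{__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def _write_table(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig):
    """Load or simulate genotypes, phenotype and block definitions."""
    sim_truth = None
    blocks = None
    if config.vcf or config.dosage:
        G = (read_vcf(config.vcf, multiallelic=config.multiallelic)
             if config.vcf else read_dosage_matrix(config.dosage))
        if not config.phenotype:
            raise ValueError("a phenotype table is required with genotype input")
        y = read_phenotype(config.phenotype)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        G = simulate_genotypes(sim)
        y, sim_truth = simulate_phenotype(G, sim)
        blocks = block_partition(sim)
        logger.info("simulated %d samples x %d SNPs (seed %d)", G.n_samples, G.n_snps, sim.seed)
    return G, y, blocks, sim_truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of key results and
    artifact paths.  Any stage failure aborts with the stage name."""
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    with open(out("config_snapshot.yaml"), "w") as fh:
        fh.write(config.to_yaml())

    stage = "load_inputs"
    artifacts: dict[str, object] = {}
    try:
        G_raw, y_raw, sim_blocks, sim_truth = _load_inputs(config)

        stage = "filter"
        G_f = filter_snps(G_raw, config.filters.maf_min, config.filters.het_max,
                          config.filters.miss_max)
        logger.info("stage filter: %d -> %d SNPs", G_raw.n_snps, G_f.n_snps)

        stage = "align"
        G_f, y = align_samples(G_f, y_raw)

        stage = "impute"
        G = impute_missing_mean(G_f)

        stage = "kinship"
        K = centered_kinship(G)
        K.write(out("kinship.tsv"))

        stage = "prune"
        kept = prune_by_dprime(G, config.prune.window_snps, config.prune.step_snps,
                               config.prune.threshold)
        with open(out("pruned_snps.txt"), "w") as fh:
            for j in kept:
                fh.write(G.snps[j].id + "\n")

        stage = "pca"
        W = pca_covariates(G.take_snps(kept), k=config.n_pcs)
        W.write(out("covariates.tsv"))

        stage = "lmm"
        results = lmm_associate(G, y, K, W)
        _write_table(results_frame(results), out("lmm_assoc.tsv"), config)

        stage = "meff"
        if config.blocks_bed:
            bed = pd.read_csv(config.blocks_bed, sep="\t", comment="#", header=None,
                              names=["chrom", "start", "end", "name"])
            blocks = blocks_from_bed(G, bed)
        elif sim_blocks is not None and G.n_snps == G_raw.n_snps:
            blocks = sim_blocks
        else:
            blocks = blocks_from_dprime(G, threshold=0.8)
        thresholds = gao_meff(G, blocks, mode=config.meff_mode,
                              variance_fraction=config.meff_variance_fraction,
                              alpha=config.alpha)
        logger.info("stage meff: m_eff=%d (%s), Gao line %.3f",
                    thresholds.m_eff, thresholds.mode, thresholds.significant_logp)

        stage = "subset"
        sub_p = subset_by_rank(results, config.subset_fraction, "lowest_p")
        sub_b = subset_by_rank(results, config.subset_fraction, "largest_abs_beta")
        sub_u = subset_union(sub_p, sub_b)
        for sub in (sub_p, sub_b, sub_u):
            sub.write(out(f"subset_{sub.name}.txt"))
        logger.info("stage subset: %s=%d, %s=%d, union=%d SNPs",
                    sub_p.name, len(sub_p.snp_ids), sub_b.name, len(sub_b.snp_ids),
                    len(sub_u.snp_ids))

        stage = "bslmm"
        posteriors: dict[str, BslmmPosterior] = {}
        posteriors["GWA"] = bslmm_fit(G, y, K, W, config.bslmm)
        if config.subset_bslmm:
            id_pos = {sid: j for j, sid in enumerate(G.snp_ids)}
            for sub in (sub_p, sub_b, sub_u):
                Gsub = G.take_snps([id_pos[s] for s in sub.snp_ids])
                posteriors[sub.name] = bslmm_fit(Gsub, y, K, W, config.bslmm)
        for name, post in posteriors.items():
            post.write_hyp(out(f"bslmm_{name}.hyp.tsv"))
            post.write_param(out(f"bslmm_{name}.param.tsv"))
        _write_table(manhattan_bslmm(posteriors["GWA"]), out("manhattan_bslmm.tsv"), config)
        _write_table(manhattan_lmm(results, thresholds), out("manhattan_lmm.tsv"), config)

        stage = "cpa"
        cpa = None
        if config.gff and config.pathway_table:
            pathway = read_pathway_table(config.pathway_table)
            genes = load_pathway_genes(config.gff, pathway)
            cpa = run_cpa(G, y, K, W, genes, thresholds, config.bslmm,
                          pip_threshold=config.pip_threshold)
            _write_table(cpa.lmm_frame(), out("cpa_lmm.tsv"), config)
            _write_table(cpa.gene_table, out("cpa_gene_table.tsv"), config)
            cpa.posterior.write_hyp(out("bslmm_CPA.hyp.tsv"))
            cpa.posterior.write_param(out("bslmm_CPA.param.tsv"))
            posteriors["CPA"] = cpa.posterior

        stage = "report"
        h2 = estimate_h2(y, K, W)
        pve_table, hyper_table = render_tables(posteriors, lmm_h2=h2)
        _write_table(pve_table, out("table1_pve.tsv"), config)
        _write_table(hyper_table, out("table2_hyperparameters.tsv"), config)
        major = classify_major(posteriors["GWA"], pip_threshold=config.pip_threshold)
        _write_table(
            pd.DataFrame([dataclasses.asdict(c) for c in major]),
            out("major_effect_calls.tsv"), config,
        )

        artifacts.update(
            genotypes=G, phenotype=y, kinship=K, covariates=W,
            lmm_results=results, thresholds=thresholds,
            subsets={s.name: s for s in (sub_p, sub_b, sub_u)},
            posteriors=posteriors, cpa=cpa, h2=h2,
            sim_truth=sim_truth, major_calls=major,
            out_dir=config.out_dir,
        )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}; completed artifacts are in {config.out_dir}"
        ) from exc
    logger.info("pipeline complete: artifacts in %s", config.out_dir)
    return artifacts
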