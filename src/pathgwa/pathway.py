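"""Candidate pathway association (CPA).

Instead of scanning the whole genome, the association models are rerun
on the SNPs falling inside genes that encode the enzymes of a chosen
biosynthetic pathway.  The pathway is supplied as a delimited table of
(EC number, enzyme name, gene ID) rows — one row per EC–gene pair, so
the artifact stays network-free — and gene coordinates come from a GFF3
annotation.  Kinship, structure covariates and significance thresholds
are carried over unchanged from the genome-wide analysis: the Gao
threshold remains the one set by the full SNP panel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bslmm import BslmmConfig, BslmmPosterior, MajorEffectCall, bslmm_fit, classify_major
from .genotype_io import GenotypeMatrix, PhenotypeVector
from .lmm import LmmSnpResult, ScanThresholds, SnpSubset, lmm_associate, results_frame
from .relatedness import KinshipMatrix, StructureCovariates

logger = logging.getLogger("pathgwa")

__all__ = [
    "PathwayDefinition",
    "GeneInterval",
    "CpaReport",
    "read_pathway_table",
    "load_pathway_genes",
    "extract_pathway_snps",
    "run_cpa",
]

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass
class PathwayDefinition:
    """Enzyme → gene mapping for one biosynthetic pathway."""

    pathway_name: str
    enzymes: list[tuple[str, str]]  # (ec_number, enzyme_name)
    gene_map: dict[str, list[str]]  # ec_number -> gene IDs (may be empty)

    def __post_init__(self) -> None:
        for ec, _ in self.enzymes:
            if not _EC_RE.match(ec):
                raise ValueError(f"malformed EC number {ec!r} (need 4 dot-separated fields)")

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ec, _ in self.enzymes:
            for g in self.gene_map.get(ec, []):
                seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive genomic span of a gene; strand never affects
    SNP membership."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_pathway_table(path: str, pathway_name: str = "pathway") -> PathwayDefinition:
    """3-column delimited table: ec_number, enzyme_name, gene_id (header
    required; empty gene_id marks an enzyme with no annotated gene)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if df.shape[1] < 3:
        raise ValueError("pathway table needs columns: ec_number, enzyme_name, gene_id")
    enzymes: list[tuple[str, str]] = []
    gene_map: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        ec, name, gid = str(row.iloc[0]).strip(), str(row.iloc[1]).strip(), str(row.iloc[2]).strip()
        if (ec, name) not in enzymes:
            enzymes.append((ec, name))
        gene_map.setdefault(ec, [])
        if gid and gid not in gene_map[ec]:
            gene_map[ec].append(gid)
    return PathwayDefinition(pathway_name=pathway_name, enzymes=enzymes, gene_map=gene_map)


def load_pathway_genes(annotation: str, pathway: PathwayDefinition) -> list[GeneInterval]:
    """Resolve pathway gene IDs against 'gene' features of a GFF3 file.

    Unresolved gene IDs are logged, as is the count of enzymes with no
    located gene; an enzyme absent from the annotation is not an error.
    """
    import gffutils

    db = gffutils.create_db(
        annotation, dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    by_id: dict[str, GeneInterval] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.id
        by_id[gid] = GeneInterval(
            gene_id=gid, chrom=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand or ".",
        )
        for alias in feat.attributes.get("Name", []):
            by_id.setdefault(alias, by_id[gid])

    intervals: list[GeneInterval] = []
    unresolved: list[str] = []
    enzymes_without_genes = 0
    for ec, _name in pathway.enzymes:
        genes = pathway.gene_map.get(ec, [])
        hit = False
        for gid in genes:
            if gid in by_id:
                iv = by_id[gid]
                if iv not in intervals:
                    intervals.append(iv)
                hit = True
            else:
                unresolved.append(gid)
        if not hit:
            enzymes_without_genes += 1
    if unresolved:
        logger.warning("pathway gene IDs absent from annotation: %s", ", ".join(unresolved))
    logger.info(
        "load_pathway_genes: %d/%d enzymes located (%d without an annotated gene), %d gene intervals",
        len(pathway.enzymes) - enzymes_without_genes, len(pathway.enzymes),
        enzymes_without_genes, len(intervals),
    )
    if not intervals:
        raise ValueError(f"no pathway gene of {pathway.pathway_name!r} resolved in {annotation}")
    return intervals


def extract_pathway_snps(
    G: GenotypeMatrix, genes: list[GeneInterval], flank_bp: int = 0
) -> SnpSubset:
    """SNPs whose position falls within any gene body ± ``flank_bp``.

    Bounds are 1-based inclusive; a SNP shared by overlapping genes
    appears once.  The default flank of 0 restricts membership to the
    annotated gene span.
    """
    chosen: dict[str, tuple[str, int]] = {}
    for s in G.snps:
        for g in genes:
            if s.chrom == g.chrom and g.start - flank_bp <= s.pos <= g.end + flank_bp:
                chosen[s.id] = (s.chrom, s.pos)
                break
    ids = sorted(chosen, key=lambda sid: (chosen[sid][0], chosen[sid][1]))
    return SnpSubset(
        name="pathway",
        snp_ids=ids,
        keys=[chosen[s] for s in ids],
        provenance=f"{len(genes)} gene intervals, flank {flank_bp} bp",
    )


@dataclass
class CpaReport:
    """Joint LMM + BSLMM summary of the pathway SNP subset."""

    subset: SnpSubset
    lmm_results: list[LmmSnpResult]
    thresholds: ScanThresholds  # genome-wide thresholds, carried over
    posterior: BslmmPosterior
    major_calls: list[MajorEffectCall]
    gene_table: pd.DataFrame  # per-gene top sparse effects

    def lmm_frame(self) -> pd.DataFrame:
        return results_frame(self.lmm_results)


def run_cpa(
    G: GenotypeMatrix,
    y: PhenotypeVector,
    K: KinshipMatrix,
    W: StructureCovariates,
    genes: list[GeneInterval],
    thresholds: ScanThresholds,
    bslmm_config: BslmmConfig,
    flank_bp: int = 0,
    pip_threshold: float = 0.10,
) -> CpaReport:
    """LMM and BSLMM on the pathway SNP subset.

    Kinship and structure covariates must be the genome-wide estimates;
    ``thresholds`` is the genome-wide Gao correction (the pathway subset
    does not earn a laxer multiple-testing burden).
    """
    subset = extract_pathway_snps(G, genes, flank_bp=flank_bp)
    if not subset.snp_ids:
        raise ValueError("pathway subset is empty: no SNP falls inside a pathway gene")
    pos = {sid: j for j, sid in enumerate(G.snp_ids)}
    Gsub = G.take_snps([pos[sid] for sid in subset.snp_ids])

    lmm_results = lmm_associate(Gsub, y, K, W)
    posterior = bslmm_fit(Gsub, y, K, W, bslmm_config)
    major = classify_major(posterior, pip_threshold=pip_threshold)

    effects = posterior.sparse_effects()
    rows = []
    for g in genes:
        idx = [
            j for j, sid in enumerate(posterior.snp_ids)
            if Gsub.snps[j].chrom == g.chrom and g.start - flank_bp <= Gsub.snps[j].pos <= g.end + flank_bp
        ]
        if not idx:
            rows.append({"gene": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
                         "n_snps": 0, "top_snp": "", "top_sparse_effect": 0.0,
                         "top_pip": 0.0, "hpdi_lo": np.nan, "hpdi_hi": np.nan})
            continue
        top = max(idx, key=lambda j: effects[j])
        iv = posterior.effect_hpdi(top)
        rows.append(
            {
                "gene": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
                "n_snps": len(idx),
                "top_snp": posterior.snp_ids[top],
                "top_sparse_effect": float(effects[top]),
                "top_pip": float(posterior.pip[top]),
                "hpdi_lo": iv[0] if iv else np.nan,
                "hpdi_hi": iv[1] if iv else np.nan,
            }
        )
    gene_table = pd.DataFrame(rows).sort_values(
        "top_sparse_effect", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return CpaReport(
        subset=subset,
        lmm_results=lmm_results,
        thresholds=thresholds,
        posterior=posterior,
        major_calls=major,
        gene_table=gene_table,
    )
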