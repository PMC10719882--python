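"""Genotype, phenotype and dosage-matrix I/O.

The pipeline's internal data model is a samples × SNPs additive dosage
matrix (alt-allele counts 0/1/2, ``NaN`` for missing calls) with per-SNP
metadata, plus a per-sample quantitative trait vector.  VCF input is read
with :mod:`cyvcf2`; plain delimited dosage matrices and two-column
phenotype tables are read with :mod:`pandas`.

Coordinates are 1-based throughout (VCF convention); interval logic that
needs half-open coordinates converts explicitly at the module boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathgwa")

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeVector",
    "read_vcf",
    "write_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_phenotype",
    "write_phenotype",
    "align_samples",
    "filter_snps",
    "impute_missing_mean",
]


class GenotypeError(ValueError):
    """Raised for malformed or degenerate genotype input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    ``maf``, ``het`` and ``missing_rate`` are derived from the dosage
    column and are recomputed (never trusted) whenever the matrix is
    subset or modified.
    """

    chrom: str
    pos: int  # 1-based physical position, bp
    id: str
    ref_allele: str
    alt_allele: str
    maf: float = 0.0
    het: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeError(f"SNP {self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(f"SNP {self.id}: ref and alt alleles are identical")


def _chrom_sort_key(chrom: str):
    """Natural sort: 'Chr2' before 'Chr10'; purely numeric labels numeric."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _snp_stats(col: np.ndarray) -> tuple[float, float, float]:
    """(maf, het, missing_rate) from one dosage column."""
    obs = col[~np.isnan(col)]
    n = col.size
    missing_rate = 1.0 - obs.size / n if n else 0.0
    if obs.size == 0:
        return 0.0, 0.0, missing_rate
    p_alt = float(obs.mean()) / 2.0
    maf = min(p_alt, 1.0 - p_alt)
    het = float(np.mean(obs == 1.0))
    return maf, het, missing_rate


@dataclass
class GenotypeMatrix:
    """Samples × SNPs dosage matrix with per-SNP metadata.

    ``dosages`` holds alt-allele counts in {0, 1, 2} as float64, with
    ``NaN`` marking missing calls.  Sample IDs are unique; SNPs are unique
    on (chrom, pos) and sorted by chromosome (natural order) then position.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (n_samples, n_snps), float64

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise GenotypeError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicate sample IDs")
        keys = [(s.chrom, s.pos, s.alt_allele) for s in self.snps]
        if len(set(keys)) != len(keys):
            raise GenotypeError("duplicate SNP (chrom, pos, alt) records")
        order = sorted(range(len(keys)), key=lambda i: (_chrom_sort_key(keys[i][0]), keys[i][1]))
        if order != list(range(len(keys))):
            self.snps = [self.snps[i] for i in order]
            self.dosages = self.dosages[:, order]

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_frame(self) -> pd.DataFrame:
        """Per-SNP metadata as a DataFrame (chrom, pos, id, alleles, stats)."""
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "id": [s.id for s in self.snps],
                "ref": [s.ref_allele for s in self.snps],
                "alt": [s.alt_allele for s in self.snps],
                "maf": [s.maf for s in self.snps],
                "het": [s.het for s in self.snps],
                "missing_rate": [s.missing_rate for s in self.snps],
            }
        )

    def take_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Subset to the given SNP column indices (stats preserved)."""
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Subset to the given sample row indices; per-SNP stats recomputed."""
        idx = list(indices)
        dos = self.dosages[idx, :].copy()
        snps = [
            replace(s, **dict(zip(("maf", "het", "missing_rate"), _snp_stats(dos[:, j]))))
            for j, s in enumerate(self.snps)
        ]
        return GenotypeMatrix(samples=[self.samples[i] for i in idx], snps=snps, dosages=dos)


def build_genotype_matrix(
    samples: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
    dosages: np.ndarray,
    ids: Sequence[str] | None = None,
    ref: Sequence[str] | None = None,
    alt: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix, computing per-SNP statistics."""
    dosages = np.asarray(dosages, dtype=np.float64)
    p = dosages.shape[1]
    ids = list(ids) if ids is not None else [f"{c}:{q}" for c, q in zip(chroms, positions)]
    ref = list(ref) if ref is not None else ["A"] * p
    alt = list(alt) if alt is not None else ["T"] * p
    snps = []
    for j in range(p):
        maf, het, miss = _snp_stats(dosages[:, j])
        snps.append(
            SnpRecord(
                chrom=str(chroms[j]), pos=int(positions[j]), id=ids[j],
                ref_allele=ref[j], alt_allele=alt[j],
                maf=maf, het=het, missing_rate=miss,
            )
        )
    return GenotypeMatrix(samples=list(samples), snps=snps, dosages=dosages)


@dataclass
class PhenotypeVector:
    """One quantitative trait value per sample; NaN flags a missing phenotype."""

    samples: list[str]
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples),):
            raise GenotypeError("phenotype length does not match sample count")
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicate sample IDs in phenotype")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", region)
    if not m:
        raise GenotypeError(f"malformed region {region!r}; expected chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_vcf(
    path: str,
    region: str | None = None,
    multiallelic: str = "reject",
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Parameters
    ----------
    path
        VCF file (plain or bgzipped).
    region
        Optional ``chrom:start-end`` restriction (1-based inclusive).
    multiallelic
        Policy for records with more than one ALT allele: ``"reject"``
        raises naming the site, ``"split"`` emits one biallelic row per
        ALT allele, ``"drop"`` skips the record.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "split", "drop"):
        raise GenotypeError(f"unknown multiallelic policy {multiallelic!r}")
    reg = _parse_region(region) if region else None

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise GenotypeError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if reg is not None:
            c, lo, hi = reg
            if var.CHROM != c or not (lo <= var.POS <= hi):
                continue
        alt_alleles = var.ALT
        if len(alt_alleles) == 0:
            continue
        if len(alt_alleles) > 1:
            if multiallelic == "reject":
                raise GenotypeError(
                    f"multi-allelic record at {var.CHROM}:{var.POS} "
                    f"(ALT={','.join(alt_alleles)}); rerun with multiallelic='split' or 'drop'"
                )
            if multiallelic == "drop":
                continue
        # SNPs only: single-nucleotide REF and ALT
        genos = var.genotypes  # [[a1, a2, phased], ...]
        for k, alt in enumerate(alt_alleles, start=1):
            if len(var.REF) != 1 or len(alt) != 1:
                continue
            col = np.empty(len(samples), dtype=np.float64)
            for i, g in enumerate(genos):
                alleles = [a for a in g[:-1] if a >= 0]
                col[i] = np.nan if not alleles else float(sum(a == k for a in alleles))
            chroms.append(var.CHROM)
            positions.append(var.POS)
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            ids.append(vid if len(alt_alleles) == 1 else f"{vid}_{alt}")
            refs.append(var.REF)
            alts.append(alt)
            cols.append(col)
    if not cols:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    dosages = np.column_stack(cols)
    return build_genotype_matrix(samples, chroms, positions, dosages, ids, refs, alts)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal VCFv4.2 with GT fields.

    Dosage 1 is emitted as ``0/1``, 2 as ``1/1``, NaN as ``./.``; the
    round-trip through :func:`read_vcf` restores the matrix exactly.
    """
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in G.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples) + "\n")
        for j, s in enumerate(G.snps):
            calls = "\t".join(
                "./." if np.isnan(d) else gt[float(d)] for d in G.dosages[:, j]
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# delimited matrices and phenotype tables
# ---------------------------------------------------------------------------


def read_dosage_matrix(path: str) -> GenotypeMatrix:
    """Plain dosage matrix: samples as rows, header of SNP IDs ('chrom:pos')."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    chroms, positions = [], []
    for snp_id in df.columns:
        c, _, q = str(snp_id).rpartition(":")
        if not c or not q.isdigit():
            raise GenotypeError(f"dosage header {snp_id!r} is not 'chrom:pos'")
        chroms.append(c)
        positions.append(int(q))
    return build_genotype_matrix(
        [str(s) for s in df.index], chroms, positions, df.to_numpy(dtype=np.float64),
        ids=[str(c) for c in df.columns],
    )


def write_dosage_matrix(G: GenotypeMatrix, path: str, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df = pd.DataFrame(G.dosages, index=G.samples, columns=G.snp_ids)
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t")


def read_phenotype(path: str, trait_name: str | None = None) -> PhenotypeVector:
    """Two-column delimited table (sample_id, value) with a header row."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise GenotypeError(f"phenotype table {path} needs 2 columns (sample_id, value)")
    name = trait_name or str(df.columns[1])
    return PhenotypeVector(
        samples=[str(s) for s in df.iloc[:, 0]],
        values=pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(),
        trait_name=name,
    )


def write_phenotype(y: PhenotypeVector, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id\t{y.trait_name}\n")
        for s, v in zip(y.samples, y.values):
            fh.write(f"{s}\t{'NA' if np.isnan(v) else repr(float(v))}\n")


# ---------------------------------------------------------------------------
# alignment, filtering, imputation
# ---------------------------------------------------------------------------


def align_samples(G: GenotypeMatrix, y: PhenotypeVector) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Restrict genotypes and phenotype to shared samples, in a common order.

    Samples with a missing (NaN) phenotype are dropped here, with a logged
    count — never silently inside downstream model fits.
    """
    pheno = dict(zip(y.samples, y.values))
    shared = [s for s in G.samples if s in pheno]
    n_missing = sum(1 for s in shared if np.isnan(pheno[s]))
    kept = [s for s in shared if not np.isnan(pheno[s])]
    if len(kept) < 2:
        raise GenotypeError(
            f"fewer than 2 usable samples shared between genotypes ({G.n_samples}) "
            f"and phenotype ({len(y.samples)})"
        )
    dropped = (G.n_samples - len(shared)) + (len(y.samples) - len(shared)) + n_missing
    logger.info(
        "align_samples: kept %d samples (%d genotype-only, %d phenotype-only, %d missing trait dropped)",
        len(kept), G.n_samples - len(shared), len(y.samples) - len(shared), n_missing,
    )
    del dropped
    idx = {s: i for i, s in enumerate(G.samples)}
    G2 = G.take_samples([idx[s] for s in kept])
    y2 = PhenotypeVector(samples=kept, values=np.array([pheno[s] for s in kept]), trait_name=y.trait_name)
    return G2, y2


def filter_snps(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    het_max: float = 0.10,
    miss_max: float = 1.0,
) -> GenotypeMatrix:
    """Drop SNPs by minor-allele frequency, heterozygosity and missingness.

    Defaults mirror the panel construction for an inbred association panel:
    SNPs with MAF below 5% or heterozygosity above 10% are excluded.
    Retains SNPs with ``maf >= maf_min`` and ``het <= het_max`` and
    ``missing_rate <= miss_max``; column order is preserved.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise GenotypeError("maf_min must be in [0, 0.5]")
    if not (0.0 <= het_max <= 1.0 and 0.0 <= miss_max <= 1.0):
        raise GenotypeError("het_max and miss_max must be in [0, 1]")
    fail_maf = fail_het = fail_miss = 0
    keep = []
    for j, s in enumerate(G.snps):
        ok = True
        if s.maf < maf_min:
            fail_maf += 1
            ok = False
        if s.het > het_max:
            fail_het += 1
            ok = False
        if s.missing_rate > miss_max:
            fail_miss += 1
            ok = False
        if ok:
            keep.append(j)
    logger.info(
        "filter_snps: kept %d/%d (removed: maf<%g: %d, het>%g: %d, miss>%g: %d)",
        len(keep), G.n_snps, maf_min, fail_maf, het_max, fail_het, miss_max, fail_miss,
    )
    if not keep:
        raise GenotypeError(
            f"all {G.n_snps} SNPs removed (maf<{maf_min}: {fail_maf}, "
            f"het>{het_max}: {fail_het}, miss>{miss_max}: {fail_miss})"
        )
    return G.take_snps(keep)


def impute_missing_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call by its SNP's mean dosage over observed calls."""
    dos = G.dosages.copy()
    for j in range(dos.shape[1]):
        col = dos[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        obs = col[~mask]
        if obs.size == 0:
            raise GenotypeError(f"SNP {G.snps[j].id} has no observed calls; cannot impute")
        col[mask] = obs.mean()
    snps = [
        replace(s, **dict(zip(("maf", "het", "missing_rate"), _snp_stats(dos[:, j]))))
        for j, s in enumerate(G.snps)
    ]
    return GenotypeMatrix(samples=list(G.samples), snps=snps, dosages=dos)
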