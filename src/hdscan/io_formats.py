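"""Readers/writers for the standard formats the pipeline touches.

Genotypes come in as VCF 4.x (via cyvcf2) or PLINK bed/bim/fam; phenotypes
and methylation matrices as delimited tables. Internal coordinates are
1-based inclusive; BED export converts to 0-based half-open.

Genotype coding: integer count of the ALT (VCF) / A1 (PLINK) allele, with
``-1`` for missing. Multi-allelic and non-SNP records are dropped on load.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: smallest beta value kept after clamping; keeps the M transform finite
BETA_EPS = 1e-6

PHENO_COLUMNS = (
    "sample", "pedigree", "tg1", "tg2", "tg3", "tg4",
    "sex", "age", "center", "smoking", "atp", "idf",
)

CATEGORY_LEVELS = {
    "sex": {0, 1},
    "smoking": {0, 1},
    "atp": {0, 1},
    "idf": {0, 1},
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes plus SNP map and pedigree labels."""

    samples: list[str]
    pedigree: np.ndarray           # pedigree/cluster id per sample, dtype object
    genotypes: np.ndarray          # (n_samples, n_snps) int8, MISSING for no-call
    snp_ids: np.ndarray            # (n_snps,) object
    chrom: np.ndarray              # (n_snps,) object
    pos: np.ndarray                # (n_snps,) int64, 1-based
    alleles: np.ndarray            # (n_snps, 2) object, (ref, alt)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise FormatError("genotype codes outside {0,1,2,missing}")
        if len(self.samples) != len(self.pedigree):
            raise FormatError("every sample needs a pedigree ID")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def maf(self) -> np.ndarray:
        """Sample minor allele frequency per SNP, missing excluded."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def alt_freq(self) -> np.ndarray:
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return g.mean(axis=0).filled(np.nan) / 2.0


@dataclass
class PhenotypeTable:
    """Per-sample TG visits 1-4 plus covariates, missing preserved as NaN."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"phenotype table lacks columns: {missing}")
        for c in ("tg1", "tg2", "tg3", "tg4"):
            vals = self.table[c]
            if (vals.dropna() < 0).any():
                raise FormatError(f"negative TG in column {c}")
        for c, levels in CATEGORY_LEVELS.items():
            bad = set(self.table[c].dropna().unique()) - levels
            if bad:
                raise FormatError(f"unknown levels {bad} in column {c}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].astype(str).tolist()


@dataclass
class MethylationSet:
    """CpG x sample beta values at two visits, with probe annotations."""

    cpg_ids: np.ndarray            # (n_cpg,) object
    chrom: np.ndarray              # (n_cpg,) object
    pos: np.ndarray                # (n_cpg,) int64
    probe_type: np.ndarray        # (n_cpg,) object, 'I' or 'II'
    samples: list[str]
    beta: dict[int, np.ndarray] = field(default_factory=dict)  # visit -> (n_cpg, n_samples)

    def __post_init__(self) -> None:
        if len(np.unique(self.cpg_ids)) != len(self.cpg_ids):
            raise FormatError("duplicate CpG IDs")
        if not np.isin(self.probe_type, ("I", "II")).all():
            raise FormatError("probe_type must be 'I' or 'II' for every CpG")
        for v, b in self.beta.items():
            if b.size and (np.nanmin(b) < -1e-9 or np.nanmax(b) > 1 + 1e-9):
                raise FormatError(f"beta outside [0,1] at visit {v}")
            self.beta[v] = np.clip(b, BETA_EPS, 1.0 - BETA_EPS)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_ids)


# ---------------------------------------------------------------------------
# genotype readers / writers

def read_genotypes(path: str, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or PLINK bed/bim/fam into a GenotypeMatrix.

    ``format`` is 'vcf' or 'plink'; inferred from the extension when None.
    Pedigree IDs come from the fam file (PLINK) or are parsed from sample
    names of the form ``FAM_IND`` (VCF; otherwise each sample is its own
    cluster).
    """
    if format is None:
        format = "plink" if str(path).endswith(".bed") else "vcf"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink":
        return _read_plink(path)
    raise FormatError(f"unknown genotype format: {format!r}")


def _pedigree_from_names(samples: list[str]) -> np.ndarray:
    peds = []
    for s in samples:
        peds.append(s.split("_")[0] if "_" in s else s)
    return np.array(peds, dtype=object)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, alleles, rows = [], [], [], [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
        gt = var.gt_types  # 0=hom ref, 1=het, 2=missing(UNKNOWN), 3=hom alt
        code = np.array([0, 1, MISSING, 2], dtype=np.int8)[gt]
        rows.append(code)
    vcf.close()
    if n_dropped:
        logger.info("read_genotypes: dropped %d multi-allelic/non-SNP records", n_dropped)
    geno = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        samples=samples,
        pedigree=_pedigree_from_names(samples),
        genotypes=geno,
        snp_ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        alleles=np.array(alleles, dtype=object).reshape(-1, 2),
    )


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes in a .bed byte: 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_plink(bed_path: str) -> GenotypeMatrix:
    stem = str(bed_path)[:-4] if str(bed_path).endswith(".bed") else str(bed_path)
    bim = pd.read_csv(
        stem + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        stem + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    n_samples, n_snps = len(fam), len(bim)
    with open(stem + ".bed", "rb") as fh:
        if fh.read(3) != _BED_MAGIC:
            raise FormatError("not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n_samples + 3) // 4
    if raw.size != bytes_per_snp * n_snps:
        raise FormatError("PLINK .bed size inconsistent with .bim/.fam")
    raw = raw.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, sample index runs low-bit first within a byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_snps, -1)[:, :n_samples]]
    return GenotypeMatrix(
        samples=fam["iid"].tolist(),
        pedigree=fam["fid"].to_numpy(dtype=object),
        genotypes=codes.T.copy(),
        snp_ids=bim["id"].to_numpy(dtype=object),
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos=bim["pos"].to_numpy(np.int64),
        alleles=bim[["a2", "a1"]].to_numpy(dtype=object),  # (ref, counted)
    )


def write_plink(gm: GenotypeMatrix, stem: str) -> None:
    """Write a GenotypeMatrix as PLINK bed/bim/fam (SNP-major)."""
    pd.DataFrame({
        "chrom": gm.chrom, "id": gm.snp_ids, "cm": 0, "pos": gm.pos,
        "a1": gm.alleles[:, 1], "a2": gm.alleles[:, 0],
    }).to_csv(stem + ".bim", sep="\t", header=False, index=False)
    pd.DataFrame({
        "fid": gm.pedigree, "iid": gm.samples, "pat": 0, "mat": 0,
        "sex": 0, "pheno": -9,
    }).to_csv(stem + ".fam", sep="\t", header=False, index=False)
    encode = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    n_samples = gm.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    padded = np.full((gm.n_snps, bytes_per_snp * 4), 0b11, dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for k, v in encode.items():
        lut[k if k != MISSING else 3] = v
    g = gm.genotypes.T.copy()
    g[g == MISSING] = 3
    padded[:, :n_samples] = lut[g]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(gm.n_snps, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(stem + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in gm.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_snps):
            row = "\t".join(gt_str[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t{gm.snp_ids[j]}\t"
                     f"{gm.alleles[j, 0]}\t{gm.alleles[j, 1]}\t.\tPASS\t.\tGT\t{row}\n")


# ---------------------------------------------------------------------------
# phenotype / methylation tables

def read_phenotypes(path: str, column_map: dict[str, str] | None = None,
                    sep: str = "\t") -> PhenotypeTable:
    """Read a delimited phenotype table.

    ``column_map`` maps file column names onto the internal schema
    (sample, pedigree, tg1..tg4, sex, age, center, smoking, atp, idf).
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype file lacks columns: {missing}")
    for c in ("tg1", "tg2", "tg3", "tg4", "age"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return PhenotypeTable(df[list(PHENO_COLUMNS)].copy())


def write_phenotypes(pt: PhenotypeTable, path: str) -> None:
    pt.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_methylation(path: str, annot_path: str, sep: str = "\t") -> MethylationSet:
    """Read beta matrices for visits 2 and 4 plus a probe annotation table.

    ``path`` holds columns cpg, visit, then one column per sample;
    ``annot_path`` holds cpg, chrom, pos, probe_type. Probes lacking an
    annotation row are dropped with a logged count.
    """
    mat = pd.read_csv(path, sep=sep)
    annot = pd.read_csv(annot_path, sep=sep, dtype={"chrom": str, "probe_type": str})
    if annot["cpg"].duplicated().any():
        raise FormatError("duplicate CpG IDs in annotation")
    sample_cols = [c for c in mat.columns if c not in ("cpg", "visit")]
    annotated = set(annot["cpg"])
    keep = mat["cpg"].isin(annotated)
    n_drop = mat.loc[~keep, "cpg"].nunique()
    if n_drop:
        logger.info("read_methylation: dropped %d unannotated CpGs", n_drop)
    mat = mat[keep]
    cpgs = [c for c in annot["cpg"] if c in set(mat["cpg"])]
    annot = annot.set_index("cpg").loc[cpgs]
    beta = {}
    for visit, sub in mat.groupby("visit"):
        if sub["cpg"].duplicated().any():
            raise FormatError(f"duplicate CpG IDs at visit {visit}")
        beta[int(visit)] = sub.set_index("cpg").loc[cpgs, sample_cols].to_numpy(float)
    return MethylationSet(
        cpg_ids=np.array(cpgs, dtype=object),
        chrom=annot["chrom"].to_numpy(dtype=object),
        pos=annot["pos"].to_numpy(np.int64),
        probe_type=annot["probe_type"].to_numpy(dtype=object),
        samples=sample_cols,
        beta=beta,
    )


def write_methylation(ms: MethylationSet, path: str, annot_path: str) -> None:
    frames = []
    for visit in sorted(ms.beta):
        df = pd.DataFrame(ms.beta[visit], columns=ms.samples)
        df.insert(0, "visit", visit)
        df.insert(0, "cpg", ms.cpg_ids)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame({
        "cpg": ms.cpg_ids, "chrom": ms.chrom, "pos": ms.pos,
        "probe_type": ms.probe_type,
    }).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export

def read_bed_regions(path: str) -> list[tuple]:
    """Read BED intervals as internal 1-based inclusive (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise FormatError(f"BED interval end <= start: {line.strip()}")
            out.append((chrom, start + 1, end))
    return out


def write_regions(regions, path: str) -> None:
    """Write HD regions as BED6 (0-based half-open, score = 1000 x intensity)."""
    with open(path, "w") as fh:
        fh.write('track name="hd_regions" description="homozygosity regions"\n')
        for r in regions:
            if r.end <= r.start:
                raise FormatError(f"region end <= start: {r}")
            score = int(round(1000 * r.mean_intensity))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.sample}\t{score}\t.\n")
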