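"""File input/output: genotype TSV/VCF, phenotype, covariates, kinship.

Text conventions:

* genotype TSV — rows are samples, first column is the sample ID, header
  row carries marker IDs; numeric additive coding.
* phenotype TSV — two columns (sample ID, value), with header.
* covariate TSV — sample ID column followed by one column per covariate.
* kinship TSV — square matrix with sample-ID header row and first column.
* VCF — biallelic SNPs become additive dosages (0/1/2 copies of ALT);
  multi-allelic records are skipped with a logged count; missing genotypes
  are mean-imputed per marker with a logged fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger("fastrr")

__all__ = [
    "read_genotypes", "write_genotype_tsv", "read_phenotype",
    "write_phenotype_tsv", "read_covariates", "read_kinship",
    "write_kinship", "write_truth_tsv", "write_vcf",
]


def read_genotypes(path, fmt: str = "tsv", coding: str = "centered") -> GenotypeMatrix:
    """Load a genotype matrix from ``tsv`` or ``vcf``.

    For VCF, ``coding='dosage'`` returns ALT-allele counts in {0, 1, 2};
    the default ``'centered'`` shifts them to {-1, 0, +1}.  TSV input is
    taken verbatim (the file already carries its coding).
    """
    if fmt == "tsv":
        return _read_genotype_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path, coding=coding)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no marker columns found")
    try:
        mat = df.to_numpy(dtype=np.float64)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric genotype entries ({e})") from None
    return GenotypeMatrix(
        matrix=mat,
        marker_ids=df.columns.to_numpy(dtype=str),
        sample_ids=df.index.to_numpy(dtype=str),
    )


def _read_vcf(path, coding: str = "centered") -> GenotypeMatrix:
    from cyvcf2 import VCF

    if coding not in ("centered", "dosage"):
        raise ValueError("coding must be 'centered' or 'dosage'")
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    cols, ids, positions = [], [], []
    n_multi = 0
    n_missing = 0
    n_total_gt = 0
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dosage = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        miss = np.isnan(dosage)
        n_total_gt += len(dosage)
        if miss.any():
            n_missing += int(miss.sum())
            fill = np.nanmean(dosage) if not miss.all() else 0.0
            dosage[miss] = fill
        cols.append(dosage)
        ids.append(v.ID if v.ID and v.ID != "." else f"{v.CHROM}:{v.POS}")
        positions.append(len(cols))
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    if n_missing:
        log.info("mean-imputed %.3g%% missing genotypes",
                 100.0 * n_missing / max(n_total_gt, 1))
    if not cols:
        raise ValueError(f"{path}: no usable biallelic records")
    mat = np.column_stack(cols)
    if coding == "centered":
        mat = mat - 1.0
    return GenotypeMatrix(
        matrix=mat,
        marker_ids=np.array(ids),
        positions=np.array(positions, dtype=np.int64),
        sample_ids=samples,
    )


def write_genotype_tsv(geno: GenotypeMatrix, path):
    df = pd.DataFrame(np.asarray(geno.matrix), index=geno.sample_ids,
                      columns=geno.marker_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_phenotype(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expected a value column")
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s


def write_phenotype_tsv(sample_ids, y, path, name="phenotype"):
    pd.Series(np.asarray(y, dtype=float), index=np.asarray(sample_ids, dtype=str),
              name=name).rename_axis("sample_id").to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_kinship(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    K = df.to_numpy(dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError(f"{path}: kinship matrix is not square")
    return K


def write_kinship(K, sample_ids, path):
    ids = np.asarray(sample_ids, dtype=str)
    pd.DataFrame(np.asarray(K, dtype=float), index=ids, columns=ids) \
        .rename_axis("sample_id").to_csv(path, sep="\t")


def write_truth_tsv(truth, path):
    pd.DataFrame({
        "position": np.asarray(truth.qtn_positions, dtype=int),
        "effect": np.asarray(truth.qtn_effects, dtype=float),
    }).to_csv(path, sep="\t", index=False)


def write_vcf(geno: GenotypeMatrix, path, chrom="1"):
    """Export a two-class or three-class coded matrix as a minimal VCF.

    Coding -1/0/+1 maps to genotypes 0/0, 0/1, 1/1 (dosage = coding + 1).
    """
    mat = np.asarray(geno.matrix)
    vals = np.unique(mat)
    if not np.all(np.isin(vals, [-1.0, 0.0, 1.0])):
        raise ValueError("VCF export expects coding in {-1, 0, +1}")
    gt_map = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.sample_ids)) + "\n")
        for j in range(geno.n_markers):
            gts = "\t".join(gt_map[float(g)] for g in mat[:, j])
            fh.write(f"{chrom}\t{geno.positions[j]}\t{geno.marker_ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
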