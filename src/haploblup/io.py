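"""Readers, writers and block planning for the standard file formats.

Coordinate conventions are centralized here: VCF positions are 1-based,
BED intervals 0-based half-open, so a SNP at 1-based position P lies in
BED interval [start, end) iff start < P <= end.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .grm import BlockPlan, PhasedGenotypes

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_phenotypes",
    "read_bed",
    "plan_blocks",
    "write_grm",
    "read_grm",
]


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Load phased bi-allelic SNPs from a VCF.

    Multi-allelic records, unphased genotypes (the model assumes haplotypes
    of all individuals are known) and missing genotypes are rejected with
    the offending record identified.
    """
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    haps, positions, chroms = [], [], []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"{where}: only bi-allelic SNP records supported")
        row = np.empty((len(samples), 2), dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValueError(f"{where}: missing genotype for {samples[s]}")
            if not phased:
                raise ValueError(
                    f"{where}: unphased genotype for {samples[s]}; the model "
                    "requires known haplotypes (pre-phased input)"
                )
            row[s] = (a, b)
        haps.append(row)
        positions.append(var.POS)
        chroms.append(var.CHROM)
    if not haps:
        raise ValueError(f"{path}: no SNP records found")
    hap = np.stack(haps, axis=2)  # (q, 2, m)
    return PhasedGenotypes(
        haplotypes=hap,
        samples=samples,
        positions=np.asarray(positions),
        chromosomes=tuple(chroms),
    )


def write_phased_vcf(geno: PhasedGenotypes, path: str | Path) -> None:
    """Write genotypes as a minimal phased VCF v4.2 (REF=A, ALT=C)."""
    positions = (
        geno.positions
        if geno.positions is not None
        else np.arange(1, geno.m + 1)
    )
    chroms = geno.chromosomes if geno.chromosomes is not None else ("1",) * geno.m
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chrom_set = []
        for c in chroms:
            if c not in chrom_set:
                chrom_set.append(c)
        for c in chrom_set:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for j in range(geno.m):
            gts = "\t".join(
                f"{geno.haplotypes[i, 0, j]}|{geno.haplotypes[i, 1, j]}"
                for i in range(geno.q)
            )
            fh.write(
                f"{chroms[j]}\t{positions[j]}\tsnp{j + 1}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype table: id, y, then numeric fixed-effect covariates.

    Missing phenotypes (empty or NA) are kept as NaN — such individuals are
    treated as the validation population downstream.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least id and phenotype columns")
    df = df.rename(columns={df.columns[0]: "id", df.columns[1]: "y"})
    df["id"] = df["id"].astype(str)
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals (0-based half-open): chrom, start, end[, name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs chrom, start, end columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"block{i + 1}" for i in range(len(df))]
    df["chrom"] = df["chrom"].astype(str)
    return df


def plan_blocks(
    geno: PhasedGenotypes,
    snps_per_block: int | None = None,
    block_length: int | None = None,
    bed: pd.DataFrame | str | Path | None = None,
) -> BlockPlan:
    """Deterministic haplotype-block plan from exactly one rule.

    Fixed-count: ceil(m / N) blocks of N consecutive SNPs in genome order.
    Fixed-length: SNPs binned by position into windows of ``block_length``
    bases per chromosome.  BED: intervals intersected with SNP positions;
    intervals containing no SNP are dropped with a warning.
    """
    rules = sum(x is not None for x in (snps_per_block, block_length, bed))
    if rules != 1:
        raise ValueError(
            "exactly one of snps_per_block, block_length or bed is required"
        )
    if snps_per_block is not None:
        if snps_per_block < 1:
            raise ValueError("snps_per_block must be >= 1")
        idx = np.arange(geno.m)
        blocks = [idx[i : i + snps_per_block] for i in range(0, geno.m, snps_per_block)]
        return BlockPlan(blocks=tuple(blocks))
    if geno.positions is None:
        raise ValueError("positions are required for length/BED block rules")
    positions = np.asarray(geno.positions)
    chroms = np.asarray(
        geno.chromosomes if geno.chromosomes is not None else ["1"] * geno.m
    )
    blocks, names = [], []
    if block_length is not None:
        if block_length < 1:
            raise ValueError("block_length must be >= 1")
        for chrom in dict.fromkeys(chroms):
            on = np.nonzero(chroms == chrom)[0]
            pos = positions[on]
            bins = (pos - pos.min()) // block_length
            for b in np.unique(bins):
                blocks.append(on[bins == b])
                names.append(f"{chrom}:{int(b)}")
        return BlockPlan(blocks=tuple(blocks), names=tuple(names))
    bed_df = read_bed(bed) if not isinstance(bed, pd.DataFrame) else bed
    for row in bed_df.itertuples(index=False):
        # BED half-open 0-based vs VCF 1-based: start < pos <= end
        hit = np.nonzero(
            (chroms == str(row.chrom))
            & (positions > row.start)
            & (positions <= row.end)
        )[0]
        if hit.size == 0:
            warnings.warn(
                f"BED interval {row.chrom}:{row.start}-{row.end} contains no "
                "SNP and was dropped",
                stacklevel=2,
            )
            continue
        blocks.append(hit)
        names.append(str(row.name))
    if not blocks:
        raise ValueError("no BED interval contained any SNP")
    return BlockPlan(blocks=tuple(blocks), names=tuple(names))


def write_grm(
    matrix: np.ndarray,
    samples: tuple[str, ...],
    path: str | Path,
    long_path: str | Path | None = None,
) -> None:
    """Square delimited GRM with a sample-ID header, plus optional long form."""
    df = pd.DataFrame(matrix, index=list(samples), columns=list(samples))
    df.to_csv(path, sep="\t", index_label="id")
    if long_path is not None:
        rows = []
        for a in range(len(samples)):
            for b in range(a, len(samples)):
                rows.append((samples[a], samples[b], matrix[a, b]))
        pd.DataFrame(rows, columns=["id1", "id2", "value"]).to_csv(
            long_path, sep="\t", index=False
        )


def read_grm(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a square GRM written by :func:`write_grm`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)
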