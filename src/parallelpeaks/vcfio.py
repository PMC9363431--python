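"""Reading and writing the pipeline's file formats.

VCF 4.2 (GT-only biallelic SNPs) is read through cyvcf2 and written by a
minimal text writer (REF is the ancestral allele by the simulator's
convention). The population map is a TSV with the columns
``sample population transect side altitude_class altitude_m species``.
BED files are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

POPMAP_COLUMNS = [
    "sample", "population", "transect", "side",
    "altitude_class", "altitude_m", "species",
]


def write_vcf(path, chrom, pos, genotypes, sample_ids, contigs=None,
              ref="A", alt="T") -> None:
    """Write a biallelic GT-only VCF. ``pos`` is 0-based internally and
    written 1-based; dosage -1 is written as a missing genotype."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    geno = np.asarray(genotypes)
    if geno.shape != (pos.size, len(sample_ids)):
        raise ValueError("genotype matrix shape does not match sites x samples")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for i in range(pos.size):
            gts = "\t".join(gt_strings[int(g)] for g in geno[i])
            fh.write(f"{chrom[i]}\t{int(pos[i]) + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read a biallelic VCF into (chrom, pos0, dosage matrix, sample ids).

    Positions are converted to 0-based. Dosage counts ALT alleles;
    missing genotypes become -1. Non-biallelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, rows = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"site {v.CHROM}:{v.POS} is not biallelic")
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        gt = v.gt_types.astype(np.int8)  # with gts012: 0,1,2 dosage; 3 unknown
        gt[gt == 3] = -1
        rows.append(gt)
    geno = (np.vstack(rows) if rows
            else np.empty((0, len(samples)), dtype=np.int8))
    return (np.array(chroms, dtype=object), np.array(poss, dtype=np.int64),
            geno, samples)


def read_popmap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POPMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population map is missing columns: {missing}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in population map")
    # every population maps to exactly one transect/side/class
    per_pop = df.groupby("population")[["transect", "side", "altitude_class"]].nunique()
    bad = per_pop[(per_pop > 1).any(axis=1)]
    if len(bad):
        raise ValueError(f"inconsistent metadata for populations: {list(bad.index)}")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "name", 4: "score", 5: "strand"})
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
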