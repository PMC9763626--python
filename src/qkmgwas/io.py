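"""Standard-format I/O: minimal VCF 4.2 and TSV tables.

Reading goes through cyvcf2 (GT field only; biallelic SNP records;
``./.`` marks missing; phased separators accepted; multiallelic records
are rejected with their coordinates).  Writing emits a minimal
VCF 4.2 with unphased genotypes, which round-trips through the reader
with zero dosage mismatches.  Tabular outputs are TSV with optional
``#``-prefixed provenance header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotype import GenotypeMatrix
from .metabolites import MetaboliteMatrix

__all__ = ["read_vcf", "write_vcf", "write_tsv", "read_grades",
           "write_metabolites", "read_metabolites", "write_truth"]

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


class VcfParseError(ValueError):
    """Malformed or unsupported VCF content."""


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF with GT into a dosage GenotypeMatrix.

    Multiallelic records raise :class:`VcfParseError` naming CHROM:POS.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: no samples / missing GT field")
    rows, chroms, pos, ref, alt = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise VcfParseError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT) or '.'}); split or drop it first")
        # gts012=True: 0/1/2 = alt count, 3 = missing
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    vcf.close()
    if not rows:
        raise VcfParseError(f"{path}: no variant records")
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref,
                             "alt": alt})
    return GenotypeMatrix(np.vstack(rows).T, variants, samples)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only, unphased)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.variants["chrom"]):
            sub = G.variants[G.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max())}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j in range(G.n_snps):
            v = G.variants.iloc[j]
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_STRINGS[d]
                for d in G.dosages[:, j])
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{v['chrom']}:{int(v['pos'])}"
                     f"\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_tsv(df: pd.DataFrame, path, header_lines=(), index=False) -> None:
    """TSV with '#'-prefixed provenance lines before the header row."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_grades(path) -> pd.DataFrame:
    """Grade table TSV: accession, replicate, timepoint_h, wilting_rate [, grade]."""
    df = read_tsv(path)
    required = {"accession", "replicate", "timepoint_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grade table lacks columns {sorted(missing)}")
    return df


def write_metabolites(M: MetaboliteMatrix, path) -> None:
    """Features x samples TSV with condition and group annotation rows."""
    path = Path(path)
    ab = M.abundances.T  # features as rows
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(map(str, ab.columns)) + "\n")
        fh.write("#condition\t"
                 + "\t".join(M.sample_meta["condition"]) + "\n")
        fh.write("#group\t" + "\t".join(M.sample_meta["group"]) + "\n")
        fh.write("#accession\t" + "\t".join(M.sample_meta["accession"]) + "\n")
        ab.to_csv(fh, sep="\t", header=False)


def read_metabolites(path) -> MetaboliteMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        meta_rows = {}
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            parts = line.rstrip("\n").split("\t")
            meta_rows[parts[0][1:]] = parts[1:]
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        ab = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    ab.columns = header
    ab.index.name = "feature"
    meta = pd.DataFrame(
        {"accession": meta_rows.get("accession", header),
         "condition": meta_rows["condition"],
         "group": meta_rows.get("group", ["intermediate"] * len(header))},
        index=header)
    return MetaboliteMatrix(ab.T, meta)


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
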