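"""Standard-format I/O: VCF genotype ingestion/emission, site annotation
tables, and report writers."""

from __future__ import annotations

import hashlib
import math
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .sfs import GenotypeMatrix, MISSING

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_pop_map",
    "annotate_sites",
    "read_annotation",
    "provenance_hash",
]


def _gq_to_prob(gq: float) -> float:
    """Phred-scaled genotype quality -> posterior probability."""
    return 1.0 - 10.0 ** (-gq / 10.0)


def _prob_to_gq(p: float) -> int:
    p = min(max(p, 0.0), 1.0 - 1e-10)
    return int(round(-10.0 * math.log10(1.0 - p)))


def read_pop_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"])
    return dict(zip(df["sample"].astype(str), df["pop"].astype(str)))


def read_vcf(path, pop_map: dict[str, str], ploidy: int = 2) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a GenotypeMatrix.

    Multi-allelic records are skipped (count reported via the returned
    matrix's length vs the file).  GQ is mapped to a posterior probability
    1 - 10^(-GQ/10); 1-based coordinates are preserved in site_ids as
    "chrom:pos".
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise ValueError(f"samples missing from pop_map: {missing}")
    calls_cols = []
    qual_cols = []
    site_ids = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1), last col = phased
        alleles = gts[:, :-1]
        dosage = np.where(
            np.any(alleles < 0, axis=1),
            MISSING,
            np.clip(alleles, 0, 1).sum(axis=1),
        ).astype(np.int8)
        if ploidy == 1:
            # haploid context from diploid-style records: 0/0 -> 0, 1/1 -> 1,
            # het -> raw heteroplasmic marker
            from .sfs import HET_RAW

            hap = np.where(dosage == MISSING, MISSING,
                           np.where(dosage == 1, HET_RAW,
                                    np.where(dosage == 2, 1, 0))).astype(np.int8)
            dosage = hap
        calls_cols.append(dosage)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is None:
            qual_cols.append(np.ones(len(samples)))
        else:
            qual_cols.append(np.array([_gq_to_prob(float(v)) for v in gq[:, 0]]))
        site_ids.append(f"{var.CHROM}:{var.POS}")
    if n_skipped:
        import logging

        logging.getLogger(__name__).info("skipped %d non-biallelic records", n_skipped)
    calls = np.array(calls_cols, dtype=np.int8).T if calls_cols else np.zeros((len(samples), 0), np.int8)
    quality = np.array(qual_cols).T if qual_cols else np.ones((len(samples), 0))
    labels = [pop_map[s] for s in samples]
    return GenotypeMatrix(samples, labels, calls, site_ids,
                          genotype_quality=quality, ploidy=ploidy)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Emit a minimal uncompressed VCF (GT and GQ fields)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for sid in geno.site_ids:
            c = sid.split(":")[0]
            if c not in chroms:
                chroms.append(c)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        gt_map_dip = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        gt_map_hap = {0: "0/0", 1: "1/1", 2: "0/1", MISSING: "./."}
        gt_map = gt_map_dip if geno.ploidy == 2 else gt_map_hap
        for s, sid in enumerate(geno.site_ids):
            chrom, pos = sid.split(":")
            fields = []
            for i in range(len(geno.individuals)):
                gt = gt_map[int(geno.calls[i, s])]
                if geno.genotype_quality is not None:
                    gq = _prob_to_gq(float(geno.genotype_quality[i, s]))
                    fields.append(f"{gt}:{gq}")
                else:
                    fields.append(gt)
            fmt = "GT:GQ" if geno.genotype_quality is not None else "GT"
            fh.write(f"{chrom}\t{pos}\t.\tA\tG\t.\tPASS\t.\t{fmt}\t" + "\t".join(fields) + "\n")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"site_id", "category"} <= set(df.columns):
        raise ValueError("annotation needs site_id and category columns")
    dup = df[df.duplicated("site_id", keep=False)]
    if len(dup):
        conflicting = dup.groupby("site_id")["category"].nunique()
        if (conflicting > 1).any():
            raise ValueError(
                f"conflicting annotations for {list(conflicting[conflicting > 1].index)[:5]}"
            )
        df = df.drop_duplicates("site_id")
    return df


CATEGORIES = ("synonymous", "non_synonymous", "non_coding")


def annotate_sites(matrix: GenotypeMatrix, annotation: pd.DataFrame):
    """Partition the matrix's sites by functional category; unannotated
    sites default to non_coding.  Returns {category: GenotypeMatrix}."""
    cat = dict(zip(annotation["site_id"].astype(str), annotation["category"]))
    unknown = set(cat.values()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    assignment = np.array([cat.get(sid, "non_coding") for sid in matrix.site_ids])
    return {
        c: matrix.take_sites(np.flatnonzero(assignment == c)) for c in CATEGORIES
    }


def provenance_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
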