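"""Identity-by-state allele sharing and mtDNA summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sfs import GenotypeMatrix, HET_RAW, MISSING

__all__ = ["IBSMatrix", "ibs_matrix", "drop_heteroplasmic_sites", "snp_density"]


@dataclass
class IBSMatrix:
    """Pairwise proportions of identical genotypes over co-called sites."""

    sample_ids: list[str]
    values: np.ndarray
    n_sites_used: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("IBS matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def save(self, path) -> None:
        self.to_frame().round(6).to_csv(path, sep="\t", float_format="%.6f")


def ibs_matrix(geno: GenotypeMatrix, allele_sharing: bool = False) -> IBSMatrix:
    """Per pair, the fraction of co-called sites with the same genotype
    (diploid calls compared as dosages, haploid as alleles).

    With ``allele_sharing=True`` diploid pairs instead score partial matches
    as half (|dosage difference| of 1 scores 0.5).  A pair with zero
    co-called sites gets NaN.
    """
    calls = geno.calls.astype(float)
    calls[geno.calls == MISSING] = np.nan
    n = len(geno.individuals)
    values = np.ones((n, n))
    used = np.zeros((n, n), dtype=int)
    for i in range(n):
        used[i, i] = int(np.sum(~np.isnan(calls[i])))
        for j in range(i + 1, n):
            ok = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            m = int(ok.sum())
            used[i, j] = used[j, i] = m
            if m == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            if allele_sharing and geno.ploidy == 2:
                diff = np.abs(calls[i, ok] - calls[j, ok])
                score = np.mean(1.0 - diff / 2.0)
            else:
                score = np.mean(calls[i, ok] == calls[j, ok])
            values[i, j] = values[j, i] = score
    return IBSMatrix(list(geno.individuals), values, used)


def drop_heteroplasmic_sites(geno: GenotypeMatrix):
    """Remove every site carrying at least one raw heterozygous call in a
    haploid-context matrix.  Returns (filtered matrix, removed fraction)."""
    if geno.ploidy != 1:
        raise ValueError("heteroplasmy filtering applies to haploid matrices")
    flagged = np.any(geno.calls == HET_RAW, axis=0)
    keep = np.flatnonzero(~flagged)
    fraction = float(flagged.mean()) if geno.calls.shape[1] else 0.0
    return geno.take_sites(keep), fraction


def snp_density(n_snps: int, n_callable: int) -> float:
    """Average spacing between SNPs: callable bases per SNP."""
    if n_snps <= 0:
        raise ValueError("need at least one SNP")
    return n_callable / n_snps
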