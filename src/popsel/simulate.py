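"""Synthetic-data generators: every input the pipeline consumes can be
produced here, seeded and bit-reproducible.

SFS-level truth uses Poisson draws around the expected spectra (matching
the Poisson-random-field likelihood the fits assume); genotype matrices and
mtDNA haplotype sets are sampled on top to exercise the filtering and
summary machinery; MK tables are drawn from the same log-linear structure
the random-effects classifier models, with known gene effects as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographicModel, SpectraCache, expected_sfs
from .dfe import DFEModel, expected_sfs_under_dfe
from .mk import MKTable
from .sfs import GenotypeMatrix, HET_RAW, MISSING, Spectrum

__all__ = [
    "SimulationConfig",
    "simulate_sfs",
    "simulate_genotypes",
    "simulate_mk_tables",
    "simulate_mtdna",
]

THETA_RATIO_DEFAULT = 2.5  # non-synonymous / synonymous mutation influx


@dataclass
class SimulationConfig:
    """Bundle of generator settings; ``seed`` is mandatory and every draw is
    a pure function of it."""

    seed: int
    model: DemographicModel = field(default_factory=DemographicModel.illustrative_default)
    dfe: DFEModel | None = None
    gamma: float | None = None
    theta_syn: float = 2000.0
    theta_non: float | None = None  # defaults to 2.5 x theta_syn
    sample_sizes: tuple[int, int] = (8, 8)
    n_genes: int = 500
    mean_L_n: float = 1500.0
    mean_L_s: float = 500.0
    effect_sd: float = 0.0
    mk_baseline: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.theta_non is None:
            self.theta_non = THETA_RATIO_DEFAULT * self.theta_syn


def _expected(config: SimulationConfig, cache: SpectraCache | None,
              theta: float, selected: bool) -> Spectrum:
    if selected and config.dfe is not None:
        if cache is None:
            raise ValueError("DFE-based simulation needs a SpectraCache")
        return expected_sfs_under_dfe(cache, config.dfe, theta)
    gamma = config.gamma if selected and config.gamma is not None else 0.0
    return expected_sfs(config.model, gamma, config.sample_sizes, theta=theta)


def simulate_sfs(
    config: SimulationConfig,
    cache: SpectraCache | None = None,
    selected: bool = True,
    fold: bool = False,
) -> Spectrum:
    """Poisson draw around the expected spectrum (DFE-mixture or fixed
    gamma), deterministic given the config seed."""
    theta = config.theta_non if selected else config.theta_syn
    exp = _expected(config, cache, theta, selected)
    if fold and not exp.folded:
        exp = exp.fold()
    rng = np.random.default_rng(config.seed)
    counts = np.zeros_like(exp.counts)
    sel = ~exp.mask
    counts[sel] = rng.poisson(exp.counts[sel])
    return Spectrum(counts, folded=exp.folded, mask=exp.mask.copy())


def simulate_genotypes(
    config: SimulationConfig,
    n_sites: int,
    missingness: float = 0.0,
    low_quality_rate: float = 0.0,
    cache: SpectraCache | None = None,
    selected: bool = False,
) -> GenotypeMatrix:
    """Diploid two-population genotype matrix with site allele counts drawn
    from the normalized expected SFS and alleles assigned by permutation
    within populations; optional missingness and sub-threshold genotype
    qualities exercise the build filters."""
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    n1, n2 = config.sample_sizes
    if n1 % 2 or n2 % 2:
        raise ValueError("diploid simulation needs even chromosome counts")
    exp = _expected(config, cache, config.theta_syn, selected)
    rng = np.random.default_rng(config.seed)
    probs = exp.counts.copy()
    probs[exp.mask] = 0.0
    flat = probs.ravel() / probs.sum()
    picks = rng.choice(len(flat), size=n_sites, p=flat)
    ii, jj = np.unravel_index(picks, probs.shape)

    ind1, ind2 = n1 // 2, n2 // 2
    n_ind = ind1 + ind2
    calls = np.zeros((n_ind, n_sites), dtype=np.int8)
    for s in range(n_sites):
        chrom1 = np.zeros(n1, dtype=np.int8)
        chrom1[: ii[s]] = 1
        rng.shuffle(chrom1)
        chrom2 = np.zeros(n2, dtype=np.int8)
        chrom2[: jj[s]] = 1
        rng.shuffle(chrom2)
        calls[:ind1, s] = chrom1[0::2] + chrom1[1::2]
        calls[ind1:, s] = chrom2[0::2] + chrom2[1::2]

    quality = np.full(calls.shape, 0.99)
    if low_quality_rate > 0:
        low = rng.uniform(size=calls.shape) < low_quality_rate
        quality[low] = rng.uniform(0.3, 0.95, size=int(low.sum()))
    if missingness > 0:
        miss = rng.uniform(size=calls.shape) < missingness
        calls[miss] = MISSING

    individuals = [f"B{i+1}" for i in range(ind1)] + [f"S{i+1}" for i in range(ind2)]
    labels = ["pop1"] * ind1 + ["pop2"] * ind2
    site_ids = [f"chr1:{1000 + 10 * s}" for s in range(n_sites)]
    return GenotypeMatrix(individuals, labels, calls, site_ids,
                          genotype_quality=quality, ploidy=2)


def simulate_mk_tables(config: SimulationConfig,
                       spiked: dict[str, float] | None = None):
    """MK tables drawn Poisson from the log-linear random-effects structure.

    Gene-level effects: replacement main effect u_g ~ N(0, effect_sd^2) and
    selection effect v_g ~ N(0, effect_sd^2), optionally overridden per gene
    via ``spiked`` {gene_id: v}.  Returns (tables, truth DataFrame with the
    generating effects and sign labels).
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(config.seed)
    base = {"b0": -6.0, "bR": -0.7, "bF": 1.8, "bRF": 0.0}
    base.update(config.mk_baseline)
    G = config.n_genes
    L_n = np.maximum(rng.poisson(config.mean_L_n, G), 90)
    L_s = np.maximum(rng.poisson(config.mean_L_s, G), 30)
    u = rng.normal(0.0, config.effect_sd, G) if config.effect_sd > 0 else np.zeros(G)
    v = rng.normal(0.0, config.effect_sd, G) if config.effect_sd > 0 else np.zeros(G)
    ids = [f"gene{g:04d}" for g in range(G)]
    if spiked:
        for gid, val in spiked.items():
            v[ids.index(gid)] = val
    lam_ps = np.exp(base["b0"] + np.log(L_s))
    lam_pn = np.exp(base["b0"] + base["bR"] + u + np.log(L_n))
    lam_ds = np.exp(base["b0"] + base["bF"] + np.log(L_s))
    lam_dn = np.exp(base["b0"] + base["bR"] + base["bF"] + base["bRF"] + u + v + np.log(L_n))
    tables = []
    for g in range(G):
        tables.append(
            MKTable(
                gene_id=ids[g],
                D_n=int(rng.poisson(lam_dn[g])),
                D_s=int(rng.poisson(lam_ds[g])),
                P_n=int(rng.poisson(lam_pn[g])),
                P_s=int(rng.poisson(lam_ps[g])),
                L_n=int(L_n[g]),
                L_s=int(L_s[g]),
            )
        )
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "u": u,
            "v": v,
            "label": np.where(v > 0, "positive", np.where(v < 0, "negative", "neutral")),
        }
    )
    return tables, truth


def _coalescent_tree(n: int, rng) -> list[tuple[list[int], float]]:
    """Kingman coalescent: list of (leaf set below branch, branch length)."""
    branches: list[tuple[list[int], float]] = []
    t = 0.0
    active = [([i], 0.0) for i in range(n)]  # (leaf set, height at bottom)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(min(i, j))], active[int(max(i, j))]
        branches.append((a[0], t - a[1]))
        branches.append((b[0], t - b[1]))
        merged = (sorted(a[0] + b[0]), t)
        active = [x for idx, x in enumerate(active) if idx not in (int(i), int(j))]
        active.append(merged)
    return branches


def simulate_mtdna(
    n_samples: int,
    n_sites: int,
    density: float,
    het_rate: float = 0.0,
    seed: int = 0,
    n_clades: int = 1,
    clade_depth: float = 5.0,
) -> GenotypeMatrix:
    """Haploid haplotypes on a random coalescent genealogy with Poisson
    mutations targeting one SNP per ``1/density`` callable bases; spurious
    heterozygous calls injected at ``het_rate`` per segregating site.

    ``n_clades=2`` joins two subtrees by a long stem (``clade_depth`` in
    coalescent units) to create IBS-testable structure.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if n_clades == 2:
        half = n_samples // 2
        branches = []
        for leaves, offset in (
            (list(range(half)), 0),
            (list(range(half, n_samples)), half),
        ):
            sub = _coalescent_tree(len(leaves), rng)
            branches.extend(([l + offset for l in ls], ln) for ls, ln in sub)
        branches.append((list(range(half)), clade_depth))
        branches.append((list(range(half, n_samples)), clade_depth))
    else:
        branches = _coalescent_tree(n_samples, rng)

    n_snps = rng.poisson(density * n_sites)
    lengths = np.array([ln for _, ln in branches])
    probs = lengths / lengths.sum()
    calls = np.zeros((n_samples, n_snps), dtype=np.int8)
    for s in range(n_snps):
        b = rng.choice(len(branches), p=probs)
        calls[branches[b][0], s] = 1
    # keep only sites segregating among the samples
    seg = (calls.sum(axis=0) > 0) & (calls.sum(axis=0) < n_samples)
    calls = calls[:, seg]
    if het_rate > 0 and calls.shape[1]:
        flagged = rng.uniform(size=calls.shape[1]) < het_rate
        for s in np.flatnonzero(flagged):
            calls[rng.integers(n_samples), s] = HET_RAW
    ids = [f"mt{i+1}" for i in range(n_samples)]
    labels = (["cladeA"] * (n_samples // 2) + ["cladeB"] * (n_samples - n_samples // 2)
              if n_clades == 2 else ["pop"] * n_samples)
    site_ids = [f"mt:{i+1}" for i in range(calls.shape[1])]
    return GenotypeMatrix(ids, labels, calls, site_ids, ploidy=1)
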