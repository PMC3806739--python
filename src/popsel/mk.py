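"""McDonald-Kreitman statistics and a Bayesian Poisson random-effects
classifier of genes into negative / neutral / positive selection.

Each gene contributes four Poisson counts (synonymous / non-synonymous x
fixed / polymorphic) with log-means built from fixed effects (replacement
indicator R, fixed-vs-polymorphic indicator F, their interaction, and
log-length offsets) plus zero-mean gene-level random effects on the
replacement main effect and on the replacement x fixed interaction.  The
latter is the per-gene selection effect: a gene is called positive when the
95% credible interval of that effect lies above 0, negative when below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "MKTable",
    "GeneSelectionEstimate",
    "MCMCSettings",
    "per_site_rate",
    "ns_s_rate_ratio",
    "mk_chi2",
    "filter_genes",
    "fit_random_effects_mk",
    "classify_genes",
    "read_mk_tables",
    "write_mk_tables",
]


@dataclass
class MKTable:
    """Per-gene counts of fixed differences and polymorphisms by functional
    class, with aligned lengths in bases."""

    gene_id: str
    D_n: int
    D_s: int
    P_n: int
    P_s: int
    L_n: int = 0
    L_s: int = 0

    def __post_init__(self) -> None:
        for name in ("D_n", "D_s", "P_n", "P_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def read_mk_tables(path) -> list[MKTable]:
    df = pd.read_csv(path, sep="\t")
    return [
        MKTable(str(r.gene_id), int(r.D_n), int(r.D_s), int(r.P_n),
                int(r.P_s), int(r.L_n), int(r.L_s))
        for r in df.itertuples()
    ]


def write_mk_tables(tables: list[MKTable], path) -> None:
    pd.DataFrame(
        [(t.gene_id, t.D_n, t.D_s, t.P_n, t.P_s, t.L_n, t.L_s) for t in tables],
        columns=["gene_id", "D_n", "D_s", "P_n", "P_s", "L_n", "L_s"],
    ).to_csv(path, sep="\t", index=False)


def per_site_rate(count: int, length_bases: int) -> float:
    """Percent per-site rate: 100 * count / length."""
    if length_bases <= 0:
        raise ValueError("length must be > 0")
    return 100.0 * count / length_bases


def ns_s_rate_ratio(table: MKTable, column: str) -> float:
    """Percent ratio of non-synonymous to synonymous per-site rates for the
    fixed or polymorphic column."""
    if column == "fixed":
        cn, cs = table.D_n, table.D_s
    elif column == "polymorphic":
        cn, cs = table.P_n, table.P_s
    else:
        raise ValueError("column must be 'fixed' or 'polymorphic'")
    rate_s = per_site_rate(cs, table.L_s)
    if rate_s == 0:
        raise ValueError("zero synonymous rate")
    return 100.0 * per_site_rate(cn, table.L_n) / rate_s


def mk_chi2(table: MKTable, continuity_correction: bool = True):
    """Pearson chi-square of independence on the 2x2 (syn/non-syn by
    fixed/polymorphic) counts; Yates-corrected by default (the correction is
    clamped at zero difference).  Returns (statistic, p_value)."""
    obs = np.array([[table.D_s, table.P_s], [table.D_n, table.P_n]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in MK table")
    res = chi2_contingency(obs, correction=continuity_correction)
    return float(res[0]), float(res[1])


def filter_genes(tables: list[MKTable], rule: str = "max") -> list[MKTable]:
    """Keep genes with at least two non-synonymous mutations in either the
    fixed or the polymorphic column (``rule="max"``: max(D_n, P_n) >= 2;
    ``rule="sum"``: D_n + P_n >= 2)."""
    if rule == "max":
        return [t for t in tables if max(t.D_n, t.P_n) >= 2]
    if rule == "sum":
        return [t for t in tables if t.D_n + t.P_n >= 2]
    raise ValueError("rule must be 'max' or 'sum'")


@dataclass
class GeneSelectionEstimate:
    gene_id: str
    selection_effect: float
    ci_low: float
    ci_high: float
    classification: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.selection_effect <= self.ci_high:
            raise ValueError("credible interval must contain the point estimate")


@dataclass
class MCMCSettings:
    n_chains: int = 4
    n_warmup: int = 1500
    n_samples: int = 1500
    rhat_threshold: float = 1.1
    sigma_prior_sd: float = 1.0
    check_convergence: bool = True


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor; chains: (n_chain, n_draw)."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


class _MKChain:
    """Gibbs/Metropolis sampler for the Poisson random-effects model.

    The four column log-rates (the invertible recoding of intercept,
    replacement, fixed and interaction fixed effects) get exact conjugate
    gamma draws under a weak Gamma(0.5, 0.001) prior on each rate; the
    gene-level effects are non-centered with vectorized per-gene MH; the
    half-normal scales move on the log scale by MH.
    """

    PRIOR_SHAPE = 0.5
    PRIOR_RATE = 1e-3

    def __init__(self, counts, offsets, settings, rng):
        # counts: (G, 4) columns [P_s, P_n, D_s, D_n]; offsets: (G, 2) log L_s, log L_n
        self.y = counts
        self.Ls = np.exp(offsets[:, 0])
        self.Ln = np.exp(offsets[:, 1])
        self.logLn = offsets[:, 1]
        self.cfg = settings
        self.rng = rng
        G = counts.shape[0]
        self.G = G
        self.S = counts.sum(axis=0)  # column totals (sufficient statistics)
        tot = self.S + 0.5
        self.lam = np.array([
            tot[0] / self.Ls.sum(),
            tot[1] / self.Ln.sum(),
            tot[2] / self.Ls.sum(),
            tot[3] / self.Ln.sum(),
        ])
        self.zu = rng.normal(0, 0.1, G)
        self.zv = rng.normal(0, 0.1, G)
        self.log_su = np.log(0.3)
        self.log_sv = np.log(0.3)
        self.step_z = np.full(G, 0.5)
        self.step_s = {"log_su": 0.3, "log_sv": 0.3}
        self.step_iw = {"log_su": 0.3, "log_sv": 0.3}

    @property
    def beta(self):
        """(b0, bR, bF, bRF) recovered from the column log-rates."""
        l = np.log(self.lam)
        return np.array([l[0], l[1] - l[0], l[2] - l[0], l[3] - l[2] - l[1] + l[0]])

    def _gene_loglik(self, lam_pn, lam_dn, u, v):
        l1 = np.log(lam_pn) + u + self.logLn
        l3 = np.log(lam_dn) + u + v + self.logLn
        # cap keeps wild proposals finite (they are rejected anyway)
        e1 = np.exp(np.minimum(l1, 500.0))
        e3 = np.exp(np.minimum(l3, 500.0))
        return (self.y[:, 1] * l1 - e1) + (self.y[:, 3] * l3 - e3)

    def step(self, adapt: bool):
        rng = self.rng
        su, sv = np.exp(self.log_su), np.exp(self.log_sv)
        u, v = su * self.zu, sv * self.zv
        eu = np.exp(u)
        euv = np.exp(u + v)

        # exact gamma draws for the four column rates
        a, b = self.PRIOR_SHAPE, self.PRIOR_RATE
        exposures = np.array([
            self.Ls.sum(),
            (self.Ln * eu).sum(),
            self.Ls.sum(),
            (self.Ln * euv).sum(),
        ])
        self.lam = rng.gamma(self.S + a, 1.0 / (exposures + b))

        # gene-level z blocks (vectorized independent MH)
        for which in ("u", "v"):
            z = self.zu if which == "u" else self.zv
            prop_z = z + rng.normal(0, self.step_z)
            if which == "u":
                cur = self._gene_loglik(self.lam[1], self.lam[3], su * z, sv * self.zv)
                new = self._gene_loglik(self.lam[1], self.lam[3], su * prop_z, sv * self.zv)
            else:
                cur = self._gene_loglik(self.lam[1], self.lam[3], su * self.zu, sv * z)
                new = self._gene_loglik(self.lam[1], self.lam[3], su * self.zu, sv * prop_z)
            logr = (new - cur) - 0.5 * (prop_z**2 - z**2)
            acc = np.log(rng.uniform(size=self.G)) < logr
            z[acc] = prop_z[acc]
            if adapt:
                self.step_z *= np.exp(0.05 * (acc - 0.44))

        # scale parameters (non-centered: likelihood depends on sigma * z)
        for name in ("log_su", "log_sv"):
            cur_ls = getattr(self, name)
            prop_ls = cur_ls + rng.normal(0, self.step_s[name])
            su_c, sv_c = np.exp(self.log_su), np.exp(self.log_sv)
            su_p, sv_p = su_c, sv_c
            if name == "log_su":
                su_p = np.exp(prop_ls)
            else:
                sv_p = np.exp(prop_ls)
            cur = self._gene_loglik(self.lam[1], self.lam[3], su_c * self.zu, sv_c * self.zv).sum()
            new = self._gene_loglik(self.lam[1], self.lam[3], su_p * self.zu, sv_p * self.zv).sum()
            # half-normal prior on sigma with log-scale Jacobian
            pr = (-0.5 * (np.exp(2 * prop_ls) - np.exp(2 * cur_ls)) / self.cfg.sigma_prior_sd**2
                  + (prop_ls - cur_ls))
            ok = np.log(rng.uniform()) < new - cur + pr
            if ok:
                setattr(self, name, prop_ls)
            if adapt:
                self.step_s[name] *= np.exp(0.05 * (float(ok) - 0.3))

        # interweaved (sufficiency) rescale: move sigma with u = sigma*z held
        # fixed, which mixes sigma when the per-gene likelihoods are strong
        for name, zname in (("log_su", "zu"), ("log_sv", "zv")):
            cur_ls = getattr(self, name)
            z = getattr(self, zname)
            eps = rng.normal(0, self.step_iw[name])
            prop_ls = cur_ls + eps
            prop_z = z * np.exp(-eps)
            dprior_z = -0.5 * (prop_z @ prop_z - z @ z)
            dprior_s = (-0.5 * (np.exp(2 * prop_ls) - np.exp(2 * cur_ls))
                        / self.cfg.sigma_prior_sd**2 + eps)
            jac = -self.G * eps
            ok = np.log(rng.uniform()) < dprior_z + dprior_s + jac
            if ok:
                setattr(self, name, prop_ls)
                setattr(self, zname, prop_z)
            if adapt:
                self.step_iw[name] *= np.exp(0.05 * (float(ok) - 0.3))


def fit_random_effects_mk(
    tables: list[MKTable],
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
) -> list[GeneSelectionEstimate]:
    """Posterior summaries of the per-gene selection effect (the gene-level
    replacement x fixed random effect), classified by the 95% credible
    interval; deterministic given ``seed`` and settings."""
    if len(tables) < 20:
        raise ValueError("random-effects model needs >= 20 genes for shrinkage")
    cfg = mcmc or MCMCSettings()
    counts = np.array([[t.P_s, t.P_n, t.D_s, t.D_n] for t in tables], dtype=float)
    lengths = np.array([[max(t.L_s, 1), max(t.L_n, 1)] for t in tables], dtype=float)
    offsets = np.log(lengths)

    G = len(tables)
    draws_v = []
    scalar_draws = {k: [] for k in ("b0", "bR", "bF", "bRF", "sigma_u", "sigma_v")}
    for c in range(cfg.n_chains):
        rng = np.random.default_rng([seed, c])
        chain = _MKChain(counts, offsets, cfg, rng)
        for it in range(cfg.n_warmup):
            chain.step(adapt=True)
        keep_v = np.empty((cfg.n_samples, G))
        keep_scalar = {k: np.empty(cfg.n_samples) for k in scalar_draws}
        for it in range(cfg.n_samples):
            chain.step(adapt=False)
            keep_v[it] = np.exp(chain.log_sv) * chain.zv
            keep_scalar["b0"][it], keep_scalar["bR"][it] = chain.beta[0], chain.beta[1]
            keep_scalar["bF"][it], keep_scalar["bRF"][it] = chain.beta[2], chain.beta[3]
            keep_scalar["sigma_u"][it] = np.exp(chain.log_su)
            keep_scalar["sigma_v"][it] = np.exp(chain.log_sv)
        draws_v.append(keep_v)
        for k in scalar_draws:
            scalar_draws[k].append(keep_scalar[k])

    if cfg.check_convergence:
        # gate on the reported quantities: fixed effects and every gene's
        # selection effect (scale hyperparameters pinned at the zero
        # boundary mix slowly without affecting the classifications)
        diagnostics = {
            k: _split_rhat(np.stack(v))
            for k, v in scalar_draws.items()
            if k in ("b0", "bR", "bF", "bRF")
        }
        v_stack = np.stack(draws_v)  # (chain, draw, G)
        gene_rhats = np.array([_split_rhat(v_stack[:, :, g]) for g in range(G)])
        diagnostics["max_gene_effect"] = float(gene_rhats.max())
        bad = {k: r for k, r in diagnostics.items() if r > cfg.rhat_threshold}
        if bad:
            raise RuntimeError(f"MCMC did not converge: split-Rhat {bad}")

    allv = np.concatenate(draws_v, axis=0)  # (chains*samples, G)
    means = allv.mean(axis=0)
    lo = np.quantile(allv, 0.025, axis=0)
    hi = np.quantile(allv, 0.975, axis=0)
    out = []
    for g, t in enumerate(tables):
        if lo[g] > 0:
            cls = "positive"
        elif hi[g] < 0:
            cls = "negative"
        else:
            cls = "neutral"
        out.append(
            GeneSelectionEstimate(
                gene_id=t.gene_id,
                selection_effect=float(means[g]),
                ci_low=float(lo[g]),
                ci_high=float(hi[g]),
                classification=cls,
            )
        )
    return out


def classify_genes(estimates: list[GeneSelectionEstimate]) -> dict[str, int]:
    """Counts of genes per selection class."""
    out = {"negative": 0, "neutral": 0, "positive": 0}
    for e in estimates:
        out[e.classification] += 1
    return out
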