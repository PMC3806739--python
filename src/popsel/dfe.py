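"""Mixture distributions of scaled selection coefficients fitted to folded
non-synonymous spectra by Poisson likelihood.

A DFE is discretized onto a :class:`~popsel.demography.SelectionGrid` by
integrating its density over the Voronoi cell of each grid point in
log|gamma| space; continuous mass beyond the grid minimum (gamma = -2000)
is lumped into a lethal class that contributes zero polymorphism.  Point
masses are spread log-linearly between the two bracketing grid points so
the implied expected spectrum is continuous in the location parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import expon as expon_dist, gamma as gamma_dist, norm as norm_dist

from .demography import GAMMA_LETHAL, SelectionGrid, SpectraCache
from .sfs import Spectrum

__all__ = [
    "DFEModel",
    "DFEWeights",
    "FitResult",
    "dfe_weights",
    "expected_sfs_under_dfe",
    "poisson_loglik",
    "fit_dfe",
    "class_masses",
    "bootstrap_ci",
]

FAMILIES = ("point_lethal", "expon_lethal", "norm_lethal", "gamma")


@dataclass
class DFEModel:
    """Parametric mixture over scaled selection coefficients gamma.

    families and parameters:

    - ``point_lethal``: ``p_point`` at ``gamma_point`` (< 0), mass
      ``1 - p_point`` lethal;
    - ``expon_lethal``: |gamma| ~ Exponential(``mean``) on the negative
      branch, plus ``p_lethal``;
    - ``norm_lethal``: gamma ~ Normal(``mean``, ``sd``), plus ``p_lethal``;
    - ``gamma``: |gamma| ~ Gamma(``shape``, ``scale``) on the negative
      branch.
    """

    family: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        required = {
            "point_lethal": {"p_point", "gamma_point"},
            "expon_lethal": {"mean", "p_lethal"},
            "norm_lethal": {"mean", "sd", "p_lethal"},
            "gamma": {"shape", "scale"},
        }[self.family]
        if set(p) != required:
            raise ValueError(f"{self.family} needs params {sorted(required)}")
        for key in ("p_point", "p_lethal"):
            if key in p and not 0.0 <= p[key] <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1]")
        for key in ("sd", "scale", "shape", "mean"):
            if key in p and self.family != "norm_lethal" and p[key] <= 0:
                raise ValueError(f"{key} must be > 0")
        if self.family == "norm_lethal" and p["sd"] <= 0:
            raise ValueError("sd must be > 0")
        if self.family == "point_lethal" and p["gamma_point"] >= 0:
            raise ValueError("gamma_point must be negative")

    def lethal_mass(self) -> float:
        if self.family == "point_lethal":
            return 1.0 - self.params["p_point"]
        return self.params.get("p_lethal", 0.0)

    def cdf_gamma(self, x: float) -> float:
        """P(gamma <= x) of the continuous component (excludes point/lethal
        masses)."""
        p = self.params
        if self.family == "point_lethal":
            return 0.0
        if self.family == "expon_lethal":
            # gamma = -|g|, |g| ~ Expon(mean):  P(gamma <= x) = P(|g| >= -x)
            if x >= 0:
                return 1.0
            return float(expon_dist.sf(-x, scale=p["mean"]))
        if self.family == "norm_lethal":
            return float(norm_dist.cdf(x, loc=p["mean"], scale=p["sd"]))
        if x >= 0:
            return 1.0
        return float(gamma_dist.sf(-x, a=p["shape"], scale=p["scale"]))

    def continuous_mass(self) -> float:
        return 1.0 - self.lethal_mass()


@dataclass
class DFEWeights:
    """Discretized DFE: per-grid-point masses plus a lethal lump."""

    grid: SelectionGrid
    grid_weights: np.ndarray
    lethal_mass: float

    def total(self) -> float:
        return float(self.grid_weights.sum() + self.lethal_mass)


def _cell_edges(values: np.ndarray) -> np.ndarray:
    """Voronoi cell edges in log-magnitude space for a same-sign branch of
    grid values, returned on the gamma scale in the branch's sort order."""
    lg = np.log(np.abs(values))
    mid = (lg[:-1] + lg[1:]) / 2.0
    sign = np.sign(values[0])
    return sign * np.exp(mid)


def dfe_weights(dfe: DFEModel, grid: SelectionGrid) -> DFEWeights:
    """Probability mass per grid point (Voronoi-cell integrals of the
    continuous density; log-linear spreading for point masses); continuous
    mass below gamma = -2000 joins the lethal class; weights + lethal sum
    to 1."""
    g = grid.gamma_values
    w = np.zeros(len(g))
    lethal = dfe.lethal_mass()

    if dfe.family == "point_lethal":
        gp = dfe.params["gamma_point"]
        pp = dfe.params["p_point"]
        if gp <= GAMMA_LETHAL:
            lethal += pp
        else:
            neg = np.flatnonzero(g < 0)
            lg = np.log(-g[neg])  # decreasing magnitude along the grid
            t = np.log(-gp)
            if t >= lg[0]:
                w[neg[0]] += pp
            elif t <= lg[-1]:
                w[neg[-1]] += pp
            else:
                hi = int(np.searchsorted(-lg, -t))  # first idx with lg < t
                l0, l1 = lg[hi - 1], lg[hi]
                frac = (t - l0) / (l1 - l0)
                w[neg[hi - 1]] += pp * (1.0 - frac)
                w[neg[hi]] += pp * frac
        return DFEWeights(grid, w, lethal)

    scale = dfe.continuous_mass()
    neg = np.flatnonzero(g < 0)
    pos = np.flatnonzero(g > 0)
    zero = np.flatnonzero(g == 0)

    if len(neg):
        # cells bounded by log-magnitude midpoints; anything below the grid
        # minimum is lethal, the innermost cell closes at 0
        lethal += scale * dfe.cdf_gamma(g[neg][0])
        uppers = np.concatenate([_cell_edges(g[neg]), [0.0]])
        prev = g[neg][0]
        for idx, up in zip(neg, uppers):
            w[idx] = scale * (dfe.cdf_gamma(up) - dfe.cdf_gamma(prev))
            prev = up

    if len(pos):
        # innermost cell opens at 0, the outermost extends to +inf
        pedges = _cell_edges(g[pos])
        lowers = np.concatenate([[0.0], pedges])
        uppers = np.concatenate([pedges, [np.inf]])
        for idx, lo, up in zip(pos, lowers, uppers):
            w[idx] = scale * (dfe.cdf_gamma(up) - dfe.cdf_gamma(lo))
    elif len(zero):
        # no positive branch: everything at or above 0 lands on gamma = 0
        w[zero[0]] += scale * (1.0 - dfe.cdf_gamma(0.0))

    return DFEWeights(grid, w, lethal)


def expected_sfs_under_dfe(cache: SpectraCache, dfe: DFEModel,
                           theta_non: float) -> Spectrum:
    """theta_non * sum_k weight_k * cached unit-theta spectrum at gamma_k;
    the lethal mass contributes zero polymorphism."""
    weights = dfe_weights(dfe, cache.grid)
    stack = cache.stack()
    counts = theta_non * np.tensordot(weights.grid_weights, stack, axes=(0, 0))
    template = cache.spectra[0]
    return Spectrum(counts, folded=template.folded, mask=template.mask.copy())


def poisson_loglik(model: Spectrum, data: Spectrum) -> float:
    """Sum over unmasked entries of -m + d*ln(m) - ln(d!); -inf where the
    model is 0 but the data are not."""
    if model.counts.shape != data.counts.shape:
        raise ValueError("shape mismatch")
    if model.folded != data.folded or np.any(model.mask != data.mask):
        raise ValueError("folding/mask mismatch")
    m = model.counts[~model.mask]
    d = data.counts[~data.mask]
    if np.any((m == 0) & (d > 0)):
        return -np.inf
    ok = m > 0
    return float(np.sum(-m[ok] + d[ok] * np.log(m[ok]) - gammaln(d[ok] + 1.0)))


@dataclass
class FitResult:
    family: str
    params: dict[str, float]
    loglik: float
    theta_non: float
    n_restarts: int
    converged: bool
    restart_logliks: list[float] = field(default_factory=list)
    bootstrap_intervals: dict[str, tuple[float, float]] | None = None

    def dfe(self) -> DFEModel:
        return DFEModel(self.family, dict(self.params))

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "params": self.params,
            "loglik": self.loglik,
            "theta_non": self.theta_non,
            "converged": self.converged,
        }
        if self.bootstrap_intervals is not None:
            out["bootstrap_intervals"] = {
                k: list(v) for k, v in self.bootstrap_intervals.items()
            }
        return out

    def report(self) -> str:
        lines = [f"family\t{self.family}",
                 f"loglik\t{self.loglik:.6f}",
                 f"theta_non\t{self.theta_non:.6g}"]
        for k, v in self.params.items():
            lines.append(f"{k}\t{v:.6g}")
        if self.bootstrap_intervals:
            for k, (lo, hi) in self.bootstrap_intervals.items():
                lines.append(f"ci95_{k}\t{lo:.6g}\t{hi:.6g}")
        return "\n".join(lines) + "\n"


# parameter transforms: optimize in an unconstrained-ish box per family
_BOUNDS = {
    "point_lethal": [("p_point", 0.0, 1.0, "lin"),
                     ("gamma_point", 1e-6, 2000.0, "log_neg")],
    "expon_lethal": [("mean", 1e-4, 1e4, "log"),
                     ("p_lethal", 0.0, 1.0, "lin")],
    "norm_lethal": [("mean", -2000.0, 100.0, "lin"),
                    ("sd", 1e-3, 1e4, "log"),
                    ("p_lethal", 0.0, 1.0, "lin")],
    "gamma": [("shape", 0.01, 100.0, "log"),
              ("scale", 1e-3, 1e6, "log")],
}


def _to_internal(name_value, lo, hi, kind):
    if kind == "lin":
        return name_value
    if kind == "log":
        return np.log(name_value)
    return np.log(-name_value)  # log_neg


def _from_internal(x, kind):
    if kind == "lin":
        return x
    if kind == "log":
        return np.exp(x)
    return -np.exp(x)


def _internal_bounds(family):
    out = []
    for _, lo, hi, kind in _BOUNDS[family]:
        if kind == "lin":
            out.append((lo, hi))
        else:
            out.append((np.log(lo), np.log(hi)))
    return out


def _params_from_vector(family, x):
    return {
        name: float(_from_internal(xi, kind))
        for (name, _, _, kind), xi in zip(_BOUNDS[family], x)
    }


def fit_dfe(
    data: Spectrum,
    cache: SpectraCache,
    family: str,
    theta_non: float | str = "free",
    n_restarts: int = 5,
    seed: int = 0,
    fold_cache: bool = True,
) -> FitResult:
    """Maximize the Poisson likelihood over the family's parameters by
    bounded multi-start L-BFGS-B (deterministic given ``seed``).

    ``theta_non`` is either a fixed mutation-influx rate (the paper-style
    2.5 x theta_syn constraint) or ``"free"`` to profile it analytically at
    every evaluation (recovery-study mode; note lethal mass and theta are
    then confounded for point_lethal).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    stack = cache.stack()
    template = cache.spectra[0]
    if fold_cache and data.folded and not template.folded:
        folded = [s.fold() for s in cache.spectra]
        stack = np.stack([s.counts for s in folded])
        template = folded[0]
    if template.counts.shape != data.counts.shape or template.folded != data.folded:
        raise ValueError("cache spectra incompatible with data")
    mask = template.mask | data.mask
    dvec = data.counts[~mask]
    svec = stack[:, ~mask] if stack.ndim == 2 else stack.reshape(len(stack), -1)[:, ~mask.ravel()]
    lgamm = gammaln(dvec + 1.0).sum()
    free_theta = isinstance(theta_non, str)

    def negll(x):
        params = _params_from_vector(family, x)
        try:
            dfe = DFEModel(family, params)
        except ValueError:
            return 1e12
        w = dfe_weights(dfe, cache.grid)
        unit = w.grid_weights @ svec
        if free_theta:
            tot_unit = unit.sum()
            if tot_unit <= 0:
                return 1e12
            th = dvec.sum() / tot_unit
        else:
            th = theta_non
        m = th * unit
        if np.any((m <= 0) & (dvec > 0)):
            return 1e12
        ok = m > 0
        return float(-(np.sum(-m[ok] + dvec[ok] * np.log(m[ok])) - lgamm))

    rng = np.random.default_rng(seed)
    bounds = _internal_bounds(family)
    best = None
    logliks = []
    for _ in range(max(n_restarts, 1)):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        logliks.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {n_restarts} restarts failed: {logliks}")
    params = _params_from_vector(family, best.x)
    dfe = DFEModel(family, params)
    w = dfe_weights(dfe, cache.grid)
    unit = w.grid_weights @ svec
    theta_hat = (dvec.sum() / unit.sum()) if free_theta else float(theta_non)
    return FitResult(
        family=family,
        params=params,
        loglik=-float(best.fun),
        theta_non=float(theta_hat),
        n_restarts=n_restarts,
        converged=bool(best.success),
        restart_logliks=logliks,
    )


# s-bin boundaries of the class-mass table (selection coefficient scale)
_S_EDGES = (-1e-2, -1e-3, -1e-4)


def class_masses(dfe: DFEModel, N_anc: float) -> np.ndarray:
    """DFE mass (percent) in the four s-bins (s = gamma / (2*N_anc)):
    s < -1e-2, -1e-2 < s < -1e-3, -1e-3 < s < -1e-4, s > -1e-4.  Lethal
    mass counts as s < -1e-2."""
    if N_anc <= 0:
        raise ValueError("N_anc must be > 0")
    g_edges = [2.0 * N_anc * s for s in _S_EDGES]
    masses = np.zeros(4)
    masses[0] += dfe.lethal_mass()
    if dfe.family == "point_lethal":
        gp = dfe.params["gamma_point"]
        p = dfe.params["p_point"]
        if gp < g_edges[0]:
            masses[0] += p
        elif gp < g_edges[1]:
            masses[1] += p
        elif gp < g_edges[2]:
            masses[2] += p
        else:
            masses[3] += p
    else:
        scale = dfe.continuous_mass()
        cdf = dfe.cdf_gamma
        masses[0] += scale * cdf(g_edges[0])
        masses[1] += scale * (cdf(g_edges[1]) - cdf(g_edges[0]))
        masses[2] += scale * (cdf(g_edges[2]) - cdf(g_edges[1]))
        masses[3] += scale * (1.0 - cdf(g_edges[2]))
    return 100.0 * masses


def bootstrap_ci(
    data: Spectrum,
    cache: SpectraCache,
    family: str,
    n_boot: int = 100,
    seed: int = 0,
    theta_non: float | str = "free",
    n_restarts: int = 3,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile intervals from SNP-level multinomial resampling of the
    spectrum (sites are the linkage-conservative resampling unit)."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    sel = ~data.mask
    probs = data.counts[sel]
    total = int(round(probs.sum()))
    if total <= 0:
        raise ValueError("cannot resample an empty spectrum")
    probs = probs / probs.sum()
    draws: dict[str, list[float]] = {}
    failures = 0
    for b in range(n_boot):
        resampled = rng.multinomial(total, probs).astype(float)
        counts = np.zeros_like(data.counts)
        counts[sel] = resampled
        boot = Spectrum(counts, folded=data.folded, mask=data.mask.copy())
        try:
            # fixed fit seed: identical resamples must give identical refits
            fit = fit_dfe(boot, cache, family, theta_non=theta_non,
                          n_restarts=n_restarts, seed=seed)
        except RuntimeError:
            failures += 1
            continue
        for k, v in fit.params.items():
            draws.setdefault(k, []).append(v)
    if failures > 0.1 * n_boot:
        import warnings

        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    return {
        k: (float(np.quantile(v, alpha)), float(np.quantile(v, 1.0 - alpha)))
        for k, v in draws.items()
    }
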