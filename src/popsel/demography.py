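"""Expected site-frequency spectra under a two-population
isolation-with-migration demography with genic selection.

The forward machinery is a finite-volume discretization of the
Wright-Fisher diffusion on the [0,1] allele-frequency scale, with time in
units of 2*N_anc generations, relative sizes ``nu`` interpolated
exponentially over the divergence epoch, scaled migration ``m = 2*N_anc*
(per-generation fraction)`` and scaled selection ``gamma = 2*N_anc*s``
(genic, h = 1/2), so the advection coefficient is ``gamma*x*(1-x)``.
Equilibria are obtained by a direct steady-state solve; the divergence
epoch is integrated by implicit operator splitting (ADI).  A discrete
Wright-Fisher transition-matrix oracle is provided for validation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_banded
from scipy.special import comb, gammaln
from scipy.stats import binom as binom_dist, hypergeom

from .sfs import Spectrum

__all__ = [
    "DemographicModel",
    "SelectionGrid",
    "SpectraCache",
    "equilibrium_selected_sfs",
    "expected_sfs",
    "wf_oracle_sfs",
    "build_cache",
    "build_equilibrium_cache",
]

#: gamma below which a mutation class is treated as lethal (zero polymorphism)
GAMMA_LETHAL = -2000.0


@dataclass
class DemographicModel:
    """Isolation-with-migration model with exponential size change.

    Times are in units of 2*N_anc generations; sizes are relative to N_anc.
    ``nu*_0`` are the relative sizes at the split, ``nu*`` at present.
    """

    N_anc: float
    T_split: float
    nu1_0: float
    nu1: float
    nu2_0: float
    nu2: float
    m12: float
    m21: float
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in ("full", "no_migration", "no_growth"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "no_migration":
            self.m12 = self.m21 = 0.0
        if self.variant == "no_growth":
            self.nu1_0 = self.nu1
            self.nu2_0 = self.nu2
        for name in ("N_anc", "T_split", "nu1_0", "nu1", "nu2_0", "nu2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be >= 0")

    def nu_trajectories(self):
        """Callables nu1(t), nu2(t) for t in [0, T_split] (exponential)."""
        T = self.T_split

        def _traj(nu0, nu1):
            r = np.log(nu1 / nu0) / T
            return lambda t: nu0 * np.exp(r * t)

        return _traj(self.nu1_0, self.nu1), _traj(self.nu2_0, self.nu2)

    @classmethod
    def illustrative_default(cls) -> "DemographicModel":
        """A non-canonical two-population configuration for synthetic work:
        a ~6x expansion in population 2 and a modest decline in population 1
        after a recent split.  These are NOT fitted values from any study."""
        return cls(
            N_anc=17000.0,
            T_split=0.15,
            nu1_0=1.0,
            nu1=0.6,
            nu2_0=1.0,
            nu2=6.0,
            m12=0.5,
            m21=0.5,
        )


@dataclass
class SelectionGrid:
    """Ordered grid of scaled selection coefficients gamma = 2*N_anc*s."""

    gamma_values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_values, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("gamma grid must be strictly increasing")
        self.gamma_values = g

    def __len__(self) -> int:
        return len(self.gamma_values)

    @classmethod
    def default(cls) -> "SelectionGrid":
        """2000 log-uniform negative values on [-2000, -1e-6], gamma = 0, and
        500 log-uniform positive values on [1e-6, 100] (2501 points)."""
        return cls.build(2000, 500)

    @classmethod
    def reduced(cls, n_neg: int = 47, n_pos: int = 12) -> "SelectionGrid":
        """Desk-scale grid (default 60 points) with the same bounds."""
        return cls.build(n_neg, n_pos)

    @classmethod
    def build(cls, n_neg: int, n_pos: int, neg_min: float = -2000.0,
              neg_max: float = -1e-6, pos_min: float = 1e-6,
              pos_max: float = 100.0) -> "SelectionGrid":
        neg = -np.geomspace(-neg_min, -neg_max, n_neg)
        pos = np.geomspace(pos_min, pos_max, n_pos)
        return cls(np.concatenate([neg, [0.0], pos]))


# ---------------------------------------------------------------------------
# closed-form equilibrium (Poisson random field)


def _sel_density(q: float, gamma: float) -> float:
    """Equilibrium density of segregating frequency under genic selection:
    f(q) = (1 - exp(-2*gamma*(1-q))) / ((1 - exp(-2*gamma)) * q * (1-q)),
    evaluated stably for large |gamma|; 1/q in the neutral limit."""
    g = 2.0 * gamma
    if abs(g) < 1e-9:
        return 1.0 / q
    if g > 0:
        num = -np.expm1(-g * (1 - q))
        den = -np.expm1(-g)
        return num / den / (q * (1 - q))
    a = -g
    # ratio expm1(a*(1-q))/expm1(a) in log space to dodge overflow
    la = a * (1 - q) + np.log1p(-np.exp(-min(a * (1 - q), 700.0))) if a * (1 - q) > 1e-8 \
        else np.log(np.expm1(a * (1 - q)))
    lden = a + np.log1p(-np.exp(-min(a, 700.0)))
    return np.exp(la - lden) / (q * (1 - q))


def equilibrium_selected_sfs(gamma: float, n: int, theta: float = 1.0) -> Spectrum:
    """Expected single-population equilibrium SFS by adaptive quadrature:
    E[eta_i] = theta * Int_0^1 C(n,i) q^i (1-q)^(n-i) f(q) dq."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    out = np.zeros(n + 1)
    for i in range(1, n):
        lbin = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)

        def f(q, i=i, lbin=lbin):
            return np.exp(lbin + i * np.log(q) + (n - i) * np.log1p(-q)) * _sel_density(q, gamma)

        val, _ = quad(f, 0.0, 1.0, limit=400, epsabs=1e-13, epsrel=1e-10)
        out[i] = theta * val
    return Spectrum(out)


# ---------------------------------------------------------------------------
# diffusion discretization


def frequency_grid(pts: int, gamma: float = 0.0) -> np.ndarray:
    """Non-uniform [0,1] grid refined near the boundaries; for strong
    selection extra log-spaced points resolve the 1/(2|gamma|) scale."""
    u = np.linspace(0.0, 1.0, pts)
    x = np.sin(np.pi * u / 2.0) ** 2
    if abs(gamma) > 30:
        lo = max(1e-7, 0.05 / abs(2.0 * gamma))
        extra = np.geomspace(lo, 0.2, pts // 2)
        x = np.unique(np.concatenate([x, extra]))
    return x


def _vfunc(x, nu):
    return x * (1.0 - x) / nu


def _compute_delj(dx, MInt, VInt):
    """Exponential-fitting interface weight (Chang-Cooper style upwinding)."""
    wj = 2.0 * MInt * dx
    out = np.full(np.shape(MInt), 0.5)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        epsj = np.exp(wj / VInt)
        d = (-epsj * wj + epsj * VInt - VInt) / (wj - epsj * wj)
    ok = np.isfinite(d) & (wj != 0) & (epsj != 1.0)
    out[ok] = d[ok]
    ov = ~np.isfinite(epsj) & (wj != 0)
    if np.any(ov):
        out[ov] = 1.0 - (VInt / wj)[ov]
    return out


def _tridiag_operator(xx, nu, MInt, Mfirst, Mlast, absorbing=True):
    """Finite-volume tridiagonal generator A with d(phi)/dt = A phi.

    ``MInt`` holds the advection coefficient at the cell interfaces; it may
    be 1D (single system) or 2D of shape (L-1, ncol) for a batch of systems
    sharing the grid (used by the ADI sweeps, where the migration term makes
    the advection depend on the other population's frequency).  ``Mfirst``
    and ``Mlast`` are the advection values at x=0 and x=1; density is
    absorbed at a boundary only where advection does not push inward.
    """
    L = len(xx)
    dx = np.diff(xx)
    dfactor = np.empty(L)
    dfactor[0] = 2.0 / dx[0]
    dfactor[-1] = 2.0 / dx[-1]
    dfactor[1:-1] = 2.0 / (dx[:-1] + dx[1:])
    xInt = (xx[:-1] + xx[1:]) / 2.0
    VInt = _vfunc(xInt, nu)
    V = _vfunc(xx, nu)

    MInt = np.asarray(MInt, dtype=float)
    batch = MInt.ndim == 2
    if batch:
        dx_b = dx[:, None]
        VInt_b = VInt[:, None]
        V_b = V[:, None]
        dfac_b = dfactor[:, None]
        ncol = MInt.shape[1]
        shape = (L, ncol)
    else:
        dx_b, VInt_b, V_b, dfac_b = dx, VInt, V, dfactor
        shape = (L,)

    delj = _compute_delj(dx_b, MInt, VInt_b)
    cM_j = MInt * delj
    cM_j1 = MInt * (1.0 - delj)
    cV_j = V_b[:-1] / (2.0 * dx_b)
    cV_j1 = V_b[1:] / (2.0 * dx_b)

    lower = np.zeros(shape)
    diag = np.zeros(shape)
    upper = np.zeros(shape)
    diag[:-1] += -dfac_b[:-1] * (cM_j + cV_j)
    upper[:-1] += -dfac_b[:-1] * (cM_j1 - cV_j1)
    lower[1:] += dfac_b[1:] * (cM_j + cV_j)
    diag[1:] += dfac_b[1:] * (cM_j1 - cV_j1)

    if absorbing:
        # remove fixed/lost density at the endpoints (1D steady states);
        # the 2D sweeps instead deposit it on the boundary lines, where it
        # keeps evolving in the other population's frequency
        Mfirst = np.asarray(Mfirst, dtype=float)
        Mlast = np.asarray(Mlast, dtype=float)
        bc0 = (0.5 / nu - Mfirst) * 2.0 / dx[0]
        bc1 = (0.5 / nu + Mlast) * 2.0 / dx[-1]
        diag[0] = diag[0] - np.where(Mfirst <= 0, bc0, 0.0)
        diag[-1] = diag[-1] - np.where(Mlast >= 0, bc1, 0.0)
    return lower, diag, upper


def _thomas(lower, diag, upper, rhs):
    """Tridiagonal solve, vectorized over trailing column axis."""
    L = rhs.shape[0]
    cp = np.empty_like(rhs)
    dp = np.empty_like(rhs)
    cp[0] = upper[0] / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, L):
        m = diag[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / m
        dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / m
    x = np.empty_like(rhs)
    x[-1] = dp[-1]
    for i in range(L - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


def _equilibrium_phi(xx, nu, gamma, theta0=1.0):
    """Steady-state density under constant influx: direct solve of A phi = -src."""
    L = len(xx)
    xInt = (xx[:-1] + xx[1:]) / 2.0
    MInt = gamma * xInt * (1.0 - xInt)
    lower, diag, upper = _tridiag_operator(xx, nu, MInt, 0.0, 0.0)
    src = np.zeros(L)
    src[1] = 1.0 / xx[1] * theta0 / 2.0 * 2.0 / (xx[2] - xx[0])
    ab = np.zeros((3, L))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return solve_banded((1, 1), ab, -src)


def _phi_1d_to_2d(phi1, xx):
    L = len(xx)
    phi2 = np.zeros((L, L))
    for i in range(L):
        hw = xx[min(i + 1, L - 1)] - xx[max(i - 1, 0)]
        phi2[i, i] = phi1[i] * 2.0 / hw
    return phi2


def _inject_2d(phi, dt, xx, theta0):
    phi[1, 0] += dt / xx[1] * theta0 / 2.0 * 4.0 / ((xx[2] - xx[0]) * xx[1])
    phi[0, 1] += dt / xx[1] * theta0 / 2.0 * 4.0 / ((xx[2] - xx[0]) * xx[1])
    return phi


def _integrate_2d(phi, xx, T, nu1_f, nu2_f, m12, m21, gamma, theta0=1.0,
                  dt_fac=0.005):
    """Operator-split implicit integration of the 2D diffusion over [0, T]."""
    L = len(xx)
    xInt = (xx[:-1] + xx[1:]) / 2.0
    sel = gamma * xInt * (1.0 - xInt)
    # advection at x-interfaces for every column y (and symmetrically for y)
    Mx = sel[:, None] + m12 * (xx[None, :] - xInt[:, None])
    My = sel[:, None] + m21 * (xx[None, :] - xInt[:, None])
    Mx0, Mx1 = m12 * xx, m12 * (xx - 1.0)
    My0, My1 = m21 * xx, m21 * (xx - 1.0)
    # advection timescale ~ 1/|gamma|: shrink dt for strong selection or the
    # split steps oscillate
    dt0 = min(dt_fac, 2.0 / (1.0 + abs(gamma)))
    if T > 0:
        dt0 = min(dt0, T / 10.0)
    nsteps = max(int(np.ceil(T / dt0)), 1)
    dt = T / nsteps
    t = 0.0
    for step in range(nsteps):
        tm = t + dt / 2.0
        nu1, nu2 = nu1_f(tm), nu2_f(tm)
        phi = _inject_2d(phi, dt, xx, theta0)

        def _corner_absorption(dia, nu, M0, M1):
            # the boundary lines (first/last column of the sweep) feed the
            # monomorphic corners; delete that flux or it piles up in the
            # smallest cells and the implicit solve oscillates
            dx = np.diff(xx)
            for c in (0, -1):
                if M0[c] <= 0:
                    dia[0, c] -= (0.5 / nu - M0[c]) * 2.0 / dx[0]
                if M1[c] >= 0:
                    dia[-1, c] -= (0.5 / nu + M1[c]) * 2.0 / dx[-1]
            return dia

        def sweep_x(p):
            low, dia, up = _tridiag_operator(xx, nu1, Mx, Mx0, Mx1,
                                             absorbing=False)
            dia = _corner_absorption(dia, nu1, Mx0, Mx1)
            return _thomas(-dt * low, 1.0 - dt * dia, -dt * up, p)

        def sweep_y(p):
            pT = np.ascontiguousarray(p.T)
            low, dia, up = _tridiag_operator(xx, nu2, My, My0, My1,
                                             absorbing=False)
            dia = _corner_absorption(dia, nu2, My0, My1)
            pT = _thomas(-dt * low, 1.0 - dt * dia, -dt * up, pT)
            return np.ascontiguousarray(pT.T)

        # alternate sweep order so the splitting bias cancels pairwise and
        # exchanging the two populations transposes the result
        if step % 2 == 0:
            phi = sweep_y(sweep_x(phi))
        else:
            phi = sweep_x(sweep_y(phi))
        # drop the monomorphic corner spikes: they are never sampled and a
        # delta there makes the implicit solves undershoot along the axes
        phi[0, 0] = phi[0, -1] = phi[-1, 0] = phi[-1, -1] = 0.0
        t += dt
    return phi


def _trapz_weights(xx):
    w = np.empty(len(xx))
    dx = np.diff(xx)
    w[0] = dx[0] / 2.0
    w[-1] = dx[-1] / 2.0
    w[1:-1] = (dx[:-1] + dx[1:]) / 2.0
    return w


def _binom_matrix(n, xx):
    i = np.arange(n + 1)[:, None]
    return comb(n, i) * xx[None, :] ** i * (1.0 - xx[None, :]) ** (n - i)


def _gauss_cell(f, a, b, order=24):
    t, w = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (b - a) * t + 0.5 * (b + a)
    return 0.5 * (b - a) * (f(x) * w).sum(axis=-1)


def _sampling_weights(n, xx):
    """Quadrature matrix W[i, k] with ∑_k W[i,k] φ_k ≈ ∫ B(i;n,x) φ(x) dx.

    Trapezoid in the interior; in the first/last cells the density behaves
    like 1/x (resp. 1/(1-x)), so those cells are integrated against that
    profile anchored at the adjacent interior node.  Boundary nodes keep
    their trapezoid weight: they carry the absorbed line masses.
    """
    B = _binom_matrix(n, xx)
    W = B * _trapz_weights(xx)
    i = np.arange(n + 1)[:, None]
    x1, xm = xx[1], xx[-2]
    dx0, dxl = xx[1] - xx[0], xx[-1] - xx[-2]

    def lo_profile(x):
        return comb(n, i) * x ** (i - 1) * (1.0 - x) ** (n - i)

    def hi_profile(x):
        return comb(n, i) * x**i * (1.0 - x) ** (n - i - 1)

    # i = 0 (resp. i = n) would integrate the non-integrable 1/x (1/(1-x))
    # profile; those entries are carried by the boundary-line masses instead
    lo = x1 * _gauss_cell(lo_profile, 0.0, x1) - dx0 / 2.0 * B[:, 1]
    hi = (1.0 - xm) * _gauss_cell(hi_profile, xm, 1.0) - dxl / 2.0 * B[:, -2]
    W[1:, 1] += lo[1:]
    W[:-1, -2] += hi[:-1]
    return W


def _sample_2d(phi, xx, n1, n2):
    W1 = _sampling_weights(n1, xx)
    W2 = _sampling_weights(n2, xx)
    return W1 @ phi @ W2.T


def expected_sfs(
    model: DemographicModel,
    gamma: float,
    sizes: tuple[int, int],
    theta: float = 1.0,
    pts: int = 100,
    dt_fac: float = 0.005,
    neg_tol: float = 1e-4,
) -> Spectrum:
    """2D expected SFS: single-population selected equilibrium, split onto
    the diagonal, integrated through the divergence epoch (drift, selection,
    migration, exponential size change), then binomially sampled down to
    ``sizes`` chromosomes per population."""
    n1, n2 = (int(s) for s in sizes)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 chromosomes per population")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if gamma <= GAMMA_LETHAL:
        return Spectrum(np.zeros((n1 + 1, n2 + 1)))
    xx = frequency_grid(pts, gamma)
    phi1 = np.clip(_equilibrium_phi(xx, 1.0, gamma, theta0=theta), 0.0, None)
    phi = _phi_1d_to_2d(phi1, xx)
    nu1_f, nu2_f = model.nu_trajectories()
    phi = _integrate_2d(phi, xx, model.T_split, nu1_f, nu2_f,
                        model.m12, model.m21, gamma, theta0=theta,
                        dt_fac=dt_fac)
    fs = _sample_2d(phi, xx, n1, n2)
    scale = max(abs(fs).max(), 1e-300)
    if fs.min() < -neg_tol * scale:
        raise RuntimeError(
            f"negative densities beyond tolerance at gamma={gamma}: "
            f"min {fs.min():.3g} vs scale {scale:.3g}; refine pts/dt_fac"
        )
    return Spectrum(np.clip(fs, 0.0, None))


# ---------------------------------------------------------------------------
# discrete Wright-Fisher oracle


def wf_oracle_sfs(
    N: int,
    gamma: float,
    n: int,
    epochs: list[tuple[float, int]] | None = None,
) -> Spectrum:
    """Expected SFS from the exact binomial Wright-Fisher transition matrix
    with genic selection s = gamma/(2N) and constant unit-theta mutation
    influx (1/2 new mutation per generation at count 1 for the reference
    size; nu/2 for an epoch of relative size nu).

    The stationary state at the reference size ``N`` is obtained by a direct
    linear solve; optional ``epochs`` — (relative size, generations) pairs —
    are then iterated forward, resampling frequencies binomially when the
    population size changes.  Sampling down to ``n`` chromosomes is
    hypergeometric.
    """
    if N > 500:
        raise ValueError("N too large for the dense-matrix oracle (max 500)")
    if n > 2 * N:
        raise ValueError("n cannot exceed 2N")
    s = gamma / (2.0 * N)

    def sel_p(x):
        return x * np.exp(s) / (x * np.exp(s) + (1.0 - x))

    def transition(n_from, n_to):
        """P(k offspring of n_to | j parents of n_from) incl. selection."""
        j = np.arange(n_from + 1)
        k = np.arange(n_to + 1)
        return binom_dist.pmf(k[None, :], n_to, sel_p(j / n_from)[:, None])

    twoN = 2 * N
    M = transition(twoN, twoN)
    Q = M[1:twoN, 1:twoN]
    b = np.zeros(twoN - 1)
    b[0] = 0.5
    # mutations enter before reproduction; the census is post-selection, so
    # an effectively lethal mutation never appears in the standing state
    E = np.linalg.solve(np.eye(twoN - 1) - Q.T, Q.T @ b)
    full = np.zeros(twoN + 1)
    full[1:twoN] = E
    cur = twoN
    if epochs:
        for nu, gens in epochs:
            new = int(round(2 * N * nu))
            if new > 1000:
                raise ValueError("epoch size too large for the dense oracle")
            if new != cur:
                full = transition(cur, new).T @ full
                full[0] = full[-1] = 0.0
                cur = new
            Me = transition(cur, cur)
            Qe = Me[1:cur, 1:cur]
            be = np.zeros(cur - 1)
            be[0] = nu / 2.0
            Ee = full[1:cur]
            for _ in range(int(gens)):
                Ee = Qe.T @ (Ee + be)
            full = np.zeros(cur + 1)
            full[1:cur] = Ee
    k = np.arange(cur + 1)
    proj = np.array(
        [np.sum(hypergeom.pmf(i, cur, k, n) * full) for i in range(n + 1)]
    )
    return Spectrum(proj)


# ---------------------------------------------------------------------------
# per-gamma cache


@dataclass
class SpectraCache:
    """Unit-theta expected spectra keyed one-to-one by selection-grid values."""

    grid: SelectionGrid
    spectra: list[Spectrum]
    sizes: tuple[int, ...]
    model: DemographicModel | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.grid):
            raise ValueError("cache must hold one spectrum per grid value")
        for s in self.spectra:
            if np.any(s.counts[~s.mask] < 0):
                raise ValueError("cached spectra must be non-negative")

    def __len__(self) -> int:
        return len(self.spectra)

    def stack(self) -> np.ndarray:
        """(n_gamma, *shape) array of cached counts."""
        return np.stack([s.counts for s in self.spectra])

    def at_gamma(self, gamma: float) -> np.ndarray:
        """Counts at an off-grid gamma by linear interpolation in log|gamma|
        within the matching sign branch (documented reduced-grid behavior)."""
        g = self.grid.gamma_values
        if gamma in g:
            return self.spectra[int(np.flatnonzero(g == gamma)[0])].counts
        if gamma <= GAMMA_LETHAL:
            return np.zeros_like(self.spectra[0].counts)
        branch = np.sign(gamma)
        sel = np.flatnonzero(np.sign(g) == branch)
        lg = np.log(np.abs(g[sel]))
        target = np.log(abs(gamma))
        order = np.argsort(lg)
        lg_s = lg[order]
        pos = np.clip(np.searchsorted(lg_s, target), 1, len(lg_s) - 1)
        l0, l1 = lg_s[pos - 1], lg_s[pos]
        w = (target - l0) / (l1 - l0)
        c0 = self.spectra[sel[order[pos - 1]]].counts
        c1 = self.spectra[sel[order[pos]]].counts
        return (1 - w) * c0 + w * c1

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "gamma_values": [float(g) for g in self.grid.gamma_values],
            "sizes": list(self.sizes),
            "model": asdict(self.model) if self.model else None,
            "meta": self.meta,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        for i, s in enumerate(self.spectra):
            s.save(os.path.join(directory, f"spectrum_{i:05d}.txt"))

    @classmethod
    def load(cls, directory: str) -> "SpectraCache":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        grid = SelectionGrid(np.array(manifest["gamma_values"]))
        spectra = [
            Spectrum.load(os.path.join(directory, f"spectrum_{i:05d}.txt"))
            for i in range(len(grid))
        ]
        model = DemographicModel(**manifest["model"]) if manifest["model"] else None
        return cls(grid=grid, spectra=spectra, sizes=tuple(manifest["sizes"]),
                   model=model, meta=manifest.get("meta", {}))


def build_cache(
    model: DemographicModel,
    grid: SelectionGrid,
    sizes: tuple[int, int],
    pts: int = 100,
    dt_fac: float = 0.005,
    progress: bool = False,
) -> SpectraCache:
    """One unit-theta 2D expected spectrum per grid gamma."""
    spectra = []
    for i, g in enumerate(grid.gamma_values):
        try:
            spectra.append(expected_sfs(model, g, sizes, theta=1.0, pts=pts,
                                        dt_fac=dt_fac))
        except Exception as exc:  # noqa: BLE001 - annotate offending gamma
            raise RuntimeError(f"cache build failed at gamma={g}: {exc}") from exc
        if progress and (i + 1) % 10 == 0:
            print(f"cache: {i + 1}/{len(grid)}")
    return SpectraCache(grid=grid, spectra=spectra, sizes=tuple(sizes),
                        model=model, meta={"pts": pts, "dt_fac": dt_fac})


def build_equilibrium_cache(grid: SelectionGrid, n: int) -> SpectraCache:
    """Single-population closed-form equilibrium cache (cheap; used for
    grid-resolution studies where the demography is irrelevant)."""
    spectra = []
    for g in grid.gamma_values:
        if g <= GAMMA_LETHAL:
            spectra.append(Spectrum(np.zeros(n + 1)))
        else:
            spectra.append(equilibrium_selected_sfs(g, n))
    return SpectraCache(grid=grid, spectra=spectra, sizes=(n,), model=None,
                        meta={"kind": "equilibrium"})
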