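"""Site-frequency spectra: construction, hypergeometric projection, folding,
rescaling and residual comparison.

The :class:`Spectrum` is the central observable of the analysis.  It is a
dense array of (possibly fractional) SNP counts indexed by derived-allele
count, one axis per population, together with a boolean mask marking entries
that carry no weight (at minimum the absent/fixed corners).  Folded spectra
are indexed by minor-allele configuration; the mirrored half stays in the
array but is masked and zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "MISSING",
    "HET_RAW",
    "GenotypeMatrix",
    "Spectrum",
    "build_spectrum",
    "project",
    "fold",
    "rescale_to_segregating",
    "residual_spectrum",
]

#: sentinel for a missing call in :attr:`GenotypeMatrix.calls`
MISSING = -1
#: sentinel for a raw heterozygous call inside a haploid-context matrix
HET_RAW = 2


@dataclass
class GenotypeMatrix:
    """Individuals x sites genotype calls with population labels.

    ``calls`` holds per-individual allele dosages: ``{0, 1, 2}`` for diploid
    autosomes, ``{0, 1}`` for haploid mtDNA (where the value ``2`` marks a
    raw heterozygous artifact call), and ``MISSING`` (-1) for no-calls.
    ``genotype_quality`` is the per-call posterior probability in [0, 1];
    ``None`` means every call is fully trusted.
    """

    individuals: list[str]
    pop_labels: list[str]
    calls: np.ndarray
    site_ids: list[str]
    genotype_quality: np.ndarray | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.individuals), len(self.site_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.site_ids)} sites"
            )
        if len(self.pop_labels) != len(self.individuals):
            raise ValueError("pop_labels must align with individuals")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids must be unique")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        top = 2 if self.ploidy == 2 else HET_RAW  # haploid may carry raw hets
        valid = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= top))
        if not np.all(valid):
            raise ValueError("calls must be allele dosages or MISSING")
        if self.genotype_quality is not None:
            q = np.asarray(self.genotype_quality, dtype=float)
            if q.shape != self.calls.shape:
                raise ValueError("genotype_quality shape mismatch")
            if np.any((q < 0) | (q > 1)):
                raise ValueError("genotype_quality must lie in [0, 1]")
            self.genotype_quality = q

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pop_labels) == pop)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        q = None if self.genotype_quality is None else self.genotype_quality[:, idx]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            pop_labels=list(self.pop_labels),
            calls=self.calls[:, idx],
            site_ids=[self.site_ids[i] for i in idx],
            genotype_quality=q,
            ploidy=self.ploidy,
        )


def _default_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[(0,) * len(shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


def _folded_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = _default_mask(shape)
    total = np.zeros(shape)
    for ax, s in enumerate(shape):
        idx = [None] * len(shape)
        idx[ax] = slice(None)
        total = total + np.arange(s)[tuple(idx)]
    ntot = sum(s - 1 for s in shape)
    mask |= total > ntot / 2
    return mask


@dataclass
class Spectrum:
    """SNP counts indexed by derived (or folded minor) allele counts.

    ``counts`` has shape ``(n1+1,)`` or ``(n1+1, n2+1)`` for sample sizes in
    chromosomes.  ``mask`` is True where an entry is excluded; masked entries
    are kept at zero.
    """

    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.array(self.counts, dtype=float)
        if self.counts.ndim not in (1, 2):
            raise ValueError("Spectrum must be 1D or 2D")
        if self.mask is None:
            self.mask = (
                _folded_mask(self.counts.shape)
                if self.folded
                else _default_mask(self.counts.shape)
            )
        else:
            self.mask = np.array(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")
        if np.any(self.counts[~self.mask] < 0):
            raise ValueError("negative counts on unmasked entries")
        self.counts[self.mask] = 0.0

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.counts.shape)

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    def segregating_total(self) -> float:
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.counts.copy(), folded=self.folded, mask=self.mask.copy())

    # conveniences mirroring the module-level operations
    def project(self, new_sizes) -> "Spectrum":
        return project(self, new_sizes)

    def fold(self) -> "Spectrum":
        return fold(self)

    def rescale_to_segregating(self, target_total: float) -> "Spectrum":
        return rescale_to_segregating(self, target_total)

    # --- plain-text serialization (round-trips bit-exactly) ---
    def to_text(self) -> str:
        sizes = " ".join(str(s) for s in self.sample_sizes)
        lines = [f"{sizes} {int(self.folded)}"]
        c2 = np.atleast_2d(self.counts)
        for row in c2:
            lines.append(" ".join(np.format_float_scientific(v, precision=17) for v in row))
        m2 = np.atleast_2d(self.mask)
        for row in m2:
            lines.append(" ".join("1" if v else "0" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Spectrum":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0].split()
        sizes = [int(v) for v in header[:-1]]
        folded = bool(int(header[-1]))
        shape = tuple(s + 1 for s in sizes)
        nrow = shape[0] if len(shape) > 1 else 1
        counts = np.array([[float(v) for v in ln.split()] for ln in lines[1 : 1 + nrow]])
        mask = np.array(
            [[v == "1" for v in ln.split()] for ln in lines[1 + nrow : 1 + 2 * nrow]]
        )
        if len(shape) == 1:
            counts, mask = counts[0], mask[0]
        return cls(counts.reshape(shape), folded=folded, mask=mask.reshape(shape))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "Spectrum":
        with open(path) as fh:
            return cls.from_text(fh.read())


# ---------------------------------------------------------------------------
# spectrum construction from genotypes


def build_spectrum(
    geno: GenotypeMatrix,
    min_quality: float = 0.95,
    fold_spectrum: bool = False,
    missing_mode: str = "project",
    target_sizes: tuple[int, int] | None = None,
) -> Spectrum:
    """Tally a two-population joint SFS from a genotype matrix.

    Calls with posterior probability <= ``min_quality`` are treated as
    missing (the default keeps only calls strictly above 0.95).  Sites that
    are not fully called either contribute through per-site hypergeometric
    projection down to ``target_sizes`` (``missing_mode="project"``, default:
    the largest fully-called size over all retained sites) or are dropped
    (``missing_mode="strict"``).  Monomorphic sites land in the masked
    corners.
    """
    if missing_mode not in ("project", "strict"):
        raise ValueError("missing_mode must be 'project' or 'strict'")
    if not 0.0 <= min_quality <= 1.0:
        raise ValueError("min_quality must lie in [0, 1]")
    pops = geno.populations
    if len(pops) != 2:
        raise ValueError(f"need exactly two populations, got {pops}")
    idx1, idx2 = geno.pop_indices(pops[0]), geno.pop_indices(pops[1])
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("empty population")
    if geno.ploidy == 1 and np.any(geno.calls == HET_RAW):
        raise ValueError("haploid matrix carries raw heterozygous calls; filter first")

    calls = geno.calls.astype(float)
    calls[calls == MISSING] = np.nan
    if geno.genotype_quality is not None:
        calls[geno.genotype_quality <= min_quality] = np.nan

    ploidy = geno.ploidy
    full_sizes = (ploidy * len(idx1), ploidy * len(idx2))

    der = np.vstack(
        [np.nansum(calls[idx1], axis=0), np.nansum(calls[idx2], axis=0)]
    )  # (2, n_sites) derived counts among called chromosomes
    ncalled = np.vstack(
        [
            ploidy * np.sum(~np.isnan(calls[idx1]), axis=0),
            ploidy * np.sum(~np.isnan(calls[idx2]), axis=0),
        ]
    ).astype(int)

    if missing_mode == "strict":
        keep = np.all(ncalled == np.array(full_sizes)[:, None], axis=0)
        sizes = full_sizes
        arr = np.zeros((sizes[0] + 1, sizes[1] + 1))
        d = der[:, keep].astype(int)
        np.add.at(arr, (d[0], d[1]), 1.0)
    else:
        usable = np.all(ncalled >= 2, axis=0)
        if target_sizes is None:
            if not np.any(usable):
                raise ValueError("no usable sites")
            sizes = tuple(int(v) for v in ncalled[:, usable].min(axis=1))
        else:
            sizes = tuple(int(v) for v in target_sizes)
        keep = np.all(ncalled >= np.array(sizes)[:, None], axis=0)
        arr = np.zeros((sizes[0] + 1, sizes[1] + 1))
        d = der[:, keep].astype(int)
        nc = ncalled[:, keep]
        exact = np.all(nc == np.array(sizes)[:, None], axis=0)
        np.add.at(arr, (d[0, exact], d[1, exact]), 1.0)
        if np.any(~exact):
            # per-site product-hypergeometric weight spread over target bins
            dd, nn = d[:, ~exact], nc[:, ~exact]
            j1 = np.arange(sizes[0] + 1)
            j2 = np.arange(sizes[1] + 1)
            w1 = hypergeom.pmf(j1[None, :], nn[0][:, None], dd[0][:, None], sizes[0])
            w2 = hypergeom.pmf(j2[None, :], nn[1][:, None], dd[1][:, None], sizes[1])
            arr += np.einsum("si,sj->ij", w1, w2)

    spec = Spectrum(arr, folded=False)
    if fold_spectrum:
        spec = fold(spec)
    return spec


# ---------------------------------------------------------------------------
# projection / folding / rescaling / residuals


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """P[i, j] = hypergeometric P(j derived in n_to draws | i derived in n_from)."""
    i = np.arange(n_from + 1)
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j[None, :], n_from, i[:, None], n_to)


def project(spec: Spectrum, new_sizes) -> Spectrum:
    """Redistribute each entry by sampling ``new_sizes`` chromosomes without
    replacement.  Folding status is preserved (fold is re-applied after
    projecting a folded spectrum)."""
    new_sizes = tuple(int(v) for v in np.atleast_1d(new_sizes))
    old_sizes = spec.sample_sizes
    if len(new_sizes) != len(old_sizes):
        raise ValueError("dimension mismatch")
    for new, old in zip(new_sizes, old_sizes):
        if new > old:
            raise ValueError(f"cannot project {old} chromosomes up to {new}")
        if new < 2:
            raise ValueError("projected sample size must be >= 2")
    arr = spec.counts.copy()
    arr[spec.mask] = 0.0
    for ax, (new, old) in enumerate(zip(new_sizes, old_sizes)):
        P = _projection_matrix(old, new)
        arr = np.tensordot(arr, P, axes=([ax], [0]))
        arr = np.moveaxis(arr, -1, ax)
    out = Spectrum(arr, folded=False)
    if spec.folded:
        out = fold(out)
    return out


def fold(spec: Spectrum) -> Spectrum:
    """Fold onto minor-allele configurations (1D: minor count; 2D: total
    minor count across both populations), conserving unmasked weight."""
    if spec.folded:
        raise ValueError("spectrum is already folded")
    arr = spec.counts.copy()
    arr[spec.mask] = 0.0
    rev = arr[tuple(slice(None, None, -1) for _ in range(arr.ndim))]
    total = np.zeros(arr.shape)
    for ax, s in enumerate(arr.shape):
        idx = [None] * arr.ndim
        idx[ax] = slice(None)
        total = total + np.arange(s)[tuple(idx)]
    ntot = sum(spec.sample_sizes)
    folded = arr + rev
    folded[total == ntot / 2] *= 0.5  # self-conjugate fold line counted twice
    folded[total > ntot / 2] = 0.0
    mask = _folded_mask(arr.shape) | (spec.mask & spec.mask[tuple(slice(None, None, -1) for _ in range(arr.ndim))])
    return Spectrum(folded, folded=True, mask=mask)


def rescale_to_segregating(spec: Spectrum, target_total: float) -> Spectrum:
    cur = spec.segregating_total()
    if cur <= 0:
        raise ValueError("zero segregating total")
    out = spec.copy()
    out.counts[~out.mask] *= target_total / cur
    return out


def residual_spectrum(a: Spectrum, b: Spectrum) -> np.ma.MaskedArray:
    """Symmetrized Poisson-style residuals (a - b)/sqrt((a + b)/2), zero when
    both entries are zero.  Sign is positive where ``a`` exceeds ``b``."""
    if a.counts.shape != b.counts.shape:
        raise ValueError("shape mismatch")
    if a.folded != b.folded:
        raise ValueError("folding mismatch")
    mask = a.mask | b.mask
    num = a.counts - b.counts
    den = np.sqrt((a.counts + b.counts) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.ma.MaskedArray(res, mask=mask)
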