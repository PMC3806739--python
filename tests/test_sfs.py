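import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsel.sfs import (
    MISSING,
    GenotypeMatrix,
    Spectrum,
    build_spectrum,
    fold,
    project,
    rescale_to_segregating,
    residual_spectrum,
)

from conftest import random_spectrum


def make_matrix(calls, pops=None, quality=None, ploidy=2):
    calls = np.asarray(calls)
    n_ind, n_sites = calls.shape
    pops = pops or ["pop1"] * (n_ind // 2) + ["pop2"] * (n_ind - n_ind // 2)
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n_ind)],
        pop_labels=pops,
        calls=calls,
        site_ids=[f"s{k}" for k in range(n_sites)],
        genotype_quality=quality,
        ploidy=ploidy,
    )


class TestGenotypeMatrix:
    def test_rejects_bad_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            make_matrix([[3], [0]])

    def test_rejects_duplicate_sites(self):
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix(["a", "b"], ["p", "q"], np.zeros((2, 2), int), ["x", "x"])

    def test_rejects_bad_quality(self):
        with pytest.raises(ValueError, match="quality"):
            make_matrix([[0], [1]], quality=np.array([[1.2], [0.5]]))


class TestBuildSpectrum:
    def test_single_het_lands_at_one_zero(self):
        # 5+5 diploids, one SNP heterozygous in one pop1 individual
        calls = np.zeros((10, 1), dtype=int)
        calls[0, 0] = 1
        spec = build_spectrum(make_matrix(calls))
        assert spec.counts.shape == (11, 11)
        assert spec.counts[1, 0] == 1.0
        assert spec.segregating_total() == 1.0

    def test_monomorphic_site_masked(self):
        spec = build_spectrum(make_matrix(np.zeros((10, 1), dtype=int)))
        assert spec.mask[0, 0]
        assert spec.segregating_total() == 0.0

    def test_matches_bruteforce_tally(self, rng):
        # random complete 10-individual, 200-site matrix vs per-site oracle
        calls = rng.integers(0, 3, size=(10, 200))
        spec = build_spectrum(make_matrix(calls))
        oracle = np.zeros((11, 11))
        for s in range(200):
            d1 = calls[:5, s].sum()
            d2 = calls[5:, s].sum()
            oracle[d1, d2] += 1
        oracle[0, 0] = oracle[10, 10] = 0
        np.testing.assert_allclose(spec.counts, oracle)

    def test_quality_filter_excludes_at_threshold(self):
        calls = np.zeros((4, 1), dtype=int)
        calls[0, 0] = 2
        quality = np.full((4, 1), 0.99)
        quality[0, 0] = 0.95  # <= 0.95 must be excluded
        spec = build_spectrum(make_matrix(calls, quality=quality), missing_mode="strict")
        assert spec.segregating_total() == 0.0

    def test_missing_projected_hypergeometrically(self):
        # one derived allele among 4 called chromosomes in pop1 at one site,
        # another site fully called: spectrum projected to (4, 4)
        calls = np.array(
            [[1, 0], [MISSING, 0], [0, 0], [0, 0], [0, 1], [0, 0]]
        )
        pops = ["pop1"] * 3 + ["pop2"] * 3
        geno = make_matrix(calls, pops=pops)
        # default target = largest fully-called size per population
        assert build_spectrum(geno).sample_sizes == (4, 6)
        spec = build_spectrum(geno, target_sizes=(4, 4))
        assert spec.sample_sizes == (4, 4)
        # site 1: d=1 of 4 kept whole; site 2: pop2 d=1 of 6 -> hypergeom to 4
        assert spec.counts[1, 0] == pytest.approx(1.0)
        assert spec.counts[0, 1] == pytest.approx(4 / 6)

    def test_strict_mode_drops_missing(self):
        calls = np.array([[1, 1], [MISSING, 0], [0, 0], [0, 0]])
        spec = build_spectrum(make_matrix(calls), missing_mode="strict")
        assert spec.segregating_total() == 1.0

    def test_empty_population_errors(self):
        with pytest.raises(ValueError, match="two populations"):
            build_spectrum(make_matrix([[0], [1]], pops=["p", "p"]))


class TestProject:
    def test_identity_projection(self, rng):
        spec = random_spectrum(rng, (9,))
        out = project(spec, (8,))
        np.testing.assert_allclose(out.counts, spec.counts)

    def test_singleton_hypergeometric(self):
        counts = np.zeros(5)
        counts[1] = 1.0
        out = project(Spectrum(counts), (2,))
        assert out.counts[1] == pytest.approx(0.5)
        assert out.segregating_total() == pytest.approx(0.5)

    def test_projection_up_errors(self, rng):
        with pytest.raises(ValueError, match="project"):
            project(random_spectrum(rng, (9,)), (10,))

    def test_matches_monte_carlo_subsampling(self):
        # explicit chromosome subsampling oracle, >= 1e5 draws, fixed seed
        rng = np.random.default_rng(42)
        counts = np.zeros(11)
        counts[1:10] = rng.uniform(5, 30, 9)
        spec = Spectrum(counts)
        out = project(spec, (6,))
        draws = 200_000
        tally = np.zeros(7)
        # sample sites proportional to counts, subsample 6 of 10 chromosomes
        probs = counts[1:10] / counts[1:10].sum()
        ders = rng.choice(np.arange(1, 10), size=draws, p=probs)
        for d in ders:
            chroms = np.zeros(10)
            chroms[:d] = 1
            tally[int(rng.permutation(chroms)[:6].sum())] += 1
        total = counts[1:10].sum()
        mc = tally / draws * total
        se = np.sqrt(np.maximum(tally, 1)) / draws * total
        inner = slice(1, 6)
        assert np.all(np.abs(out.counts[inner] - mc[inner]) < 3 * se[inner] + 1e-9)

    def test_never_increases_segregating_total(self, rng):
        for _ in range(5):
            spec = random_spectrum(rng, (11,))
            out = project(spec, (6,))
            assert out.segregating_total() <= spec.segregating_total() + 1e-9

    def test_linearity(self, rng):
        a = random_spectrum(rng, (9, 9))
        b = random_spectrum(rng, (9, 9))
        lhs = project(Spectrum(2.0 * a.counts + 3.0 * b.counts), (4, 4))
        rhs = 2.0 * project(a, (4, 4)).counts + 3.0 * project(b, (4, 4)).counts
        np.testing.assert_allclose(lhs.counts, rhs, atol=1e-12)

    @given(n=st.integers(4, 12), m=st.integers(2, 4), data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_fold_project_commute(self, n, m, data):
        m = min(2 * m, n)
        vals = data.draw(
            st.lists(st.floats(0, 50), min_size=n + 1, max_size=n + 1)
        )
        spec = Spectrum(np.array(vals))
        a = project(fold(spec), (m,))
        b = fold(project(spec, (m,)))
        np.testing.assert_allclose(a.counts, b.counts, atol=1e-9)
        assert a.folded and b.folded


class TestFold:
    def test_mirror_sum_example(self):
        spec = Spectrum(np.array([0.0, 3.0, 2.0, 1.0, 0.0]))
        out = fold(spec)
        assert out.counts[1] == 4.0
        assert out.counts[2] == 2.0  # self-conjugate middle bin
        assert out.mask[3] and out.mask[4]

    def test_double_fold_errors(self):
        spec = fold(Spectrum(np.array([0.0, 1.0, 1.0, 1.0, 0.0])))
        with pytest.raises(ValueError, match="folded"):
            fold(spec)

    def test_conserves_total_2d(self, rng):
        spec = random_spectrum(rng, (9, 9))
        out = fold(spec)
        assert out.segregating_total() == pytest.approx(spec.segregating_total())

    def test_folded_mask_layout(self):
        out = fold(Spectrum(np.ones((5, 5))))
        total = np.add.outer(np.arange(5), np.arange(5))
        assert np.all(out.mask[total > 4])


class TestRescale:
    def test_halving(self, rng):
        spec = random_spectrum(rng, (9,))
        out = rescale_to_segregating(spec, spec.segregating_total() / 2)
        np.testing.assert_allclose(out.counts, spec.counts / 2)

    def test_identity(self, rng):
        spec = random_spectrum(rng, (9,))
        out = rescale_to_segregating(spec, spec.segregating_total())
        np.testing.assert_allclose(out.counts, spec.counts)

    def test_equalizes_totals(self, rng):
        a = random_spectrum(rng, (9, 9))
        b = random_spectrum(rng, (9, 9))
        out = rescale_to_segregating(a, b.segregating_total())
        assert out.segregating_total() == pytest.approx(b.segregating_total())

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero"):
            rescale_to_segregating(Spectrum(np.zeros(5)), 10.0)


class TestResiduals:
    def test_identity_zero(self, rng):
        a = random_spectrum(rng, (9,))
        res = residual_spectrum(a, a)
        np.testing.assert_allclose(res.filled(0), 0.0)

    def test_closed_form_entry(self):
        a = Spectrum(np.array([0.0, 8.0, 0.0]))
        b = Spectrum(np.array([0.0, 2.0, 0.0]))
        res = residual_spectrum(a, b)
        assert res[1] == pytest.approx((8 - 2) / np.sqrt(5))

    def test_antisymmetry(self, rng):
        a = random_spectrum(rng, (7, 7))
        b = random_spectrum(rng, (7, 7))
        np.testing.assert_allclose(
            residual_spectrum(a, b).filled(0), -residual_spectrum(b, a).filled(0)
        )

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="shape"):
            residual_spectrum(random_spectrum(rng, (7,)), random_spectrum(rng, (9,)))


class TestSerialization:
    def test_round_trip_bit_exact(self, rng):
        for shape, folded in [((9,), False), ((9, 9), True)]:
            spec = random_spectrum(rng, shape, folded=folded)
            spec.counts[~spec.mask] *= np.pi  # non-trivial floats
            back = Spectrum.from_text(spec.to_text())
            assert back.folded == spec.folded
            np.testing.assert_array_equal(back.counts, spec.counts)
            np.testing.assert_array_equal(back.mask, spec.mask)
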