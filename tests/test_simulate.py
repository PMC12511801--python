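import numpy as np
import pytest
import scipy.stats

import surfconn as sc
from surfconn.metrics import ScanCollection, dicc
from surfconn.simulate import (
    BundleComponent,
    BundleMixture,
    TrueDensity,
    consistency_experiment,
    estimation_error,
    make_bundle_mixture,
    make_scan_collection,
    sample_endpoints,
)
from surfconn.smoothing import build_adjacency, smooth_fast


@pytest.fixture(scope="module")
def kernel_trio(ico3, ico3_basis):
    return [
        ("diffusion", sc.spectral_kernel(ico3_basis, sc.KernelSpec("diffusion", 0.4))),
        ("matern", sc.spectral_kernel(ico3_basis, sc.KernelSpec("matern", 0.4, smoothness=2.0))),
        ("spherical_heat", sc.shk_matrix(ico3.vertices, 0.4**2 / 2)),
    ]


class TestBundleMixture:
    def test_single_bundle_peak_and_symmetry(self, ico2_basis):
        mix = BundleMixture((BundleComponent(5, 5, 0.4, 1.0),))
        d = make_bundle_mixture(ico2_basis, mix)
        np.testing.assert_array_equal(d.values, d.values.T)
        assert d.values[5, 5] == d.values.max()

    def test_unit_mass_normalization(self, two_bundle):
        density, _ = two_bundle
        total = density.values @ density.mass @ density.mass
        assert abs(total - 1.0) < 1e-10
        assert (density.values >= 0).all()

    def test_mixture_linearity(self, ico2_basis):
        c1 = BundleComponent(3, 40, 0.4, 1.0)
        c2 = BundleComponent(10, 90, 0.5, 1.0)
        d1 = make_bundle_mixture(ico2_basis, BundleMixture((c1,)))
        d2 = make_bundle_mixture(ico2_basis, BundleMixture((c2,)))
        both = make_bundle_mixture(
            ico2_basis,
            BundleMixture(
                (
                    BundleComponent(3, 40, 0.4, 0.5),
                    BundleComponent(10, 90, 0.5, 0.5),
                )
            ),
        )
        # single-bundle densities have unit mass, so the equal-weight mixture
        # is their entrywise average
        np.testing.assert_allclose(
            both.values, 0.5 * (d1.values + d2.values), atol=1e-12
        )

    def test_rejects_bad_components(self, ico2_basis):
        with pytest.raises(ValueError):
            BundleMixture((BundleComponent(0, 1, -0.1, 1.0),))
        with pytest.raises(ValueError):
            make_bundle_mixture(
                ico2_basis, BundleMixture((BundleComponent(0, 10**6, 0.4, 1.0),))
            )


class TestSampler:
    def test_point_mass_density(self, ico2_basis):
        m = ico2_basis.mass
        vals = np.zeros((m.size, m.size))
        vals[7, 30] = vals[30, 7] = 1.0
        d = TrueDensity(values=vals / (vals @ m @ m), mass=m)
        ep = sample_endpoints(d, 50, seed=1)
        for a, b in ep.pairs:
            assert {a, b} == {7, 30}

    def test_seed_determinism(self, two_bundle):
        density, _ = two_bundle
        a = sample_endpoints(density, 100, seed=9)
        b = sample_endpoints(density, 100, seed=9)
        c = sample_endpoints(density, 100, seed=10)
        np.testing.assert_array_equal(a.pairs, b.pairs)
        assert not np.array_equal(a.pairs, c.pairs)

    def test_empirical_frequencies_match_target(self, two_bundle):
        """Chi-square goodness of fit on coarse bins of the pair grid."""
        density, _ = two_bundle
        m = density.mass
        w = density.values * np.outer(m, m)
        w = w.ravel() / w.sum()
        ep = sample_endpoints(density, 4000, seed=17)
        flat = ep.pairs[:, 0] * m.size + ep.pairs[:, 1]
        # bin cells by decreasing target probability into ~12 equal-mass bins
        order = np.argsort(w)[::-1]
        csum = np.cumsum(w[order])
        edges = np.searchsorted(csum, np.linspace(0, 1, 13)[1:-1])
        bin_of_cell = np.empty(w.size, dtype=int)
        start = 0
        for k, e in enumerate(list(edges) + [w.size]):
            bin_of_cell[order[start:e]] = k
            start = e
        observed = np.bincount(bin_of_cell[flat], minlength=12)
        expected = np.bincount(bin_of_cell, weights=w, minlength=12) * 4000
        keep = expected > 5
        stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = scipy.stats.chi2.sf(stat, keep.sum() - 1)
        assert pval > 0.01


class TestEstimationError:
    def test_zero_for_exact_match(self, two_bundle):
        density, _ = two_bundle
        assert estimation_error(density.values, density) == 0.0

    def test_uniform_offset_closed_form(self, ico2_basis):
        m = ico2_basis.mass
        vol = m.sum()
        base = np.zeros((m.size, m.size))
        delta = 0.37
        err = estimation_error(base + delta, base, mass=m)
        assert err == pytest.approx(delta * vol, rel=1e-12)

    def test_matches_double_loop_oracle(self, ico2_basis, rng):
        m = ico2_basis.mass
        a = rng.standard_normal((m.size, m.size))
        b = rng.standard_normal((m.size, m.size))
        direct = np.sqrt(
            sum(
                (a[i, j] - b[i, j]) ** 2 * m[i] * m[j]
                for i in range(m.size)
                for j in range(m.size)
            )
        )
        assert estimation_error(a, b, mass=m) == pytest.approx(direct, rel=1e-10)


@pytest.fixture(scope="module")
def consistency_result(two_bundle, kernel_trio):
    density, _ = two_bundle
    return consistency_experiment(
        density, kernel_trio, [25, 50, 100, 200, 400], replicates=20, seed=11
    )


class TestConsistency:
    def test_error_decreases_with_sample_size(self, consistency_result):
        """Mean error falls with N for every kernel (2-SE slack)."""
        result = consistency_result
        means = result.mean_errors()
        ses = result.standard_errors()
        for ki in range(len(result.kernel_labels)):
            for i in range(len(result.sample_sizes) - 1):
                slack = 2.0 * np.hypot(ses[ki, i], ses[ki, i + 1])
                assert means[ki, i + 1] < means[ki, i] + slack

    def test_large_n_beats_smallest(self, two_bundle, kernel_trio):
        density, _ = two_bundle
        res = consistency_experiment(
            density, kernel_trio, [25, 10000], replicates=3, seed=5
        )
        means = res.mean_errors()
        assert (means[:, 1] < means[:, 0]).all()

    def test_diffusion_lowest_error_at_small_n(self, consistency_result):
        """On the packaged scenario the diffusion kernel wins at small N."""
        result = consistency_result
        means = result.mean_errors()
        small = means[:, :3].mean(axis=1)  # N <= 100
        labels = result.kernel_labels
        assert labels[int(np.argmin(small))] == "diffusion"

    def test_fixed_seed_reproduces_table(self, two_bundle, kernel_trio, consistency_result):
        density, _ = two_bundle
        result = consistency_result
        res2 = consistency_experiment(
            density, kernel_trio, [25, 50, 100, 200, 400], replicates=20, seed=11
        )
        np.testing.assert_array_equal(res2.errors, result.errors)


@pytest.fixture(scope="module")
def kernel(ico2_basis):
    return sc.spectral_kernel(ico2_basis, sc.KernelSpec("diffusion", 0.5))


@pytest.fixture(scope="module")
def mixture(ico2_basis):
    from surfconn.simulate import default_two_bundle_mixture

    _, mix = default_two_bundle_mixture(ico2_basis)
    return mix


class TestScanCollection:
    def test_no_subject_effect_gives_low_dicc(self, ico2_basis, mixture, kernel):
        scans, _ = make_scan_collection(
            ico2_basis, mixture, kernel,
            n_subjects=10, n_repeats=2, subject_effect=0.0,
            n_streamlines=150, seed=3,
        )
        assert abs(dicc(ScanCollection(scans))) < 0.25

    def test_large_subject_effect_gives_high_dicc(self, ico2_basis, mixture, kernel):
        scans, _ = make_scan_collection(
            ico2_basis, mixture, kernel,
            n_subjects=8, n_repeats=2, subject_effect=1.0,
            n_streamlines=2000, seed=3,
        )
        assert dicc(ScanCollection(scans)) > 0.8

    def test_seed_determinism(self, ico2_basis, mixture, kernel):
        a, _ = make_scan_collection(
            ico2_basis, mixture, kernel,
            n_subjects=3, n_repeats=2, subject_effect=0.5,
            n_streamlines=50, seed=21,
        )
        b, _ = make_scan_collection(
            ico2_basis, mixture, kernel,
            n_subjects=3, n_repeats=2, subject_effect=0.5,
            n_streamlines=50, seed=21,
        )
        for sa, sb in zip(a, b):
            for pa, pb in zip(sa, sb):
                np.testing.assert_array_equal(pa.values, pb.values)
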