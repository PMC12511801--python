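import numpy as np
import pytest
import scipy.special
from hypothesis import given, settings
from hypothesis import strategies as st

import surfconn as sc
from surfconn.kernels import (
    KAPPA_MAX,
    KAPPA_MIN,
    SIGMA_MAX,
    SIGMA_MIN,
    load_kernel,
    save_kernel,
)


class TestTruncation:
    def test_paper_endpoints(self):
        assert sc.shk_truncation(0.0001) == 368
        assert sc.shk_truncation(0.05) == 14

    def test_matches_linear_scan_oracle(self):
        sigma, tol = 0.01, 0.001
        j = 1
        while (2 * j + 1) * np.exp(-j * (j + 1) * sigma) >= tol:
            j += 1
        assert sc.shk_truncation(sigma, tol) == j

    def test_monotone_in_sigma(self):
        grid = sc.bandwidth_grid("spherical_heat")
        js = [sc.shk_truncation(s) for s in grid]
        assert all(a >= b for a, b in zip(js, js[1:]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sc.shk_truncation(0.0)


class TestLegendre:
    def test_base_cases(self):
        assert sc.legendre(0, 0.3) == 1.0
        assert sc.legendre(1, -0.25) == -0.25
        assert sc.legendre(2, 0.0) == pytest.approx(-0.5)

    @pytest.mark.parametrize("j", [0, 1, 5, 17])
    def test_value_one_at_one(self, j):
        assert sc.legendre(j, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.uniform(-1, 1, 50)
        for j in (2, 7, 30):
            np.testing.assert_allclose(
                sc.legendre(j, x), scipy.special.eval_legendre(j, x), atol=1e-10
            )

    @settings(deadline=None, max_examples=30)
    @given(
        j=st.integers(min_value=0, max_value=60),
        x=st.floats(min_value=-1.0, max_value=1.0),
    )
    def test_bounded_by_one(self, j, x):
        assert abs(sc.legendre(j, x)) <= 1.0 + 1e-9

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sc.legendre(3, 1.5)


class TestSHKMatrix:
    def test_symmetry_and_rotation_invariance(self, ico2, rng):
        u = ico2.vertices
        K = sc.shk_matrix(u, 0.05).values
        np.testing.assert_array_equal(K, K.T)
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        K2 = sc.shk_matrix(u @ Q.T, 0.05).values
        assert np.abs(K - K2).max() < 1e-10

    def test_rejects_non_unit_vectors(self):
        with pytest.raises(ValueError, match="unit norm"):
            sc.shk_matrix(np.array([[1.0, 0, 0], [2.0, 0, 0]]), 0.01)

    def test_mass_weighted_rows_integrate_to_one(self, ico3, ico3_basis):
        K = sc.shk_matrix(ico3.vertices, 0.05).values
        rows = K @ ico3_basis.mass
        assert np.abs(rows - 1.0).max() < 0.01


class TestSpectralKernel:
    @pytest.mark.parametrize(
        "spec",
        [
            sc.KernelSpec("diffusion", 1.3),
            sc.KernelSpec("matern", 1.3, smoothness=2.5),
        ],
    )
    def test_unit_mass_row_sums(self, ico3_basis, spec):
        K = sc.spectral_kernel(ico3_basis, spec)
        rows = K.values @ ico3_basis.mass
        assert np.abs(rows - 1.0).max() < 1e-8
        np.testing.assert_array_equal(K.values, K.values.T)

    def test_large_bandwidth_collapses_to_constant(self, ico3_basis):
        K = sc.spectral_kernel(ico3_basis, sc.KernelSpec("diffusion", 1e3))
        vol = ico3_basis.mass.sum()
        assert np.abs(K.values - 1.0 / vol).max() < 1e-6

    def test_positive_semidefinite_weights(self, ico3_basis):
        for spec in (
            sc.KernelSpec("diffusion", 0.7),
            sc.KernelSpec("matern", 0.7, smoothness=1.5),
        ):
            K = sc.spectral_kernel(ico3_basis, spec)
            F = ico3_basis.eigenvectors
            m = ico3_basis.mass
            proj = F.T @ (m[:, None] * K.values * m[None, :]) @ F
            # projected form is diagonal with the nonnegative spectral weights
            np.linalg.cholesky(proj + 1e-12 * np.eye(proj.shape[0]))

    def test_sign_flip_invariance(self, ico2_basis, rng):
        flips = rng.choice([-1.0, 1.0], size=ico2_basis.truncation)
        flipped = sc.SpectralBasis(
            eigenvalues=ico2_basis.eigenvalues,
            eigenvectors=ico2_basis.eigenvectors * flips[None, :],
            mass=ico2_basis.mass,
        )
        spec = sc.KernelSpec("diffusion", 0.9)
        K1 = sc.spectral_kernel(ico2_basis, spec).values
        K2 = sc.spectral_kernel(flipped, spec).values
        assert np.abs(K1 - K2).max() < 1e-12

    def test_matern_requires_smoothness(self):
        with pytest.raises(ValueError, match="smoothness"):
            sc.KernelSpec("matern", 1.0)

    def test_raw_normalization_differs(self, ico2_basis):
        raw = sc.spectral_kernel(
            ico2_basis, sc.KernelSpec("matern", 1.0, smoothness=2.0, normalization="raw")
        )
        unit = sc.spectral_kernel(
            ico2_basis, sc.KernelSpec("matern", 1.0, smoothness=2.0)
        )
        phi0 = (2 * 2.0 / 1.0) ** (-3.0)
        np.testing.assert_allclose(raw.values, unit.values * phi0, rtol=1e-10)


def test_sphere_identity_diffusion_vs_shk(ico5_basis):
    """On S², the diffusion kernel with κ²/2 = σ equals the spherical heat
    kernel (addition theorem); residual is FEM eigen-error only."""
    mesh, basis = ico5_basis
    sigma = 0.05
    Kd = sc.spectral_kernel(basis, sc.KernelSpec("diffusion", np.sqrt(2 * sigma)))
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    Ks = sc.shk_matrix(u, sigma)
    rel = np.abs(Kd.values - Ks.values).max() / np.abs(Ks.values).max()
    assert rel < 0.02


def test_matern_limit_is_monotone():
    devs = sc.matern_limit_check(2.0, 1.0, [1, 10, 100, 1e4])
    assert (np.diff(devs) < 0).all()
    assert devs[-1] < 1e-3
    assert sc.matern_limit_check(0.0, 1.0, [1, 10])[0] == 0.0


class TestBlockKernel:
    def test_block_structure(self, ico2_basis):
        spec = sc.KernelSpec("diffusion", 0.8)
        KL = sc.spectral_kernel(ico2_basis, spec)
        KR = sc.spectral_kernel(ico2_basis, spec)
        K = sc.block_kernel(KL, KR)
        n = ico2_basis.n_vertices
        assert K.values.shape == (2 * n, 2 * n)
        assert np.abs(K.values[:n, n:]).max() == 0.0
        np.testing.assert_array_equal(K.values, K.values.T)
        assert K.block_sizes == (n, n)

    def test_spec_mismatch_rejected(self, ico2_basis):
        KL = sc.spectral_kernel(ico2_basis, sc.KernelSpec("diffusion", 0.8))
        KR = sc.spectral_kernel(ico2_basis, sc.KernelSpec("diffusion", 0.9))
        with pytest.raises(ValueError, match="match"):
            sc.block_kernel(KL, KR)


class TestBandwidthGrid:
    def test_endpoints(self):
        kg = sc.bandwidth_grid("diffusion")
        assert kg[0] == pytest.approx(KAPPA_MIN) and kg[-1] == pytest.approx(KAPPA_MAX)
        sg = sc.bandwidth_grid("spherical_heat")
        assert sg[0] == pytest.approx(SIGMA_MIN) and sg[-1] == pytest.approx(SIGMA_MAX)
        assert len(kg) == len(sg) == 10

    def test_log_spacing_constant_ratio(self):
        g = sc.bandwidth_grid("matern")
        ratios = g[1:] / g[:-1]
        assert np.abs(ratios - ratios[0]).max() < 1e-12

    def test_linear_spacing_option(self):
        g = sc.bandwidth_grid("spherical_heat", spacing="linear")
        np.testing.assert_allclose(np.diff(g), np.diff(g)[0], rtol=1e-9)


def test_kernel_hdf5_roundtrip(tmp_path, ico2_basis):
    K = sc.spectral_kernel(ico2_basis, sc.KernelSpec("matern", 1.1, smoothness=2.0))
    path = str(tmp_path / "K.h5")
    save_kernel(K, path)
    back = load_kernel(path)
    np.testing.assert_array_equal(back.values, K.values)
    assert back.spec == K.spec
    assert back.block_sizes == K.block_sizes
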