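"""LS / SCLS / FCLS unmixing against closed-form and exhaustive oracles."""

import numpy as np
import pytest
import scipy.optimize

from swirphantom import (
    ConcentrationPanelsScene,
    EndmemberMatrix,
    Optics,
    fcls_unmix,
    ls_unmix,
    scls_unmix,
    select_endmembers_from_image,
    simulate_concentration_panels,
    unmix_cube,
)
from swirphantom.errors import DimensionMismatchError, SingularDesignError

from conftest import simplex_grid_search


def random_endmembers(rng, L=12, p=3):
    return rng.uniform(0.05, 1.0, size=(L, p))


def scls_kkt_oracle(r, M):
    """Equality-constrained QP via the raw KKT system (Lagrange multiplier)."""
    p = M.shape[1]
    G = M.T @ M
    kkt = np.block([[2 * G, np.ones((p, 1))], [np.ones((1, p)), np.zeros((1, 1))]])
    rhs = np.concatenate([2 * M.T @ r, [1.0]])
    return np.linalg.solve(kkt, rhs)[:p]


def nnls_sum_to_one_oracle(r, M, delta=1e4):
    """FCLS cross-check: nonnegative LS on the sum-to-one-augmented system."""
    A = np.vstack([M, delta * np.ones(M.shape[1])])
    b = np.concatenate([r, [delta]])
    alpha, _ = scipy.optimize.nnls(A, b)
    return alpha


class TestLsUnmix:
    def test_pure_endmember_recovered(self, rng):
        M = random_endmembers(rng)
        out = ls_unmix(M[:, 1], M)
        np.testing.assert_allclose(out.alpha, [0, 1, 0], atol=1e-10)
        assert out.residual == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_mixture_recovered(self, rng):
        M = random_endmembers(rng, p=2)
        out = ls_unmix(0.3 * M[:, 0] + 0.7 * M[:, 1], M)
        np.testing.assert_allclose(out.alpha, [0.3, 0.7], atol=1e-10)

    def test_orthogonal_spectrum_gives_zero(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        out = ls_unmix(np.array([0.0, 0.0, 5.0]), M)
        np.testing.assert_allclose(out.alpha, [0.0, 0.0], atol=1e-12)

    def test_matches_normal_equations(self, rng):
        M = random_endmembers(rng, L=20, p=4)
        r = rng.random(20)
        expected = np.linalg.solve(M.T @ M, M.T @ r)
        np.testing.assert_allclose(ls_unmix(r, M).alpha, expected, atol=1e-10)

    def test_collinear_columns_rejected(self):
        col = np.linspace(0.1, 1.0, 8)
        with pytest.raises(SingularDesignError):
            ls_unmix(np.ones(8), np.column_stack([col, 2 * col]))


class TestSclsUnmix:
    def test_sum_to_one_always_holds(self, rng):
        for _ in range(20):
            M = random_endmembers(rng, p=rng.integers(2, 5))
            out = scls_unmix(rng.random(12), M)
            assert abs(out.alpha.sum() - 1.0) < 1e-9

    def test_already_normalized_ls_unchanged(self, rng):
        M = random_endmembers(rng, p=2)
        r = 0.4 * M[:, 0] + 0.6 * M[:, 1]
        np.testing.assert_allclose(scls_unmix(r, M).alpha, ls_unmix(r, M).alpha, atol=1e-9)

    def test_matches_kkt_oracle(self, rng):
        for _ in range(30):
            M = random_endmembers(rng, L=15, p=int(rng.integers(2, 5)))
            r = rng.random(15)
            np.testing.assert_allclose(
                scls_unmix(r, M).alpha, scls_kkt_oracle(r, M), atol=1e-8
            )


class TestFclsUnmix:
    def test_vertex_spectrum_maps_to_vertex(self, rng):
        M = random_endmembers(rng)
        out = fcls_unmix(M[:, 0], M)
        np.testing.assert_allclose(out.alpha, [1, 0, 0], atol=1e-8)

    def test_negative_scls_coordinate_clamped(self, rng):
        # construct r beyond the m1 vertex so SCLS goes negative on m2
        M = random_endmembers(rng, p=2)
        r = 1.2 * M[:, 0] - 0.2 * M[:, 1]
        assert scls_unmix(r, M).alpha.min() < 0
        out = fcls_unmix(r, M)
        np.testing.assert_allclose(out.alpha, [1.0, 0.0], atol=1e-9)

    def test_simplex_constraints_on_random_inputs(self, rng):
        for _ in range(200):
            p = int(rng.integers(2, 5))
            M = random_endmembers(rng, p=p)
            out = fcls_unmix(rng.random(12) * 2, M)
            assert np.all(out.alpha >= 0)
            assert abs(out.alpha.sum() - 1.0) < 1e-9

    def test_interior_noiseless_recovery(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 5))
            M = random_endmembers(rng, p=p)
            alpha0 = rng.dirichlet(np.full(p, 2.0))
            out = fcls_unmix(M @ alpha0, M)
            np.testing.assert_allclose(out.alpha, alpha0, atol=1e-8)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(15):
            p = int(rng.integers(2, 4))
            M = random_endmembers(rng, L=6, p=p)
            r = rng.random(6) * 1.5
            out = fcls_unmix(r, M)
            best, best_obj = simplex_grid_search(r, M, step=1e-3)
            assert np.max(np.abs(out.alpha - best)) < 2e-3
            assert out.residual <= best_obj + 1e-6

    def test_matches_nnls_cross_check(self, rng):
        for _ in range(20):
            p = int(rng.integers(2, 5))
            M = random_endmembers(rng, p=p)
            r = rng.random(12) * 1.5
            np.testing.assert_allclose(
                fcls_unmix(r, M).alpha, nnls_sum_to_one_oracle(r, M), atol=1e-6
            )

    def test_endmember_permutation_equivariance(self, rng):
        M = random_endmembers(rng, p=4)
        r = rng.random(12)
        perm = rng.permutation(4)
        np.testing.assert_allclose(
            fcls_unmix(r, M[:, perm]).alpha, fcls_unmix(r, M).alpha[perm], atol=1e-9
        )

    def test_scls_equals_fcls_when_nonnegative(self, rng):
        for _ in range(30):
            M = random_endmembers(rng, p=3)
            alpha0 = rng.dirichlet(np.ones(3)) * 0.9 + 0.03
            r = M @ alpha0 + rng.normal(0, 1e-4, 12)
            s = scls_unmix(r, M)
            if np.all(s.alpha >= 0):
                np.testing.assert_allclose(fcls_unmix(r, M).alpha, s.alpha, atol=1e-8)


class TestUnmixCube:
    def test_noiseless_panels_recover_true_abundance(self):
        sc = ConcentrationPanelsScene(panel_shape=(4, 4), optics=Optics(noise_sigma=0.0))
        cube, gt = simulate_concentration_panels(sc)
        lo, hi = sc.endpoint_spectra()
        M = EndmemberMatrix(
            M=np.column_stack([lo.reflectance, hi.reflectance]), names=("lo", "hi")
        )
        planes = unmix_cube(cube, M, model="FCLS")
        np.testing.assert_allclose(planes, gt.abundance, atol=1e-6)

    def test_fcls_planes_on_simplex_everywhere(self, rng):
        sc = ConcentrationPanelsScene(panel_shape=(5, 5), seed=1)
        cube, _ = simulate_concentration_panels(sc)
        lo, hi = sc.endpoint_spectra()
        M = EndmemberMatrix(
            M=np.column_stack([lo.reflectance, hi.reflectance]), names=("lo", "hi")
        )
        planes = unmix_cube(cube, M, model="FCLS")
        assert planes.min() >= 0
        np.testing.assert_allclose(planes.sum(axis=-1), 1.0, atol=1e-9)

    def test_pure_endmember_cube_gives_unit_plane(self, rng):
        from swirphantom import SpectralCube

        M = random_endmembers(rng, L=8, p=2)
        cube = SpectralCube(
            data=np.tile(M[:, 0].astype(np.float32), (3, 3, 1)),
            wavelengths=np.arange(8, dtype=float),
        )
        planes = unmix_cube(cube, EndmemberMatrix(M=M, names=("a", "b")), model="FCLS")
        np.testing.assert_allclose(planes[:, :, 0], 1.0, atol=1e-6)
        np.testing.assert_allclose(planes[:, :, 1], 0.0, atol=1e-6)

    def test_band_mismatch_rejected(self, rng, random_cube):
        M = EndmemberMatrix(M=random_endmembers(rng, L=8, p=2), names=("a", "b"))
        with pytest.raises(DimensionMismatchError):
            unmix_cube(random_cube(2, 2, 7), M)


class TestSelectEndmembers:
    def test_constant_region_returns_its_spectrum(self):
        sc = ConcentrationPanelsScene(panel_shape=(3, 3), optics=Optics(noise_sigma=0.0))
        cube, _ = simulate_concentration_panels(sc)
        lo, hi = sc.endpoint_spectra()
        M = select_endmembers_from_image(cube, [np.s_[:, 0:3], np.s_[:, 9:12]])
        np.testing.assert_allclose(M.M[:, 0], lo.reflectance, rtol=1e-6)
        np.testing.assert_allclose(M.M[:, 1], hi.reflectance, rtol=1e-6)

    def test_single_pixel_regions(self, random_cube):
        cube = random_cube(4, 4, 8)
        M = select_endmembers_from_image(cube, [np.s_[0:1, 0:1], np.s_[3:4, 3:4]])
        np.testing.assert_allclose(M.M[:, 0], cube.data[0, 0], rtol=1e-6)
        np.testing.assert_allclose(M.M[:, 1], cube.data[3, 3], rtol=1e-6)

    def test_region_mean_beats_single_pixel_variance(self):
        # mean-spectrum estimator has lower spread across noise seeds
        lo_errors, px_errors = [], []
        for seed in range(30):
            sc = ConcentrationPanelsScene(panel_shape=(6, 6), seed=seed)
            cube, _ = simulate_concentration_panels(sc)
            truth = sc.endpoint_spectra()[0].reflectance
            region_mean = cube.data[:, 0:6, :].reshape(-1, cube.n_bands).mean(axis=0)
            lo_errors.append(np.linalg.norm(region_mean - truth))
            px_errors.append(np.linalg.norm(cube.data[0, 0] - truth))
        assert np.mean(lo_errors) < np.mean(px_errors)

    def test_empty_region_rejected(self, random_cube):
        with pytest.raises(ValueError):
            select_endmembers_from_image(random_cube(), [np.s_[0:0, 0:0], np.s_[0:1, 0:1]])
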