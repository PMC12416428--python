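"""Shape/texture tensors, log strains and interfacial (Batchelor) stress."""

import numpy as np
import pytest

from foam3d import mechanics
from foam3d.mechanics import (
    DegenerateTensorError,
    batchelor_stress,
    shape_strain,
    shape_tensor,
    texture_strain,
    texture_tensor,
)

from conftest import rasterize_ellipsoid, rasterize_sphere

AXIS_LINKS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def ellipsoid_stress_oracle(a, b, c, volume, n_quad=2000):
    """Dense quadrature of the tension dyad over an analytic ellipsoid."""
    t = np.linspace(0, np.pi, n_quad)
    p = np.linspace(0, 2 * np.pi, n_quad)
    T, P = np.meshgrid(t, p, indexing="ij")
    rt = np.stack(
        [-a * np.sin(T), b * np.cos(T) * np.cos(P), c * np.cos(T) * np.sin(P)], -1
    )
    rp = np.stack(
        [np.zeros_like(T), -b * np.sin(T) * np.sin(P), c * np.sin(T) * np.cos(P)], -1
    )
    cr = np.cross(rt, rp)
    dA = np.linalg.norm(cr, axis=-1)
    n = np.where(dA[..., None] > 1e-12, cr / np.maximum(dA, 1e-12)[..., None], 0.0)
    w = dA * (t[1] - t[0]) * (p[1] - p[0])
    integ = np.eye(3) * w.sum() / 3 - np.einsum("tp,tpi,tpj->ij", w, n, n)
    return integ / volume


class TestShapeTensor:
    def test_cube_27_voxels(self):
        coords = np.argwhere(np.ones((3, 3, 3)))
        centroid, S = shape_tensor(coords)
        assert np.allclose(centroid, [1, 1, 1])
        assert np.allclose(S, (2.0 / 3.0) * np.eye(3))

    def test_single_voxel(self):
        _, S = shape_tensor([[4, 4, 4]])
        assert np.allclose(S, 0)

    def test_ellipsoid_second_moments(self):
        axes = (18.0, 12.0, 8.0)
        mask = rasterize_ellipsoid((44, 44, 44), (22, 22, 22), axes)
        _, S = shape_tensor(np.argwhere(mask))
        expected = np.array([a**2 / 5.0 for a in axes])
        got = np.sort(np.linalg.eigvalsh(S))[::-1]
        assert np.all(np.abs(got - expected) / expected < 0.03)


class TestShapeStrain:
    def test_isotropic_tensor_gives_zero(self):
        assert np.allclose(shape_strain(3.7 * np.eye(3)), 0)

    def test_stretched_sphere_recovers_log_strain(self):
        eps = np.log(1.2)
        R = 16.0
        axes = (1.2 * R, R / np.sqrt(1.2), R / np.sqrt(1.2))
        mask = rasterize_ellipsoid((80, 80, 80), (40, 40, 40), axes)
        _, S = shape_tensor(np.argwhere(mask))
        U = shape_strain(S)
        got = np.sort(np.linalg.eigvalsh(U))[::-1]
        expected = np.array([eps, -eps / 2, -eps / 2])
        assert np.all(np.abs(got - expected) / np.abs(expected) < 0.05)
        assert abs(np.trace(U)) < 1e-10

    def test_rotation_equivariance(self):
        # right-angle rotation (z,y,x) -> (y,z,x) permutes the voxel set exactly
        mask = rasterize_ellipsoid((40, 40, 40), (20, 20, 20), (14, 9, 6))
        coords = np.argwhere(mask)
        P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        _, S = shape_tensor(coords)
        _, S_rot = shape_tensor(coords @ P.T)
        assert np.allclose(S_rot, P @ S @ P.T)
        assert np.allclose(shape_strain(S_rot), P @ shape_strain(S) @ P.T)

    def test_singular_tensor_flagged(self):
        with pytest.raises(DegenerateTensorError):
            shape_strain(np.diag([1.0, 1.0, 0.0]))


class TestTextureTensor:
    def test_six_axis_links(self):
        d = 7.0
        M = texture_tensor([0, 0, 0], d * AXIS_LINKS)
        assert np.allclose(M, (d**2 / 3.0) * np.eye(3))

    def test_single_link(self):
        M = texture_tensor([0, 0, 0], [[5.0, 0, 0]])
        assert np.allclose(M, np.diag([25.0, 0, 0]))

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        nbrs = rng.normal(size=(8, 3))
        M1 = texture_tensor([0, 0, 0], nbrs)
        M2 = texture_tensor([0, 0, 0], 2 * nbrs)
        assert np.allclose(M2, 4 * M1)


class TestTextureStrain:
    def test_isotropic_gives_zero(self):
        assert np.allclose(texture_strain(2.2 * np.eye(3)), 0)

    def test_closed_form_eigenvalues(self):
        U = texture_strain(np.diag([4.0, 1.0, 1.0]) * 3.3)
        lam = np.log([4.0, 1.0, 1.0])
        expected = 0.5 * (lam - lam.mean())
        assert np.allclose(np.sort(np.linalg.eigvalsh(U)), np.sort(expected))
        assert abs(np.trace(U)) < 1e-10

    def test_affine_deformed_lattice_recovers_log_strain(self):
        eps = np.log(1.2)
        F = np.diag([1.2, 1.2**-0.5, 1.2**-0.5])
        links = 10.0 * AXIS_LINKS
        M = texture_tensor([0, 0, 0], (F @ links.T).T)
        U = texture_strain(M)
        got = np.sort(np.linalg.eigvalsh(U))[::-1]
        expected = np.array([eps, -eps / 2, -eps / 2])
        assert np.all(np.abs(got - expected) / np.abs(expected) < 0.05)


class TestBatchelorStress:
    def test_sphere_is_nearly_stress_free(self):
        R = 12
        labels = rasterize_sphere((32, 32, 32), (16, 16, 16), R).astype(np.int32)
        rec = batchelor_stress(labels, 1, gamma=1.0)
        assert np.linalg.norm(rec.sigma) <= 0.03 * 1.0 / R
        assert abs(np.trace(rec.sigma)) < 1e-6 * max(np.linalg.norm(rec.sigma), 1e-30)

    def test_prolate_ellipsoid_matches_quadrature_oracle(self):
        a, b = 36.0, 18.0
        mask = rasterize_ellipsoid((90, 50, 50), (45, 25, 25), (a, b, b))
        rec = batchelor_stress(mask.astype(np.int32), 1, gamma=1.0)
        oracle = ellipsoid_stress_oracle(a, b, b, volume=mask.sum())
        err = np.linalg.norm(rec.sigma - oracle) / np.linalg.norm(oracle)
        assert err < 0.02
        # uniaxial tension along the long (z) axis
        evals = np.linalg.eigvalsh(rec.sigma)
        assert evals[-1] > 0 and np.allclose(evals[0], evals[1], rtol=0.05)
        axis = np.linalg.eigh(rec.sigma).eigenvectors[:, -1]
        assert abs(axis[0]) > 0.999

    def test_linear_in_surface_tension(self):
        labels = rasterize_sphere((28, 28, 28), (14, 14, 14), 9).astype(np.int32)
        s1 = batchelor_stress(labels, 1, gamma=1.0).sigma
        s2 = batchelor_stress(labels, 1, gamma=2.0).sigma
        assert np.allclose(s2, 2 * s1)

    def test_sphere_residual_decreases_with_radius(self):
        norms = []
        for R in (8, 12, 16, 24):
            m = 2 * R + 8
            labels = rasterize_sphere((m, m, m), (m / 2,) * 3, R).astype(np.int32)
            norms.append(np.linalg.norm(batchelor_stress(labels, 1).sigma))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_edge_touching_bubble_rejected(self):
        labels = rasterize_sphere((24, 24, 24), (2, 12, 12), 6).astype(np.int32)
        with pytest.raises(ValueError, match="edge-bubble removal"):
            batchelor_stress(labels, 1)

    def test_rotation_equivariance_by_permutation(self):
        mask = rasterize_ellipsoid((60, 40, 40), (30, 20, 20), (22, 11, 11))
        labels = mask.astype(np.int32)
        rotated = np.transpose(labels, (1, 0, 2))  # swap z and y axes
        P = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        s = batchelor_stress(labels, 1).sigma
        s_rot = batchelor_stress(rotated, 1).sigma
        # the marching-cubes triangulation is not exactly symmetric under
        # axis transposition; conjugation holds to far below the mesh error
        assert np.abs(s_rot - P @ s @ P.T).max() < 1e-4 * np.linalg.norm(s)


def test_texture_table_on_packing(grid_packing, grid_regions):
    from foam3d import contacts

    _, labels, _, _ = grid_packing
    net = contacts.get_contacts(labels, dilation=2)
    table = mechanics.texture_table(grid_regions, net.topology)
    assert len(table) == 27
    inner = table[table.n_links == 6]
    assert len(inner) == 1  # the central bubble of the 3x3x3 lattice
    # lattice links are near-axis-aligned and equal: texture nearly isotropic
    row = inner.iloc[0]
    U = np.array([
        [row.UM_zz, row.UM_zy, row.UM_zx],
        [row.UM_zy, row.UM_yy, row.UM_yx],
        [row.UM_zx, row.UM_yx, row.UM_xx],
    ])
    assert np.abs(np.linalg.eigvalsh(U)).max() < 0.05
    assert abs(U.trace()) < 1e-10
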