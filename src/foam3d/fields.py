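"""Spatial averaging of per-bubble quantities and coordinate passage.

Grid averaging turns positioned scalars, vectors or tensors into Cartesian
gridded fields (componentwise arithmetic mean per cell).  The passage
helpers convert points, vectors and tensors between the Cartesian (z, y, x)
frame and cylindrical or spherical frames by conjugation with the local
orthonormal basis; tensor invariants are preserved to machine precision and
the round trip is the identity.

Conventions: the cylindrical axis is the z axis through a caller-chosen
origin; the azimuth theta is measured from +x toward +y.  Cylindrical
component order is (r, theta, z); spherical is (r, theta, phi) with theta
the polar angle from +z and phi the azimuth.
"""

from __future__ import annotations

import numpy as np

from .structure import GriddedField, GridSpec, _cell_index


def grid_average(
    positions: np.ndarray,
    values: np.ndarray,
    grid: GridSpec,
    min_count: int = 1,
) -> GriddedField:
    """Componentwise per-cell mean of positioned records.

    ``positions`` is (N, 3) in voxel coordinates; ``values`` is (N, ...)
    with any trailing component shape (scalar, vector, flattened tensor).
    Cells with fewer than ``min_count`` contributors are NaN; the
    contributor counts are returned alongside.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values):
        raise ValueError("positions and values must align")
    if np.any(positions < 0) or np.any(positions >= np.asarray(grid.extent)):
        raise ValueError("positions must lie within the grid extent")
    n_cells = grid.n_cells
    n_flat = int(np.prod(n_cells))
    cell = (
        (positions[:, 0].astype(int) // grid.cell_shape[0]) * (n_cells[1] * n_cells[2])
        + (positions[:, 1].astype(int) // grid.cell_shape[1]) * n_cells[2]
        + (positions[:, 2].astype(int) // grid.cell_shape[2])
    )
    counts = np.bincount(cell, minlength=n_flat)
    comp_shape = values.shape[1:]
    flat_vals = values.reshape(len(values), -1)
    sums = np.zeros((n_flat, flat_vals.shape[1]))
    for k in range(flat_vals.shape[1]):
        sums[:, k] = np.bincount(cell, weights=flat_vals[:, k], minlength=n_flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / np.maximum(counts, 1)[:, None]
    means[counts < min_count] = np.nan
    return GriddedField(
        values=means.reshape(n_cells + comp_shape),
        counts=counts.reshape(n_cells),
        full=grid.full_cells(),
    )


def _cyl_basis(points: np.ndarray, origin) -> tuple[np.ndarray, np.ndarray]:
    """Per-point rotation Q with rows (e_r, e_theta, e_z) in (z,y,x) comps."""
    pts = np.asarray(points, dtype=float)
    oz, oy, ox = origin
    y = pts[:, 1] - oy
    x = pts[:, 2] - ox
    r = np.hypot(x, y)
    on_axis = r < 1e-12
    theta = np.arctan2(y, x)
    cos, sin = np.cos(theta), np.sin(theta)
    Q = np.zeros((len(pts), 3, 3))
    Q[:, 0] = np.stack([np.zeros_like(cos), sin, cos], axis=1)   # e_r
    Q[:, 1] = np.stack([np.zeros_like(cos), cos, -sin], axis=1)  # e_theta
    Q[:, 2, 0] = 1.0                                             # e_z
    coords = np.stack([r, theta, pts[:, 0] - oz], axis=1)
    coords[on_axis, 1] = np.nan  # azimuth undefined on the axis
    return coords, Q


def _sph_basis(points: np.ndarray, origin) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    rel = pts - np.asarray(origin, dtype=float)
    z, y, x = rel[:, 0], rel[:, 1], rel[:, 2]
    r = np.linalg.norm(rel, axis=1)
    rho = np.hypot(x, y)
    theta = np.arctan2(rho, z)   # polar angle from +z
    phi = np.arctan2(y, x)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    Q = np.zeros((len(pts), 3, 3))
    Q[:, 0] = np.stack([ct, st * sp, st * cp], axis=1)            # e_r
    Q[:, 1] = np.stack([-st, ct * sp, ct * cp], axis=1)           # e_theta
    Q[:, 2] = np.stack([np.zeros_like(ct), cp, -sp], axis=1)      # e_phi
    coords = np.stack([r, theta, phi], axis=1)
    coords[rho < 1e-12, 2] = np.nan
    return coords, Q


def _convert(points, vectors, tensors, origin, basis):
    coords, Q = basis(points, origin)
    out = {"points": coords}
    if vectors is not None:
        out["vectors"] = np.einsum("nij,nj->ni", Q, np.asarray(vectors, float))
    if tensors is not None:
        out["tensors"] = np.einsum(
            "nij,njk,nlk->nil", Q, np.asarray(tensors, float), Q
        )
    out["basis"] = Q
    return out


def to_cylindrical(points, vectors=None, tensors=None, origin=(0.0, 0.0, 0.0)):
    """Convert points/vectors/tensors to the cylindrical frame.

    Points become (r, theta, z); vector and tensor components are expressed
    in the local (e_r, e_theta, e_z) basis.  On-axis points get NaN azimuth
    (flagged, not silently zeroed); their basis uses theta = 0.
    """
    return _convert(points, vectors, tensors, origin, _cyl_basis)


def from_cylindrical(points_cyl, vectors=None, tensors=None, origin=(0.0, 0.0, 0.0)):
    """Inverse passage; ``points_cyl`` rows are (r, theta, z)."""
    pc = np.asarray(points_cyl, dtype=float)
    r, theta, z = pc[:, 0], pc[:, 1], pc[:, 2]
    oz, oy, ox = origin
    pts = np.stack(
        [z + oz, r * np.sin(theta) + oy, r * np.cos(theta) + ox], axis=1
    )
    _, Q = _cyl_basis(pts, origin)
    out = {"points": pts}
    if vectors is not None:
        out["vectors"] = np.einsum("nji,nj->ni", Q, np.asarray(vectors, float))
    if tensors is not None:
        out["tensors"] = np.einsum(
            "nji,njk,nkl->nil", Q, np.asarray(tensors, float), Q
        )
    return out


def to_spherical(points, vectors=None, tensors=None, origin=(0.0, 0.0, 0.0)):
    """Spherical passage with the same conjugation contract as cylindrical."""
    return _convert(points, vectors, tensors, origin, _sph_basis)
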