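"""Structural parameters of a foam image.

Liquid fraction (global or on a Cartesian grid), per-bubble geometry with
shape and strain tensors, bubble-size statistics (mean and Sauter radii,
polydispersity) and the local-thickness field of either phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops

from . import io as _io
from . import mechanics


@dataclass(frozen=True)
class GridSpec:
    """Cartesian grid tiling an image extent.

    Partial cells at the upper edges are kept and flagged (``full=False``)
    rather than discarded.
    """

    cell_shape: tuple[int, int, int]
    extent: tuple[int, int, int]

    def __post_init__(self):
        if any(c < 1 for c in self.cell_shape):
            raise ValueError("cell_shape must be positive")

    @property
    def n_cells(self) -> tuple[int, int, int]:
        return tuple(
            -(-e // c) for e, c in zip(self.extent, self.cell_shape)
        )

    def full_cells(self) -> np.ndarray:
        """Boolean array marking cells fully inside the extent."""
        full = np.ones(self.n_cells, dtype=bool)
        for axis, (e, c) in enumerate(zip(self.extent, self.cell_shape)):
            if e % c:
                sl = [slice(None)] * 3
                sl[axis] = -1
                full[tuple(sl)] = False
        return full


@dataclass
class GriddedField:
    values: np.ndarray   # per-cell values, NaN where invalid
    counts: np.ndarray   # contributing voxel (or record) count per cell
    full: np.ndarray     # cell fully inside the extent


def _cell_index(shape, cell_shape):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    n_cells = tuple(-(-s // c) for s, c in zip(shape, cell_shape))
    idx = (
        (grids[0] // cell_shape[0]) * (n_cells[1] * n_cells[2])
        + (grids[1] // cell_shape[1]) * n_cells[2]
        + (grids[2] // cell_shape[2])
    )
    return idx, n_cells


def liquid_fraction(
    phase: np.ndarray,
    mask: np.ndarray | None = None,
    grid: GridSpec | None = None,
):
    """Liquid fraction: liquid voxels over valid voxels.

    Globally returns a scalar; with a :class:`GridSpec` returns a
    :class:`GriddedField` of per-cell fractions.  Cells with zero valid
    voxels carry NaN, not 0.
    """
    phase = np.asarray(phase)
    valid = np.ones(phase.shape, bool) if mask is None else mask.astype(bool)
    if grid is None:
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError("no valid voxels")
        return float((phase.astype(bool) & valid).sum() / n_valid)
    if tuple(grid.extent) != phase.shape:
        raise ValueError("grid extent does not match the phase map shape")
    idx, n_cells = _cell_index(phase.shape, grid.cell_shape)
    n_flat = int(np.prod(n_cells))
    counts = np.bincount(idx[valid].ravel(), minlength=n_flat)
    liquid = np.bincount(idx[valid & phase.astype(bool)].ravel(), minlength=n_flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(counts > 0, liquid / np.maximum(counts, 1), np.nan)
    return GriddedField(
        values=phi.reshape(n_cells),
        counts=counts.reshape(n_cells),
        full=grid.full_cells(),
    )


def region_properties(labels: np.ndarray, compute_tensors: bool = True) -> pd.DataFrame:
    """Per-bubble property table, one row per label in ascending order.

    Columns: label, centroid (z, y, x), volume V (voxels), equivalent radius
    R_V = (3V/4pi)^(1/3), and (optionally) the six components of the shape
    tensor S and of the shape strain U_S.  Bubbles whose shape tensor is
    singular (flat) are flagged ``degenerate`` with NaN strain.
    """
    labels = np.asarray(labels)
    props = regionprops(labels)
    if not props:
        raise ValueError("empty label map: no regions")
    rows = []
    for p in sorted(props, key=lambda p: p.label):
        V = int(p.area)
        row = {
            "label": int(p.label),
            "z": p.centroid[0],
            "y": p.centroid[1],
            "x": p.centroid[2],
            "V": V,
            "R_V": (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0),
        }
        if compute_tensors:
            _, S = mechanics.shape_tensor(p.coords)
            row.update(zip(_io.tensor_columns("S"), _io.flatten_tensor(S)))
            try:
                U = mechanics.shape_strain(S)
                row["degenerate"] = False
            except mechanics.DegenerateTensorError:
                U = np.full((3, 3), np.nan)
                row["degenerate"] = True
            row.update(zip(_io.tensor_columns("US"), _io.flatten_tensor(U)))
        rows.append(row)
    return pd.DataFrame(rows)


def radius_statistics(radii) -> tuple[float, float, float]:
    """Mean radius, Sauter radius and polydispersity of a bubble population.

    Accepts an array of radii or a region table with an ``R_V`` column.
    The Sauter radius ``R32 = <R^3>/<R^2>`` is weighted toward large
    bubbles and satisfies ``R32 >= <R>`` (power-mean inequality).  The
    polydispersity is ``p32 = R32/<R> - 1``, non-negative and zero exactly
    for a monodisperse population.
    """
    if isinstance(radii, pd.DataFrame):
        radii = radii["R_V"].to_numpy()
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty radius set")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    mean_r = r.mean()
    r32 = (r**3).mean() / (r**2).mean()
    p32 = r32 / mean_r - 1.0
    return float(mean_r), float(r32), float(p32)


def _ball_structure(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (z**2 + y**2 + x**2) <= radius**2 + 1e-9


def local_thickness(phase: np.ndarray, phase_of_interest: str = "liquid") -> np.ndarray:
    """Local thickness field by the maximal-inscribed-sphere definition.

    ``thickness(v)`` is the diameter ``2 r`` of the largest sphere fully
    inside the selected phase that contains voxel ``v`` (a sphere of radius
    ``r`` centered at ``w`` covers the voxels with ``|v - w| <= r``, with
    ``r`` the Euclidean distance transform at ``w``).  Zero outside the
    phase.  Computed by dilating the distance-transform level sets in
    decreasing radius order, which is exact under the above convention.
    """
    phase = np.asarray(phase)
    if phase_of_interest == "liquid":
        region = phase.astype(bool)
    elif phase_of_interest == "gas":
        region = ~phase.astype(bool)
    else:
        raise ValueError("phase_of_interest must be 'liquid' or 'gas'")
    if not region.any():
        raise ValueError(f"selected phase {phase_of_interest!r} is empty")
    dt = ndimage.distance_transform_edt(region)
    out = np.zeros(phase.shape, dtype=float)
    for r in np.unique(dt[region])[::-1]:
        seeds = dt == r
        covered = ndimage.binary_dilation(seeds, structure=_ball_structure(r))
        newly = covered & region & (out == 0)
        out[newly] = 2.0 * r
    return out
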