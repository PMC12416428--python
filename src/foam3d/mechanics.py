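"""Per-bubble elastic strain proxies and interfacial stress.

A bubble in a jammed foam behaves like a 3D spring: its elastic stress is
tied to the anisotropy of its deformation.  Three measures are provided.

Shape route.  The shape tensor ``S = <(r - rbar)(r - rbar)^T>`` is the
second-moment tensor of the bubble voxels about the centroid.  The strain
``U_S`` is the Hencky (logarithmic) deviation of S from the isotropic state
``S0 = (l1 l2 l3)^(1/3) Id`` built from the geometric mean of the
eigenvalues; with S carrying units of length squared the per-axis stretch is
``sqrt(l_i)``, so ``U_S = 1/2 ln(S / S0)`` in the eigenbasis.  The geometric
mean makes U_S exactly traceless.

Texture route.  The texture tensor ``M = <l l^T>`` averages the outer
products of the link vectors l from a bubble center to its neighbor centers.
``U_M = 1/2 ln(M / M0)`` with the same construction; the 1/2 accounts for M
being quadratic in length.  Both strain measures therefore recover the
applied logarithmic strain of an affine deformation.

Stress route (Batchelor).  The elastic stress carried by the gas-liquid
interfaces bounding a bubble is the surface integral of the deviatoric part
of the interfacial tension dyad,

    sigma = (Gamma / V) * integral (Id/3 - n n^T) dA,

with Gamma the surface tension, V the bubble volume and n the interface
normal.  The sign follows the tension-positive convention: a planar film
under tension contributes positive deviatoric stress in its own plane (a
film of area A normal to z gives Gamma A / V * diag(-2/3, 1/3, 1/3)).
The isotropic (pressure) part is not included, as pressure is not
accessible from the image; the tensor is deviatoric by construction.  The
interface is triangulated by marching cubes at the half level of the
binary bubble region after a small Gaussian pre-smoothing (default 1
voxel) that suppresses the staircase bias of voxel surface normals; both
steps are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes

from . import io as _io


class DegenerateTensorError(ValueError):
    """Raised for singular shape/texture tensors (flat or collapsed bubbles)."""


def shape_tensor(voxels: np.ndarray):
    """Centroid and second-moment shape tensor of a bubble voxel set.

    Parameters
    ----------
    voxels : (N, 3) array of voxel coordinates (z, y, x).
    """
    pts = np.asarray(voxels, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("voxels must be a non-empty (N, 3) coordinate array")
    centroid = pts.mean(axis=0)
    d = pts - centroid
    S = d.T @ d / len(pts)
    return centroid, S


def _log_strain(T: np.ndarray, name: str) -> np.ndarray:
    """Half-logarithmic deviation of a PSD length^2 tensor from isotropy."""
    T = np.asarray(T, dtype=float)
    Tsym = 0.5 * (T + T.T)
    evals, evecs = np.linalg.eigh(Tsym)
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        raise DegenerateTensorError(f"singular {name} tensor: eigenvalues {evals}")
    log_dev = np.log(evals) - np.log(evals).mean()
    return (evecs * (0.5 * log_dev)) @ evecs.T


def shape_strain(S: np.ndarray) -> np.ndarray:
    """Strain tensor U_S: log deviation of the shape tensor from isotropy.

    Symmetric and exactly traceless; zero for an isotropic S.  A sphere
    stretched by the volume-preserving ``diag(e^eps, e^{-eps/2}, e^{-eps/2})``
    yields eigenvalues ``(eps, -eps/2, -eps/2)``.
    """
    return _log_strain(S, "shape")


def texture_tensor(center: np.ndarray, neighbor_centers: np.ndarray) -> np.ndarray:
    """Texture tensor M = <l l^T> over links to the neighboring centers."""
    center = np.asarray(center, dtype=float)
    nbrs = np.asarray(neighbor_centers, dtype=float)
    if nbrs.ndim != 2 or nbrs.shape[1] != 3 or len(nbrs) == 0:
        raise ValueError("needs at least one neighbor center (N, 3)")
    links = nbrs - center
    return links.T @ links / len(links)


def texture_strain(M: np.ndarray) -> np.ndarray:
    """Strain tensor U_M: half the log deviation of the texture from isotropy.

    The half factor accounts for the texture tensor being quadratic in
    length.  Symmetric and exactly traceless.
    """
    return _log_strain(M, "texture")


@dataclass
class StressRecord:
    label: int
    sigma: np.ndarray      # 3x3 symmetric deviatoric tensor, units of Gamma/length
    V: float               # bubble volume (voxel_size^3 units)
    S_area: float          # total interface area (voxel_size^2 units)
    gamma: float           # surface tension


def batchelor_stress(
    labels: np.ndarray,
    label: int,
    gamma: float = 1.0,
    voxel_size: float = 1.0,
    smooth_sigma: float = 1.0,
) -> StressRecord:
    """Interfacial (Batchelor) elastic stress tensor of one bubble.

    Meshes the bubble's gas-liquid interface with marching cubes at the 0.5
    level of its binary region (Gaussian pre-smoothed by ``smooth_sigma``
    voxels to remove the staircase bias of voxelized normals) and
    accumulates the per-triangle deviatoric tension dyad ``Id/3 - n n^T``
    weighted by triangle area, scaled by ``gamma / V``.  The bubble region
    must not touch the image boundary (the interface would be open);
    remove edge bubbles first.
    """
    labels = np.asarray(labels)
    region = labels == label
    if not region.any():
        raise ValueError(f"label {label} not present")
    idx = np.argwhere(region)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    if (lo == 0).any() or (hi == np.array(labels.shape) - 1).any():
        raise ValueError(
            f"label {label} touches the image boundary; its interface mesh "
            "would be open -- run edge-bubble removal first"
        )
    # the region has no support outside its bounding box, so cropping there
    # and zero-padding is exact; 3 pad voxels keep the smoothed 0.5 level
    # surface closed inside the crop
    sl = tuple(slice(a - 1, b + 2) for a, b in zip(lo, hi))
    sub = np.pad(region[sl].astype(np.float32), 3)
    if smooth_sigma > 0:
        sub = ndimage.gaussian_filter(sub, smooth_sigma)
    verts, faces, _, _ = marching_cubes(sub, level=0.5)
    tri = verts[faces].astype(np.float64) * voxel_size
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    double_area = np.linalg.norm(cross, axis=1)
    keep = double_area > 1e-12
    cross, double_area = cross[keep], double_area[keep]
    normals = cross / double_area[:, None]
    areas = 0.5 * double_area
    dyads = np.einsum("t,ti,tj->ij", areas, normals, normals)
    integral = np.eye(3) * (areas.sum() / 3.0) - dyads  # tension positive
    V = float(region.sum()) * voxel_size**3
    sigma = gamma * integral / V
    return StressRecord(
        label=int(label), sigma=sigma, V=V, S_area=float(areas.sum()), gamma=gamma
    )


def stress_table(
    labels: np.ndarray,
    gamma: float = 1.0,
    voxel_size: float = 1.0,
    label_ids=None,
    smooth_sigma: float = 1.0,
) -> pd.DataFrame:
    """Batchelor stress of every (interior) bubble, one row per label."""
    labels = np.asarray(labels)
    if label_ids is None:
        label_ids = [int(v) for v in np.unique(labels) if v != 0]
    rows = []
    for lab in label_ids:
        rec = batchelor_stress(
            labels, lab, gamma=gamma, voxel_size=voxel_size, smooth_sigma=smooth_sigma
        )
        row = {"label": lab, "V": rec.V, "S_area": rec.S_area, "gamma": gamma}
        row.update(zip(_io.tensor_columns("sigma"), _io.flatten_tensor(rec.sigma)))
        rows.append(row)
    return pd.DataFrame(rows)


def texture_table(regions: pd.DataFrame, topology: pd.DataFrame) -> pd.DataFrame:
    """Texture tensor and strain per bubble from a region table and topology.

    ``regions`` needs columns label, z, y, x; ``topology`` label and
    neighbors.  Bubbles with no neighbors or a singular (coplanar) texture
    are flagged degenerate with NaN tensors.
    """
    centers = {
        int(r.label): np.array([r.z, r.y, r.x]) for r in regions.itertuples()
    }
    rows = []
    for row in topology.itertuples():
        lab = int(row.label)
        if lab not in centers:
            continue
        nbrs = [n for n in row.neighbors if int(n) in centers]
        record = {"label": lab, "n_links": len(nbrs)}
        M = U = None
        if nbrs:
            M = texture_tensor(centers[lab], np.array([centers[int(n)] for n in nbrs]))
            try:
                U = texture_strain(M)
            except DegenerateTensorError:
                U = None
        record["degenerate"] = U is None
        nan6 = [np.nan] * 6
        record.update(
            zip(_io.tensor_columns("M"), _io.flatten_tensor(M) if M is not None else nan6)
        )
        record.update(
            zip(_io.tensor_columns("UM"), _io.flatten_tensor(U) if U is not None else nan6)
        )
        rows.append(record)
    return pd.DataFrame(rows)
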