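"""Synthetic wet-foam volumes with exact ground truth.

Real foam tomograms are terabyte-scale beamline reconstructions; this module
emulates their statistical structure at desk scale so that every downstream
stage (phase segmentation, watershed bubble segmentation, contact extraction,
strain/stress tensors, tracking, T1 detection) can be validated against a
known answer.

A packing is built by random sequential addition (or a jittered lattice) of
non-overlapping spheres, rasterized as a Laguerre (power-diagram) tessellation
capped by the sphere radii and separated by a liquid film of prescribed
thickness.  The construction gives exact per-bubble volumes, centroids and a
designed contact topology.

All randomness flows from the integer ``seed`` of the spec; no global random
state is touched, so identical specs produce bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import contacts as _contacts


class PackingError(RuntimeError):
    """Raised when a requested packing cannot be placed inside the box."""


@dataclass(frozen=True)
class FoamSpec:
    """Parameters of a synthetic foam packing.

    Parameters
    ----------
    box_shape :
        Volume shape in voxels, (z, y, x); every axis must be >= 16.
    n_bubbles :
        Number of bubbles to place (>= 1).
    radius_law :
        ``("constant", r)`` or ``("lognormal", mu, sigma)`` with ``mu``,
        ``sigma`` the log-space parameters; radii are in voxels.
    film_thickness :
        Liquid film thickness separating neighboring bubbles, in voxels.
    seed :
        Integer seed for all randomness of the generator.
    drift :
        Rigid displacement per frame (z, y, x) used by sequence helpers.
    arrangement :
        ``"random"`` for random sequential addition, ``"grid"`` for a
        jittered cubic lattice (``n_bubbles`` must then be a perfect cube).
    """

    box_shape: tuple[int, int, int]
    n_bubbles: int
    radius_law: tuple
    film_thickness: float = 1.0
    seed: int = 0
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    arrangement: str = "random"

    def __post_init__(self):
        if len(self.box_shape) != 3 or any(int(s) < 16 for s in self.box_shape):
            raise ValueError("box_shape must be 3 axes, each >= 16 voxels")
        if self.n_bubbles < 1:
            raise ValueError("n_bubbles must be >= 1")
        if self.film_thickness < 0:
            raise ValueError("film_thickness must be >= 0")
        law = self.radius_law
        if law[0] == "constant":
            if len(law) != 2 or law[1] <= 0:
                raise ValueError("constant radius law is ('constant', r>0)")
        elif law[0] == "lognormal":
            if len(law) != 3 or law[2] < 0:
                raise ValueError("lognormal law is ('lognormal', mu, sigma>=0)")
        else:
            raise ValueError(f"unknown radius law {law[0]!r}")
        if self.arrangement not in ("random", "grid"):
            raise ValueError("arrangement must be 'random' or 'grid'")


@dataclass
class GroundTruth:
    """Exact per-bubble reference values attached to a synthetic packing."""

    centroids: np.ndarray          # (n, 3) voxel coordinates (z, y, x)
    radii: np.ndarray              # nominal sphere radii, voxels
    volumes: np.ndarray            # rasterized voxel counts
    equivalent_radii: np.ndarray   # (3V/4pi)^(1/3), voxels
    adjacency: set                 # unordered label pairs (p, q), p < q
    labels: np.ndarray = field(repr=False, default=None)  # label ids, 1-based
    displacements: np.ndarray | None = None  # (n, 3) per-bubble, for sequences


def _draw_radii(spec: FoamSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.radius_law
    if law[0] == "constant":
        return np.full(spec.n_bubbles, float(law[1]))
    return rng.lognormal(mean=law[1], sigma=law[2], size=spec.n_bubbles)


def _place_random(spec: FoamSpec, radii: np.ndarray, rng: np.random.Generator):
    """Random sequential addition of non-overlapping spheres (plus film)."""
    box = np.asarray(spec.box_shape, dtype=float)
    order = np.argsort(radii)[::-1]  # large spheres first: better packing odds
    centers = np.zeros((spec.n_bubbles, 3))
    placed: list[int] = []
    max_tries = 2000
    for i in order:
        r = radii[i]
        lo = r + 1.0
        hi = box - 1.0 - r
        if np.any(hi <= lo):
            raise PackingError(
                f"radius {r:.1f} does not fit in box {spec.box_shape}; "
                f"placed {len(placed)} of {spec.n_bubbles} bubbles"
            )
        for _ in range(max_tries):
            c = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(c - centers[j]) >= r + radii[j] + spec.film_thickness
                for j in placed
            ):
                centers[i] = c
                placed.append(i)
                break
        else:
            raise PackingError(
                f"could not place bubble {len(placed) + 1} of {spec.n_bubbles} "
                f"after {max_tries} tries; achievable count is {len(placed)}"
            )
    return centers


def _place_grid(spec: FoamSpec, radii: np.ndarray, rng: np.random.Generator):
    """Jittered cubic lattice; ``n_bubbles`` must be a perfect cube."""
    m = round(spec.n_bubbles ** (1.0 / 3.0))
    if m**3 != spec.n_bubbles:
        raise ValueError("grid arrangement needs n_bubbles to be a perfect cube")
    box = np.asarray(spec.box_shape, dtype=float)
    spacing = box / m
    jitter_amp = min(1.0, 0.05 * spacing.min())
    idx = np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), axis=-1)
    centers = (idx.reshape(-1, 3) + 0.5) * spacing
    centers = centers + rng.uniform(-jitter_amp, jitter_amp, size=centers.shape)
    # outer-layer spheres may be clipped by the box (edge bubbles are a real
    # feature of tomograms and are handled by edge-bubble removal downstream),
    # but the centers themselves must stay inside
    if np.any(centers < 1.0) or np.any(centers > box - 2.0):
        raise PackingError("grid centers exit the box; reduce n or grow box")
    return centers


def rasterize_laguerre(
    box_shape: Sequence[int],
    centers: np.ndarray,
    radii: np.ndarray,
    film_thickness: float,
) -> np.ndarray:
    """Rasterize spheres as a film-separated Laguerre tessellation.

    Each voxel is assigned to the seed minimizing the power distance
    ``|v - c_i|^2 - r_i^2``, restricted to the seed's sphere, and carved back
    from the Laguerre cell boundary by half the film thickness, so that
    neighboring bubbles are separated by a liquid layer of the prescribed
    thickness.  Returns an integer label map, 0 = liquid, i+1 = bubble i.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(centers)
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float32) for s in box_shape], indexing="ij"
    )
    # pass 1: nearest seed by power distance
    best = np.full(box_shape, np.inf, dtype=np.float32)
    own = np.zeros(box_shape, dtype=np.int32)
    d2 = np.empty(box_shape, dtype=np.float32)
    for i, (c, r) in enumerate(zip(centers, radii)):
        d2[...] = 0.0
        for a in range(3):
            d2 += (grids[a] - np.float32(c[a])) ** 2
        power = d2 - np.float32(r * r)
        closer = power < best
        best[closer] = power[closer]
        own[closer] = i
    # pass 2: distance to the nearest Laguerre bisector plane.  For seeds i, j
    # the power difference is linear with gradient 2(c_j - c_i), so the slack
    # (power_j - power_i) / (2 |c_j - c_i|) is the exact plane distance.
    seed_dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    np.fill_diagonal(seed_dist, np.inf)
    boundary = np.full(box_shape, np.inf, dtype=np.float32)
    if n > 1:
        best_of_own = best
        for j, (c, r) in enumerate(zip(centers, radii)):
            d2[...] = 0.0
            for a in range(3):
                d2 += (grids[a] - np.float32(c[a])) ** 2
            power = d2 - np.float32(r * r)
            denom = 2.0 * seed_dist[own, j].astype(np.float32)
            slack = (power - best_of_own) / denom
            slack[own == j] = np.inf
            np.minimum(boundary, slack, out=boundary)
    labels = np.zeros(box_shape, dtype=np.int32)
    half_film = 0.5 * film_thickness
    for i, (c, r) in enumerate(zip(centers, radii)):
        d2[...] = 0.0
        for a in range(3):
            d2 += (grids[a] - np.float32(c[a])) ** 2
        inside = (d2 <= np.float32(r * r)) & (own == i) & (boundary >= half_film)
        labels[inside] = i + 1
    return labels


def _surface_coords(region: np.ndarray, offset: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(region)
    surf = region & ~eroded
    return np.argwhere(surf) + offset


def _true_adjacency(labels: np.ndarray, radii: np.ndarray, film: float) -> set:
    """Label pairs separated by only the designed liquid film.

    Two bubbles are adjacent when the minimal voxel-center distance between
    their surfaces does not exceed ``film + 2.5`` voxels (the film gap plus
    rasterization allowance); the generator keeps non-contacting pairs well
    beyond this, so the criterion is unambiguous on synthetic packings.
    """
    objects = ndimage.find_objects(labels)
    n = len(objects)
    threshold = film + 2.5
    surfaces = {}
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        offset = np.array([s.start for s in sl])
        surfaces[lab] = _surface_coords(labels[sl] == lab, offset)
    adjacency = set()
    labs = sorted(surfaces)
    trees = {lab: cKDTree(surfaces[lab]) for lab in labs}
    for a_i, p in enumerate(labs):
        for q in labs[a_i + 1 :]:
            d, _ = trees[p].query(surfaces[q], k=1)
            if d.min() <= threshold:
                adjacency.add((p, q))
    return adjacency


def make_packing(spec: FoamSpec):
    """Build a synthetic foam packing.

    Returns
    -------
    labels : ndarray of int32
        Label map, 0 = liquid, 1..n = bubbles.
    phase : ndarray of uint8
        Phase map, 1 = liquid, 0 = gas.
    truth : GroundTruth
    """
    rng = np.random.default_rng(spec.seed)
    radii = _draw_radii(spec, rng)
    if spec.arrangement == "grid":
        centers = _place_grid(spec, radii, rng)
    else:
        centers = _place_random(spec, radii, rng)
    labels = rasterize_laguerre(spec.box_shape, centers, radii, spec.film_thickness)
    counts = np.bincount(labels.ravel(), minlength=spec.n_bubbles + 1)
    missing = np.nonzero(counts[1:] == 0)[0]
    if missing.size:
        raise PackingError(
            f"{missing.size} bubbles rasterized to zero voxels; "
            f"achievable count is {spec.n_bubbles - missing.size}"
        )
    idx = np.arange(1, spec.n_bubbles + 1)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
    volumes = counts[1:].astype(np.int64)
    eq_radii = (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
    adjacency = _true_adjacency(labels, radii, spec.film_thickness)
    phase = (labels == 0).astype(np.uint8)
    truth = GroundTruth(
        centroids=centroids,
        radii=radii,
        volumes=volumes,
        equivalent_radii=eq_radii,
        adjacency=adjacency,
        labels=idx,
    )
    return labels, phase, truth


def render_tomogram(
    phase: np.ndarray,
    gas_level: float,
    liquid_level: float,
    blur_sigma: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a phase map into a grayscale tomogram-like volume.

    The two phases get distinct plateau intensities, the partial-volume
    effect of the imaging chain is emulated by a Gaussian blur, and detector
    noise by additive white Gaussian noise.
    """
    if gas_level == liquid_level:
        raise ValueError("gas_level and liquid_level must differ")
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    vol = np.where(np.asarray(phase) > 0, liquid_level, gas_level).astype(np.float32)
    if blur_sigma > 0:
        vol = ndimage.gaussian_filter(vol, blur_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape).astype(np.float32)
    return vol


@dataclass
class DeformResult:
    frames: list              # list of label maps, frame 0 is the input
    escaped: dict             # frame index -> sorted labels advected out of box
    expected_centroids: list  # per frame, (n,3) analytic centroid positions


def deform_sequence(
    labels: np.ndarray,
    affine: np.ndarray,
    translation: Sequence[float],
    n_frames: int,
) -> DeformResult:
    """Advect a label map through repeated application of an affine map.

    Frame ``k`` applies the map ``x -> A x + t`` cumulatively ``k`` times
    (about the voxel origin); labels are resampled by nearest neighbor so
    label values are preserved exactly.  Bubbles advected outside the box are
    flagged in ``escaped`` rather than silently dropped.
    """
    A = np.asarray(affine, dtype=float)
    t = np.asarray(translation, dtype=float)
    if A.shape != (3, 3) or abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine must be an invertible 3x3 matrix")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    labs0 = set(np.unique(labels)) - {0}
    idx = sorted(labs0)
    c0 = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, idx))
    frames = [labels.copy()]
    expected = [c0]
    escaped: dict[int, list[int]] = {}
    A_c = np.eye(3)
    t_c = np.zeros(3)
    for k in range(1, n_frames):
        A_c = A @ A_c
        t_c = A @ t_c + t
        inv = np.linalg.inv(A_c)
        frame = ndimage.affine_transform(
            labels, matrix=inv, offset=-inv @ t_c, order=0, prefilter=False,
            mode="constant", cval=0,
        )
        frames.append(frame)
        expected.append((A_c @ c0.T).T + t_c)
        lost = sorted(labs0 - set(np.unique(frame)))
        if lost:
            escaped[k] = lost
    return DeformResult(frames=frames, escaped=escaped, expected_centroids=expected)


@dataclass
class T1Fixture:
    """Two-frame, four-bubble contact-swap fixture with known ground truth."""

    labels_t: np.ndarray
    labels_t1: np.ndarray
    net_t: "_contacts.ContactNetwork"
    net_t1: "_contacts.ContactNetwork"
    lost_pair: tuple | None
    new_pair: tuple | None
    quadruplet: tuple


def make_t1_fixture(swap: bool = True, radius: float = 10.0) -> T1Fixture:
    """Four bubbles in a tetrahedral-like arrangement undergoing a T1.

    Bubbles 1 and 2 start in contact along z; bubbles 3 and 4 sit on either
    side along y, each touching both 1 and 2.  During the swap the 1-2 film
    vanishes and a new 3-4 film forms between the two former common
    neighbors; with ``swap=False`` the second frame repeats the first.
    """
    box = (48, 48, 48)
    c = 24.0
    r = radius
    # close pairs overlap (centers 1.8 r apart -> split at the midplane),
    # open pairs are 2.4 r apart -> a 0.4 r liquid gap, clearly no contact.
    near, far = 0.9 * r, 1.2 * r
    centers_t = np.array(
        [[c - near, c, c], [c + near, c, c], [c, c - far, c], [c, c + far, c]]
    )
    centers_t1 = np.array(
        [[c - far, c, c], [c + far, c, c], [c, c - near, c], [c, c + near, c]]
    )
    radii = np.full(4, r)
    labels_t = rasterize_laguerre(box, centers_t, radii, film_thickness=0.0)
    if swap:
        labels_t1 = rasterize_laguerre(box, centers_t1, radii, film_thickness=0.0)
    else:
        labels_t1 = labels_t.copy()
    net_t = _contacts.get_contacts(labels_t, dilation=1)
    net_t1 = _contacts.get_contacts(labels_t1, dilation=1)
    pairs_t = _contacts.pair_set(net_t.pairs)
    pairs_t1 = _contacts.pair_set(net_t1.pairs)
    diagonal = {(1, 3), (1, 4), (2, 3), (2, 4)}
    if not diagonal <= pairs_t or not diagonal <= pairs_t1:
        raise AssertionError("fixture geometry broken: diagonal contacts missing")
    if swap:
        if (1, 2) not in pairs_t or (3, 4) in pairs_t:
            raise AssertionError("fixture geometry broken at frame t")
        if (3, 4) not in pairs_t1 or (1, 2) in pairs_t1:
            raise AssertionError("fixture geometry broken at frame t+1")
    return T1Fixture(
        labels_t=labels_t,
        labels_t1=labels_t1,
        net_t=net_t,
        net_t1=net_t1,
        lost_pair=(1, 2) if swap else None,
        new_pair=(3, 4) if swap else None,
        quadruplet=(1, 2, 3, 4),
    )
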