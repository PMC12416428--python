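"""Grayscale tomogram to clean bubble-segmented label map.

The processing chain mirrors the standard workflow for tomograms of wet
foams: background removal, phase segmentation, speckle removal, watershed
bubble segmentation and edge-bubble removal.

Conventions (fixed and documented rather than configurable):

* axis order is (z, y, x), zero-based voxel indexing;
* in phase maps 1 = liquid, 0 = gas;
* the gas phase is 26-connected, the liquid phase 6-connected;
* fixed thresholding is half-open: intensity >= threshold is the high class.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def remove_background(vol: np.ndarray, scale: float) -> np.ndarray:
    """Subtract a Gaussian low-pass background estimate, keeping the mean.

    ``scale`` (the Gaussian sigma, in voxels) should be larger than the
    bubble diameter so that the estimate tracks slow illumination drifts and
    not the foam structure itself.  A spatially constant input is returned
    unchanged.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    vol = np.asarray(vol, dtype=np.float32)
    background = ndimage.gaussian_filter(vol, scale)
    return vol - background + background.mean()


def segment_phase(
    vol: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    mask: np.ndarray | None = None,
    liquid_high: bool = True,
) -> np.ndarray:
    """Binarize a grayscale volume into liquid (1) and gas (0).

    With ``method="otsu"`` the threshold is estimated on the voxels inside
    ``mask`` (all voxels when no mask); with ``method="fixed"`` the caller
    supplies ``threshold``.  Intensity >= threshold is the high class, which
    is liquid when ``liquid_high`` (aqueous liquid absorbs more than gas in
    a typical X-ray tomogram).  Voxels outside the mask are set to gas and
    must be tracked via the mask by the caller.
    """
    vol = np.asarray(vol)
    values = vol[mask.astype(bool)] if mask is not None else vol
    if method == "otsu":
        if values.size == 0 or np.ptp(values) == 0:
            raise ValueError("degenerate (single-valued) histogram: cannot run Otsu")
        t = threshold_otsu(values.ravel())
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    high = vol >= t
    liquid = high if liquid_high else ~high
    phase = liquid.astype(np.uint8)
    if mask is not None:
        phase[~mask.astype(bool)] = 0
    return phase


def _flip_small(phase, value, min_size, structure):
    """Flip connected components of ``phase == value`` smaller than min_size."""
    comp, n = ndimage.label(phase == value, structure=structure)
    if n == 0:
        return phase
    sizes = np.bincount(comp.ravel())
    small = np.nonzero(sizes < min_size)[0]
    small = small[small > 0]
    if small.size:
        phase = phase.copy()
        phase[np.isin(comp, small)] = 1 - value
    return phase


def remove_speckles(
    phase: np.ndarray, min_size_liquid: int = 0, min_size_gas: int = 0
) -> np.ndarray:
    """Flip speckle components smaller than the per-phase size thresholds.

    Gas specks (26-connected) are filled first, then liquid specks
    (6-connected); with both thresholds at 0 the map is returned unchanged.
    The operation is idempotent: re-running it on its own output is the
    identity.
    """
    if min_size_liquid < 0 or min_size_gas < 0:
        raise ValueError("speckle size thresholds must be >= 0")
    phase = np.asarray(phase).astype(np.uint8)
    if min_size_gas > 0:
        phase = _flip_small(phase, 0, min_size_gas, _CONN26)
    if min_size_liquid > 0:
        phase = _flip_small(phase, 1, min_size_liquid, _CONN6)
    return phase


def segment_bubbles(
    phase: np.ndarray,
    h: float = 2.0,
    min_volume: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Marker-controlled watershed segmentation of the gas phase into bubbles.

    Markers are the h-maxima (depth ``h``, in distance units) of the
    Euclidean distance transform of the gas phase; the watershed floods the
    negated distance map.  Every gas voxel is assigned to exactly one label,
    so the labels partition the gas phase.  Regions smaller than
    ``min_volume`` voxels are merged into their largest (by volume) neighbor.
    """
    phase = np.asarray(phase)
    gas = phase == 0
    if mask is not None:
        gas = gas & mask.astype(bool)
    if not gas.any():
        raise ValueError("empty gas phase: nothing to segment")
    dt = ndimage.distance_transform_edt(gas)
    maxima = h_maxima(dt, h)
    markers, n_markers = ndimage.label(maxima, structure=_CONN26)
    if n_markers == 0:  # h exceeds the global dynamic: single basin
        markers = np.zeros_like(phase, dtype=np.int32)
        markers[np.unravel_index(np.argmax(dt), dt.shape)] = 1
    labels = watershed(-dt, markers=markers, mask=gas)
    if min_volume > 0:
        labels = _merge_small_regions(labels, min_volume)
    return labels.astype(np.int32)


def _merge_small_regions(labels: np.ndarray, min_volume: int) -> np.ndarray:
    """Merge regions smaller than min_volume into their largest neighbor."""
    labels = labels.copy()
    for _ in range(labels.max() + 1):  # bounded: each pass removes >= 1 label
        sizes = np.bincount(labels.ravel())
        small = [
            lab for lab in range(1, len(sizes)) if 0 < sizes[lab] < min_volume
        ]
        if not small:
            break
        lab = min(small, key=lambda s: (sizes[s], s))
        region = labels == lab
        grown = ndimage.binary_dilation(region, structure=_CONN26)
        neigh = np.unique(labels[grown & ~region])
        neigh = neigh[(neigh != 0) & (neigh != lab)]
        if neigh.size == 0:
            break  # isolated region: nothing to merge into
        target = max(neigh, key=lambda n: (sizes[n] if n < len(sizes) else 0, -n))
        labels[region] = target
    return labels


def remove_edge_bubbles(
    labels: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Zero out labels touching any image face or the validity-mask boundary."""
    labels = np.asarray(labels)
    border = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[axis] = end
            border[tuple(sl)] = True
    if mask is not None:
        inside = mask.astype(bool)
        rim = ndimage.binary_dilation(~inside, structure=_CONN6) & inside
        border = (border & inside) | rim
        edge_labels = set(np.unique(labels[border])) | set(np.unique(labels[~inside]))
    else:
        edge_labels = set(np.unique(labels[border]))
    edge_labels.discard(0)
    if not edge_labels:
        return labels.copy()
    out = labels.copy()
    out[np.isin(labels, sorted(edge_labels))] = 0
    return out


def process_chain(
    vol: np.ndarray,
    background_scale: float = 0.0,
    method: str = "otsu",
    threshold: float | None = None,
    liquid_high: bool = True,
    mask: np.ndarray | None = None,
    min_size_liquid: int = 0,
    min_size_gas: int = 0,
    h: float = 2.0,
    min_volume: int = 0,
    keep_edge_bubbles: bool = False,
):
    """Run the full processing chain; returns (phase, labels)."""
    if background_scale > 0:
        vol = remove_background(vol, background_scale)
    phase = segment_phase(
        vol, method=method, threshold=threshold, mask=mask, liquid_high=liquid_high
    )
    phase = remove_speckles(phase, min_size_liquid, min_size_gas)
    labels = segment_bubbles(phase, h=h, min_volume=min_volume, mask=mask)
    if not keep_edge_bubbles:
        labels = remove_edge_bubbles(labels, mask=mask)
    return phase, labels
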