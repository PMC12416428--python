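import numpy as np
import pytest

import foam3d
from foam3d import structure


def rasterize_sphere(shape, center, radius):
    grids = np.mgrid[tuple(slice(0, s) for s in shape)].astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def rasterize_ellipsoid(shape, center, semi_axes):
    grids = np.mgrid[tuple(slice(0, s) for s in shape)].astype(float)
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def best_label_matching(labels_a, labels_b):
    """Greedy bijective label matching by overlap; returns per-pair Jaccard."""
    a, b = labels_a.ravel(), labels_b.ravel()
    both = (a > 0) & (b > 0)
    pairs, counts = np.unique(
        np.stack([a[both], b[both]]), axis=1, return_counts=True
    )
    size_a = np.bincount(a)
    size_b = np.bincount(b)
    order = np.argsort(counts)[::-1]
    used_a, used_b, jaccards = set(), set(), {}
    for k in order:
        la, lb = int(pairs[0, k]), int(pairs[1, k])
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        inter = counts[k]
        jaccards[la] = inter / (size_a[la] + size_b[lb] - inter)
    return jaccards


@pytest.fixture(scope="session")
def grid_packing():
    """27 near-monodisperse bubbles on a jittered lattice with thin films."""
    spec = foam3d.FoamSpec(
        box_shape=(60, 60, 60),
        n_bubbles=27,
        radius_law=("constant", 9.8),
        film_thickness=1.0,
        seed=3,
        arrangement="grid",
    )
    labels, phase, truth = foam3d.make_packing(spec)
    return spec, labels, phase, truth


@pytest.fixture(scope="session")
def grid_regions(grid_packing):
    _, labels, _, _ = grid_packing
    return structure.region_properties(labels)


@pytest.fixture(scope="session")
def t1_fixture():
    return foam3d.make_t1_fixture()
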