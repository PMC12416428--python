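"""Bubble contact network and per-film geometry.

Two bubbles are in contact when their regions, each dilated by a Euclidean
ball of radius ``dilation`` voxels, overlap (face-adjacent regions always
qualify).  The overlap voxels form the labeled contact (film) region.  Each
film is then fitted by an ellipse through the eigen-decomposition of its
second-moment tensor: the normal is the eigenvector of the smallest
eigenvalue and the in-plane semi-axes follow the uniform-disc calibration
``a = 2 sqrt(lambda)``, giving the planar film area ``A = pi a b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class ContactNetwork:
    """Adjacency of a bubble-segmented image.

    ``topology`` has one row per bubble (label, coordination number Z,
    neighbor labels); ``pairs`` one row per film (contact_id, label_p <
    label_q); ``contact_labels`` is a 3D image of film regions labeled by
    contact_id.
    """

    topology: pd.DataFrame
    pairs: pd.DataFrame
    contact_labels: np.ndarray


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return g[(g**2).sum(axis=1) <= radius**2 + 1e-9]


def _ball_structure(radius: int) -> np.ndarray:
    r = int(radius)
    z, y, x = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (z**2 + y**2 + x**2) <= radius**2 + 1e-9


def get_contacts(labels: np.ndarray, dilation: int = 1) -> ContactNetwork:
    """Extract the contact network of a labeled bubble image."""
    labels = np.asarray(labels)
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    objects = ndimage.find_objects(labels)
    structure = _ball_structure(dilation)
    dilated: dict[int, tuple[tuple, np.ndarray]] = {}
    labs = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        labs.append(lab)
        grown = tuple(
            slice(max(s.start - dilation, 0), min(s.stop + dilation, n))
            for s, n in zip(sl, labels.shape)
        )
        mask = ndimage.binary_dilation(labels[grown] == lab, structure=structure)
        dilated[lab] = (grown, mask)

    pair_rows = []
    contact_labels = np.zeros(labels.shape, dtype=np.int32)
    neighbors: dict[int, set] = {lab: set() for lab in labs}
    contact_id = 0
    for i, p in enumerate(labs):
        sl_p, mask_p = dilated[p]
        for q in labs[i + 1 :]:
            sl_q, mask_q = dilated[q]
            inter = tuple(
                slice(max(a.start, b.start), min(a.stop, b.stop))
                for a, b in zip(sl_p, sl_q)
            )
            if any(s.start >= s.stop for s in inter):
                continue
            sub_p = mask_p[
                tuple(slice(s.start - o.start, s.stop - o.start) for s, o in zip(inter, sl_p))
            ]
            sub_q = mask_q[
                tuple(slice(s.start - o.start, s.stop - o.start) for s, o in zip(inter, sl_q))
            ]
            overlap = sub_p & sub_q
            if not overlap.any():
                continue
            contact_id += 1
            pair_rows.append((contact_id, p, q))
            region = contact_labels[inter]
            region[overlap & (region == 0)] = contact_id
            neighbors[p].add(q)
            neighbors[q].add(p)

    topology = pd.DataFrame(
        {
            "label": labs,
            "Z": [len(neighbors[lab]) for lab in labs],
            "neighbors": [tuple(sorted(neighbors[lab])) for lab in labs],
        }
    )
    pairs = pd.DataFrame(pair_rows, columns=["contact_id", "label_p", "label_q"])
    return ContactNetwork(topology=topology, pairs=pairs, contact_labels=contact_labels)


def pair_set(pairs: pd.DataFrame) -> set:
    """Unordered label pairs of a pair table, as a set of sorted tuples."""
    return {
        tuple(sorted((int(p), int(q))))
        for p, q in zip(pairs["label_p"], pairs["label_q"])
    }


def topology_dict(topology: pd.DataFrame) -> dict:
    """Label -> set of neighbor labels."""
    return {
        int(row.label): set(int(n) for n in row.neighbors)
        for row in topology.itertuples()
    }


def contact_properties(net: ContactNetwork) -> pd.DataFrame:
    """Fit each labeled contact region by a planar elliptical film.

    Returns one row per contact with the unit normal (sign convention:
    positive z component, ties broken by y then x), the semi-axes a >= b,
    the planar area ``pi a b`` and the film centroid.  Contacts with fewer
    than three voxels or a collinear voxel set are flagged degenerate and
    carry NaN geometry.
    """
    img = net.contact_labels
    coords = np.argwhere(img > 0)
    ids = img[tuple(coords.T)]
    order = np.argsort(ids, kind="stable")
    coords, ids = coords[order], ids[order]
    boundaries = np.searchsorted(ids, np.arange(1, len(net.pairs) + 2))
    rows = []
    for row in net.pairs.itertuples():
        cid = int(row.contact_id)
        pts = coords[boundaries[cid - 1] : boundaries[cid]].astype(float)
        n_vox = len(pts)
        record = {
            "contact_id": cid,
            "label_p": int(row.label_p),
            "label_q": int(row.label_q),
            "n_voxels": n_vox,
        }
        degenerate = n_vox < 3
        if not degenerate:
            centroid = pts.mean(axis=0)
            T = (pts - centroid).T @ (pts - centroid) / n_vox
            evals, evecs = np.linalg.eigh(T)  # ascending
            # collinear: only one significant eigenvalue
            degenerate = evals[1] <= 1e-9 * max(evals[2], 1.0)
        if degenerate:
            record.update(
                nz=np.nan, ny=np.nan, nx=np.nan, a=np.nan, b=np.nan,
                area=np.nan, cz=np.nan, cy=np.nan, cx=np.nan, degenerate=True,
            )
        else:
            normal = evecs[:, 0]
            for comp in normal:  # sign convention: first nonzero of (z,y,x) > 0
                if abs(comp) > 1e-12:
                    if comp < 0:
                        normal = -normal
                    break
            a = 2.0 * np.sqrt(evals[2])
            b = 2.0 * np.sqrt(evals[1])
            record.update(
                nz=normal[0], ny=normal[1], nx=normal[2],
                a=a, b=b, area=np.pi * a * b,
                cz=centroid[0], cy=centroid[1], cx=centroid[2],
                degenerate=False,
            )
        rows.append(record)
    return pd.DataFrame(rows)
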