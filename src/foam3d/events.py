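"""Lost/new contact bookkeeping and bijective T1-event detection.

Bubbles in a jammed foam escape their cages through elementary contact
rearrangements (T1 events): a film between two bubbles vanishes while a new
film forms between two of their common neighbors, so four bubbles swap
contacts.  Detection proceeds in three steps: contact pairs of frame t are
translated into the label space of frame t+1 through the tracking, the
lost set L and new set N are formed by set difference, and a T1 is emitted
only when a lost pair and a new pair select each other uniquely (bijective
forward/backward match over common neighbors).  Non-bijective cases --
higher-order rearrangements or tracking dropouts -- are reported
separately, never as T1 events.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def translate_pairs(pairs_t: pd.DataFrame, tracks: pd.DataFrame) -> pd.DataFrame:
    """Map a contact-pair table through the tracking into frame-t+1 labels.

    Pairs with any lost/ambiguous member are flagged ``untranslatable`` and
    must be excluded from lost/new bookkeeping.
    """
    from .tracking import match_dict

    mapping = match_dict(tracks)
    rows = []
    for row in pairs_t.itertuples():
        p, q = int(row.label_p), int(row.label_q)
        tp, tq = mapping.get(p), mapping.get(q)
        ok = tp is not None and tq is not None
        a, b = (sorted((tp, tq)) if ok else (np.nan, np.nan))
        rows.append(
            {
                "contact_id": int(row.contact_id),
                "label_p_t": p, "label_q_t": q,
                "label_p": a, "label_q": b,
                "untranslatable": not ok,
            }
        )
    return pd.DataFrame(rows)


def _as_pair_set(pairs) -> set:
    if isinstance(pairs, pd.DataFrame):
        ok = pairs
        if "untranslatable" in pairs.columns:
            ok = pairs[~pairs["untranslatable"]]
        return {
            (int(min(p, q)), int(max(p, q)))
            for p, q in zip(ok["label_p"], ok["label_q"])
        }
    return {tuple(sorted(map(int, pq))) for pq in pairs}


def lost_new(pairs_t_translated, pairs_t1) -> tuple[set, set]:
    """Lost and new contact sets between two frames (frame-t+1 label space).

    ``L`` = translated pairs absent at t+1; ``N`` = pairs at t+1 absent from
    the translated set.  Unordered-pair set semantics.
    """
    a = _as_pair_set(pairs_t_translated)
    b = _as_pair_set(pairs_t1)
    return a - b, b - a


def detect_t1(
    L: set,
    N: set,
    topology_t: dict,
    topology_t1: dict,
    neighbor_frame: str = "union",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bijective T1 identification from the lost and new contact sets.

    For each lost pair the candidate new pairs are those whose two members
    are both common neighbors of the lost pair; the backward pass is
    symmetric.  A T1 is emitted only when the forward and backward
    assignments agree one-to-one; everything else lands in the second
    (non-bijective) table.  All labels and topologies must live in the
    frame-t+1 label space (translate frame-t quantities first).

    ``neighbor_frame`` selects where common neighborhood is evaluated:
    ``"union"`` (a neighbor counts if present at either frame, the default),
    ``"t"`` or ``"t1"``.
    """
    if neighbor_frame not in ("union", "t", "t1"):
        raise ValueError("neighbor_frame must be 'union', 't' or 't1'")

    def nbrs(lab):
        a = topology_t.get(lab, set())
        b = topology_t1.get(lab, set())
        return {"union": a | b, "t": a, "t1": b}[neighbor_frame]

    L = sorted(_as_pair_set(L))
    N = sorted(_as_pair_set(N))
    forward = {}
    for lost in L:
        common = nbrs(lost[0]) & nbrs(lost[1])
        forward[lost] = [new for new in N if set(new) <= common]
    backward = {}
    for new in N:
        common = nbrs(new[0]) & nbrs(new[1])
        backward[new] = [lost for lost in L if set(lost) <= common]

    t1_rows, other_rows = [], []
    claimed_new = set()
    for lost in L:
        cands = forward[lost]
        bijective = (
            len(cands) == 1
            and backward.get(cands[0], []) == [lost]
            and len(set(lost) | set(cands[0])) == 4
        )
        if bijective and cands[0] not in claimed_new:
            new = cands[0]
            claimed_new.add(new)
            t1_rows.append(
                {
                    "lost_p": lost[0], "lost_q": lost[1],
                    "new_p": new[0], "new_q": new[1],
                }
            )
        else:
            other_rows.append(
                {
                    "lost_p": lost[0], "lost_q": lost[1],
                    "n_candidates": len(cands),
                    "reason": "no-candidate" if not cands else "non-bijective",
                }
            )
    matched_lost = {(r["lost_p"], r["lost_q"]) for r in t1_rows}
    for new in N:
        if new in claimed_new:
            continue
        cands = [lost for lost in backward[new] if lost not in matched_lost]
        other_rows.append(
            {
                "new_p": new[0], "new_q": new[1],
                "n_candidates": len(backward[new]),
                "reason": "no-candidate" if not backward[new] else "non-bijective",
            }
        )
    return pd.DataFrame(t1_rows), pd.DataFrame(other_rows)


def pair_angle(
    c1,
    c2,
    axis_origin=(0.0, 0.0),
) -> float:
    """Orientation angle of a bubble-pair bar in the vertical shear plane.

    The bar joining the two centroids is projected into the cylindrical
    (z, r*theta) plane of a vertical cylinder whose axis passes through
    ``axis_origin`` (y, x); alpha is measured from the horizontal
    (azimuthal) direction, in degrees, in [0, 180).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if np.allclose(c1, c2):
        raise ValueError("coincident centroids: undefined orientation")
    mid = 0.5 * (c1 + c2)
    ry, rx = mid[1] - axis_origin[0], mid[2] - axis_origin[1]
    r = np.hypot(ry, rx)
    if r < 1e-12:
        raise ValueError("pair midpoint on the cylinder axis: undefined azimuth")
    e_theta = np.array([0.0, rx / r, -ry / r])  # azimuthal direction, (z,y,x)
    d = c2 - c1
    dz = d[0]
    dh = float(d @ e_theta)
    return float(np.degrees(np.arctan2(dz, dh)) % 180.0)


def t1_table(
    t1s: pd.DataFrame,
    regions_t1: pd.DataFrame,
    frame: int,
    axis_origin=None,
) -> pd.DataFrame:
    """Join centroids and orientation angles onto a detected-T1 table.

    Centroids are taken at frame t+1 (where all four bubbles exist under the
    frame-t+1 label space); alpha_lost / alpha_new are the bar angles of the
    lost and new pairs in the cylindrical view about a vertical axis through
    ``axis_origin`` (defaults to the image center implied by the centroids).
    """
    cent = {
        int(r.label): np.array([r.z, r.y, r.x]) for r in regions_t1.itertuples()
    }
    if axis_origin is None:
        pts = np.array(list(cent.values()))
        axis_origin = (pts[:, 1].mean(), pts[:, 2].mean())
    rows = []
    for r in t1s.itertuples():
        quad = [int(r.lost_p), int(r.lost_q), int(r.new_p), int(r.new_q)]
        if any(lab not in cent for lab in quad):
            continue
        row = {"frame": frame, "lost_p": quad[0], "lost_q": quad[1],
               "new_p": quad[2], "new_q": quad[3]}
        for tag, lab in zip(
            ("lp", "lq", "np", "nq"), quad
        ):
            row[f"{tag}_z"], row[f"{tag}_y"], row[f"{tag}_x"] = cent[lab]
        row["alpha_lost"] = pair_angle(cent[quad[0]], cent[quad[1]], axis_origin)
        row["alpha_new"] = pair_angle(cent[quad[2]], cent[quad[3]], axis_origin)
        rows.append(row)
    return pd.DataFrame(rows)
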