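"""Lost/new contact bookkeeping, T1 detection and event orientation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import foam3d
from foam3d import contacts, events, structure, tracking
from foam3d.synth import rasterize_laguerre


def identity_tracks(labels):
    return pd.DataFrame(
        {"label_t": labels, "label_t1": labels, "status": ["matched"] * len(labels)}
    )


class TestTranslatePairs:
    def test_identity_tracking_keeps_pairs(self, t1_fixture):
        pairs = t1_fixture.net_t.pairs
        out = events.translate_pairs(pairs, identity_tracks([1, 2, 3, 4]))
        assert not out.untranslatable.any()
        assert events._as_pair_set(out) == contacts.pair_set(pairs)

    def test_permutation_maps_pairs(self, t1_fixture):
        pairs = t1_fixture.net_t.pairs
        perm = {1: 4, 2: 3, 3: 2, 4: 1}
        tracks = pd.DataFrame(
            {"label_t": [1, 2, 3, 4], "label_t1": [4, 3, 2, 1],
             "status": ["matched"] * 4}
        )
        out = events.translate_pairs(pairs, tracks)
        expected = {
            tuple(sorted((perm[p], perm[q])))
            for p, q in contacts.pair_set(pairs)
        }
        assert events._as_pair_set(out) == expected

    def test_lost_member_flags_pair(self, t1_fixture):
        pairs = t1_fixture.net_t.pairs
        tracks = pd.DataFrame(
            {"label_t": [1, 2, 3, 4], "label_t1": [1, 2, 3, pd.NA],
             "status": ["matched"] * 3 + ["lost"]}
        )
        out = events.translate_pairs(pairs, tracks)
        flagged = out[out.untranslatable]
        assert set(map(tuple, flagged[["label_p_t", "label_q_t"]].values)) == {
            (1, 4), (2, 4)
        }


class TestLostNew:
    def test_identical_sets_empty(self, t1_fixture):
        pairs = t1_fixture.net_t.pairs
        out = events.translate_pairs(pairs, identity_tracks([1, 2, 3, 4]))
        L, N = events.lost_new(out, pairs)
        assert L == set() and N == set()

    def test_t1_fixture_single_swap(self, t1_fixture):
        fx = t1_fixture
        out = events.translate_pairs(fx.net_t.pairs, identity_tracks([1, 2, 3, 4]))
        L, N = events.lost_new(out, fx.net_t1.pairs)
        assert L == {(1, 2)} and N == {(3, 4)}

    def test_random_tables_match_set_difference_oracle(self):
        rng = np.random.default_rng(7)
        universe = list(itertools.combinations(range(1, 9), 2))
        for _ in range(20):
            a = {universe[i] for i in rng.choice(len(universe), 8, replace=False)}
            b = {universe[i] for i in rng.choice(len(universe), 8, replace=False)}
            L, N = events.lost_new(a, b)
            assert L == a - b and N == b - a


class TestDetectT1:
    def test_fixture_yields_single_t1(self, t1_fixture):
        fx = t1_fixture
        out = events.translate_pairs(fx.net_t.pairs, identity_tracks([1, 2, 3, 4]))
        L, N = events.lost_new(out, fx.net_t1.pairs)
        t1s, other = events.detect_t1(
            L, N,
            contacts.topology_dict(fx.net_t.topology),
            contacts.topology_dict(fx.net_t1.topology),
        )
        assert len(t1s) == 1 and len(other) == 0
        row = t1s.iloc[0]
        assert (row.lost_p, row.lost_q) == fx.lost_pair
        assert (row.new_p, row.new_q) == fx.new_pair

    def test_unchanged_topology_yields_none(self, t1_fixture):
        topo = contacts.topology_dict(t1_fixture.net_t.topology)
        t1s, other = events.detect_t1(set(), set(), topo, topo)
        assert len(t1s) == 0 and len(other) == 0

    def test_time_reversed_fixture_swaps_roles(self, t1_fixture):
        fx = t1_fixture
        out = events.translate_pairs(fx.net_t1.pairs, identity_tracks([1, 2, 3, 4]))
        L, N = events.lost_new(out, fx.net_t.pairs)
        assert L == {(3, 4)} and N == {(1, 2)}
        t1s, _ = events.detect_t1(
            L, N,
            contacts.topology_dict(fx.net_t1.topology),
            contacts.topology_dict(fx.net_t.topology),
        )
        assert len(t1s) == 1
        assert (t1s.iloc[0].lost_p, t1s.iloc[0].lost_q) == fx.new_pair
        assert (t1s.iloc[0].new_p, t1s.iloc[0].new_q) == fx.lost_pair

    def test_two_independent_swaps_detected_separately(self, t1_fixture):
        fx = t1_fixture
        topo_t = contacts.topology_dict(fx.net_t.topology)
        topo_t1 = contacts.topology_dict(fx.net_t1.topology)
        shift = 10
        topo_t.update({k + shift: {v + shift for v in s} for k, s in topo_t.items()})
        topo_t1.update({k + shift: {v + shift for v in s} for k, s in topo_t1.items()})
        L = {(1, 2), (11, 12)}
        N = {(3, 4), (13, 14)}
        t1s, other = events.detect_t1(L, N, topo_t, topo_t1)
        assert len(t1s) == 2 and len(other) == 0
        quads = [
            {r.lost_p, r.lost_q, r.new_p, r.new_q} for r in t1s.itertuples()
        ]
        assert quads[0].isdisjoint(quads[1])

    def test_nonbijective_case_excluded(self):
        # two lost pairs sharing the same candidate new pair: not elementary
        topo = {1: {2, 3, 4, 5}, 2: {1, 3, 4}, 5: {1, 3, 4},
                3: {1, 2, 4, 5}, 4: {1, 2, 3, 5}}
        L = {(1, 2), (1, 5)}
        N = {(3, 4)}
        t1s, other = events.detect_t1(L, N, topo, topo)
        assert len(t1s) == 0
        assert len(other) >= 2

    def test_swap_embedded_in_packing(self):
        """A contact swap among four bubbles of a 50-bubble foam is the only
        detected T1 after the full pairwise chain."""
        spec = foam3d.FoamSpec(
            box_shape=(110, 110, 110), n_bubbles=46,
            radius_law=("constant", 7.0), film_thickness=1.0, seed=13,
        )
        rng = np.random.default_rng(13)
        distractors = foam3d.synth._place_random(spec, np.full(46, 7.0), rng)
        # keep a clearance around the image center for the quadruplet
        keep = np.linalg.norm(distractors - 55.0, axis=1) > 32
        distractors = distractors[keep]
        c, r = 55.0, 10.0
        near, far = 0.9 * r, 1.2 * r
        quad_t = np.array(
            [[c - near, c, c], [c + near, c, c], [c, c - far, c], [c, c + far, c]]
        )
        quad_t1 = np.array(
            [[c - far, c, c], [c + far, c, c], [c, c - near, c], [c, c + near, c]]
        )
        radii = np.concatenate([np.full(4, r), np.full(len(distractors), 7.0)])
        lab_t = rasterize_laguerre(
            (110, 110, 110), np.vstack([quad_t, distractors]), radii, 1.0
        )
        lab_t1 = rasterize_laguerre(
            (110, 110, 110), np.vstack([quad_t1, distractors]), radii, 1.0
        )
        reg_t = structure.region_properties(lab_t, compute_tensors=False)
        reg_t1 = structure.region_properties(lab_t1, compute_tensors=False)
        tracks = tracking.track_labels(reg_t, reg_t1)
        assert (tracks.status == "matched").all()
        net_t = contacts.get_contacts(lab_t, dilation=1)
        net_t1 = contacts.get_contacts(lab_t1, dilation=1)
        translated = events.translate_pairs(net_t.pairs, tracks)
        L, N = events.lost_new(translated, net_t1.pairs)
        mapping = tracking.match_dict(tracks)
        topo_t = {
            mapping[k]: {mapping[v] for v in s if v in mapping}
            for k, s in contacts.topology_dict(net_t.topology).items()
            if k in mapping
        }
        t1s, _ = events.detect_t1(L, N, topo_t, contacts.topology_dict(net_t1.topology))
        assert len(t1s) == 1
        row = t1s.iloc[0]
        assert {row.lost_p, row.lost_q} == {1, 2}
        assert {row.new_p, row.new_q} == {3, 4}


class TestPairAngle:
    def test_horizontal_bar_is_zero(self):
        # midpoint at (0, 0, 10): e_theta = +y; a bar along y is horizontal
        assert events.pair_angle([0, -3, 10], [0, 3, 10]) == pytest.approx(0.0)

    def test_equal_components_is_45_degrees(self):
        a = events.pair_angle([-3, -3, 10], [3, 3, 10])
        assert a == pytest.approx(45.0, abs=0.5)

    def test_vertical_bar_is_90_degrees(self):
        assert events.pair_angle([-3, 0, 10], [3, 0, 10]) == pytest.approx(90.0)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError):
            events.pair_angle([1, 2, 3], [1, 2, 3])

    def test_isotropic_bars_give_uniform_angles(self):
        rng = np.random.default_rng(21)
        n = 10_000
        mids = rng.uniform(-50, 50, (n, 3))
        mids[:, 1:] += 200.0  # keep midpoints far off-axis
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        alphas = [
            events.pair_angle(m - d, m + d) for m, d in zip(mids, dirs)
        ]
        hist, _ = np.histogram(alphas, bins=18, range=(0, 180))
        expected = n / 18
        # binomial three-sigma band per bin
        sigma = np.sqrt(n * (1 / 18) * (17 / 18))
        assert np.abs(hist - expected).max() < 5 * sigma
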