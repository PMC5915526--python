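import math

import numpy as np
import pytest
import skimage.draw as draw

from neuritree.io import Image2D
from neuritree.phantom import PhantomSpec, generate_phantom
from neuritree.segmentation import BinaryMask, segment
from neuritree.soma import SomaRegion, detect_somas
from neuritree.trace import (NeuriteStart, Seed, SeedIndex, TraceConfig,
                             compute_seeds, distance_map, extract_trees,
                             initialize_neurites, next_seed_search,
                             tile_large_image, trace_neurite)


def brute_force_edt(mask):
    """O(n^2) oracle: min distance from each foreground pixel to background."""
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    for r, c in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1)).min()
    return out


class TestDistanceMap:
    def test_all_background_is_zero(self):
        f = BinaryMask(np.zeros((10, 10), bool))
        np.testing.assert_array_equal(distance_map(f), np.zeros((10, 10)))

    def test_single_foreground_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert distance_map(BinaryMask(m))[4, 4] == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            m = rng.random((32, 32)) > 0.6
            if m.all():
                m[0, 0] = False
            np.testing.assert_allclose(distance_map(BinaryMask(m)),
                                       brute_force_edt(m))

    def test_all_foreground_rejected(self):
        with pytest.raises(ValueError):
            distance_map(BinaryMask(np.ones((5, 5), bool)))


class TestComputeSeeds:
    def test_bar_seeds_on_middle_row(self):
        f = np.zeros((40, 80), dtype=bool)
        f[18:23, 5:75] = True  # 5-px tall bar, centre row 20
        seeds = compute_seeds(BinaryMask(f))
        assert len(seeds) > 0
        assert all(s.position[0] == 20 for s in seeds)

    def test_suppression_ball_rule(self):
        f = np.zeros((60, 120), dtype=bool)
        f[10:20, 5:115] = True
        f[35:40, 5:115] = True
        seeds = compute_seeds(BinaryMask(f))
        for i, a in enumerate(seeds):
            for b in seeds[i + 1:]:
                d = np.linalg.norm(a.position - b.position)
                assert d >= max(a.radius, b.radius) - 1e-9

    def test_empty_mask_gives_no_seeds(self):
        assert compute_seeds(BinaryMask(np.zeros((30, 30), bool))) == []

    def test_seed_positions_on_foreground(self, two_neuron_run):
        f = two_neuron_run.mask.f
        for s in two_neuron_run.seeds:
            r, c = np.round(s.position).astype(int)
            assert f[r, c]
            assert s.radius > 0


def straight_bar_setup():
    f = np.zeros((40, 120), dtype=bool)
    f[18:23, 5:115] = True
    mask = BinaryMask(f)
    seeds = compute_seeds(mask)
    return mask, seeds


class TestNextSeedSearch:
    def test_dead_ahead_seed_found_immediately(self):
        seeds = [Seed(position=np.array([20.0, 25.0]), radius=2.0, index=0)]
        index = SeedIndex(seeds)
        got = next_seed_search(np.array([20.0, 20.0]), 0.0, index,
                               TraceConfig())
        assert got is seeds[0]

    def test_seed_beyond_fan_limit_never_selected(self):
        cfg = TraceConfig()
        pos = np.array([50.0, 50.0])
        results = []
        for dist in (2.0, 5.0, 15.0, 25.0):
            ang = cfg.max_fan_half_angle + 0.05
            p = pos + dist * np.array([math.sin(ang), math.cos(ang)])
            index = SeedIndex([Seed(position=p, radius=2.0, index=0)])
            results.append(next_seed_search(pos, 0.0, index, cfg))
        assert all(r is None for r in results)

    def test_crossing_prefers_aligned_over_nearer_lateral(self):
        """At an X-junction the trace keeps its own neurite: the farther
        but aligned seed wins over the closer one on the crossing branch."""
        pos = np.array([50.0, 50.0])
        theta = 0.0
        dev_a, dev_b = math.radians(5), math.radians(85)
        seed_a = Seed(position=pos + 8.0 * np.array(
            [math.sin(dev_a), math.cos(dev_a)]), radius=2.0, index=0)
        seed_b = Seed(position=pos + 4.0 * np.array(
            [math.sin(dev_b), math.cos(dev_b)]), radius=2.0, index=1)
        got = next_seed_search(pos, theta, SeedIndex([seed_a, seed_b]),
                               TraceConfig())
        assert got is seed_a

    def test_exhausted_rounds_return_none(self):
        far = Seed(position=np.array([20.0, 90.0]), radius=2.0, index=0)
        got = next_seed_search(np.array([20.0, 20.0]), 0.0,
                               SeedIndex([far]), TraceConfig())
        assert got is None  # max reach is 10 + 9*2 = 28 px


class TestTraceNeurite:
    def test_straight_bar_visits_seeds_in_order(self):
        mask, seeds = straight_bar_setup()
        index = SeedIndex(seeds)
        start = NeuriteStart(soma_label=1, point=np.array([20.0, 5.0]),
                             theta0=0.0)
        neurite, _ = trace_neurite(start, index, TraceConfig())
        assert neurite.n_nodes >= len(seeds)  # start + every seed
        cols = neurite.nodes[:, 1]
        assert np.all(np.diff(cols) > 0)
        assert np.all(np.diff(neurite.arclength) > 0)

    def test_no_reachable_seed_terminates_at_start(self):
        start = NeuriteStart(soma_label=1, point=np.array([5.0, 5.0]),
                             theta0=0.0)
        neurite, _ = trace_neurite(start, SeedIndex([]), TraceConfig())
        assert neurite.n_nodes == 1

    def test_turning_angle_bounded(self, standard_suite):
        """Consecutive segment directions never differ by more than the
        fan half-angle limit."""
        cfg = TraceConfig()
        for run in standard_suite[:4]:
            for tree in run.trees:
                for nr in tree.neurites:
                    if nr.n_nodes < 3:
                        continue
                    seg = np.diff(nr.nodes, axis=0)
                    ang = np.arctan2(seg[:, 0], seg[:, 1])
                    turn = np.abs((np.diff(ang) + np.pi) % (2 * np.pi)
                                  - np.pi)
                    assert turn.max() <= cfg.max_fan_half_angle + 1e-9


class TestInitializeNeurites:
    @staticmethod
    def disk_with_bars(angles, shape=(200, 200), soma_radius=20,
                       bar_halfwidth=2.5):
        m = np.zeros(shape, dtype=bool)
        rr, cc = draw.disk((100, 100), soma_radius, shape=shape)
        m[rr, cc] = True
        soma = SomaRegion.from_mask(1, m.copy())
        f = m.copy()
        for a in angles:
            d = np.array([math.sin(a), math.cos(a)])
            for t in np.arange(0, 70, 0.25):
                p = np.array([100.0, 100.0]) + (soma_radius - 2 + t) * d
                rr, cc = draw.disk(tuple(p), bar_halfwidth, shape=shape)
                f[rr, cc] = True
        return soma, BinaryMask(f)

    def test_three_radial_bars_found_with_accurate_angles(self):
        angles = [0.0, 2.0, 4.0]
        soma, f = self.disk_with_bars(angles)
        starts = initialize_neurites(soma, f, TraceConfig())
        assert len(starts) == 3
        for s in starts:
            dev = min(abs((s.theta0 - a + math.pi) % (2 * math.pi) - math.pi)
                      for a in angles)
            assert math.degrees(dev) <= 5.0

    def test_soma_without_neurites_gives_no_starts(self):
        soma, _ = self.disk_with_bars([])
        f = BinaryMask(soma.mask.copy())
        assert initialize_neurites(soma, f, TraceConfig()) == []

    def test_rotating_input_rotates_orientations(self):
        angles = [0.3, 2.2, 4.1]
        soma, f = self.disk_with_bars(angles)
        starts = initialize_neurites(soma, f, TraceConfig())
        soma_r = SomaRegion.from_mask(1, np.rot90(soma.mask).copy())
        f_r = BinaryMask(np.rot90(f.f).copy())
        starts_r = initialize_neurites(soma_r, f_r, TraceConfig())
        assert len(starts_r) == len(starts)
        # rot90 maps direction (dr, dc) -> (-dc, dr), i.e. theta -> theta - pi/2
        want = sorted((s.theta0 - math.pi / 2) % (2 * math.pi)
                      for s in starts)
        got = sorted(s.theta0 for s in starts_r)
        for w, g in zip(want, got):
            dev = abs((w - g + math.pi) % (2 * math.pi) - math.pi)
            assert math.degrees(dev) <= 5.0

    def test_soma_outside_foreground_rejected(self):
        soma, f = self.disk_with_bars([0.0])
        bad = BinaryMask(np.zeros_like(f.f))
        with pytest.raises(ValueError):
            initialize_neurites(soma, bad, TraceConfig())


class TestExtractTrees:
    def test_two_separated_neurons_fully_sorted(self):
        spec = PhantomSpec(shape=(512, 512), n_neurons=2,
                           neurites_per_soma=(3, 3), seed=1)
        stacks, truth = generate_phantom(spec)
        mask = segment(Image2D(stacks["structural"].voxels[0]))
        somas = detect_somas(mask)
        trees, _ = extract_trees(somas, mask)
        assert len(trees) == 2
        from neuritree.evaluate import match_neurites
        res = match_neurites(trees, truth.trees)
        assert res.fn == 0 and res.fp == 0
        assert res.tp == sum(t.n_neurites for t in truth.trees)

    def test_y_bifurcation_spawns_child_branch(self):
        """A Y-shaped neurite yields one neurite plus one child branch
        whose nodes cover both arms."""
        f = np.zeros((220, 220), dtype=bool)
        rr, cc = draw.disk((110, 20), 14, shape=f.shape)
        f[rr, cc] = True
        soma = SomaRegion.from_mask(1, f.copy())
        # stem then two arms at +-30 degrees
        for t in np.arange(0, 60, 0.25):
            rr, cc = draw.disk((110, 30 + t), 2.5, shape=f.shape)
            f[rr, cc] = True
        for sign in (+1, -1):
            d = np.array([sign * math.sin(0.5), math.cos(0.5)])
            for t in np.arange(0, 70, 0.25):
                p = np.array([110.0, 90.0]) + t * d
                rr, cc = draw.disk(tuple(p), 2.5, shape=f.shape)
                f[rr, cc] = True
        mask = BinaryMask(f)
        trees, _ = extract_trees([soma], mask)
        tree = trees[0]
        assert tree.n_neurites == 2
        assert sum(nr.parent is not None for nr in tree.neurites) == 1
        # both arm tips covered
        tips = np.array([[110 + 70 * math.sin(0.5), 90 + 70 * math.cos(0.5)],
                         [110 - 70 * math.sin(0.5), 90 + 70 * math.cos(0.5)]])
        nodes = tree.all_nodes()
        for tip in tips:
            assert np.linalg.norm(nodes - tip, axis=1).min() < 8.0

    def test_seed_consumption_unique_across_trees(self, standard_suite):
        """No seed position appears in two different neurons' trees."""
        for run in standard_suite[:4]:
            seen = {}
            for tree in run.trees:
                for pos in map(tuple, np.round(tree.all_nodes(), 6)):
                    if pos in seen:
                        assert seen[pos] == tree.neuron_id
                    seen[pos] = tree.neuron_id

    def test_trees_are_valid_rooted_trees(self, standard_suite):
        for run in standard_suite:
            for tree in run.trees:
                tree.validate()

    def test_no_somas_rejected(self):
        with pytest.raises(ValueError):
            extract_trees([], BinaryMask(np.zeros((10, 10), bool)))


class TestCrossingResolution:
    def test_two_neuron_crossing_stays_on_own_neurite(self):
        spec = PhantomSpec(shape=(512, 512), n_neurons=1,
                           n_forced_crossings=1,
                           crossing_angle=(math.pi / 2, math.pi / 2), seed=4)
        stacks, truth = generate_phantom(spec)
        mask = segment(Image2D(stacks["structural"].voxels[0]))
        somas = detect_somas(mask)
        trees, _ = extract_trees(somas, mask)
        from neuritree.evaluate import crossing_resolution_rate
        score = crossing_resolution_rate(trees, truth)
        assert score.total == 1
        assert score.solved == 1


class TestTiling:
    @staticmethod
    def somas_at(centers, shape=(800, 800), radius=12):
        regions = []
        for i, c in enumerate(centers, start=1):
            m = np.zeros(shape, dtype=bool)
            rr, cc = draw.disk(c, radius, shape=shape)
            m[rr, cc] = True
            regions.append(SomaRegion.from_mask(i, m))
        return regions, BinaryMask(np.zeros(shape, dtype=bool))

    def test_close_somas_share_one_tile(self):
        somas, f = self.somas_at([(100, 100), (140, 160), (180, 120)])
        tiles = tile_large_image(f, somas, max_tile=600, overlap=32,
                                 cluster_cutoff=100)
        assert len(tiles) == 1
        rect, members = tiles[0]
        assert len(members) == 3
        for s in members:
            rr, cc = np.nonzero(s.mask)
            assert rect[0] <= rr.min() and rr.max() < rect[1]
            assert rect[2] <= cc.min() and cc.max() < rect[3]

    def test_two_distant_clusters_get_two_tiles(self):
        somas, f = self.somas_at([(100, 100), (130, 140),
                                  (600, 620), (640, 660)])
        tiles = tile_large_image(f, somas, max_tile=400, overlap=32,
                                 cluster_cutoff=100)
        assert len(tiles) == 2
        sizes = sorted(len(members) for _, members in tiles)
        assert sizes == [2, 2]

    def test_every_soma_in_exactly_one_tile(self):
        somas, f = self.somas_at([(100, 100), (130, 140), (300, 500),
                                  (600, 620), (640, 660), (400, 100)])
        tiles = tile_large_image(f, somas, max_tile=500, overlap=32,
                                 cluster_cutoff=120)
        assigned = [s.label for _, members in tiles for s in members]
        assert sorted(assigned) == [1, 2, 3, 4, 5, 6]

    def test_oversized_soma_rejected(self):
        somas, f = self.somas_at([(400, 400)], radius=80)
        with pytest.raises(ValueError):
            tile_large_image(f, somas, max_tile=100, overlap=16)
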