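import numpy as np
import pytest

from lensfree_detect import ClusterConfig, cluster_mask, cluster_mask_oracle


def mask_from_points(points, shape=(100, 100)):
    m = np.zeros(shape, dtype=bool)
    for r, c in points:
        m[r, c] = True
    return m


def random_border_clear_mask(seed, shape=(100, 100), patch=25, n_clusters=4):
    """Sparse mask whose clusters stay >= linkage AND merge distance away
    from every patch border and from each other."""
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, dtype=bool)
    centers = []
    for _ in range(n_clusters):
        for _ in range(200):
            pr = rng.integers(0, shape[0] // patch) * patch
            pc = rng.integers(0, shape[1] // patch) * patch
            r = pr + rng.integers(8, patch - 8)
            c = pc + rng.integers(8, patch - 8)
            if all(np.hypot(r - rr, c - cc) > 16 for rr, cc in centers):
                centers.append((r, c))
                break
        else:
            continue
        r, c = centers[-1]
        n_px = rng.integers(2, 6)
        m[r, c] = True
        for _ in range(n_px):
            dr, dc = rng.integers(-2, 3, size=2)
            rr, cc = np.clip(r + dr, 0, shape[0] - 1), np.clip(c + dc, 0, shape[1] - 1)
            m[rr, cc] = True
    return m


class TestClusterMask:
    def test_empty_mask_empty_list(self):
        assert cluster_mask(np.zeros((50, 50), dtype=bool)) == []

    def test_two_pixels_linked_midpoint_mean(self):
        clusters = cluster_mask(mask_from_points([(5, 5), (5, 7)]))
        assert len(clusters) == 1
        assert clusters[0].midpoint == (5, 6)

    def test_chain_links_and_isolated_dropped(self):
        clusters = cluster_mask(mask_from_points([(2, 2), (2, 4), (2, 6), (20, 20)]))
        assert len(clusters) == 1
        assert clusters[0].midpoint == (2, 4)
        assert set(clusters[0].members) == {(2, 2), (2, 4), (2, 6)}

    def test_three_px_gap_does_not_link(self):
        clusters = cluster_mask(mask_from_points([(5, 5), (5, 8), (5, 11)]),
                                ClusterConfig(min_size=1, merge_dist=0))
        assert len(clusters) == 3

    def test_midpoint_rounds_half_away_from_zero(self):
        # mean col of {4, 5} = 4.5 -> 5
        clusters = cluster_mask(mask_from_points([(3, 4), (3, 5)]))
        assert clusters[0].midpoint == (3, 5)

    def test_midpoint_inside_bounding_box(self):
        clusters = cluster_mask(random_border_clear_mask(7), ClusterConfig())
        for cl in clusters:
            rows = [m[0] for m in cl.members]
            cols = [m[1] for m in cl.members]
            assert min(rows) <= cl.midpoint[0] <= max(rows)
            assert min(cols) <= cl.midpoint[1] <= max(cols)

    def test_translation_equivariance_by_patch_multiples(self):
        pts = [(10, 10), (10, 12), (11, 11), (40, 60), (41, 61), (42, 60)]
        base = cluster_mask(mask_from_points(pts, (200, 200)))
        shifted = cluster_mask(mask_from_points(
            [(r + 25, c + 50) for r, c in pts], (200, 200)))
        got = sorted(c.midpoint for c in shifted)
        want = sorted((r + 25, c + 50) for r, c in (c.midpoint for c in base))
        assert got == want

    def test_partition_disjoint_and_covering(self):
        m = random_border_clear_mask(3)
        clusters = cluster_mask(m, ClusterConfig(min_size=1))
        seen = set()
        for cl in clusters:
            for member in cl.members:
                assert member not in seen
                seen.add(member)
        assert seen == {tuple(p) for p in np.argwhere(m)}


class TestOracleAgreement:
    def test_oracle_empty(self):
        assert cluster_mask_oracle(np.zeros((20, 20), dtype=bool)) == []

    def test_100_random_sparse_masks_match_oracle(self):
        for seed in range(100):
            m = random_border_clear_mask(seed)
            got = cluster_mask(m)
            want = cluster_mask_oracle(m)
            assert [c.midpoint for c in got] == [c.midpoint for c in want], seed
            assert [c.members for c in got] == [c.members for c in want], seed

    def test_boundary_straddling_pair_merged(self):
        # patch border at col 25; two pixels distance 2 apart across it
        m = mask_from_points([(10, 24), (10, 26)])
        want = cluster_mask_oracle(m)
        got = cluster_mask(m)
        assert len(want) == 1
        assert len(got) == 1
        assert got[0].midpoint == want[0].midpoint == (10, 25)

    def test_large_cluster_straddling_four_patches(self):
        # dense blob centred on the (25, 25) patch corner
        pts = [(r, c) for r in range(20, 31) for c in range(20, 31)
               if (r - 25) ** 2 + (c - 25) ** 2 <= 25]
        m = mask_from_points(pts)
        got = cluster_mask(m)
        want = cluster_mask_oracle(m)
        assert len(got) == len(want) == 1
        assert got[0].midpoint == want[0].midpoint

    def test_distinct_clusters_near_border_not_merged(self):
        # two clusters straddling nothing, 8 px apart across a border:
        # farther than linkage, farther than merge_dist -> stay separate
        pts = [(10, 20), (10, 21), (10, 29), (10, 30)]
        m = mask_from_points(pts)
        got = cluster_mask(m)
        want = cluster_mask_oracle(m)
        assert len(got) == len(want) == 2
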