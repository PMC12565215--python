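import math

import numpy as np
import pytest

from mycograze.individuals import (
    SporocarpPoint,
    cluster_individuals,
    individual_number,
    observations_from_points,
)


def brute_force_codes(coords, separation=2.0):
    """Independent oracle: union-find over all pairwise distances, then the
    connection gap of each group as the smallest threshold making it connected."""
    coords = [tuple(c) for c in coords]
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def dist(i, j):
        return math.dist(coords[i], coords[j])

    for i in range(n):
        for j in range(i + 1, n):
            if dist(i, j) <= separation:
                parent[find(i)] = find(j)

    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    codes = []
    for members in clusters.values():
        if len(members) == 1:
            codes.append(1)
            continue
        # smallest threshold at which the group is connected (Kruskal-style)
        edges = sorted(
            (dist(i, j), i, j) for k, i in enumerate(members) for j in members[k + 1 :]
        )
        par = {i: i for i in members}

        def f2(i):
            while par[i] != i:
                par[i] = par[par[i]]
                i = par[i]
            return i

        gap = 0.0
        joined = 0
        for d, i, j in edges:
            ri, rj = f2(i), f2(j)
            if ri != rj:
                par[ri] = rj
                joined += 1
                gap = d
                if joined == len(members) - 1:
                    break
        if gap <= 0.5:
            codes.append(2)
        elif gap <= 1.0:
            codes.append(3)
        else:
            codes.append(4)
    return sorted(codes)


class TestTableRules:
    def test_single_sporocarp_is_one_individual(self):
        assert [c.code for c in cluster_individuals([(0.0, 0.0)])] == [1]

    def test_tight_pair_codes_two(self):
        codes = cluster_individuals([(0, 0), (0.4, 0)])
        assert [c.code for c in codes] == [2]

    def test_distant_pair_splits_into_two_individuals(self):
        codes = cluster_individuals([(0, 0), (2.5, 0)])
        assert sorted(c.code for c in codes) == [1, 1]

    def test_three_point_chain_codes_three(self):
        codes = cluster_individuals([(0, 0), (0.9, 0), (1.8, 0)])
        assert len(codes) == 1
        assert codes[0].code == 3
        assert codes[0].max_gap == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "gap, expected",
        [(0.5, 2), (0.50001, 3), (1.0, 3), (1.00001, 4), (2.0, 4)],
    )
    def test_thresholds_inclusive(self, gap, expected):
        codes = cluster_individuals([(0, 0), (gap, 0)])
        assert [c.code for c in codes] == [expected]

    def test_split_strictly_above_separation(self):
        # exactly 2 m chains into one group (code 4); 2.001 m splits
        assert len(cluster_individuals([(0, 0), (2.0, 0)])) == 1
        assert len(cluster_individuals([(0, 0), (2.001, 0)])) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_individuals([])


class TestIndividualNumber:
    def test_single_point(self):
        assert individual_number([(0, 0)]) == 1

    def test_codes_are_additive_across_groups(self):
        # one tight pair (code 2) plus a far singleton (code 1)
        assert individual_number([(0, 0), (0.3, 0), (5, 5)]) == 3

    def test_combine_max_alternative(self):
        assert individual_number([(0, 0), (0.3, 0), (5, 5)], combine="max") == 2

    def test_all_far_apart(self):
        rng = np.random.default_rng(5)
        pts = [(x * 3.0, rng.uniform(0, 0.4)) for x in range(10)]
        # brute-force confirms every pair exceeds the separation
        assert all(
            math.dist(pts[i], pts[j]) > 2.0
            for i in range(10)
            for j in range(i + 1, 10)
        )
        assert individual_number(pts) == 10


class TestOracleAgreement:
    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            pts = rng.uniform(0, 8, (n, 2)).tolist()
            got = sorted(c.code for c in cluster_individuals(pts))
            assert got == brute_force_codes(pts)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            pts = rng.uniform(0, 6, (n, 2))
            theta = rng.uniform(0, 2 * math.pi)
            rot = np.array(
                [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
            )
            moved = pts @ rot.T + rng.uniform(-30, 30, 2)
            a = sorted(c.code for c in cluster_individuals(pts.tolist()))
            b = sorted(c.code for c in cluster_individuals(moved.tolist()))
            assert a == b

    def test_adding_a_point_bounded_change(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            pts = rng.uniform(0, 6, (n, 2)).tolist()
            base = individual_number(pts)
            extra = pts + [rng.uniform(0, 6, 2).tolist()]
            new = individual_number(extra)
            assert new >= 1
            assert new >= base - 3  # merging can absorb at most a code-4 drop


def test_points_to_observation_records():
    pts = [
        SporocarpPoint("A", "f/g/q1/s1", 0.0, 0.0),
        SporocarpPoint("A", "f/g/q1/s1", 0.3, 0.0),
        SporocarpPoint("B", "f/g/q1/s1", 5.0, 5.0),
    ]
    records = observations_from_points(pts)
    assert records == [
        {"unit": "f/g/q1/s1", "species": "A", "individual_number": 2},
        {"unit": "f/g/q1/s1", "species": "B", "individual_number": 1},
    ]
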