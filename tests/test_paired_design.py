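"""Distant-pair construction and paired peptide design."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from discopep.fixtures import paired_scaffold_spec
from discopep.paired_design import (
    DegeneratePairError,
    alternate_pairs,
    build_pairs,
    design_paired,
    most_distant_pair,
    pair_table,
    second_pair,
    third_pair,
)

from conftest import context_from_spec, make_residue


def octahedron_residues(radius=10.0):
    # numbers 10..60: +x, -x, +y, -y, +z, -z
    coords = [
        (radius, 0, 0), (-radius, 0, 0), (0, radius, 0),
        (0, -radius, 0), (0, 0, radius), (0, 0, -radius),
    ]
    return [make_residue(10 * (i + 1), c) for i, c in enumerate(coords)]


def cloud_residues(n, seed, box=50.0):
    rng = np.random.default_rng(seed)
    return [make_residue(i + 1, rng.uniform(0, box, 3)) for i in range(n)]


class TestMostDistantPair:
    def test_cube_diagonal(self):
        side = 10.0
        corners = [
            make_residue(i + 1, (x, y, z))
            for i, (x, y, z) in enumerate(
                (x, y, z) for x in (0, side) for y in (0, side) for z in (0, side)
            )
        ]
        pair = most_distant_pair(corners)
        assert pair.distance == pytest.approx(side * np.sqrt(3))

    def test_two_points(self):
        pts = [make_residue(1, (0, 0, 0)), make_residue(2, (4, 0, 0))]
        pair = most_distant_pair(pts)
        assert pair.keys == (("A", 1, ""), ("A", 2, ""))
        with pytest.raises(DegeneratePairError):
            most_distant_pair(pts[:1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_cloud(self, seed):
        residues = cloud_residues(200, seed)
        points = np.array([r.ca for r in residues])
        oracle = cdist(points, points).max()
        assert most_distant_pair(residues).distance == pytest.approx(oracle)

    def test_anchor_fixes_one_endpoint(self):
        residues = octahedron_residues()
        anchored = most_distant_pair(residues, anchor=("A", 30, ""))
        assert ("A", 30, "") in anchored.keys
        assert ("A", 40, "") in anchored.keys  # farthest from +y is -y


class TestSecondPair:
    def test_octahedron_picks_the_y_pair_by_tie_break(self):
        residues = octahedron_residues()
        pair1 = most_distant_pair(residues)
        assert pair1.keys == (("A", 10, ""), ("A", 20, ""))  # x pair by key order
        pair2 = second_pair(residues, pair1)
        assert pair2.keys == (("A", 30, ""), ("A", 40, ""))
        assert pair2.distance == pytest.approx(20.0)

    def test_band_boundary_inclusive_at_five_angstrom(self):
        residues = [
            make_residue(1, (-20, 0, 0)),
            make_residue(2, (20, 0, 0)),
            make_residue(3, (5.0, 8, 0)),    # exactly 5.0 from the plane
            make_residue(4, (-5.0, -8, 0)),
            make_residue(5, (5.1, 12, 0)),   # 5.1 -> excluded
        ]
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        assert set(pair2.keys) == {("A", 3, ""), ("A", 4, "")}

    def test_no_candidates_raises(self):
        residues = [make_residue(i, (10.0 * i, 0, 0)) for i in range(1, 5)]
        pair1 = most_distant_pair(residues)
        with pytest.raises(DegeneratePairError):
            second_pair(residues, pair1, plane_tolerance=2.0)


class TestThirdPair:
    def test_octahedron_yields_the_z_pair(self):
        residues = octahedron_residues()
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        pair3 = third_pair(residues, pair1, pair2)
        assert pair3.keys == (("A", 50, ""), ("A", 60, ""))
        assert pair3.distance == pytest.approx(20.0)

    def test_zero_thickness_without_coplanar_points_raises(self):
        residues = cloud_residues(30, seed=12)
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        with pytest.raises(DegeneratePairError):
            third_pair(residues, pair1, pair2, slab_thickness=0.0)

    def test_exactly_coplanar_points_survive_zero_thickness(self):
        residues = octahedron_residues()
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        pair3 = third_pair(residues, pair1, pair2, slab_thickness=0.0)
        assert pair3.keys == (("A", 50, ""), ("A", 60, ""))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_with_same_slab_rule(self, seed):
        residues = cloud_residues(80, 10 + seed)
        points = np.array([sorted(residues, key=lambda r: r.key)[i].ca
                           for i in range(len(residues))])
        keys = sorted(r.key for r in residues)
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        mask = np.ones(len(keys), dtype=bool)
        for pair in (pair1, pair2):
            a = points[keys.index(pair.residue_a)]
            b = points[keys.index(pair.residue_b)]
            u = (b - a) / np.linalg.norm(b - a)
            mid = (a + b) / 2
            mask &= np.abs((points - mid) @ u) <= 5.0
        if mask.sum() < 2:
            with pytest.raises(DegeneratePairError):
                third_pair(residues, pair1, pair2)
            return
        idx = np.flatnonzero(mask)
        oracle = max(
            np.linalg.norm(points[i] - points[j])
            for i in idx for j in idx if i < j
        )
        assert third_pair(residues, pair1, pair2).distance == pytest.approx(oracle)


class TestAlternatePairs:
    def test_octahedron_alternate_distance(self):
        residues = octahedron_residues()
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        pair3 = third_pair(residues, pair1, pair2)
        pair4, pair5 = alternate_pairs(residues, pair2, pair3)
        assert pair4.distance == pytest.approx(10 * np.sqrt(2))
        assert pair5.distance == pytest.approx(10 * np.sqrt(2))
        # anchored at an endpoint of the source pair, partner elsewhere
        assert set(pair4.keys) & {("A", 30, ""), ("A", 40, "")}
        assert not set(pair4.keys) == {("A", 30, ""), ("A", 40, "")}

    def test_exclusion_forces_a_different_partner(self):
        # pair2's farthest point is its own partner; exclusion forces third point
        residues = [
            make_residue(1, (-12, 0, 0)),
            make_residue(2, (12, 0, 0)),
            make_residue(3, (0, 10, 0)),
            make_residue(4, (0, -10, 0)),
            make_residue(5, (0, 6, 5)),
        ]
        pair1 = most_distant_pair(residues)
        pair2 = second_pair(residues, pair1)
        assert set(pair2.keys) == {("A", 3, ""), ("A", 4, "")}
        pair4, _ = alternate_pairs(residues, pair2, None)
        assert set(pair4.keys) != set(pair2.keys)

    def test_missing_pair3_omits_pair5(self):
        # planar cross: pair3 construction degenerates, rank 5 never appears
        residues = [
            make_residue(1, (-10, 0, 0)),
            make_residue(2, (10, 0, 0)),
            make_residue(3, (0, 9, 0)),
            make_residue(4, (0, -9, 0)),
        ]
        pairs = build_pairs(residues)
        ranks = [p.rank for p in pairs]
        assert 5 not in ranks
        assert 3 not in ranks  # nothing inside both bisector slabs
        assert set(ranks) == {1, 2, 4}


class TestPairInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_pair1_dominates_all_returned_pairs(self, seed):
        ctx = context_from_spec(paired_scaffold_spec(seed=seed))
        pairs = build_pairs(ctx.accessible_residues())
        assert pairs[0].rank == 1
        for other in pairs[1:]:
            assert other.distance <= pairs[0].distance + 1e-9

    def test_rigid_motion_selects_the_same_residues(self):
        residues = cloud_residues(40, seed=6)
        rng = np.random.default_rng(6)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-40, 40, 3)
        moved = [
            make_residue(r.author_number, r.ca @ q.T + shift) for r in residues
        ]
        before = build_pairs(residues)
        after = build_pairs(moved)
        assert [(p.rank, p.keys) for p in before] == [(p.rank, p.keys) for p in after]

    def test_anchor_equal_to_free_pair1_endpoint_coincides(self):
        residues = cloud_residues(30, seed=9)
        free = most_distant_pair(residues)
        anchored = most_distant_pair(residues, anchor=free.residue_a)
        assert anchored.keys == free.keys
        assert anchored.distance == pytest.approx(free.distance)


class TestDesignPaired:
    def test_scaffold_returns_five_pairs_and_ten_peptides(self, scaffold_ctx):
        result = design_paired(scaffold_ctx, "NN", 10)
        assert len(result.pairs) == 5
        assert [p.rank for p in result.pairs] == [1, 2, 3, 4, 5]
        assert len(result.peptides) == 5
        assert sum(len(pair) for pair in result.peptides) == 10
        for pair, (pep_a, pep_b) in zip(result.pairs, result.peptides):
            for key, pep in zip(pair.keys, (pep_a, pep_b)):
                ref_seg = scaffold_ctx.segment_containing(key)
                assert pep.reference == ref_seg.id
                assert key in {
                    k for p in pep.parts for k in p.residue_keys
                }

    def test_anchor_appears_in_pair1(self, scaffold_ctx):
        anchor = scaffold_ctx.accessible_residues()[3].key
        result = design_paired(scaffold_ctx, "NN", 10, anchor=anchor)
        assert anchor in result.pairs[0].keys

    def test_two_residue_structure_degrades_to_one_pair(self):
        from discopep.fixtures import FixtureSpec, synth_structure
        from discopep.structure_io import read_structure
        from discopep.design_methods import DesignContext

        spec = FixtureSpec(
            name="duo",
            ca_coordinates=np.array([[0, 0, 0], [20, 0, 0]]),
            sequence="KD",
            author_numbers=(1, 9),
        )
        ctx = DesignContext.prepare(read_structure(synth_structure(spec)))
        result = design_paired(ctx, "NN", 1)
        assert len(result.pairs) == 1
        assert len(result.peptides[0]) == 2

    def test_residue_level_method_uses_the_endpoint_itself(self, scaffold_ctx):
        result = design_paired(
            scaffold_ctx, "SHPaa", 6, options={"proximity_cutoff": 25.0}
        )
        for pair, peps in zip(result.pairs, result.peptides):
            for key, pep in zip(pair.keys, peps):
                assert pep.reference == key

    def test_pair_report_table(self, scaffold_ctx):
        result = design_paired(scaffold_ctx, "NN", 10)
        table = pair_table(result)
        assert list(table.columns) == [
            "rank", "rule", "residue_a", "residue_b",
            "distance_A", "peptide_a", "peptide_b",
        ]
        assert len(table) == 5
        assert table["distance_A"].iloc[0] == table["distance_A"].max()
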