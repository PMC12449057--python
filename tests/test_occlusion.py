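"""Occlusion engine: neighbour queries, burial, ray casting, invariances."""

import math

import numpy as np
import pytest

from conftest import records_key
from fibos.dots import dots_on_atom
from fibos.fixtures import brute_force_occlusion, make_dimer, make_random_cluster
from fibos.occlusion import (
    build_neighbor_index,
    cast_normal,
    compute_occlusion,
    remove_buried_dots,
)
from fibos.structure import Atom, Structure


def carbon(serial, coord, r=1.7):
    return Atom(serial, "CA", "C", "ALA", "A", serial, coord=coord, radius=r)


class TestNeighborIndex:
    def test_pair_within_cutoff(self):
        s = Structure([carbon(1, [0, 0, 0]), carbon(2, [0, 0, 3.0])])
        idx = build_neighbor_index(s, d_w=2.8)
        assert idx.neighbors_of(0) == [1]
        assert idx.neighbors_of(1) == [0]

    def test_isolated_atom_has_no_neighbors(self):
        s = Structure([carbon(1, [0, 0, 0])])
        idx = build_neighbor_index(s)
        assert idx.neighbors_of(0) == []

    def test_empty_structure(self):
        idx = build_neighbor_index(Structure())
        assert idx.query_point(np.zeros(3)) == []

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(11)
        s = make_random_cluster(n=50, box=20.0, seed=3)
        idx = build_neighbor_index(s, d_w=2.8)
        coords = s.coords()
        for point in rng.uniform(0, 20, size=(100, 3)):
            expected = sorted(
                int(i) for i in np.flatnonzero(
                    np.linalg.norm(coords - point, axis=1) <= idx.cutoff
                )
            )
            assert idx.query_point(point) == expected


class TestRemoveBuriedDots:
    def test_isolated_atom_keeps_all_dots(self):
        a = carbon(1, [0, 0, 0])
        dots = dots_on_atom(a, density=5.0)
        kept, idx = remove_buried_dots(a, dots, [])
        assert kept.n_dots == dots.n_dots
        assert np.array_equal(idx, np.arange(dots.n_dots))

    def test_overlapping_dimer_matches_spherical_cap(self):
        """Buried fraction of each sphere equals the analytic cap (1 - d/2r)/2."""
        r, d = 1.7, 2.4
        s = make_dimer(r=r, d=d)
        a, b = s.atoms
        dots = dots_on_atom(a, density=1000 / (4 * math.pi * r * r))
        kept, _ = remove_buried_dots(a, dots, [b])
        frac = 1.0 - kept.n_dots / dots.n_dots
        expected = (1.0 - d / (2 * r)) / 2.0
        se = math.sqrt(expected * (1 - expected) / dots.n_dots)
        assert abs(frac - expected) < 3 * se

    def test_contained_atom_loses_everything(self):
        small = carbon(1, [0, 0, 0], r=1.0)
        big = carbon(2, [0.1, 0, 0], r=2.9)
        dots = dots_on_atom(small, density=5.0)
        kept, _ = remove_buried_dots(small, dots, [big])
        assert kept.n_dots == 0

    def test_areas_preserved_per_dot(self):
        s = make_dimer(r=1.7, d=2.4)
        a, b = s.atoms
        dots = dots_on_atom(a, density=5.0)
        kept, idx = remove_buried_dots(a, dots, [b])
        assert np.array_equal(kept.areas, dots.areas[idx])


class TestCastNormal:
    def test_vacuous_without_neighbors(self):
        assert cast_normal([0, 0, 0], [0, 0, 1], []) == (False, None, None)

    def test_collinear_hit(self):
        nb = carbon(9, [0, 0, 3.0], r=1.5)
        occluded, length, who = cast_normal([0, 0, 0], [0, 0, 1], [nb])
        assert occluded and who == 9
        assert length == pytest.approx(1.5, abs=1e-12)

    def test_off_axis_hit_matches_quadratic_root(self):
        # |t*z - (0,1,2)| = 1.2  =>  t^2 - 4t + 3.56 = 0, smaller root
        nb = carbon(9, [0, 1, 2], r=1.2)
        occluded, length, _ = cast_normal([0, 0, 0], [0, 0, 1], [nb])
        expected = (4 - math.sqrt(16 - 4 * 3.56)) / 2
        assert occluded
        assert length == pytest.approx(expected, abs=1e-12)

    def test_beyond_water_diameter_not_occluded(self):
        nb = carbon(9, [0, 0, 6.0], r=1.5)  # surface at 4.5 > d_w
        occluded, length, who = cast_normal([0, 0, 0], [0, 0, 1], [nb], d_w=2.8)
        assert (occluded, length, who) == (False, None, None)

    def test_origin_inside_sphere_gives_zero_length(self):
        nb = carbon(9, [0, 0, 0.5], r=1.2)
        occluded, length, _ = cast_normal([0, 0, 0], [0, 0, 1], [nb])
        assert occluded and length == 0.0

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            cast_normal([0, 0, 0], [0, 0, 2], [carbon(9, [0, 0, 3])])


class TestEngineProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        """Spatial-index engine equals exhaustive all-pairs ray casting."""
        s = make_random_cluster(n=12, box=11.0, seed=seed)
        density = 50 / (4 * math.pi * 1.7**2)
        engine = compute_occlusion(s, density=density)
        oracle = brute_force_occlusion(s, density=density)
        assert records_key(engine) == records_key(oracle)

    def test_symmetric_dimer_occludes_both_atoms_equally(self):
        s = make_dimer(r=1.7, d=3.4)
        records = compute_occlusion(s, density=5.0)
        counts = {1: 0, 2: 0}
        for r in records:
            if r.occluded:
                counts[r.atom_serial] += 1
        assert counts[1] > 0 and counts[2] > 0
        # the Fibonacci lattice is not mirror-symmetric; discretization only
        assert abs(counts[1] - counts[2]) <= 0.1 * max(counts.values())

    def test_isolated_atom_has_no_occlusions(self):
        s = Structure([carbon(1, [0, 0, 0])])
        records = compute_occlusion(s, density=5.0)
        assert records and not any(r.occluded for r in records)

    def test_occluded_lengths_bounded_by_water_diameter(self):
        s = make_random_cluster(n=20, box=14.0, seed=8)
        for d_w in (1.4, 2.8):
            records = compute_occlusion(s, density=2.0, d_w=d_w)
            lengths = [r.length for r in records if r.occluded]
            assert lengths
            assert all(0.0 <= L <= d_w for L in lengths)

    def test_rigid_motion_invariance_with_corotated_lattice(self, shell12):
        """A global rotation+translation applied to atoms and dots leaves
        every occlusion flag and length unchanged."""
        density = 5.0
        clouds = [dots_on_atom(a, density=density) for a in shell12]
        base = compute_occlusion(shell12, dot_clouds=clouds)

        rng = np.random.default_rng(4)
        m = rng.normal(size=(3, 3))
        q, _ = np.linalg.qr(m)
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([5.0, -3.0, 11.0])

        moved = shell12.copy()
        for a in moved:
            a.coord = q @ a.coord + shift
        moved_clouds = [c.transformed(q, shift) for c in clouds]
        rotated = compute_occlusion(moved, dot_clouds=moved_clouds)

        assert len(base) == len(rotated)
        for r0, r1 in zip(base, rotated):
            assert (r0.atom_serial, r0.dot_index, r0.occluded, r0.occluder_serial) == (
                r1.atom_serial, r1.dot_index, r1.occluded, r1.occluder_serial)
            if r0.occluded:
                assert r1.length == pytest.approx(r0.length, abs=1e-6)

    def test_closer_dimer_never_less_occluded(self):
        """At fixed lattice, shrinking the separation (down to contact)
        cannot reduce either atom's occluded-dot count."""
        prev = None
        for d in (6.0, 5.2, 4.4, 3.4):
            s = make_dimer(r=1.7, d=d)
            records = compute_occlusion(s, density=5.0)
            count = sum(r.occluded for r in records)
            if prev is not None:
                assert count >= prev
            prev = count
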