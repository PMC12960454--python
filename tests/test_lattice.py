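import numpy as np
import pytest

from coss.errors import AlignmentError, UsageError
from coss.lattice import (
    align_to_lattice,
    lattice_from_axial,
    neighbor_distance_sequence,
)


def brute_force_sequence(lattice_type, spacing, count, extent=40):
    """Independent oracle: enumerate all sites of a big lattice patch."""
    if lattice_type == "hexagonal":
        basis = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    else:
        basis = np.eye(2)
    rng = np.arange(-extent, extent + 1)
    q, r = np.meshgrid(rng, rng, indexing="ij")
    pts = np.stack([q.ravel(), r.ravel()], axis=1) @ basis
    return spacing * np.sort(np.linalg.norm(pts, axis=1))[:count]


class TestNeighborDistanceSequence:
    def test_hex_first_shell(self):
        d = neighbor_distance_sequence("hexagonal", 1.0, 7)
        assert np.allclose(d, [0, 1, 1, 1, 1, 1, 1])

    def test_hex_second_shell(self):
        d = neighbor_distance_sequence("hexagonal", 1.0, 13)
        assert np.allclose(d[7:], np.sqrt(3))

    def test_square_shells(self):
        d = neighbor_distance_sequence("square", 2.0, 9)
        assert np.allclose(d, [0, 2, 2, 2, 2] + [2 * np.sqrt(2)] * 4)

    @pytest.mark.parametrize("lattice_type", ["hexagonal", "square"])
    @pytest.mark.parametrize("spacing", [1.0, 2.5])
    def test_agrees_with_brute_force_to_200(self, lattice_type, spacing):
        got = neighbor_distance_sequence(lattice_type, spacing, 200)
        want = brute_force_sequence(lattice_type, spacing, 200)
        assert np.allclose(got, want)
        assert np.all(np.diff(got) >= -1e-12)

    def test_scales_linearly_with_spacing(self):
        a = neighbor_distance_sequence("hexagonal", 1.0, 50)
        b = neighbor_distance_sequence("hexagonal", 3.0, 50)
        assert np.allclose(b, 3.0 * a)

    def test_bad_inputs(self):
        with pytest.raises(UsageError):
            neighbor_distance_sequence("triangular", 1.0, 5)
        with pytest.raises(UsageError):
            neighbor_distance_sequence("square", 1.0, 0)


class TestAlign:
    def test_square_grid_exact(self):
        coords = np.array([(x, y) for x in range(5) for y in range(5)], float)
        lat = align_to_lattice(coords)
        assert lat.lattice_type == "square"
        assert lat.spacing == pytest.approx(1.0)
        deg = lat.degrees()
        assert deg.max() == 4
        # interior wells have full degree
        interior = np.all((coords > 0) & (coords < 4), axis=1)
        assert np.all(deg[interior] == 4)

    def test_jittered_hex(self, rng):
        base = lattice_from_axial(
            [(q, r) for q in range(12) for r in range(12)], "hexagonal", 100.0
        )
        coords = base.ideal_coords + rng.normal(0, 1.0, base.coords.shape)
        lat = align_to_lattice(coords)
        assert lat.lattice_type == "hexagonal"
        assert abs(lat.spacing - 100.0) / 100.0 < 0.01
        assert lat.degrees().max() == 6
        lat.validate()

    def test_collinear_error(self):
        with pytest.raises(AlignmentError):
            align_to_lattice([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])

    def test_too_few_points(self):
        with pytest.raises(AlignmentError):
            align_to_lattice([(0.0, 0.0), (1.0, 1.0)])

    def test_duplicate_points(self):
        with pytest.raises(AlignmentError):
            align_to_lattice([(0.0, 0.0), (0.0, 0.0), (1.0, 0.0), (0.0, 1.0)])

    def test_idempotent_on_ideal_coords(self, rng):
        base = lattice_from_axial(
            [(q, r) for q in range(8) for r in range(10)], "hexagonal", 10.0
        )
        coords = base.ideal_coords + rng.normal(0, 0.2, base.coords.shape)
        lat = align_to_lattice(coords)
        again = align_to_lattice(lat.ideal_coords)
        assert np.array_equal(lat.axial_index, again.axial_index)

    def test_excessive_jitter_names_offenders(self, rng):
        base = lattice_from_axial(
            [(q, r) for q in range(8) for r in range(8)], "square", 1.0
        )
        coords = base.ideal_coords.copy()
        coords[:10] += 0.45  # >0.25 spacing for >5% of wells
        with pytest.raises(AlignmentError, match="offenders"):
            align_to_lattice(coords, lattice_type="square")

    def test_shared_site_error(self):
        coords = np.array(
            [(x, y) for x in range(4) for y in range(4)], float
        )
        coords = np.vstack([coords, [[0.05, 0.05]]])  # snaps onto (0,0)
        with pytest.raises(AlignmentError, match="same"):
            align_to_lattice(coords, lattice_type="square", max_bad_fraction=1.0)

    @pytest.mark.parametrize("lattice_type", ["hexagonal", "square"])
    def test_adjacency_matches_distance_threshold(self, lattice_type, rng):
        base = lattice_from_axial(
            [(q, r) for q in range(9) for r in range(9)], lattice_type, 5.0
        )
        coords = base.ideal_coords + rng.normal(0, 0.1, base.coords.shape)
        lat = align_to_lattice(coords)
        ideal = lat.ideal_coords
        d = np.linalg.norm(ideal[:, None, :] - ideal[None, :, :], axis=2)
        want = (d > 1e-9) & (d < 1.25 * lat.spacing)
        got = np.zeros_like(want)
        for i, nbrs in enumerate(lat.adjacency):
            for j in nbrs:
                got[i, j] = True
        assert np.array_equal(got, want)

    def test_rotated_lattice_aligns(self, rng):
        base = lattice_from_axial(
            [(q, r) for q in range(10) for r in range(10)], "hexagonal", 2.0
        )
        theta = 0.37
        rot = np.array(
            [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
        )
        lat = align_to_lattice(base.ideal_coords @ rot + np.array([5.0, -3.0]))
        assert lat.lattice_type == "hexagonal"
        assert lat.spacing == pytest.approx(2.0, rel=1e-6)
        lat.validate()


class TestWellLattice:
    def test_interior_degree_hex(self, hex_lattice_10x10):
        deg = hex_lattice_10x10.degrees()
        ax = hex_lattice_10x10.axial_index
        interior = np.all((ax > 0) & (ax < 9), axis=1)
        assert np.all(deg[interior] == 6)

    def test_disconnected_components_allowed(self):
        lat = lattice_from_axial(
            [(0, 0), (1, 0), (10, 10), (11, 10)], "square", 1.0
        )
        assert sorted(map(len, lat.adjacency)) == [1, 1, 1, 1]
        lat.validate()

    def test_edges_sorted_unique(self, square_lattice_5x5):
        e = square_lattice_5x5.edges()
        assert np.all(e[:, 0] < e[:, 1])
        assert len(np.unique(e, axis=0)) == len(e) == 40  # 2*5*4 grid edges
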