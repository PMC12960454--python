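import numpy as np
import pytest

from coss.errors import DataError, UsageError
from coss.lattice import lattice_from_axial, neighbor_distance_sequence
from coss.smoothing import (
    distance_ordering,
    invert_field,
    normalize_weights,
    weighted_dtm,
    weighted_dtm_matrix,
    ScalarField,
)


def naive_dtm(lattice, weights, m):
    """Per-well reference evaluation, no shared precomputation.

    Mirrors the tie policy: whole distance-tie groups are accumulated in
    distance order; within the group that straddles the mass threshold,
    weights are taken largest-first.
    """
    coords = lattice.coords
    n = lattice.n_wells
    d_seq = neighbor_distance_sequence(lattice.lattice_type, lattice.spacing, n)
    tol = 1e-9 * lattice.spacing
    out = np.empty(n)
    for p in range(n):
        dist = np.linalg.norm(coords - coords[p], axis=1)
        order = np.argsort(dist, kind="stable")
        dsort = dist[order]
        acc, k = 0.0, 0
        pos = 0
        while pos < n:
            end = pos
            while end < n and dsort[end] - dsort[pos] <= tol:
                end += 1
            group = sorted(weights[order[pos:end]], reverse=True)
            if acc + sum(group) >= m - 1e-12:
                for gw in group:
                    acc += gw
                    k += 1
                    if acc >= m - 1e-12:
                        break
                break
            acc += sum(group)
            k = end
            pos = end
        out[p] = (d_seq[:k] ** 2).sum() / k
    return out


class TestNormalize:
    def test_basic(self):
        fw = normalize_weights([2, 3, 5], "g")
        assert np.allclose(fw.weights, [0.2, 0.3, 0.5])
        assert fw.feature_id == "g"

    def test_single_positive(self):
        assert np.allclose(normalize_weights([0, 0, 7]).weights, [0, 0, 1])

    def test_all_zero_error_names_feature(self):
        with pytest.raises(DataError, match="MYGENE"):
            normalize_weights([0.0, 0.0, 0.0], "MYGENE")

    def test_negative_error(self):
        with pytest.raises(DataError):
            normalize_weights([1.0, -0.5])

    def test_nan_error(self):
        with pytest.raises(DataError):
            normalize_weights([1.0, np.nan])


class TestWeightedDtm:
    def test_own_weight_above_m_gives_zero(self, hex_lattice_10x10):
        w = np.full(100, 0.5 / 99)
        w[42] = 0.5
        fw = normalize_weights(w)
        f = weighted_dtm(hex_lattice_10x10, fw, m=0.3)
        assert f.values[42] == 0.0
        assert f.stage == "dtm"

    def test_uniform_closed_form(self, hex_lattice_10x10):
        fw = normalize_weights(np.ones(100))
        f = weighted_dtm(hex_lattice_10x10, fw, m=0.07)
        assert np.allclose(f.values, 6.0 / 7.0)  # (0 + 6*1^2)/7 everywhere

    def test_uniform_closed_form_scaled_spacing(self):
        lat = lattice_from_axial(
            [(q, r) for q in range(10) for r in range(10)], "hexagonal", 2.0
        )
        f = weighted_dtm(lat, normalize_weights(np.ones(100)), m=0.07)
        assert np.allclose(f.values, 6.0 * 4.0 / 7.0)

    def test_single_massive_well_matches_naive(self, hex_lattice_10x10, rng):
        w = np.zeros(100)
        w[37] = 1.0
        fw = normalize_weights(w)
        for m in (0.05, 0.5, 0.99):
            got = weighted_dtm(hex_lattice_10x10, fw, m).values
            want = naive_dtm(hex_lattice_10x10, fw.weights, m)
            assert np.allclose(got, want)
            assert got[37] == 0.0

    def test_random_weights_match_naive(self, square_lattice_5x5, rng):
        for _ in range(5):
            w = rng.random(25)
            fw = normalize_weights(w)
            m = float(rng.uniform(0.05, 0.9))
            got = weighted_dtm(square_lattice_5x5, fw, m).values
            assert np.allclose(got, naive_dtm(square_lattice_5x5, fw.weights, m))

    def test_scale_invariance(self, hex_lattice_10x10, rng):
        raw = rng.random(100)
        a = weighted_dtm(hex_lattice_10x10, normalize_weights(raw), 0.1).values
        b = weighted_dtm(hex_lattice_10x10, normalize_weights(17.3 * raw), 0.1).values
        assert np.array_equal(a, b)

    def test_monotone_in_m(self, hex_lattice_10x10, rng):
        fw = normalize_weights(rng.random(100))
        ms = [0.05, 0.1, 0.2, 0.4, 0.8]
        fields = [weighted_dtm(hex_lattice_10x10, fw, m).values for m in ms]
        for lo, hi in zip(fields, fields[1:]):
            assert np.all(hi >= lo - 1e-12)

    def test_m_out_of_range(self, hex_lattice_10x10):
        fw = normalize_weights(np.ones(100))
        for m in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(UsageError):
                weighted_dtm(hex_lattice_10x10, fw, m)

    def test_edge_robustness_zero_weight_boundary_removed(self):
        # mass confined to a central blob: wells whose mass threshold is
        # reached inside the blob see identical dtm after removing the
        # (zero-weight) boundary wells
        full = lattice_from_axial(
            [(q, r) for q in range(11) for r in range(11)], "hexagonal", 1.0
        )
        center = full.ideal_coords[60]
        dist = np.linalg.norm(full.ideal_coords - center, axis=1)
        w = np.where(dist <= 2.5, 1.0, 0.0)
        keep = dist <= 4.5
        trimmed = lattice_from_axial(full.axial_index[keep], "hexagonal", 1.0)
        f_full = weighted_dtm(full, normalize_weights(w), 0.3).values
        f_trim = weighted_dtm(trimmed, normalize_weights(w[keep]), 0.3).values
        pattern = w[keep] > 0
        assert np.allclose(f_trim[pattern], f_full[keep][pattern])

    def test_equivalence_with_euclidean_on_uniform_interior(self, hex_lattice_10x10):
        # complete lattice + uniform weights: idealized shells coincide with
        # the actual distance shells at interior wells
        lat = hex_lattice_10x10
        fw = normalize_weights(np.ones(100))
        m = 0.07  # k = 7: first hex shell
        net = weighted_dtm(lat, fw, m).values
        coords = lat.coords
        ax = lat.axial_index
        interior = np.all((ax > 0) & (ax < 9), axis=1)
        for p in np.where(interior)[0]:
            d = np.sort(np.linalg.norm(coords - coords[p], axis=1))
            assert net[p] == pytest.approx((d[:7] ** 2).sum() / 7)

    def test_matrix_version_matches_single(self, square_lattice_5x5, rng):
        W = rng.random((4, 25))
        W /= W.sum(axis=1, keepdims=True)
        batch = weighted_dtm_matrix(square_lattice_5x5, W, 0.2)
        for i in range(4):
            single = weighted_dtm(
                square_lattice_5x5,
                normalize_weights(W[i]),
                0.2,
            ).values
            assert np.array_equal(batch[i], single)


class TestInvert:
    def test_basic(self):
        f = invert_field(ScalarField(values=np.array([0.2, 0.5, 0.5]), stage="dtm"))
        assert np.allclose(f.values, [0.3, 0.0, 0.0])
        assert f.stage == "inverted"

    def test_constant_to_zero(self):
        f = invert_field(ScalarField(values=np.full(5, 3.7), stage="dtm"))
        assert np.all(f.values == 0.0)

    def test_shift_cancellation(self, rng):
        v = rng.random(20)
        a = invert_field(ScalarField(values=v, stage="dtm")).values
        b = invert_field(ScalarField(values=v + 5.0, stage="dtm")).values
        assert np.allclose(a, b)

    def test_reverses_ordering(self, rng):
        from scipy.stats import rankdata

        v = rng.random(30)
        z = invert_field(ScalarField(values=v, stage="dtm")).values
        assert np.array_equal(rankdata(z), 31 - rankdata(v))

    def test_stage_check(self):
        with pytest.raises(UsageError):
            invert_field(ScalarField(values=np.zeros(3), stage="inverted"))


def test_distance_ordering_ties_by_index(square_lattice_5x5):
    order = distance_ordering(square_lattice_5x5)
    assert np.all(order[:, 0] == np.arange(25))  # self first
    # first shell of the center well (index 12 = (2,2)): 4 neighbours in index order
    assert sorted(order[12, 1:5].tolist()) == list(order[12, 1:5])
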