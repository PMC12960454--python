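"""Weighted distance-to-measure smoothing of expression over a lattice.

Each feature's nonnegative values are treated as masses on the wells. The
smoother replaces every well's value with the average squared *idealized*
lattice distance to the nearest wells holding a prescribed mass fraction m:
the ordering of wells is by actual Euclidean distance (raw coordinates),
but the distances entering the average come from the infinite ideal
lattice, so tissue edges and holes do not inflate the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError
from .lattice import WellLattice, neighbor_distance_sequence

#: slack when testing "accumulated mass >= m" against float round-off
MASS_EPS = 1e-12


@dataclass
class FeatureWeights:
    """One feature's per-well masses, normalized to unit total."""

    feature_id: object
    weights: np.ndarray

    def validate(self, n_wells: int) -> None:
        if len(self.weights) != n_wells:
            raise DataError(
                f"feature {self.feature_id}: {len(self.weights)} weights for "
                f"{n_wells} wells"
            )
        if np.any(self.weights < 0):
            raise DataError(f"feature {self.feature_id}: negative weights")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DataError(f"feature {self.feature_id}: weights do not sum to 1")


@dataclass
class ScalarField:
    """Per-well scalar values, either raw dtm or the inverted landscape."""

    values: np.ndarray
    stage: str  # "dtm" | "inverted"


def normalize_weights(raw, feature_id=None) -> FeatureWeights:
    """Scale nonnegative per-well values to unit total mass."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise DataError(f"feature {feature_id}: non-finite values")
    if np.any(raw < 0):
        raise DataError(f"feature {feature_id}: negative values")
    total = raw.sum()
    if total <= 0:
        raise DataError(f"feature {feature_id}: all values are zero")
    return FeatureWeights(feature_id=feature_id, weights=raw / total)


def distance_ordering(lattice: WellLattice) -> np.ndarray:
    """(n, n) matrix whose row p lists all wells sorted by Euclidean
    distance to well p (p itself first), ties broken by well index.

    Computed once per lattice and cached; shared across features.
    """
    return _ordering_with_groups(lattice)[0]


def _ordering_with_groups(lattice: WellLattice):
    """Distance ordering plus, per row, the [start, end) bounds of the
    distance-tie group each sorted position belongs to.

    Exact lattices make equidistant shells ubiquitous; the group bounds let
    the dtm computation resolve shells that straddle the mass threshold in
    a well-label-independent way.
    """
    cached = getattr(lattice, "_ordering_cache", None)
    if cached is not None:
        return cached
    coords = lattice.coords
    n = len(coords)
    tol = 1e-9 * max(lattice.spacing, 1e-300)
    order = np.empty((n, n), dtype=np.int32)
    gstart = np.empty((n, n), dtype=np.int32)
    gend = np.empty((n, n), dtype=np.int32)
    idx = np.arange(n)
    block = max(1, int(2**23 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = np.linalg.norm(coords[start:stop, None, :] - coords[None, :, :], axis=2)
        o = np.argsort(d, axis=1, kind="stable")
        order[start:stop] = o
        dsort = np.take_along_axis(d, o, axis=1)
        new_group = np.empty((stop - start, n), dtype=bool)
        new_group[:, 0] = True
        new_group[:, 1:] = np.diff(dsort, axis=1) > tol
        gs = np.where(new_group, idx[None, :], 0)
        np.maximum.accumulate(gs, axis=1, out=gs)
        gstart[start:stop] = gs
        # group end = start of the next group (or n): suffix-min of starts
        starts = np.where(new_group, idx[None, :], n)
        sufmin = np.minimum.accumulate(starts[:, ::-1], axis=1)[:, ::-1]
        ge = np.full((stop - start, n), n, dtype=np.int64)
        ge[:, :-1] = sufmin[:, 1:]
        gend[start:stop] = ge
    lattice._ordering_cache = (order, gstart, gend)
    return lattice._ordering_cache


def _cumulative_sq_distances(lattice: WellLattice) -> np.ndarray:
    cached = getattr(lattice, "_nbr_seq_cache", None)
    if cached is not None and len(cached) == lattice.n_wells:
        return cached
    d = neighbor_distance_sequence(lattice.lattice_type, lattice.spacing, lattice.n_wells)
    cum = np.cumsum(d**2)
    lattice._nbr_seq_cache = cum
    return cum


def weighted_dtm(lattice: WellLattice, fw: FeatureWeights, m: float) -> ScalarField:
    """Modified weighted distance-to-measure at every well (stage ``dtm``)."""
    _check_m(m)
    fw.validate(lattice.n_wells)
    values = _dtm_rows(lattice, fw.weights[None, :], m)[0]
    return ScalarField(values=values, stage="dtm")


def weighted_dtm_matrix(lattice: WellLattice, weights: np.ndarray, m: float) -> np.ndarray:
    """Vectorized dtm for a (features x wells) matrix of normalized weights."""
    _check_m(m)
    return _dtm_rows(lattice, weights, m)


def _check_m(m: float) -> None:
    if not (0.0 < m < 1.0):
        raise UsageError(f"mass fraction m must be in (0, 1), got {m}")


def _dtm_rows(lattice: WellLattice, weights: np.ndarray, m: float) -> np.ndarray:
    """k = min N with accumulated mass >= m, accumulating in distance order.

    Within a distance-tie group that straddles the mass threshold, masses
    are accumulated in descending-weight order, which makes k (and hence
    dtm) independent of well labelling; the d_i entering the average are
    fixed by rank, so only k matters.
    """
    order, gstart, gend = _ordering_with_groups(lattice)
    cum_d2 = _cumulative_sq_distances(lattice)
    n = lattice.n_wells
    rows = np.arange(n)
    out = np.empty((len(weights), n))
    for f, w in enumerate(weights):
        acc = np.cumsum(w[order], axis=1)
        k0 = (acc < m - MASS_EPS).sum(axis=1) + 1  # total mass 1 > m, so k0 <= n
        a = gstart[rows, k0 - 1]
        b = gend[rows, k0 - 1]
        # re-resolve the straddling tie group largest-weight-first, padded
        # and vectorized across wells (group sizes are small shell counts)
        gmax = int((b - a).max())
        j = np.arange(gmax)
        cols = np.minimum(a[:, None] + j[None, :], n - 1)
        gw = w[order[rows[:, None], cols]]
        gw[j[None, :] >= (b - a)[:, None]] = 0.0  # padding sorts to the end
        gw = -np.sort(-gw, axis=1)
        before = np.where(a > 0, acc[rows, np.maximum(a - 1, 0)], 0.0)
        c = (np.cumsum(gw, axis=1) < (m - before)[:, None] - MASS_EPS).sum(axis=1) + 1
        out[f] = cum_d2[a + c - 1] / (a + c)
    return out


def invert_field(dtm_field: ScalarField) -> ScalarField:
    """Flip the dtm surface so high expression becomes high values:
    ``z_i = max_j dtm_j - dtm_i``.
    """
    if dtm_field.stage != "dtm":
        raise UsageError(f"expected a dtm-stage field, got {dtm_field.stage!r}")
    v = dtm_field.values
    return ScalarField(values=v.max() - v, stage="inverted")
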