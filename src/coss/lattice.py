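"""Alignment of well coordinates to an ideal hexagonal or square lattice.

Well-based platforms place measurement spots on a regular hexagonal or
square grid, but reported coordinates carry jitter and arbitrary rotation.
This module snaps raw coordinates to integer lattice indices, derives the
neighbour graph, and provides the idealized neighbour-distance sequence
consumed by the smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, UsageError

HEX_OFFSETS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)], dtype=np.int64)
SQUARE_OFFSETS = np.array([(1, 0), (-1, 0), (0, 1), (0, -1)], dtype=np.int64)


def _basis_matrix(lattice_type: str, spacing: float, angle: float = 0.0) -> np.ndarray:
    """Rows are the two lattice basis vectors."""
    if lattice_type == "hexagonal":
        second = angle + np.pi / 3.0
    elif lattice_type == "square":
        second = angle + np.pi / 2.0
    else:
        raise UsageError(f"unknown lattice_type: {lattice_type!r}")
    return spacing * np.array(
        [[np.cos(angle), np.sin(angle)], [np.cos(second), np.sin(second)]]
    )


@dataclass
class WellLattice:
    """Wells snapped to an ideal lattice.

    ``ideal_coords`` reconstructs the snapped positions from the integer
    ``axial_index`` via ``axial_index @ basis + origin``.
    """

    well_ids: np.ndarray
    coords: np.ndarray
    lattice_type: str
    spacing: float
    axial_index: np.ndarray
    basis: np.ndarray
    origin: np.ndarray
    adjacency: list = field(repr=False, default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.axial_index = np.asarray(self.axial_index, dtype=np.int64)
        if self.adjacency is None:
            self.adjacency = _adjacency_from_axial(self.axial_index, self.lattice_type)
        self._ordering_cache = None
        self._nbr_seq_cache = None

    @property
    def n_wells(self) -> int:
        return len(self.axial_index)

    @property
    def ideal_coords(self) -> np.ndarray:
        return self.axial_index @ self.basis + self.origin

    def edges(self) -> np.ndarray:
        """Adjacency as an (E, 2) array with i < j."""
        out = [(i, j) for i, nbrs in enumerate(self.adjacency) for j in nbrs if i < j]
        if not out:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(sorted(out), dtype=np.int64)

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.adjacency])

    def validate(self, snap_tolerance: float = 0.25) -> None:
        keys = {tuple(ax) for ax in self.axial_index}
        if len(keys) != self.n_wells:
            raise AlignmentError("axial indices are not unique")
        max_deg = 6 if self.lattice_type == "hexagonal" else 4
        for i, nbrs in enumerate(self.adjacency):
            if len(nbrs) > max_deg:
                raise AlignmentError(f"well {i} has degree {len(nbrs)} > {max_deg}")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise AlignmentError("adjacency is not symmetric")
        resid = np.linalg.norm(self.coords - self.ideal_coords, axis=1)
        if np.any(resid > snap_tolerance * self.spacing):
            raise AlignmentError("snapped positions exceed tolerance")


def _adjacency_from_axial(axial: np.ndarray, lattice_type: str) -> list:
    offsets = HEX_OFFSETS if lattice_type == "hexagonal" else SQUARE_OFFSETS
    index = {tuple(ax): i for i, ax in enumerate(map(tuple, axial))}
    adj = []
    for ax in axial:
        nbrs = set()
        for off in offsets:
            j = index.get((ax[0] + off[0], ax[1] + off[1]))
            if j is not None:
                nbrs.add(j)
        adj.append(nbrs)
    return adj


def _nearest_neighbor_stats(coords: np.ndarray):
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return tree, d[:, 1]


def _mode_spacing(nn_dists: np.ndarray) -> float:
    """Finest-histogram-peak estimate of the grid spacing."""
    lo, hi = nn_dists.min(), nn_dists.max()
    if hi - lo < 1e-12 * max(hi, 1.0):
        return float(nn_dists.mean())
    counts, edges = np.histogram(nn_dists, bins=min(64, max(8, nn_dists.size // 4)))
    b = int(np.argmax(counts))
    sel = (nn_dists >= edges[max(0, b - 1)]) & (nn_dists <= edges[min(len(edges) - 1, b + 2)])
    return float(nn_dists[sel].mean())


def _infer_lattice_type(bearings: np.ndarray) -> str:
    r6 = np.abs(np.exp(6j * bearings).mean())
    r4 = np.abs(np.exp(4j * bearings).mean())
    return "hexagonal" if r6 >= r4 else "square"


def align_to_lattice(
    coords: Sequence,
    well_ids: Optional[Sequence] = None,
    lattice_type: Optional[str] = None,
    snap_tolerance: float = 0.25,
    max_bad_fraction: float = 0.05,
) -> WellLattice:
    """Snap raw well coordinates onto an ideal hexagonal or square lattice.

    Spacing is estimated as the modal nearest-neighbour distance, the
    lattice type (when not given) from the 6-fold vs 4-fold concentration of
    nearest-neighbour bearings, and the basis by iterated least squares on
    the integer-index fit. Raises :class:`AlignmentError` on degenerate
    geometry or when more than ``max_bad_fraction`` of wells miss
    ``snap_tolerance`` (a fraction of the spacing).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise AlignmentError("coords must be an (n, 2) array")
    n = len(coords)
    if n < 3:
        raise AlignmentError(f"need at least 3 wells, got {n}")
    if well_ids is None:
        well_ids = np.arange(n)
    well_ids = np.asarray(well_ids)
    if len(well_ids) != n:
        raise AlignmentError("well_ids length does not match coords")

    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise AlignmentError("degenerate geometry: points are collinear")

    tree, nn_d = _nearest_neighbor_stats(coords)
    if nn_d.min() <= 0:
        raise AlignmentError("duplicate well coordinates")
    spacing0 = _mode_spacing(nn_d)

    pairs = tree.query_pairs(r=1.3 * spacing0, output_type="ndarray")
    if len(pairs) == 0:
        raise AlignmentError("no neighbouring wells within 1.3x estimated spacing")
    disp = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    disp = np.vstack([disp, -disp])
    bearings = np.arctan2(disp[:, 1], disp[:, 0])

    if lattice_type is None:
        lattice_type = _infer_lattice_type(bearings)
    if lattice_type not in ("hexagonal", "square"):
        raise UsageError(f"unknown lattice_type: {lattice_type!r}")
    fold = 6 if lattice_type == "hexagonal" else 4

    # canonical primary bearing in [0, 2*pi/fold)
    mean_dir = np.exp(1j * fold * bearings).mean()
    if np.abs(mean_dir) < 0.2:
        raise AlignmentError("neighbour bearings lack the expected lattice symmetry")
    angle = np.angle(mean_dir) / fold
    angle %= 2.0 * np.pi / fold

    basis = _basis_matrix(lattice_type, spacing0, angle)
    origin = coords[0].copy()
    axial = None
    for _ in range(4):
        rel = coords - origin
        axial_new = np.rint(rel @ np.linalg.inv(basis)).astype(np.int64)
        if axial is not None and np.array_equal(axial_new, axial):
            break
        axial = axial_new
        A = np.hstack([axial, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(A, coords, rcond=None)
        basis = sol[:2]
        origin = sol[2]

    # shift so the index range starts at 0 (removes dependence on seed well)
    shift = axial.min(axis=0)
    axial = axial - shift
    origin = origin + shift @ basis

    ideal = axial @ basis + origin
    spacing = float(np.linalg.norm(basis, axis=1).mean())
    resid = np.linalg.norm(coords - ideal, axis=1)
    bad = resid > snap_tolerance * spacing
    if bad.sum() > max_bad_fraction * n:
        worst = np.argsort(resid)[::-1][:5]
        detail = ", ".join(f"{well_ids[i]} (residual {resid[i]:.3g})" for i in worst)
        raise AlignmentError(
            f"{int(bad.sum())}/{n} wells exceed snap tolerance "
            f"{snap_tolerance:.3g} x spacing; worst offenders: {detail}"
        )
    seen = {}
    for i, key in enumerate(map(tuple, axial)):
        if key in seen:
            raise AlignmentError(
                f"wells {well_ids[seen[key]]} and {well_ids[i]} snap to the same "
                f"lattice site {key}"
            )
        seen[key] = i

    return WellLattice(
        well_ids=well_ids,
        coords=coords,
        lattice_type=lattice_type,
        spacing=spacing,
        axial_index=axial,
        basis=basis,
        origin=origin,
    )


def lattice_from_axial(
    axial,
    lattice_type: str,
    spacing: float = 1.0,
    well_ids=None,
) -> WellLattice:
    """Build a lattice directly from known integer indices (no alignment)."""
    axial = np.asarray(axial, dtype=np.int64)
    basis = _basis_matrix(lattice_type, spacing)
    if well_ids is None:
        well_ids = np.arange(len(axial))
    return WellLattice(
        well_ids=np.asarray(well_ids),
        coords=axial @ basis,
        lattice_type=lattice_type,
        spacing=spacing,
        axial_index=axial,
        basis=basis,
        origin=np.zeros(2),
    )


def neighbor_distance_sequence(lattice_type: str, spacing: float, count: int) -> np.ndarray:
    """Distances from the origin to its ``count`` nearest sites of the
    infinite ideal lattice, nondecreasing, with the origin itself first
    (``d_1 = 0``). Only the multiset matters; ties are in arbitrary order.
    """
    if count < 1:
        raise UsageError("count must be >= 1")
    if lattice_type not in ("hexagonal", "square"):
        raise UsageError(f"unknown lattice_type: {lattice_type!r}")
    if spacing <= 0:
        raise UsageError("spacing must be > 0")
    basis = _basis_matrix(lattice_type, 1.0)
    m = max(2, int(np.ceil(np.sqrt(count))))
    while True:
        rng = np.arange(-m, m + 1)
        q, r = np.meshgrid(rng, rng, indexing="ij")
        pts = np.stack([q.ravel(), r.ravel()], axis=1) @ basis
        d = np.sort(np.linalg.norm(pts, axis=1))
        # sites outside |q|,|r| <= m are at distance >= ~0.86*(m+1) for hex,
        # (m+1) for square; below this cutoff the sorted prefix is complete
        cutoff = 0.86 * (m + 1)
        if d.size >= count and d[count - 1] < cutoff:
            return spacing * d[:count]
        m *= 2
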