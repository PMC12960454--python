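"""0-dimensional persistent homology of the superlevel (upper star) filtration.

Vertices carry the field value z_i, edges min(z_i, z_j). Sweeping the
threshold downward, a component is born at its highest vertex and dies when
an edge merges it into a component with a higher birth (elder rule).

Two implementations share one contract: :func:`superlevel_persistence`
(union-find, near-linear) and :func:`brute_force_persistence` (explicit
connected components per threshold, the testing oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import UsageError
from .lattice import WellLattice
from .smoothing import ScalarField

ESSENTIAL_POLICIES = ("kill_at_min", "drop")


@dataclass
class FilteredComplex:
    vertex_values: np.ndarray  # (n,)
    edges: np.ndarray          # (E, 2) int, i < j
    edge_values: np.ndarray    # (E,) = min of endpoint values


@dataclass
class Barcode:
    """Multiset of (birth, death) pairs, birth >= death (superlevel
    convention: a bar is born at a high threshold and dies at a lower one).
    """

    bars: np.ndarray  # (k, 2) float
    essential_policy: str = "kill_at_min"

    @property
    def lifetimes(self) -> np.ndarray:
        if len(self.bars) == 0:
            return np.empty(0)
        return self.bars[:, 0] - self.bars[:, 1]


def build_filtration(lattice: WellLattice, field: ScalarField) -> FilteredComplex:
    """Filtered complex on the lattice adjacency graph from an inverted field."""
    if field.stage != "inverted":
        raise UsageError(f"expected an inverted-stage field, got {field.stage!r}")
    z = np.asarray(field.values, dtype=float)
    if len(z) != lattice.n_wells:
        raise UsageError("field length does not match lattice")
    edges = lattice.edges()
    return filtration_from_graph(z, edges)


def filtration_from_graph(z: np.ndarray, edges: np.ndarray) -> FilteredComplex:
    z = np.asarray(z, dtype=float)
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    ev = np.minimum(z[edges[:, 0]], z[edges[:, 1]]) if len(edges) else np.empty(0)
    return FilteredComplex(vertex_values=z, edges=edges, edge_values=ev)


def superlevel_persistence(
    complex: FilteredComplex, essential_policy: str = "kill_at_min"
) -> Barcode:
    """Union-find sweep in decreasing threshold order.

    Every vertex starts its own component born at z_i; edges processed in
    decreasing value merge components, killing the younger (lower-birth) one
    at the edge value. Birth ties are broken by the smaller root well index
    surviving (the bar multiset does not depend on this). Components that
    never merge away are either killed at the global minimum vertex value or
    dropped, per ``essential_policy``.
    """
    _check_policy(essential_policy)
    z = complex.vertex_values
    n = len(z)
    if n == 0:
        return Barcode(bars=np.empty((0, 2)), essential_policy=essential_policy)

    parent = list(range(n))
    birth = list(z)  # birth of the component rooted at each index

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    ev = complex.edge_values
    eorder = np.lexsort((complex.edges[:, 1], complex.edges[:, 0], -ev))
    births, deaths = [], []
    for e in eorder:
        i, j = complex.edges[e]
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        # elder rule: the lower birth dies; ties -> larger root index dies
        if (birth[ri], -ri) < (birth[rj], -rj):
            ri, rj = rj, ri
        births.append(birth[rj])
        deaths.append(ev[e])
        parent[rj] = ri

    roots = {find(i) for i in range(n)}
    if essential_policy == "kill_at_min":
        zmin = float(z.min())
        for r in sorted(roots):
            births.append(birth[r])
            deaths.append(zmin)
    bars = np.column_stack([births, deaths]) if births else np.empty((0, 2))
    return Barcode(bars=bars, essential_policy=essential_policy)


def brute_force_persistence(
    complex: FilteredComplex, essential_policy: str = "kill_at_min"
) -> Barcode:
    """Oracle: recompute connected components of every superlevel subgraph.

    For each distinct vertex value t in decreasing order, build the subgraph
    of vertices with z >= t and edges with value >= t, label its components,
    and match them against the previous threshold's components to emit
    births and deaths. Quadratic-ish; intended for small inputs.
    """
    _check_policy(essential_policy)
    z = complex.vertex_values
    n = len(z)
    if n == 0:
        return Barcode(bars=np.empty((0, 2)), essential_policy=essential_policy)

    thresholds = np.unique(z)[::-1]
    edges, ev = complex.edges, complex.edge_values
    prev_labels = np.full(n, -1)   # component label per vertex, -1 inactive
    comp_birth = {}                # current label -> birth value
    bars = []
    for t in thresholds:
        active = z >= t
        idx = np.where(active)[0]
        sub = {v: i for i, v in enumerate(idx)}
        mask = ev >= t if len(edges) else np.empty(0, dtype=bool)
        sel = edges[mask] if len(edges) else edges
        rows = [sub[a] for a, b in sel]
        cols = [sub[b] for a, b in sel]
        g = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(idx), len(idx))
        )
        _, labels = connected_components(g, directed=False)

        new_birth = {}
        for lab in np.unique(labels):
            members = idx[labels == lab]
            preds = sorted(
                {prev_labels[v] for v in members if prev_labels[v] >= 0}
            )
            n_new_vertices = int(np.sum(z[members] == t))
            if preds:
                pred_births = sorted((comp_birth[p] for p in preds), reverse=True)
                new_birth[(t, lab)] = pred_births[0]
                for b in pred_births[1:]:  # merged-away predecessors
                    bars.append((b, t))
                for _ in range(n_new_vertices):  # vertices absorbed immediately
                    bars.append((t, t))
            else:
                new_birth[(t, lab)] = t
                for _ in range(n_new_vertices - 1):
                    bars.append((t, t))
        relabel = np.full(n, -1)
        for i, v in enumerate(idx):
            relabel[v] = labels[i]
        prev_labels = relabel
        comp_birth = {lab: b for (tt, lab), b in new_birth.items()}

    if essential_policy == "kill_at_min":
        zmin = float(z.min())
        for b in comp_birth.values():
            bars.append((b, zmin))
    arr = np.array(bars) if bars else np.empty((0, 2))
    return Barcode(bars=arr, essential_policy=essential_policy)


def _check_policy(policy: str) -> None:
    if policy not in ESSENTIAL_POLICIES:
        raise UsageError(
            f"essential_policy must be one of {ESSENTIAL_POLICIES}, got {policy!r}"
        )


def barcode_to_frame(barcode: Barcode, feature_id=None):
    """3-column export (feature_id, birth, death)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": feature_id,
            "birth": barcode.bars[:, 0] if len(barcode.bars) else [],
            "death": barcode.bars[:, 1] if len(barcode.bars) else [],
        }
    )
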