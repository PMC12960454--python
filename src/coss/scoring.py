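"""Reduce barcodes to per-feature spatial-structure scores.

The score of a feature is the L^p norm (default p=2) of its barcode's
lifetimes; the companion ratio statistic (max lifetime over bar count)
flags patterns dominated by a single spatial feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .lattice import WellLattice
from .persistence import Barcode, filtration_from_graph, superlevel_persistence
from .smoothing import weighted_dtm_matrix

logger = logging.getLogger(__name__)

#: relative tolerance (times the field range) below which a bar counts as noise
DEFAULT_LIFETIME_RTOL = 1e-12


@dataclass
class CoSSResult:
    feature_id: object
    coss: Optional[float]          # None when the feature could not be scored
    ratio: Optional[float]
    n_bars: Optional[int]          # bars with lifetime above tolerance
    p: float
    reason: Optional[str] = None   # why the feature was not scored


def barcode_norm(barcode: Barcode, p: float = 2.0) -> float:
    """(sum of lifetime^p)^(1/p); max lifetime for p=inf; 0 for an empty barcode."""
    if p < 1:
        raise UsageError(f"norm order p must be >= 1 (or inf), got {p}")
    lt = barcode.lifetimes
    if lt.size == 0:
        return 0.0
    if math.isinf(p):
        return float(lt.max())
    return float((lt**p).sum() ** (1.0 / p))


def count_bars(barcode: Barcode, lifetime_tolerance: float) -> int:
    return int((barcode.lifetimes > lifetime_tolerance).sum())


def ratio_statistic(
    barcode: Barcode, lifetime_tolerance: float = 0.0, l0_mode: str = "count"
) -> float:
    """Max lifetime divided by the barcode's "size".

    ``l0_mode="count"`` (default) divides by the number of bars with
    lifetime above tolerance; ``l0_mode="l1"`` divides by the sum of
    lifetimes. Returns 0 when no bar exceeds tolerance.
    """
    lt = barcode.lifetimes
    if lt.size == 0:
        return 0.0
    top = float(lt.max())
    if l0_mode == "count":
        denom = float((lt > lifetime_tolerance).sum())
    elif l0_mode == "l1":
        denom = float(lt.sum())
    else:
        raise UsageError(f"l0_mode must be 'count' or 'l1', got {l0_mode!r}")
    if denom <= 0:
        return 0.0
    return top / denom


def coss_pipeline(
    lattice: WellLattice,
    raw_expression: np.ndarray,
    feature_ids: Optional[Sequence] = None,
    m: float = 0.1,
    p: float = 2.0,
    essential_policy: str = "kill_at_min",
    lifetime_rtol: float = DEFAULT_LIFETIME_RTOL,
    l0_mode: str = "count",
) -> list[CoSSResult]:
    """Score every row of a (features x wells) nonnegative matrix.

    Composition per feature: normalize -> weighted dtm -> invert ->
    filtration on the lattice graph -> superlevel persistence -> norms.
    Features with no positive mass are reported with a null score (reason
    recorded), never dropped silently.
    """
    X = np.asarray(raw_expression, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(len(X))]
    if X.shape[1] != lattice.n_wells:
        raise UsageError(
            f"expression has {X.shape[1]} wells, lattice has {lattice.n_wells}"
        )

    results: list[CoSSResult] = []
    ok_rows, ok_pos = [], []
    for i, fid in enumerate(feature_ids):
        row = X[i]
        if not np.all(np.isfinite(row)) or np.any(row < 0):
            results.append(CoSSResult(fid, None, None, None, p, "invalid values"))
        elif row.sum() <= 0:
            results.append(CoSSResult(fid, None, None, None, p, "all-zero feature"))
        else:
            results.append(CoSSResult(fid, None, None, None, p, None))
            ok_rows.append(row / row.sum())
            ok_pos.append(i)
    n_bad = len(results) - len(ok_pos)
    if n_bad:
        logger.warning("%d features could not be scored (all-zero or invalid)", n_bad)
    if not ok_pos:
        return results

    dtm = weighted_dtm_matrix(lattice, np.asarray(ok_rows), m)
    edges = lattice.edges()
    for pos, dvals in zip(ok_pos, dtm):
        z = dvals.max() - dvals
        fc = filtration_from_graph(z, edges)
        bc = superlevel_persistence(fc, essential_policy=essential_policy)
        zrange = float(z.max() - z.min())
        tol = lifetime_rtol * zrange if zrange > 0 else 0.0
        res = results[pos]
        res.coss = barcode_norm(bc, p)
        res.ratio = ratio_statistic(bc, tol, l0_mode=l0_mode)
        res.n_bars = count_bars(bc, tol)
    return results


def results_to_frame(results: Sequence[CoSSResult]) -> pd.DataFrame:
    """Scores table, descending score, ties by feature id."""
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "coss": [r.coss for r in results],
            "ratio": [r.ratio for r in results],
            "n_bars": [r.n_bars for r in results],
            "flags": [r.reason or "" for r in results],
        }
    )
    df["feature_id"] = df["feature_id"].astype(str)
    df = df.sort_values(
        ["coss", "feature_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df
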