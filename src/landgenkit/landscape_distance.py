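"""Pairwise geographic, least-cost-path and barrier-crossing distances.

Least-cost paths run over an 8-connected lattice on the resistance raster:
the edge weight between adjacent cells a, b is ``mean(cost_a, cost_b) *
cell_size`` scaled by sqrt(2) for diagonal moves — the convention of the
ArcGIS cost-distance tooling.  Barrier "distance" between two individuals is
the number of distinct features whose geometry intersects the straight
segment joining them (a winding road crossed twice still counts once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import LineString

from .core_data import BarrierSet, DistanceMatrix, GenotypeTable, ResistanceSurface
from .errors import ValidationError

logger = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


def euclidean_matrix(g: GenotypeTable, log_transform: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances (optionally natural-log transformed).

    The log matrix keeps a zero diagonal by convention; matrix statistics only
    ever read the off-diagonal entries.  A coincident pair under
    ``log_transform`` is an error (log of zero), naming the pair.
    """
    xy = np.column_stack([g.x, g.y])
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    if log_transform:
        off = ~np.eye(len(xy), dtype=bool)
        zero = (d == 0) & off
        if zero.any():
            i, j = np.argwhere(zero)[0]
            raise ValidationError(
                f"individuals {g.individual_ids[int(i)]!r} and "
                f"{g.individual_ids[int(j)]!r} are coincident; log distance undefined"
            )
        with np.errstate(divide="ignore"):
            d = np.where(off, np.log(d), 0.0)
        kind = "log_euclidean"
    else:
        kind = "euclidean"
    return DistanceMatrix(labels=list(g.individual_ids), values=d, kind=kind)


# ---------------------------------------------------------------------------
# Least-cost paths
# ---------------------------------------------------------------------------


@dataclass
class LcpResult:
    """Least-cost-path distances plus the surface they were computed on."""

    matrix: DistanceMatrix
    surface_id: str = "surface"
    n_disconnected_pairs: int = 0


def _lattice_graph(s: ResistanceSurface) -> coo_matrix:
    """Sparse 8-connected cost graph over unmasked raster cells."""
    nr, nc = s.n_rows, s.n_cols
    cost = np.where(s.nodata_mask, np.nan, s.values)
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    # offsets covering each undirected edge once
    for dr, dc, scale in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        if dc >= 0:
            c0, c1 = slice(0, nc - dc), slice(dc, nc)
        else:
            c0, c1 = slice(-dc, nc), slice(0, nc + dc)
        ca = cost[r0, c0]
        cb = cost[r1, c1]
        w = 0.5 * (ca + cb) * s.cell_size * scale
        ok = np.isfinite(w)
        rows.append(idx[r0, c0][ok])
        cols.append(idx[r1, c1][ok])
        wts.append(w[ok])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    w = np.concatenate(wts)
    return coo_matrix((w, (r, c)), shape=(nr * nc, nr * nc))


def lcp_matrix(
    g: GenotypeTable, s: ResistanceSurface, surface_id: str = "surface"
) -> LcpResult:
    """Least-cost-path cost between every individual pair (Dijkstra).

    Individuals are snapped to the raster cell containing their coordinates;
    an individual on a masked (no-data) cell is an error.  Disconnected pairs
    get NaN entries (counted and logged) so that downstream matrix statistics
    drop them by pairwise deletion.
    """
    nr, nc = s.n_rows, s.n_cols
    cells = []
    for i, (x, y) in enumerate(zip(g.x, g.y)):
        r, c = s.cell_of(x, y)
        if s.nodata_mask[r, c]:
            raise ValidationError(
                f"individual {g.individual_ids[i]!r} falls on a NODATA cell ({r}, {c})"
            )
        cells.append(r * nc + c)
    cells = np.asarray(cells)
    graph = _lattice_graph(s)
    sources, inverse = np.unique(cells, return_inverse=True)
    dmat = dijkstra(graph, directed=False, indices=sources)
    values = dmat[inverse][:, cells]
    # individuals sharing a cell -> 0 automatically (distance to self cell)
    disconnected = ~np.isfinite(values)
    np.fill_diagonal(disconnected, False)
    n_disc = int(disconnected.sum() // 2)
    if n_disc:
        logger.warning("%d individual pairs are disconnected on surface %r", n_disc, surface_id)
    values = np.where(disconnected, np.nan, values)
    # forward/backward Dijkstra sums differ by float rounding; symmetrize
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    dm = DistanceMatrix(labels=list(g.individual_ids), values=values, kind="lcp")
    return LcpResult(matrix=dm, surface_id=surface_id, n_disconnected_pairs=n_disc)


# ---------------------------------------------------------------------------
# Barrier counts
# ---------------------------------------------------------------------------


def barrier_count_matrix(g: GenotypeTable, b: BarrierSet) -> DistanceMatrix:
    """Number of distinct barrier features intersecting each straight segment.

    Counting is per-feature: any intersection (crossing, tangency, an endpoint
    exactly on the feature, or passage through a polygon's interior) adds one
    for that feature, however many times the geometry is crossed.
    """
    n = g.n_individuals
    values = np.zeros((n, n))
    prepared = list(b.features)
    for i in range(n):
        for j in range(i + 1, n):
            seg = LineString([(g.x[i], g.y[i]), (g.x[j], g.y[j])])
            count = sum(1 for geom in prepared if geom.intersects(seg))
            values[i, j] = values[j, i] = float(count)
    return DistanceMatrix(labels=list(g.individual_ids), values=values, kind="barrier_count")
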