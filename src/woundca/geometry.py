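"""Fold-change-ordering areas, boundary lines, point P, and distance gene sets.

On the CA biplot the genes separate into six triangular areas according to
the strict ordering of their (FC6, FC12, FC24) triple:

    A: FC6 < FC12 < FC24    B: FC6 < FC24 < FC12    C: FC24 < FC6 < FC12
    D: FC24 < FC12 < FC6    E: FC12 < FC24 < FC6    F: FC12 < FC6 < FC24

Because a row's principal coordinates are a linear function of its degree
profile, each equality locus FC_a = FC_b is an exact straight line on the
plot and the three loci are concurrent at the image of the uniform profile
(point P). The empirical procedure mimicked here estimates each boundary
from data: take the q genes whose two fold changes are closest (smallest
|log ratio|), anchor the line on the two most widely separated of them, and
take point P as the least-squares intersection of the three fitted lines.

Distance-based gene sets: "distance 1" ranks genes by Euclidean biplot
distance to a time-series column score, "distance 2" by distance to a query
gene (one of the top-5 most up- or downregulated genes at a time point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AREA_ORDERINGS",
    "TIE",
    "BOUNDARY_PAIRS",
    "BoundaryLine",
    "GeometryModel",
    "assign_area",
    "assign_areas",
    "select_boundary_anchor_genes",
    "fit_line",
    "intersect_lines",
    "least_squares_point",
    "select_query_genes",
    "distance_set",
    "build_geometry",
]

#: Area label -> index order (ascending FC) over the columns (FC6, FC12, FC24).
AREA_ORDERINGS = {
    "A": (0, 1, 2),  # FC6 < FC12 < FC24
    "B": (0, 2, 1),  # FC6 < FC24 < FC12
    "C": (2, 0, 1),  # FC24 < FC6 < FC12
    "D": (2, 1, 0),  # FC24 < FC12 < FC6
    "E": (1, 2, 0),  # FC12 < FC24 < FC6
    "F": (1, 0, 2),  # FC12 < FC6 < FC24
}
_ORDER_TO_AREA = {v: k for k, v in AREA_ORDERINGS.items()}

#: Marker returned for exact ties, which belong to no open area.
TIE = "tie"

#: Boundary id -> the two FC column indices whose equality it separates.
BOUNDARY_PAIRS = {1: (0, 1), 2: (1, 2), 3: (2, 0)}


def assign_area(fc_triple) -> str:
    """Area label A-F from the strict ordering of (FC6, FC12, FC24); ties -> ``tie``."""
    fc = np.asarray(fc_triple, dtype=float)
    if fc.shape != (3,):
        raise ValueError("expected exactly three fold-change values")
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    if len(set(fc)) < 3:
        return TIE
    return _ORDER_TO_AREA[tuple(np.argsort(fc, kind="stable"))]


def assign_areas(fc: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_area` over an FC table; returns a gene-indexed Series."""
    labels = pd.Series(
        [assign_area(row) for row in fc.to_numpy()], index=fc.index, name="area"
    )
    return labels


@dataclass(frozen=True)
class BoundaryLine:
    """A fitted boundary ``y = slope * x + intercept`` anchored on two genes."""

    boundary_id: int
    slope: float
    intercept: float
    anchors: tuple[str, str] = ("", "")

    def side(self, points) -> np.ndarray:
        """Sign of ``y - (slope x + intercept)`` for each 2-D point (0 = on line)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.sign(pts[:, 1] - (self.slope * pts[:, 0] + self.intercept))


def select_boundary_anchor_genes(
    fc: pd.DataFrame, coords: pd.DataFrame, boundary_id: int, q: int = 100
) -> tuple[str, str]:
    """Pick the two genes anchoring one boundary line.

    Among the ``q`` genes whose |log(FC_a / FC_b)| for the boundary's fold
    change pair is smallest (expression nearly equal at the two times, i.e.
    lying close to the boundary), return the pair with the largest Euclidean
    separation on the biplot — the two ends of the boundary's reach.
    """
    if boundary_id not in BOUNDARY_PAIRS:
        raise ValueError(f"unknown boundary id {boundary_id!r}")
    a, b = BOUNDARY_PAIRS[boundary_id]
    vals = fc.to_numpy()
    ratio = np.abs(np.log(vals[:, a] / vals[:, b]))
    order = pd.Series(ratio, index=fc.index).sort_values(kind="stable")
    pool = order.index[: min(q, len(order))]
    if len(pool) < 2:
        raise ValueError("fewer than 2 candidate anchor genes")
    pts = coords.loc[pool].to_numpy()[:, :2]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return str(pool[i]), str(pool[j])


def fit_line(p1, p2, boundary_id: int = 0, anchors: tuple[str, str] = ("", "")) -> BoundaryLine:
    """Line through two 2-D points; vertical lines (equal x) are rejected."""
    (x1, y1), (x2, y2) = (np.asarray(p1, float), np.asarray(p2, float))
    if x1 == x2 and y1 == y2:
        raise ValueError("anchor points coincide")
    if x1 == x2:
        raise ValueError("anchor points share an x coordinate (vertical boundary)")
    slope = (y2 - y1) / (x2 - x1)
    return BoundaryLine(
        boundary_id=boundary_id, slope=slope, intercept=y1 - slope * x1, anchors=anchors
    )


def intersect_lines(l1: BoundaryLine, l2: BoundaryLine) -> tuple[float, float]:
    """Unique intersection of two non-parallel lines."""
    if l1.slope == l2.slope:
        raise ValueError("lines are parallel")
    x = (l2.intercept - l1.intercept) / (l1.slope - l2.slope)
    return float(x), float(l1.slope * x + l1.intercept)


def least_squares_point(lines) -> tuple[float, float]:
    """Point minimizing the summed squared distances to a set of lines.

    For concurrent lines this is their common intersection (zero residual);
    it is the definition of point P for the three fitted boundaries.
    """
    lines = list(lines)
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    A = np.zeros((2, 2))
    rhs = np.zeros(2)
    for ln in lines:
        norm = np.hypot(ln.slope, 1.0)
        n = np.array([ln.slope, -1.0]) / norm  # unit normal of slope*x - y + b = 0
        c = -ln.intercept / norm
        A += np.outer(n, n)
        rhs += c * n
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("lines are mutually parallel; point undefined")
    p = np.linalg.solve(A, rhs)
    return float(p[0]), float(p[1])


def select_query_genes(
    fc: pd.DataFrame, time: str, direction: str, k: int = 5
) -> list[str]:
    """The k most up- (largest FC) or downregulated (smallest FC) genes at a time.

    Sorted by extremity; exact FC ties broken by gene id for reproducibility.
    """
    col = f"FC{time.lstrip('t')}"
    if col not in fc.columns:
        raise ValueError(f"unknown time label {time!r}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if k > len(fc):
        raise ValueError(f"k={k} exceeds the {len(fc)} available genes")
    sub = fc[[col]].copy()
    sub["_gene"] = sub.index.astype(str)
    ordered = sub.sort_values(
        [col, "_gene"], ascending=[direction == "down", True], kind="stable"
    )
    return [str(g) for g in ordered.index[:k]]


def distance_set(coords: pd.DataFrame, anchor, k: int) -> pd.DataFrame:
    """The k genes closest (Euclidean, on the biplot) to a 2-D anchor point.

    Returns a DataFrame (gene-indexed, ascending ``distance`` column); ties
    broken by gene id. When the anchor is a gene's own coordinates that gene
    ranks first at distance 0.
    """
    if k > len(coords):
        raise ValueError(f"k={k} exceeds the {len(coords)} available genes")
    pts = coords.to_numpy()[:, :2]
    anchor = np.asarray(anchor, dtype=float).reshape(2)
    d = np.hypot(pts[:, 0] - anchor[0], pts[:, 1] - anchor[1])
    tbl = pd.DataFrame({"distance": d, "_gene": coords.index.astype(str)}, index=coords.index)
    tbl = tbl.sort_values(["distance", "_gene"], kind="stable").head(k)
    return tbl[["distance"]]


@dataclass
class GeometryModel:
    """Areas, fitted boundary lines, point P, and distance-based gene sets."""

    areas: pd.Series
    lines: dict[int, BoundaryLine]
    point_p: tuple[float, float]
    distance1: pd.DataFrame            # genes x time-series scores
    query_genes: dict[tuple[str, str], list[str]]
    distance_sets: dict[tuple, pd.DataFrame] = field(default_factory=dict)


def build_geometry(
    fc: pd.DataFrame,
    row_coords: pd.DataFrame,
    col_coords: pd.DataFrame,
    q: int = 100,
    top_k: tuple[int, ...] = (100, 300, 500, 1000),
    n_query: int = 5,
) -> GeometryModel:
    """Assemble the full geometric model from an FC table and CA coordinates.

    Fits the three boundary lines from anchor genes, locates point P,
    computes distance-1 tables to each time-series score, selects the top
    ``n_query`` up/down query genes per time point, and materializes the
    top-k distance sets around every time-series score and query gene
    (k values above the gene count are skipped).
    """
    areas = assign_areas(fc)
    lines: dict[int, BoundaryLine] = {}
    for bid in BOUNDARY_PAIRS:
        g1, g2 = select_boundary_anchor_genes(fc, row_coords, bid, q=q)
        lines[bid] = fit_line(
            row_coords.loc[g1].to_numpy()[:2],
            row_coords.loc[g2].to_numpy()[:2],
            boundary_id=bid,
            anchors=(g1, g2),
        )
    point_p = least_squares_point(lines.values())

    pts = row_coords.to_numpy()[:, :2]
    d1 = {
        t: np.hypot(pts[:, 0] - xy[0], pts[:, 1] - xy[1])
        for t, xy in zip(col_coords.index, col_coords.to_numpy()[:, :2])
    }
    distance1 = pd.DataFrame(d1, index=row_coords.index)

    times = [f"t{c.removeprefix('FC')}" for c in fc.columns]
    query = {
        (t, direction): select_query_genes(fc, t, direction, k=n_query)
        for t in times
        for direction in ("up", "down")
    }

    ks = [k for k in top_k if k <= len(row_coords)]
    dsets: dict[tuple, pd.DataFrame] = {}
    for t in col_coords.index:
        anchor = col_coords.loc[t].to_numpy()[:2]
        for k in ks:
            dsets[("time", str(t), k)] = distance_set(row_coords, anchor, k)
    for (t, direction), genes in query.items():
        for g in genes:
            anchor = row_coords.loc[g].to_numpy()[:2]
            for k in ks:
                dsets[("query", g, k)] = distance_set(row_coords, anchor, k)
    return GeometryModel(
        areas=areas,
        lines=lines,
        point_p=point_p,
        distance1=distance1,
        query_genes=query,
        distance_sets=dsets,
    )
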