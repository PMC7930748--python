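"""Per-cell shape metrics for epithelial sheets.

Implements the full morphometric panel used for retinal pigment epithelium
flatmounts: area, perimeter, convex-hull quantities, solidity, Feret
diameters, moment-ellipse eccentricity and aspect ratio, neighbour counts,
and the two 0-10 regularity scores:

* **Polygonality score** — how close the cell is to the *regular N-gon*,
  where N is its neighbour count.  With P, A the cell perimeter and area and
  P_h, A_h those of its convex hull,

      PSR = (P / P_h) * (1 - |1 - P / P_ref(N, A)|)
      PAR = (A / A_h) * (1 - |1 - A / A_ref(N, P)|)
      score = 10 * (PSR + PAR) / 2

  with the regular-N-gon references derived from A = (N/4) s^2 cot(pi/N):
  P_ref(N, A) = N * sqrt(4 A / (N cot(pi/N))) (perimeter of the regular
  N-gon of equal area) and A_ref(N, P) = (N/4)(P/N)^2 cot(pi/N) (area of the
  regular N-gon of equal perimeter).  A regular N-gon with N neighbours
  scores exactly 10.

* **Hexagonality score** — the same construction with N fixed at 6; 10 for a
  regular hexagon, the honeycomb reference of a healthy epithelium.

Scores are *not* clamped by default: extremely elongated cells can push the
bracket negative, and the raw value preserves ordering.  Pass
``clamp_scores=True`` to floor the ratios at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy import stats as sps

from .tessellation_io import AdjacencyGraph, CellPolygon

__all__ = [
    "ShapeMetrics",
    "SampleSummary",
    "basic_geometry",
    "feret_diameters",
    "ellipse_descriptors",
    "polygonality_score",
    "hexagonality_score",
    "measure_cell",
    "measure_cells",
    "summarize_sample",
    "METRIC_COLUMNS",
]


@dataclass
class ShapeMetrics:
    """All morphometric quantities of one cell (physical units: micrometres)."""

    cell_id: int
    area: float
    perimeter: float
    hull_area: float
    hull_perimeter: float
    n_neighbors: int
    solidity: float
    feret_max: float
    feret_min: float
    eccentricity: float
    aspect_ratio: float
    psr: float
    par: float
    hsr: float
    har: float
    polygonality_score: float
    hexagonality_score: float
    mouse: str = ""
    genotype: str = ""
    age: float = float("nan")
    sample_id: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


METRIC_COLUMNS = [
    f.name
    for f in fields(ShapeMetrics)
    if f.name not in ("cell_id", "mouse", "genotype", "age", "sample_id")
]


@dataclass
class SampleSummary:
    """Per-image summary statistics over the retained cells."""

    sample_id: str
    n_cells: int
    stats: pd.DataFrame  # rows = metrics; columns = mean, median, sd, skewness, kurtosis
    hexagonality_sd: float


# ---------------------------------------------------------------------------
# geometry primitives


def _as_vertices(poly: CellPolygon | np.ndarray) -> np.ndarray:
    if isinstance(poly, CellPolygon):
        return poly.vertices
    return np.asarray(poly, dtype=float)


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _ring_length(verts: np.ndarray) -> float:
    d = np.roll(verts, -1, axis=0) - verts
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def basic_geometry(poly: CellPolygon | np.ndarray) -> tuple[float, float, float, float, float]:
    """Area, perimeter, convex-hull area/perimeter and solidity of a polygon.

    Area uses the shoelace formula, the perimeter is the sum of edge lengths,
    and solidity = area / hull_area (1 for convex cells).
    """
    verts = _as_vertices(poly)
    verts = verts - verts.mean(axis=0)  # translation-invariant numerics
    area = _shoelace(verts)
    if area <= 0:
        raise ValueError("degenerate polygon: non-positive shoelace area")
    perimeter = _ring_length(verts)
    hull = ConvexHull(verts)
    hull_verts = verts[hull.vertices]
    hull_area = _shoelace(hull_verts) if _shoelace(hull_verts) > 0 else -_shoelace(hull_verts)
    hull_perimeter = _ring_length(hull_verts)
    return area, perimeter, hull_area, hull_perimeter, area / hull_area


def feret_diameters(poly: CellPolygon | np.ndarray) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters.

    ``feret_max`` is the largest pairwise distance between convex-hull
    vertices; ``feret_min`` is the smallest caliper width over hull-edge
    orientations (rotating calipers: the minimum width is always attained
    with one caliper flush against a hull edge).
    """
    verts = _as_vertices(poly)
    if len(verts) < 3:
        raise ValueError("need at least 3 vertices")
    hull = ConvexHull(verts)
    hv = verts[hull.vertices]
    diff = hv[:, None, :] - hv[None, :, :]
    feret_max = float(np.sqrt((diff**2).sum(-1)).max())
    edges = np.roll(hv, -1, axis=0) - hv
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    proj = hv @ normals.T  # projections of all vertices on each edge normal
    widths = proj.max(axis=0) - proj.min(axis=0)
    return feret_max, float(widths.min())


def ellipse_descriptors(poly: CellPolygon | np.ndarray) -> tuple[float, float]:
    """Eccentricity and aspect ratio of the area-equivalent ellipse.

    Second central moments of the polygon interior (Green's theorem) give a
    covariance matrix; its eigenvalues l1 >= l2 define the equivalent-ellipse
    semi-axes a = 2 sqrt(l1), b = 2 sqrt(l2).  Returns
    (sqrt(1 - (b/a)^2), a/b).  Moment-based elongation is stable for
    staircase outlines, unlike the Feret max/min ratio.
    """
    v = _as_vertices(poly)
    v = v - v.mean(axis=0)  # pre-centre: avoids cancellation for far-off polygons
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area <= 0:
        raise ValueError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    ixx = ((y**2 + y * y1 + y1**2) * cross).sum() / 12 - area * cy**2
    iyy = ((x**2 + x * x1 + x1**2) * cross).sum() / 12 - area * cx**2
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24 - area * cx * cy
    cov = np.array([[iyy, ixy], [ixy, ixx]]) / area
    l2, l1 = np.sort(np.linalg.eigvalsh(cov))
    if l2 <= 0:
        raise ValueError("degenerate second moments")
    aspect = math.sqrt(l1 / l2)
    ecc = math.sqrt(1.0 - l2 / l1)
    return ecc, aspect


# ---------------------------------------------------------------------------
# regularity scores


def _regularity_ratios(
    p_cell: float,
    a_cell: float,
    p_hull: float,
    a_hull: float,
    n: int,
    clamp: bool,
) -> tuple[float, float]:
    if min(p_cell, a_cell, p_hull, a_hull) <= 0:
        raise ValueError("geometry inputs must be positive")
    cot = 1.0 / math.tan(math.pi / n)
    p_ref = n * math.sqrt(4.0 * a_cell / (n * cot))  # perimeter of regular n-gon, equal area
    a_ref = 0.25 * n * (p_cell / n) ** 2 * cot       # area of regular n-gon, equal perimeter
    sr = (p_cell / p_hull) * (1.0 - abs(1.0 - p_cell / p_ref))
    ar = (a_cell / a_hull) * (1.0 - abs(1.0 - a_cell / a_ref))
    if clamp:
        sr, ar = max(sr, 0.0), max(ar, 0.0)
    return sr, ar


def polygonality_score(
    p_cell: float,
    a_cell: float,
    p_hull: float,
    a_hull: float,
    n_neighbors: int,
    clamp_scores: bool = False,
) -> tuple[float, float, float]:
    """(PSR, PAR, polygonality score): regularity against the regular N-gon.

    Undefined for fewer than 3 neighbours (no regular 2-gon exists): raises
    ``ValueError``; callers report such cells as missing.
    """
    if n_neighbors < 3:
        raise ValueError(
            f"polygonality score undefined for n_neighbors={n_neighbors} < 3"
        )
    psr, par = _regularity_ratios(p_cell, a_cell, p_hull, a_hull, n_neighbors, clamp_scores)
    return psr, par, 10.0 * (psr + par) / 2.0


def hexagonality_score(
    p_cell: float,
    a_cell: float,
    p_hull: float,
    a_hull: float,
    clamp_scores: bool = False,
) -> tuple[float, float, float]:
    """(HSR, HAR, hexagonality score): regularity against the regular hexagon.

    Identical to :func:`polygonality_score` with N fixed at 6.
    """
    hsr, har = _regularity_ratios(p_cell, a_cell, p_hull, a_hull, 6, clamp_scores)
    return hsr, har, 10.0 * (hsr + har) / 2.0


# ---------------------------------------------------------------------------
# per-cell and per-sample assembly


def measure_cell(
    poly: CellPolygon,
    graph: AdjacencyGraph,
    clamp_scores: bool = False,
    mouse: str = "",
    genotype: str = "",
    age: float = float("nan"),
) -> ShapeMetrics:
    """Compute the full metric panel for one cell.

    The neighbour count is the cell's degree in the adjacency graph (the cell
    must be a node there).  The polygonality score is NaN when the cell has
    fewer than 3 neighbours.
    """
    if poly.cell_id not in graph:
        raise KeyError(f"cell {poly.cell_id} absent from adjacency graph")
    area, perimeter, hull_area, hull_perimeter, solidity = basic_geometry(poly)
    fmax, fmin = feret_diameters(poly)
    ecc, aspect = ellipse_descriptors(poly)
    n = graph.degree(poly.cell_id)
    hsr, har, hex_score = hexagonality_score(
        perimeter, area, hull_perimeter, hull_area, clamp_scores
    )
    if n >= 3:
        psr, par, poly_score = polygonality_score(
            perimeter, area, hull_perimeter, hull_area, n, clamp_scores
        )
    else:
        psr = par = poly_score = float("nan")
    return ShapeMetrics(
        cell_id=poly.cell_id,
        area=area,
        perimeter=perimeter,
        hull_area=hull_area,
        hull_perimeter=hull_perimeter,
        n_neighbors=n,
        solidity=solidity,
        feret_max=fmax,
        feret_min=fmin,
        eccentricity=ecc,
        aspect_ratio=aspect,
        psr=psr,
        par=par,
        hsr=hsr,
        har=har,
        polygonality_score=poly_score,
        hexagonality_score=hex_score,
        mouse=mouse,
        genotype=genotype,
        age=age,
        sample_id=poly.sample_id,
    )


def measure_cells(
    cells: Sequence[CellPolygon],
    graph: AdjacencyGraph,
    clamp_scores: bool = False,
    **metadata,
) -> list[ShapeMetrics]:
    """Vector convenience wrapper over :func:`measure_cell`."""
    return [measure_cell(c, graph, clamp_scores=clamp_scores, **metadata) for c in cells]


_SUMMARY_METRICS = [
    "area",
    "perimeter",
    "n_neighbors",
    "solidity",
    "feret_max",
    "feret_min",
    "eccentricity",
    "aspect_ratio",
    "polygonality_score",
    "hexagonality_score",
]


def summarize_sample(metrics: Sequence[ShapeMetrics] | pd.DataFrame) -> SampleSummary:
    """Per-sample mean/median/SD/skewness/kurtosis of each metric.

    SD uses the n-1 convention; skewness and kurtosis are the standardized
    third and fourth central moments (kurtosis reported as excess).  The
    hexagonality SD — the spread of the hexagonality score across cells of
    one image, itself a disorder readout — is surfaced separately.
    """
    if isinstance(metrics, pd.DataFrame):
        df = metrics
    else:
        df = pd.DataFrame([m.to_dict() for m in metrics])
    if len(df) == 0:
        raise ValueError("cannot summarize an empty sample")
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df else ""
    rows = {}
    for m in _SUMMARY_METRICS:
        if m not in df:
            continue
        x = df[m].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        rows[m] = {
            "mean": x.mean(),
            "median": float(np.median(x)),
            "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
            "skewness": float(sps.skew(x)) if len(x) > 2 else float("nan"),
            "kurtosis": float(sps.kurtosis(x)) if len(x) > 3 else float("nan"),
        }
    stats = pd.DataFrame(rows).T
    hx = df["hexagonality_score"].to_numpy(dtype=float)
    hex_sd = float(hx.std(ddof=1)) if len(hx) > 1 else 0.0
    return SampleSummary(
        sample_id=sample_id, n_cells=len(df), stats=stats, hexagonality_sd=hex_sd
    )
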