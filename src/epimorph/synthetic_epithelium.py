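"""Synthetic epithelial sheets with controllable regularity and ground truth.

The generator stands in for retinal pigment epithelium flatmounts.  Seeds are
placed on a triangular lattice whose spacing matches a target cell area (the
Voronoi diagram of an unperturbed triangular lattice is the regular-hexagon
honeycomb), perturbed by isotropic Gaussian jitter, optionally thinned by
dropout (each removed seed enlarges its neighbours — the mutant "big cell"
phenotype), Voronoi-tessellated and clipped to a rectangular window.  Lloyd
(centroidal) relaxation steps can pull a jittered sheet back toward
regularity.  Two knobs therefore span the phenotypic axis seen in ciliopathy
mutants: ``jitter_sigma`` (disorder: lower, more variable hexagonality) and
``dropout_fraction`` (enlarged cells: higher mean and variance of area).

Cohorts nest cells in images in mice in genotype x age groups, with a
per-mouse lognormal random effect on cell area, so that the mixed-model
comparison machinery can be exercised on data with known ground truth.

All randomness flows from a single named seed through
``numpy.random.SeedSequence`` substreams (one per image), so identical seeds
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon, box

from .tessellation_io import AdjacencyGraph, CellPolygon, LabelImage, adjacency_from_polygons

__all__ = [
    "GeneratorConfig",
    "CohortDesign",
    "GroupEffect",
    "Sheet",
    "SyntheticCohort",
    "generate_sheet",
    "rasterize",
    "simulate_cohort",
    "simulate_measurements",
]


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic sheet.

    window
        (width, height) of the field of view in micrometres.
    target_cell_area
        Mean cell area in um^2 (RPE cells are typically a few hundred um^2).
    jitter_sigma
        SD of the Gaussian seed perturbation, as a fraction of the lattice
        spacing.  0 = perfect honeycomb; ~0.5 = fully disordered.
    lloyd_iterations
        Centroidal relaxation steps applied after jitter/dropout.
    dropout_fraction
        Fraction of seeds removed before tessellation, in [0, 1).
    seed
        RNG seed; the sheet is deterministic given the config.
    raster_px_per_um
        Default raster resolution used by :func:`rasterize`.
    """

    window: tuple[float, float] = (400.0, 400.0)
    target_cell_area: float = 250.0
    jitter_sigma: float = 0.0
    lloyd_iterations: int = 0
    dropout_fraction: float = 0.0
    seed: int = 0
    raster_px_per_um: float = 2.0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.lloyd_iterations < 0:
            raise ValueError("lloyd_iterations must be >= 0")
        if self.target_cell_area <= 0 or min(self.window) <= 0:
            raise ValueError("window and target_cell_area must be positive")

    @property
    def lattice_spacing(self) -> float:
        """Triangular-lattice spacing giving hexagonal cells of the target area."""
        return math.sqrt(self.target_cell_area / (math.sqrt(3) / 2.0))


@dataclass
class Sheet:
    """A generated vector tessellation clipped to its window."""

    config: GeneratorConfig
    seeds: np.ndarray            # (n, 2) final seed positions (all, incl. margin)
    polygons: list[Polygon]      # clipped cell polygons, parallel to cell_ids
    cell_ids: list[int]          # ids of cells with nonzero area inside the window
    sample_id: str = ""

    def cell_polygons(self) -> list[CellPolygon]:
        """Cells as :class:`CellPolygon` with border flags set from the window."""
        w, h = self.config.window
        out = []
        for cid, poly in zip(self.cell_ids, self.polygons):
            x, y = poly.exterior.xy
            verts = np.column_stack([x, y])[:-1]
            if _signed_area(verts) < 0:
                verts = verts[::-1]
            xs, ys = verts[:, 0], verts[:, 1]
            touches = bool(
                (np.isclose(xs, 0) | np.isclose(xs, w) | np.isclose(ys, 0) | np.isclose(ys, h)).any()
            )
            out.append(
                CellPolygon(
                    cell_id=cid,
                    vertices=verts,
                    sample_id=self.sample_id,
                    touches_border=touches,
                )
            )
        return out

    def adjacency(self) -> AdjacencyGraph:
        return adjacency_from_polygons(self.cell_polygons())

    def interior_cells(self) -> list[CellPolygon]:
        return [c for c in self.cell_polygons() if not c.touches_border]


def _signed_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _triangular_lattice(window: tuple[float, float], spacing: float, margin: float) -> np.ndarray:
    w, h = window
    dy = spacing * math.sqrt(3) / 2.0
    rows = np.arange(-margin, h + margin + dy, dy)
    pts = []
    for i, y in enumerate(rows):
        offset = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(-margin + offset, w + margin + spacing, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.concatenate(pts)


def _voronoi_cells(points: np.ndarray, clip: Polygon) -> list[Polygon]:
    """Ordered Voronoi cells of ``points`` clipped to ``clip``."""
    mp = MultiPoint(points)
    cells = shapely.voronoi_polygons(mp, extend_to=clip.buffer(1.0), ordered=True)
    out = []
    for geom in cells.geoms:
        inter = geom.intersection(clip)
        out.append(inter)
    return out


def generate_sheet(cfg: GeneratorConfig, sample_id: str = "") -> Sheet:
    """Generate one vector tessellation.

    Raises ``ValueError`` if fewer than 25 cells survive clipping (the window
    is too small relative to the target cell area for meaningful statistics).
    """
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.lattice_spacing
    margin = 3.0 * spacing
    pts = _triangular_lattice(cfg.window, spacing, margin)
    if cfg.jitter_sigma > 0:
        pts = pts + rng.normal(0.0, cfg.jitter_sigma * spacing, size=pts.shape)
    if cfg.dropout_fraction > 0:
        keep = rng.random(len(pts)) >= cfg.dropout_fraction
        pts = pts[keep]
    w, h = cfg.window
    window_box = box(0.0, 0.0, w, h)
    extended = box(-margin, -margin, w + margin, h + margin)
    for _ in range(cfg.lloyd_iterations):
        cells = _voronoi_cells(pts, extended)
        # jittered margin points can leave the extended box, making their
        # clipped cell empty; such points stay where they are
        pts = np.array(
            [
                (c.centroid.x, c.centroid.y) if not c.is_empty else tuple(p)
                for c, p in zip(cells, pts)
            ]
        )
    cells = _voronoi_cells(pts, window_box)
    ids, polys = [], []
    for i, cell in enumerate(cells):
        if not cell.is_empty and cell.area > 0 and isinstance(cell, Polygon):
            ids.append(i + 1)
            polys.append(cell)
    if len(polys) < 25:
        raise ValueError(
            f"only {len(polys)} cells inside the window; enlarge the window or shrink target_cell_area"
        )
    return Sheet(config=cfg, seeds=pts, polygons=polys, cell_ids=ids, sample_id=sample_id)


def rasterize(
    sheet: Sheet,
    raster_px_per_um: float | None = None,
    membrane_px: int = 0,
) -> LabelImage:
    """Paint the tessellation as a label raster (nearest-seed per pixel centre).

    Because the cells *are* the Voronoi regions of the final seeds, labelling
    each pixel centre with its nearest seed id is the exact rasterization of
    the vector tessellation.  With ``membrane_px >= 1``, a 1-pixel background
    line is drawn on the upper/left side of every label change, emulating the
    membrane skeletons produced by border segmentation (wider membranes are
    obtained by binary dilation of that line).
    """
    res = raster_px_per_um if raster_px_per_um is not None else sheet.config.raster_px_per_um
    spacing = sheet.config.lattice_spacing
    if res * spacing < 5:
        raise ValueError(
            f"resolution {res} px/um gives {res * spacing:.1f} px per cell diameter (< 5)"
        )
    w, h = sheet.config.window
    nx, ny = int(round(w * res)), int(round(h * res))
    xs = (np.arange(nx) + 0.5) / res
    ys = (np.arange(ny) + 0.5) / res
    gx, gy = np.meshgrid(xs, ys)
    tree = cKDTree(sheet.seeds)
    _, idx = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), workers=-1)
    labels = (idx + 1).astype(np.int32).reshape(ny, nx)
    from scipy import ndimage

    if membrane_px >= 1:
        edge = np.zeros_like(labels, dtype=bool)
        edge[:, 1:] |= labels[:, 1:] != labels[:, :-1]
        edge[1:, :] |= labels[1:, :] != labels[:-1, :]
        if membrane_px > 1:
            edge = ndimage.binary_dilation(edge, iterations=membrane_px - 1)
        labels = labels.copy()
        labels[edge] = 0
    # pixel-centre sampling of a thin sliver (or the membrane line at an
    # acute corner) can sever a fragment from its cell; absorb such
    # fragments into the background, keeping each label's largest component
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        comp, n = ndimage.label(mask, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            region = labels[sl]
            region[mask & (comp != keep)] = 0
    return LabelImage(pixels=labels, pixel_size=1.0 / res)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupEffect:
    """Multiplicative effects applied to one genotype x age group."""

    area: float = 1.0
    jitter: float = 1.0
    dropout: float = 1.0

    def __post_init__(self) -> None:
        if min(self.area, self.jitter, self.dropout) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass
class CohortDesign:
    """A hierarchical study design: genotypes x ages x mice x images.

    ``effects`` maps (genotype, age) to a :class:`GroupEffect`; missing groups
    get the identity effect.  ``mouse_sd`` is the SD of the per-mouse
    lognormal random effect multiplying the target cell area (biological
    animal-to-animal variation, the reason a mixed model is needed).
    """

    genotypes: tuple[str, ...] = ("control", "mutant")
    ages: tuple[float, ...] = (1.0,)
    mice_per_group: int = 4
    images_per_mouse: int = 2
    effects: Mapping[tuple[str, float], GroupEffect] = field(default_factory=dict)
    mouse_sd: float = 0.1
    base: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mice_per_group < 2:
            raise ValueError("need >= 2 mice per group for any statistical use")
        if self.images_per_mouse < 1:
            raise ValueError("images_per_mouse must be >= 1")
        if self.mouse_sd < 0:
            raise ValueError("mouse_sd must be >= 0")

    def effect(self, genotype: str, age: float) -> GroupEffect:
        return self.effects.get((genotype, age), GroupEffect())


@dataclass
class SyntheticCohort:
    """Generated cohort: sheets plus tidy metadata and ground truth."""

    design: CohortDesign
    sheets: list[Sheet]
    metadata: pd.DataFrame       # one row per image: sample_id, mouse, genotype, age
    ground_truth: pd.DataFrame   # one row per cell: vector areas/perimeters/neighbours
    rasters: list[LabelImage] | None = None


def simulate_cohort(
    design: CohortDesign,
    rasterize_images: bool = False,
    membrane_px: int = 1,
) -> SyntheticCohort:
    """Generate a full hierarchical cohort of synthetic sheets.

    The per-mouse random effect multiplies ``target_cell_area`` by
    ``exp(N(0, mouse_sd))``; group effects scale area, jitter and dropout.
    Every image gets its own RNG substream derived from ``design.seed``, so
    the cohort is deterministic.
    """
    root = np.random.SeedSequence(design.seed)
    sheets: list[Sheet] = []
    rasters: list[LabelImage] = [] if rasterize_images else None
    meta_rows, truth_rows = [], []
    mouse_counter = 0
    for genotype in design.genotypes:
        for age in design.ages:
            eff = design.effect(genotype, age)
            for m in range(design.mice_per_group):
                mouse_counter += 1
                mouse_id = f"{genotype}_P{age:g}_m{m + 1}"
                mouse_seq = root.spawn(1)[0]
                mouse_rng = np.random.default_rng(mouse_seq)
                mouse_effect = float(np.exp(mouse_rng.normal(0.0, design.mouse_sd)))
                for k in range(design.images_per_mouse):
                    img_seed = int(mouse_rng.integers(0, 2**31 - 1))
                    sample_id = f"{mouse_id}_img{k + 1}"
                    cfg = replace(
                        design.base,
                        target_cell_area=design.base.target_cell_area * eff.area * mouse_effect,
                        jitter_sigma=design.base.jitter_sigma * eff.jitter,
                        dropout_fraction=min(design.base.dropout_fraction * eff.dropout, 0.95),
                        seed=img_seed,
                    )
                    sheet = generate_sheet(cfg, sample_id=sample_id)
                    sheets.append(sheet)
                    if rasterize_images:
                        rasters.append(rasterize(sheet, membrane_px=membrane_px))
                    meta_rows.append(
                        {
                            "sample_id": sample_id,
                            "mouse": mouse_id,
                            "genotype": genotype,
                            "age": age,
                            "true_area_scale": design.base.target_cell_area * eff.area * mouse_effect,
                            "true_jitter": cfg.jitter_sigma,
                        }
                    )
                    graph = sheet.adjacency()
                    for cell in sheet.cell_polygons():
                        truth_rows.append(
                            {
                                "sample_id": sample_id,
                                "mouse": mouse_id,
                                "genotype": genotype,
                                "age": age,
                                "cell_id": cell.cell_id,
                                "area": cell.shapely().area,
                                "perimeter": cell.shapely().length,
                                "n_neighbors": graph.degree(cell.cell_id),
                                "touches_border": cell.touches_border,
                            }
                        )
    return SyntheticCohort(
        design=design,
        sheets=sheets,
        metadata=pd.DataFrame(meta_rows),
        ground_truth=pd.DataFrame(truth_rows),
        rasters=rasters,
    )


def simulate_measurements(
    group_params: Sequence[Mapping],
    mice_per_group: int = 4,
    cells_per_mouse: int = 500,
    mouse_sd: float = 0.1,
    seed: int = 0,
    metric: str = "area",
    lognormal: bool = False,
) -> pd.DataFrame:
    """Draw per-cell measurements from the hierarchical model, without geometry.

    Each entry of ``group_params`` is a mapping with keys ``genotype``,
    ``age``, ``mean`` and ``sd``; per-mouse effects shift (or, with
    ``lognormal=True``, multiply) the group mean.  Returns a tidy cohort
    table (columns: metric, mouse, genotype, age, sample_id) suitable for the
    group-comparison machinery.  This is the fast path for calibration and
    power studies, where the tessellation geometry is irrelevant and only the
    hierarchical error structure matters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gi, gp in enumerate(group_params):
        genotype, age = str(gp["genotype"]), float(gp.get("age", 1.0))
        mean, sd = float(gp["mean"]), float(gp["sd"])
        for m in range(mice_per_group):
            mouse_id = f"{genotype}_P{age:g}_m{m + 1}"
            b = rng.normal(0.0, mouse_sd)
            eps = rng.normal(0.0, 1.0, size=cells_per_mouse)
            if lognormal:
                vals = mean * np.exp(b + sd / mean * eps)
            else:
                vals = mean + b + sd * eps
            rows.append(
                pd.DataFrame(
                    {
                        metric: vals,
                        "mouse": mouse_id,
                        "genotype": genotype,
                        "age": age,
                        "sample_id": f"{mouse_id}_img1",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
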