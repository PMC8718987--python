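"""Bilateral (ipsilateral-vs-contralateral) spatial analysis of tissue prints.

A brain-slice print carries a 2D map of reductive capacity with anatomy
preserved. A unilateral insult (e.g. probe-placement trauma) is analysed by
exploiting bilateral symmetry: the image is split at the medial line, the
intact hemisphere is mirrored onto the damaged one so every ipsilateral
pixel is paired with its homologous contralateral pixel, and pixel-wise sum
and difference maps are formed. Per-region comparisons then sample both
sides through the same ROI mask and summarise the loss of reductive
capacity as the *oxidative increment* (contralateral mean minus ipsilateral
mean), ranked by the region's distance to the trauma site.

Mirror convention: the axis passes through the center of the midline
column m (x' = 2m - x); column m itself belongs to neither side, which
makes mirroring an exact involution on the integer grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon as draw_polygon

from .errors import (DataError, DegenerateModelError, DimensionError,
                     GeometryError, ParameterError)
from .image_io import MembraneImage

__all__ = [
    "BilateralMap",
    "RegionOfInterest",
    "RegionComparison",
    "estimate_midline",
    "mirror_pair",
    "bilateral_maps",
    "line_profile",
    "compare_region",
    "rank_regions",
    "export_surface",
]


@dataclass(frozen=True)
class BilateralMap:
    """Midline-anchored mirrored pair with pixel-wise sum and difference fields.

    ``ipsi`` and ``contra`` are (height x overlap_width) fields indexed by
    (row, d) where d = 1..overlap_width is the column offset from the
    midline; ``sum_map = ipsi + contra`` and ``diff_map = ipsi - contra``.
    For a perfectly mirror-symmetric source the difference map is
    identically zero.
    """

    source: MembraneImage
    midline_col: int
    ipsilateral_side: str
    ipsi: np.ndarray
    contra: np.ndarray
    sum_map: np.ndarray
    diff_map: np.ndarray

    @property
    def overlap_width_px(self) -> int:
        return self.ipsi.shape[1]


@dataclass(frozen=True)
class RegionOfInterest:
    """A named region, given as a simple polygon or a binary mask.

    Coordinates are in *source-image* pixels on the ipsilateral side; the
    homologous contralateral sample is obtained automatically through the
    mirror map, so ROIs are drawn once.
    """

    name: str
    polygon: tuple[tuple[float, float], ...] | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ParameterError("provide exactly one of polygon or mask")
        if self.polygon is not None and len(self.polygon) < 3:
            raise GeometryError("polygon needs >= 3 vertices")
        if self.mask is not None and not np.asarray(self.mask).any():
            raise GeometryError("mask is empty")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the ROI on a grid of the given shape."""
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise DimensionError(f"mask shape {m.shape} != image shape {shape}")
            return m
        rows = np.array([v[0] for v in self.polygon])
        cols = np.array([v[1] for v in self.polygon])
        if rows.min() < 0 or cols.min() < 0 or rows.max() > shape[0] - 1 or cols.max() > shape[1] - 1:
            raise GeometryError(f"ROI {self.name!r} polygon leaves image bounds")
        rr, cc = draw_polygon(rows, cols, shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        if not m.any():
            raise GeometryError(f"ROI {self.name!r} rasterizes to an empty mask")
        return m

    def centroid(self, shape: tuple[int, int]) -> tuple[float, float]:
        m = self.rasterize(shape)
        rr, cc = np.nonzero(m)
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class RegionComparison:
    """Per-ROI ipsi-vs-contra intensity distributions plus trauma distance."""

    name: str
    ipsi_values: np.ndarray
    contra_values: np.ndarray
    ipsi_mean: float
    contra_mean: float
    oxidative_increment: float
    distance_px: float
    density_grid: np.ndarray
    ipsi_density: np.ndarray
    contra_density: np.ndarray
    n_px: int
    flags: tuple[str, ...] = ()


def estimate_midline(img: MembraneImage, search: tuple[int, int] | None = None) -> int:
    """Locate the medial line as the column maximizing left/right mirror correlation.

    For each candidate column m (default search range: the central third of
    the image) the left block and the horizontally flipped right block over
    their overlap are compared by Pearson correlation; the best m wins, ties
    broken toward the smaller index. A uniform image has no defined midline
    and raises, prompting a manual override.
    """
    if not img.is_reductive_scale:
        raise ParameterError("estimate_midline requires a reductive-scale image")
    w = img.width_px
    if w < 9:
        raise DimensionError("image too narrow for midline estimation")
    if search is None:
        search = (w // 3, w - w // 3)
    lo = max(1, search[0])
    hi = min(w - 2, search[1])
    px = img.pixels
    best_m, best_r = None, -np.inf
    for m in range(lo, hi + 1):
        k = min(m, w - 1 - m)
        if k < 1:
            continue
        left = px[:, m - k:m]
        right = px[:, m + 1:m + 1 + k][:, ::-1]
        lf, rf = left.ravel(), right.ravel()
        if np.ptp(lf) == 0 or np.ptp(rf) == 0:  # constant block: no signal
            continue
        r = float(np.corrcoef(lf, rf)[0, 1])
        if r > best_r:
            best_r, best_m = r, m
    if best_m is None:
        raise DegenerateModelError(
            "flat correlation: image has no detectable mirror axis; supply midline manually")
    return best_m


def mirror_pair(
    img: MembraneImage, midline_col: int, ipsilateral_side: str = "right"
) -> tuple[np.ndarray, np.ndarray]:
    """Split at the midline and mirror-pair the two hemispheres.

    Returns (ipsi, contra) fields of shape (height, overlap_width) indexed
    by (row, d-1) with d the offset from the midline: for
    ``ipsilateral_side="right"``, ipsi(r, d) = I(r, m + d) and
    contra(r, d) = I(r, m - d); symmetric for "left". The midline column
    itself belongs to neither field.
    """
    if ipsilateral_side not in ("left", "right"):
        raise ParameterError("ipsilateral_side must be 'left' or 'right'")
    w = img.width_px
    if not (0 <= midline_col <= w - 1):
        raise DimensionError(f"midline column {midline_col} outside image")
    k = min(midline_col, w - 1 - midline_col)
    if k < 1:
        raise DimensionError("overlap region is empty for this midline")
    px = img.pixels
    right = px[:, midline_col + 1:midline_col + 1 + k]
    left = px[:, midline_col - k:midline_col][:, ::-1]
    if ipsilateral_side == "right":
        return right.copy(), left.copy()
    return left.copy(), right.copy()


def bilateral_maps(
    img: MembraneImage, midline_col: int, ipsilateral_side: str = "right"
) -> BilateralMap:
    """Build the pixel-addition and pixel-subtraction maps over the overlap."""
    ipsi, contra = mirror_pair(img, midline_col, ipsilateral_side)
    return BilateralMap(source=img, midline_col=midline_col,
                        ipsilateral_side=ipsilateral_side,
                        ipsi=ipsi, contra=contra,
                        sum_map=ipsi + contra, diff_map=ipsi - contra)


def line_profile(bmap: BilateralMap, col_offset: int) -> pd.DataFrame:
    """Paired dorsoventral intensity profiles at a fixed offset from the midline.

    Returns a frame with columns ``row, ipsi, contra`` for all rows;
    dorsoventral orientation means increasing row index.
    """
    if not (1 <= col_offset <= bmap.overlap_width_px):
        raise ParameterError(
            f"col_offset must be in [1, {bmap.overlap_width_px}], got {col_offset}")
    d = col_offset - 1
    return pd.DataFrame({
        "row": np.arange(bmap.ipsi.shape[0]),
        "ipsi": bmap.ipsi[:, d],
        "contra": bmap.contra[:, d],
    })


def _overlap_mask_from_source(
    bmap: BilateralMap, roi: RegionOfInterest
) -> np.ndarray:
    """Map a source-coordinate ipsilateral ROI into overlap (row, d) coordinates."""
    src_shape = (bmap.source.height_px, bmap.source.width_px)
    m = roi.rasterize(src_shape)
    rr, cc = np.nonzero(m)
    mid = bmap.midline_col
    if bmap.ipsilateral_side == "right":
        d = cc - mid  # offset, must be >= 1
    else:
        d = mid - cc
    if np.any(d < 1):
        raise GeometryError(f"ROI {roi.name!r} straddles or touches the midline")
    if np.any(d > bmap.overlap_width_px):
        raise GeometryError(f"ROI {roi.name!r} leaves the bilateral overlap region")
    out = np.zeros(bmap.ipsi.shape, dtype=bool)
    out[rr, d - 1] = True
    return out


def _grid_density(values: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Gaussian KDE (Silverman bandwidth) on a fixed grid, renormalized so the
    trapezoid integral over the grid is exactly 1. Degenerate (zero-variance)
    samples collapse to a unit spike at the nearest grid node."""
    flags: list[str] = []
    if np.ptp(values) == 0:
        dens = np.zeros_like(grid)
        i = int(np.argmin(np.abs(grid - values[0])))
        # unit mass in one trapezoid cell
        cell = np.trapezoid(np.eye(len(grid))[i], grid)
        dens[i] = 1.0 / cell if cell > 0 else 0.0
        flags.append("degenerate_density")
        return dens, flags
    kde = stats.gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    total = np.trapezoid(dens, grid)
    if total <= 0:
        raise DataError("density estimate integrates to zero")
    return dens / total, flags


def compare_region(
    bmap: BilateralMap,
    roi: RegionOfInterest,
    trauma: tuple[float, float],
    n_grid: int = 256,
) -> RegionComparison:
    """Compare ipsi vs contra intensity distributions within one ROI.

    The ROI is drawn on the ipsilateral side in source coordinates; the
    contralateral sample uses the same mask on the mirrored field, i.e. the
    homologous pixels. Densities are Gaussian KDEs (Silverman's bandwidth)
    on a common grid spanning the pooled value range padded by three
    bandwidths, renormalized to integrate to 1 on the grid. ``distance_px``
    is the Euclidean distance from the ROI centroid to the trauma point in
    source-image coordinates.
    """
    tr, tc = trauma
    if not (0 <= tr <= bmap.source.height_px - 1 and 0 <= tc <= bmap.source.width_px - 1):
        raise ParameterError(f"trauma point {trauma} outside image")
    mask = _overlap_mask_from_source(bmap, roi)
    flags: list[str] = []
    n_px = int(mask.sum())
    if n_px < 10:
        flags.append("small_roi")

    ipsi_values = bmap.ipsi[mask]
    contra_values = bmap.contra[mask]
    ipsi_mean = float(ipsi_values.mean())
    contra_mean = float(contra_values.mean())

    pooled = np.concatenate([ipsi_values, contra_values])
    lo, hi = float(pooled.min()), float(pooled.max())
    if np.ptp(pooled) > 0:
        # Silverman bandwidth of the pooled sample sets the grid padding
        bw = 1.06 * pooled.std(ddof=1) * pooled.size ** (-1 / 5)
        pad = 3.0 * bw if bw > 0 else 0.5 * (hi - lo)
    else:
        pad = max(abs(lo), 1.0) * 1e-3
    grid = np.linspace(lo - pad, hi + pad, n_grid)

    ipsi_density, f1 = _grid_density(ipsi_values, grid)
    contra_density, f2 = _grid_density(contra_values, grid)
    flags.extend(sorted(set(f1 + f2)))

    cr, cc = roi.centroid((bmap.source.height_px, bmap.source.width_px))
    dist = float(np.hypot(cr - tr, cc - tc))

    return RegionComparison(
        name=roi.name,
        ipsi_values=ipsi_values, contra_values=contra_values,
        ipsi_mean=ipsi_mean, contra_mean=contra_mean,
        oxidative_increment=contra_mean - ipsi_mean,
        distance_px=dist,
        density_grid=grid, ipsi_density=ipsi_density, contra_density=contra_density,
        n_px=n_px, flags=tuple(flags),
    )


def rank_regions(
    comparisons: list[RegionComparison],
) -> tuple[list[RegionComparison], float]:
    """Sort regions by distance to the trauma site (ties: alphabetical).

    Returns the ordered list plus the Spearman rank correlation between
    distance and oxidative increment — negative values mean regions nearest
    the trauma lost the most reductive capacity.
    """
    if not comparisons:
        raise DataError("no region comparisons to rank")
    if not all(np.isfinite(c.distance_px) for c in comparisons):
        raise DataError("all distances must be finite")
    ordered = sorted(comparisons, key=lambda c: (c.distance_px, c.name))
    dist = np.array([c.distance_px for c in ordered])
    inc = np.array([c.oxidative_increment for c in ordered])
    if len(ordered) >= 2 and np.ptp(dist) > 0 and np.ptp(inc) > 0:
        rho = float(stats.spearmanr(dist, inc).statistic)
    else:
        rho = float("nan")  # undefined for constant ranks
    return ordered, rho


def export_surface(
    field: np.ndarray | MembraneImage,
    csv_path: str | None = None,
    figure_path: str | None = None,
) -> pd.DataFrame:
    """Export a 2D field as a long-format (row, col, value) table.

    Optionally writes the table to CSV and renders a heat-map figure (the
    pseudocolor rendering is cosmetic and carries no analysis semantics).
    The table round-trips: pivoting it back reproduces the field exactly.
    """
    arr = field.pixels if isinstance(field, MembraneImage) else np.asarray(field)
    if arr.ndim != 2:
        raise DimensionError("export_surface needs a 2D field")
    rows, cols = np.indices(arr.shape)
    table = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(),
                          "value": arr.ravel()})
    if csv_path:
        table.to_csv(csv_path, index=False)
    if figure_path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(arr, cmap="afmhot", origin="upper")
        fig.colorbar(im, ax=ax, label="reductive intensity")
        ax.set_xlabel("column (px)")
        ax.set_ylabel("row (px)")
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return table
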