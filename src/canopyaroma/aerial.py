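"""Per-tree partitioning, gap analysis and georeferencing of plantation mosaics.

A rectangular block crop of an aerial image is partitioned into a fixed
grid of tree cells from the planting geometry (row spacing, within-row tree
spacing, metres per pixel).  Each cell is segmented on the CIELab a*
channel, gap-analyzed like an upward-looking photograph with the inter-row
as background, and flagged missing when the crown cover falls below a
threshold.  Cell centres are georeferenced by bilinear interpolation of the
block's four corner GPS coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gap import AnalysisSettings, CanopyArchitecture, analyze_mask
from .segmentation import ThresholdMode, binarize_aerial

__all__ = [
    "BlockLayout",
    "TreeCell",
    "PlantationMatrix",
    "partition_block",
    "assess_tree_cell",
    "georeference_grid",
    "analyze_plantation",
]

MISSING_FC_THRESHOLD = 0.1

_EMPTY_ARCH = CanopyArchitecture(
    ff=0.0, fc=0.0, phi=1.0, lai=0.0, omega0=1.0, lai_e=0.0, empty_flag=True
)


@dataclass(frozen=True)
class BlockLayout:
    """Planting geometry of one block.

    ``corner_gps`` holds four WGS84 (lat, lon) pairs in row-major order:
    (row0,col0), (row0,colN), (rowM,col0), (rowM,colN), where grid rows run
    along the planting rows (tree spacing 2 m) and grid columns across them
    (row spacing 5 m).  ``block_pixel_bounds`` is (top, left, height, width)
    of the block crop within the aerial image.
    """

    corner_gps: tuple[tuple[float, float], ...]
    pixel_scale: float  # metres per pixel
    block_pixel_bounds: tuple[int, int, int, int]
    row_spacing: float = 5.0
    tree_spacing: float = 2.0

    def __post_init__(self) -> None:
        if len(self.corner_gps) != 4:
            raise ValueError("four corner GPS pairs required")
        if self.row_spacing <= 0 or self.tree_spacing <= 0 or self.pixel_scale <= 0:
            raise ValueError("spacings and pixel scale must be positive")
        corners = np.asarray(self.corner_gps, dtype=float)
        if np.linalg.matrix_rank(corners - corners.mean(axis=0)) < 1 or (
            len(np.unique(corners, axis=0)) < 3
        ):
            raise ValueError("degenerate corner geometry")


@dataclass
class TreeCell:
    """One planting position: grid index, architecture, missing flag, location."""

    row_index: int
    col_index: int
    architecture: CanopyArchitecture
    missing: bool
    lat: float | None = None
    lon: float | None = None
    sub_image: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PlantationMatrix:
    """Grid of tree cells preserving field positions (row-major)."""

    cells: list[TreeCell]
    n_rows: int
    n_cols: int
    layout: BlockLayout | None = None

    def __post_init__(self) -> None:
        if len(self.cells) != self.n_rows * self.n_cols:
            raise ValueError("cell count must equal n_rows * n_cols")

    def cell(self, row: int, col: int) -> TreeCell:
        return self.cells[row * self.n_cols + col]

    def to_frame(self, block: str = "") -> pd.DataFrame:
        rows = []
        for c in self.cells:
            a = c.architecture
            rows.append(
                {
                    "block": block,
                    "row": c.row_index,
                    "col": c.col_index,
                    "lat": c.lat,
                    "lon": c.lon,
                    "lai": a.lai,
                    "lai_e": a.lai_e,
                    "ff": a.ff,
                    "fc": a.fc,
                    "phi": a.phi,
                    "omega0": a.omega0,
                    "missing": c.missing,
                }
            )
        return pd.DataFrame(rows)


def _grid_shape(height_px: int, width_px: int, layout: BlockLayout) -> tuple[int, int]:
    """Grid rows (along planting rows) and columns (across rows) for a block."""
    length_m = height_px * layout.pixel_scale  # along planting rows
    width_m = width_px * layout.pixel_scale  # across rows
    n_rows = max(1, round(length_m / layout.tree_spacing))
    n_cols = max(1, round(width_m / layout.row_spacing))
    if length_m < layout.tree_spacing or width_m < layout.row_spacing:
        warnings.warn(
            "block smaller than one planting spacing: using a single cell",
            stacklevel=3,
        )
    return n_rows, n_cols


def _edges(size: int, n: int) -> np.ndarray:
    return np.round(np.linspace(0, size, n + 1)).astype(int)


def partition_block(
    image: np.ndarray, layout: BlockLayout
) -> list[tuple[int, int, np.ndarray]]:
    """Crop the block and sub-crop one tile per planting position.

    Returns ``(row_index, col_index, tile)`` triples in row-major order.
    The tiling is exhaustive and non-overlapping: tile pixel counts sum to
    the block pixel count.
    """
    img = np.asarray(image)
    top, left, height, width = layout.block_pixel_bounds
    if top < 0 or left < 0 or top + height > img.shape[0] or left + width > img.shape[1]:
        raise ValueError("block bounds exceed the image")
    block = img[top : top + height, left : left + width]
    n_rows, n_cols = _grid_shape(height, width, layout)
    row_edges = _edges(height, n_rows)
    col_edges = _edges(width, n_cols)
    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            tiles.append(
                (
                    i,
                    j,
                    block[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]],
                )
            )
    return tiles


def assess_tree_cell(
    sub_image: np.ndarray,
    row_index: int,
    col_index: int,
    settings: AnalysisSettings | None = None,
    missing_threshold: float = MISSING_FC_THRESHOLD,
    missing_when_below: bool = True,
    threshold_mode: ThresholdMode = "otsu",
    fixed_value: float | None = None,
) -> TreeCell:
    """Segment and gap-analyze one tree tile; flag missing trees.

    A position whose crown cover ``fc`` falls below ``missing_threshold``
    (default 0.1) holds no tree; its architecture is zeroed.  Setting
    ``missing_when_below=False`` inverts the comparison for compatibility
    with the opposite reading of the rule.
    """
    settings = settings or AnalysisSettings()
    mask = binarize_aerial(
        sub_image, threshold_mode, fixed_value, source_id=f"r{row_index}c{col_index}"
    )
    arch = analyze_mask(mask, settings)
    missing = arch.fc < missing_threshold if missing_when_below else arch.fc > missing_threshold
    if missing:
        arch = replace(_EMPTY_ARCH, source_id=arch.source_id)
    return TreeCell(
        row_index=row_index, col_index=col_index, architecture=arch,
        missing=bool(missing), sub_image=sub_image,
    )


def georeference_grid(matrix: PlantationMatrix, layout: BlockLayout) -> PlantationMatrix:
    """Assign a latitude/longitude to every cell centre.

    The four block corners are interpolated bilinearly at the fractional
    grid coordinates of each cell centre, ``((row+0.5)/n_rows,
    (col+0.5)/n_cols)``; for corners that form a parallelogram this is the
    exact affine placement of the planting grid.
    """
    corners = np.asarray(layout.corner_gps, dtype=float)  # rows: 00, 01, 10, 11
    c00, c01, c10, c11 = corners
    for cell in matrix.cells:
        u = (cell.row_index + 0.5) / matrix.n_rows
        v = (cell.col_index + 0.5) / matrix.n_cols
        pos = (
            (1 - u) * (1 - v) * c00
            + (1 - u) * v * c01
            + u * (1 - v) * c10
            + u * v * c11
        )
        cell.lat, cell.lon = float(pos[0]), float(pos[1])
    matrix.layout = layout
    return matrix


def analyze_plantation(
    image: np.ndarray,
    layout: BlockLayout,
    settings: AnalysisSettings | None = None,
    missing_threshold: float = MISSING_FC_THRESHOLD,
    threshold_mode: ThresholdMode = "otsu",
    fixed_value: float | None = None,
) -> PlantationMatrix:
    """Partition, assess and georeference a whole block in one call.

    The automatic a* threshold is computed once from the whole block's
    histogram (strongly bimodal: canopy vs inter-row) and applied to every
    tile, so tiles that are pure inter-row — empty planting positions —
    segment as all-background instead of having their sensor noise split
    into spurious classes.
    """
    if threshold_mode == "otsu":
        from skimage.color import rgb2lab
        from skimage.filters import threshold_otsu

        top, left, height, width = layout.block_pixel_bounds
        block = np.asarray(image)[top : top + height, left : left + width]
        a_star = rgb2lab(block[..., :3].astype(np.uint8))[..., 1]
        threshold_mode, fixed_value = "fixed", float(threshold_otsu(a_star))
    tiles = partition_block(image, layout)
    n_rows = max(t[0] for t in tiles) + 1
    n_cols = max(t[1] for t in tiles) + 1
    cells = [
        assess_tree_cell(
            tile, i, j, settings, missing_threshold,
            threshold_mode=threshold_mode, fixed_value=fixed_value,
        )
        for i, j, tile in tiles
    ]
    matrix = PlantationMatrix(cells=cells, n_rows=n_rows, n_cols=n_cols)
    return georeference_grid(matrix, layout)
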