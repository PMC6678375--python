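"""Gap-grid analysis of binary canopy masks.

A cover photograph (upward-looking, sky background) or an aerial per-tree
sub-image (downward-looking, inter-row background) is reduced to a boolean
raster in which ``True`` marks foliage and ``False`` marks gap.  The raster
is subdivided into an ``m x n`` grid of cells, gaps are classified as
*large* (between-crown) or *small* (within-crown) by a per-cell gap-fraction
threshold, and six canopy-architecture parameters are derived:

==============  =================================================
``ff``          foliage projective cover, ``1 - t_g / t_p``
``fc``          crown cover, ``1 - l_g / t_p``
``phi``         crown porosity, ``1 - ff / fc``
``lai``         leaf area index, ``-fc * ln(phi) / k`` (Beer's law)
``omega0``      clumping index at the zenith,
                ``(1 - phi) * ln(1 - ff) / (ff * ln(phi))``
``lai_e``       effective LAI, ``lai * omega0``
==============  =================================================

where ``t_p`` is the total pixel count, ``t_g`` the gap pixel count and
``l_g`` the large-gap pixel count.  ``omega0 == 1`` means the foliage is
randomly dispersed; values below 1 indicate clumping.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "BinaryCanopyMask",
    "AnalysisSettings",
    "GapGrid",
    "CanopyArchitecture",
    "subdivide_and_classify",
    "compute_cover_fractions",
    "compute_lai_suite",
    "analyze_mask",
    "read_mask_png",
    "write_mask_png",
    "append_results_csv",
    "GapAnalyzer",
]

Orientation = Literal["upward", "aerial"]

RESULT_CSV_COLUMNS = [
    "source_id",
    "date",
    "lat",
    "lon",
    "ff",
    "fc",
    "phi",
    "lai",
    "omega0",
    "lai_e",
    "k",
    "grid",
    "threshold",
]


@dataclass(frozen=True)
class BinaryCanopyMask:
    """Boolean canopy raster; ``True`` = foliage, ``False`` = gap."""

    pixels: np.ndarray
    orientation: Orientation = "upward"
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("empty raster")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def gap_fraction(self) -> float:
        return float(1.0 - self.pixels.mean())


@dataclass(frozen=True)
class AnalysisSettings:
    """Parameters of the gap analysis.

    ``grid_rows`` x ``grid_cols`` defaults to the 5 x 5 subdivision; a cell
    whose gap fraction reaches ``big_gap_threshold`` (default 75 %)
    contributes its gap pixels as large gaps.  ``k`` is the Beer's-law light
    extinction coefficient (0.7 for cocoa canopies; 0.61 is the common
    cover-photography value for broadleaf species and may be substituted).
    ``porosity_floor`` keeps logarithms finite on degenerate masks.
    ``large_gap_mode`` selects between the cell-level rule (``"cell"``) and
    a connected-component rule (``"component"``: a contiguous gap region is
    large when it covers at least the threshold fraction of a cell).
    """

    grid_rows: int = 5
    grid_cols: int = 5
    big_gap_threshold: float = 0.75
    k: float = 0.7
    porosity_floor: float = 1e-6
    large_gap_mode: Literal["cell", "component"] = "cell"

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 < self.big_gap_threshold <= 1.0:
            raise ValueError("big_gap_threshold must be in (0, 1]")
        if self.k <= 0:
            raise ValueError("light extinction coefficient k must be > 0")
        if not 0.0 < self.porosity_floor < 1.0:
            raise ValueError("porosity_floor must be a small positive fraction")


@dataclass
class GapGrid:
    """Per-cell pixel tallies: total (``t_p``), gap (``t_g``), large gap (``l_g``)."""

    t_p: np.ndarray  # (m, n) int
    t_g: np.ndarray
    l_g: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.all(self.l_g <= self.t_g)
            and np.all(self.t_g <= self.t_p)
            and np.all(self.l_g >= 0)
        ):
            raise ValueError("cell tallies must satisfy 0 <= l_g <= t_g <= t_p")

    @property
    def total_pixels(self) -> int:
        return int(self.t_p.sum())

    @property
    def total_gap(self) -> int:
        return int(self.t_g.sum())

    @property
    def total_large_gap(self) -> int:
        return int(self.l_g.sum())


@dataclass(frozen=True)
class CanopyArchitecture:
    """The six-parameter canopy record for one image."""

    ff: float
    fc: float
    phi: float
    lai: float
    omega0: float
    lai_e: float
    k_used: float = 0.7
    empty_flag: bool = False
    source_id: str = ""

    def as_feature_vector(self) -> np.ndarray:
        """Feature order used by the aroma model: LAI, LAI_e, ff, fc, phi, omega0."""
        return np.array(
            [self.lai, self.lai_e, self.ff, self.fc, self.phi, self.omega0]
        )


FEATURE_NAMES = ["lai", "lai_e", "ff", "fc", "phi", "omega0"]


def _cell_edges(size: int, n_cells: int) -> np.ndarray:
    """Cell boundaries along one axis; remainder pixels join the last cell."""
    step = size // n_cells
    edges = np.arange(n_cells + 1) * step
    edges[-1] = size
    return edges


def subdivide_and_classify(
    mask: BinaryCanopyMask, settings: AnalysisSettings | None = None
) -> GapGrid:
    """Subdivide a mask into grid cells and classify gap pixels large vs small.

    Under the default cell-level rule, a cell whose gap fraction
    ``t_g / t_p`` reaches ``big_gap_threshold`` contributes all of its gap
    pixels as large (``l_g = t_g``); otherwise ``l_g = 0``.  Under the
    component rule, each connected gap region within a cell is large when
    its pixel count reaches the threshold fraction of the cell.
    """
    settings = settings or AnalysisSettings()
    h, w = mask.shape
    m, n = settings.grid_rows, settings.grid_cols
    if m > h or n > w:
        raise ValueError(
            f"grid {m}x{n} larger than mask {h}x{w}: every cell needs >= 1 pixel"
        )
    gaps = ~mask.pixels
    row_edges = _cell_edges(h, m)
    col_edges = _cell_edges(w, n)

    t_p = np.zeros((m, n), dtype=np.int64)
    t_g = np.zeros((m, n), dtype=np.int64)
    l_g = np.zeros((m, n), dtype=np.int64)
    for i in range(m):
        for j in range(n):
            cell = gaps[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            t_p[i, j] = cell.size
            t_g[i, j] = int(cell.sum())
            if t_g[i, j] == 0:
                continue
            if settings.large_gap_mode == "cell":
                if t_g[i, j] / t_p[i, j] >= settings.big_gap_threshold:
                    l_g[i, j] = t_g[i, j]
            else:
                l_g[i, j] = _component_large_gaps(
                    cell, settings.big_gap_threshold
                )
    return GapGrid(t_p=t_p, t_g=t_g, l_g=l_g)


def _component_large_gaps(cell_gaps: np.ndarray, threshold: float) -> int:
    from scipy import ndimage

    labels, n_comp = ndimage.label(cell_gaps)
    if n_comp == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(sizes[sizes >= threshold * cell_gaps.size].sum())


def compute_cover_fractions(grid: GapGrid) -> tuple[float, float, float]:
    """Whole-mask cover fractions ``(ff, fc, phi)`` from the gap grid.

    The all-sky mask (``fc == 0``) is returned as the degenerate convention
    ``ff = fc = 0, phi = 1`` rather than raising: downstream code flags it
    as an empty canopy.
    """
    t_p = grid.total_pixels
    ff = 1.0 - grid.total_gap / t_p
    fc = 1.0 - grid.total_large_gap / t_p
    if fc <= 0.0:
        return 0.0, 0.0, 1.0
    phi = 1.0 - ff / fc
    # fc >= ff always (l_g <= t_g); guard rounding at phi ~ 0
    return ff, fc, min(max(phi, 0.0), 1.0)


def compute_lai_suite(
    ff: float,
    fc: float,
    phi: float,
    settings: AnalysisSettings | None = None,
    source_id: str = "",
) -> CanopyArchitecture:
    """LAI, clumping index and effective LAI from the cover fractions.

    Beer's law inverts the within-crown porosity: ``LAI = -fc ln(phi) / k``.
    The zenith clumping index ``omega0 = (1 - phi) ln(1 - ff) / (ff ln phi)``
    equals 1 exactly when ``fc == 1`` (no between-crown gaps, i.e. random
    dispersion) and falls below 1 as gaps aggregate.  Degenerate inputs are
    clamped: porosity is floored at ``porosity_floor`` and ``ff = 1`` uses
    ``1 - porosity_floor`` inside the logarithm, so outputs stay finite.
    """
    settings = settings or AnalysisSettings()
    if not (0.0 <= ff <= 1.0 and 0.0 <= fc <= 1.0):
        raise ValueError("cover fractions must lie in [0, 1]")
    if ff > fc + 1e-12:
        raise ValueError("foliage projective cover cannot exceed crown cover")
    eps = settings.porosity_floor
    if fc == 0.0:
        # all-sky: empty canopy by convention
        return CanopyArchitecture(
            ff=0.0, fc=0.0, phi=1.0, lai=0.0, omega0=1.0, lai_e=0.0,
            k_used=settings.k, empty_flag=True, source_id=source_id,
        )
    phi_eff = min(max(phi, eps), 1.0 - eps)
    lai = -fc * math.log(phi_eff) / settings.k
    ff_eff = min(max(ff, eps), 1.0 - eps)
    if phi >= 1.0 - eps:
        # no foliage signal within crowns; treat as random dispersion
        omega0 = 1.0
    else:
        omega0 = (1.0 - phi_eff) * math.log(1.0 - ff_eff) / (
            ff_eff * math.log(phi_eff)
        )
    omega0 = min(max(omega0, 0.0), 1.0)
    return CanopyArchitecture(
        ff=ff, fc=fc, phi=phi, lai=lai, omega0=omega0, lai_e=lai * omega0,
        k_used=settings.k, empty_flag=False, source_id=source_id,
    )


def analyze_mask(
    mask: BinaryCanopyMask, settings: AnalysisSettings | None = None
) -> CanopyArchitecture:
    """Full gap analysis of one mask: subdivision, cover fractions, LAI suite."""
    settings = settings or AnalysisSettings()
    grid = subdivide_and_classify(mask, settings)
    ff, fc, phi = compute_cover_fractions(grid)
    return compute_lai_suite(ff, fc, phi, settings, source_id=mask.source_id)


# ---------------------------------------------------------------------------
# I/O

def read_mask_png(path: str | Path, orientation: Orientation = "upward") -> BinaryCanopyMask:
    """Read a single-channel mask PNG (0 = gap, 255 = foliage)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryCanopyMask(arr >= 128, orientation=orientation, source_id=Path(path).stem)


def write_mask_png(mask: BinaryCanopyMask, path: str | Path) -> None:
    Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8)).save(path)


def append_results_csv(
    path: str | Path,
    arch: CanopyArchitecture,
    settings: AnalysisSettings,
    date: str = "",
    lat: float | None = None,
    lon: float | None = None,
) -> None:
    """Append one per-image record to the results CSV (header written once)."""
    path = Path(path)
    new = not path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_CSV_COLUMNS)
        if new:
            writer.writeheader()
        writer.writerow(
            {
                "source_id": arch.source_id,
                "date": date,
                "lat": "" if lat is None else lat,
                "lon": "" if lon is None else lon,
                "ff": arch.ff,
                "fc": arch.fc,
                "phi": arch.phi,
                "lai": arch.lai,
                "omega0": arch.omega0,
                "lai_e": arch.lai_e,
                "k": settings.k,
                "grid": f"{settings.grid_rows}x{settings.grid_cols}",
                "threshold": settings.big_gap_threshold,
            }
        )


# ---------------------------------------------------------------------------
# sklearn-style wrapper

from sklearn.base import BaseEstimator, TransformerMixin


class GapAnalyzer(BaseEstimator, TransformerMixin):
    """Stateless transformer: sequence of masks -> (n, 6) feature matrix.

    Column order matches :data:`FEATURE_NAMES` (lai, lai_e, ff, fc, phi,
    omega0), the input layout of the aroma network.  Composes with sklearn
    pipelines; ``fit`` is a no-op.
    """

    def __init__(
        self,
        grid_rows: int = 5,
        grid_cols: int = 5,
        big_gap_threshold: float = 0.75,
        k: float = 0.7,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.big_gap_threshold = big_gap_threshold
        self.k = k

    def _settings(self) -> AnalysisSettings:
        return AnalysisSettings(
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            big_gap_threshold=self.big_gap_threshold,
            k=self.k,
        )

    def fit(self, X: Sequence[BinaryCanopyMask], y=None):
        self.n_features_out_ = 6
        return self

    def transform(self, X: Sequence[BinaryCanopyMask]) -> np.ndarray:
        settings = self._settings()
        return np.array(
            [analyze_mask(m, settings).as_feature_vector() for m in X]
        )
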