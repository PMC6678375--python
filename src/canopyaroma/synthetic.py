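"""Synthetic scenes and datasets with known ground truth.

Every stage of the pipeline is testable without field data:

* ``gen_canopy_mask`` draws binary canopy masks whose true LAI is known by
  construction — random (Boolean per-pixel) dispersion follows Beer's law
  exactly in expectation, while clumped mode concentrates the same gap
  budget into discs so large-gap cells appear and the clumping index
  drops below 1.
* ``gen_plantation_scene`` renders an aerial RGB mosaic of green crowns on
  a brown inter-row on a regular planting grid, with chosen positions left
  empty (missing trees).
* ``gen_aroma_dataset`` draws canopy feature vectors over the observed
  field ranges and maps them through a fixed 6->6 teacher network plus
  Gaussian noise, returning the noiseless oracle predictions alongside.

The per-tree canopy summary of the 24 field-sampled trees ships as a
packaged CSV, loaded with :func:`load_tree_summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from .aerial import BlockLayout
from .gap import BinaryCanopyMask

__all__ = [
    "CanopySpec",
    "TeacherMapping",
    "gen_canopy_mask",
    "gen_plantation_scene",
    "gen_aroma_dataset",
    "load_tree_summary",
    "FEATURE_RANGES",
]

#: Observed field ranges of the six canopy features (min, max), used to
#: draw realistic synthetic feature vectors.
FEATURE_RANGES = {
    "lai": (2.30, 4.56),
    "lai_e": (2.12, 4.08),
    "ff": (0.668, 0.939),
    "fc": (0.775, 0.994),
    "phi": (0.056, 0.188),
    "omega0": (0.723, 0.986),
}

CROWN_RGB = np.array([58, 122, 40], dtype=float)
SOIL_RGB = np.array([150, 112, 80], dtype=float)
SKY_RGB = np.array([170, 205, 240], dtype=float)


@dataclass(frozen=True)
class CanopySpec:
    """Recipe for one synthetic canopy mask."""

    true_lai: float = 3.0
    k: float = 0.7
    dispersion: Literal["random", "clumped"] = "random"
    clump_count: int = 3
    clump_scale: float = 1.0  # disc radius multiplier
    clump_grid: int = 5  # discs are anchored at cell centres of this grid
    size: tuple[int, int] = (1000, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_lai < 0:
            raise ValueError("true_lai must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @property
    def gap_probability(self) -> float:
        return float(np.exp(-self.k * self.true_lai))


def gen_canopy_mask(spec: CanopySpec) -> tuple[BinaryCanopyMask, dict]:
    """Draw a binary canopy mask with the gap fraction set by Beer's law.

    Random mode: each pixel is independently a gap with probability
    ``exp(-k * true_lai)``; crown cover is 1 in expectation and the
    clumping index is ~1.  Clumped mode: the same expected number of gap
    pixels is concentrated into ``clump_count`` discs (grown or trimmed
    pixel-by-pixel to hit the budget exactly), so large-gap cells exist
    and the clumping index falls below 1.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    p_gap = spec.gap_probability
    if spec.true_lai == 0:
        mask = np.zeros((h, w), dtype=bool)
        return (
            BinaryCanopyMask(mask, source_id="synthetic"),
            {"true_lai": 0.0, "gap_fraction": 1.0, "spec": spec},
        )
    if spec.dispersion == "random":
        foliage = rng.random((h, w)) >= p_gap
    else:
        n_gap_target = int(round(p_gap * h * w))
        if spec.clump_count < 1:
            raise ValueError("clumped mode needs clump_count >= 1")
        if spec.clump_count > spec.clump_grid**2:
            raise ValueError("infeasible clump geometry: more discs than grid cells")
        radius = spec.clump_scale * np.sqrt(n_gap_target / (np.pi * spec.clump_count))
        if radius >= min(h, w) / 2:
            raise ValueError(
                "infeasible clump geometry: disc radius exceeds half the image"
            )
        # discs centred on distinct analysis-grid cells, so the gap budget
        # concentrates into between-crown gaps rather than within-crown speckle
        m = spec.clump_grid
        cells = rng.choice(m * m, size=spec.clump_count, replace=False)
        gaps = np.zeros((h, w), dtype=bool)
        yy, xx = np.mgrid[0:h, 0:w]
        for c in cells:
            cy = (c // m + 0.5) * h / m
            cx = (c % m + 0.5) * w / m
            gaps |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        # adjust to the exact gap budget
        n_gap = int(gaps.sum())
        if n_gap > n_gap_target:
            on = np.flatnonzero(gaps.ravel())
            off = rng.choice(on, size=n_gap - n_gap_target, replace=False)
            gaps.ravel()[off] = False
        elif n_gap < n_gap_target:
            candidates = np.flatnonzero(~gaps.ravel())
            add = rng.choice(candidates, size=n_gap_target - n_gap, replace=False)
            gaps.ravel()[add] = True
        foliage = ~gaps
    mask = BinaryCanopyMask(foliage, source_id=f"synthetic_{spec.dispersion}")
    truth = {
        "true_lai": spec.true_lai,
        "k": spec.k,
        "gap_fraction": float(1.0 - foliage.mean()),
        "expected_gap_fraction": p_gap,
        "spec": spec,
    }
    return mask, truth


def _local_corners(
    n_rows: int, n_cols: int, tree_spacing: float, row_spacing: float,
    lat0: float = -17.8206, lon0: float = 146.0392,
) -> tuple[tuple[float, float], ...]:
    """Corner GPS pairs for a block anchored at (lat0, lon0)."""
    m_per_deg_lat = 111_320.0
    m_per_deg_lon = 111_320.0 * np.cos(np.deg2rad(lat0))
    dlat = float(n_rows * tree_spacing / m_per_deg_lat)
    dlon = float(n_cols * row_spacing / m_per_deg_lon)
    return (
        (lat0, lon0),
        (lat0, lon0 + dlon),
        (lat0 - dlat, lon0),
        (lat0 - dlat, lon0 + dlon),
    )


def gen_plantation_scene(
    n_rows: int,
    n_cols: int,
    cover: np.ndarray | float = 0.6,
    missing: set[tuple[int, int]] | None = None,
    pixel_scale: float = 0.1,
    tree_spacing: float = 2.0,
    row_spacing: float = 5.0,
    seed: int = 0,
    noise: float = 6.0,
) -> tuple[np.ndarray, BlockLayout, dict]:
    """Render an aerial mosaic of a planting grid with known per-tree cover.

    ``cover`` is the target foliage fraction per cell (scalar or
    ``(n_rows, n_cols)`` array); positions in ``missing`` are rendered as
    bare inter-row.  Crowns are ellipses sized to the target cover placed
    at each cell centre.  Returns the RGB image (uint8), the block layout
    (corner GPS anchored at the study site) and a ground-truth dict.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must be at least 1x1")
    missing = missing or set()
    rng = np.random.default_rng(seed)
    cover_arr = np.broadcast_to(np.asarray(cover, dtype=float), (n_rows, n_cols)).copy()
    cell_h = max(2, int(round(tree_spacing / pixel_scale)))
    cell_w = max(2, int(round(row_spacing / pixel_scale)))
    H, W = n_rows * cell_h, n_cols * cell_w
    img = SOIL_RGB + rng.normal(0, noise, size=(H, W, 3))
    yy, xx = np.mgrid[0:cell_h, 0:cell_w]
    crown_fraction = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if (i, j) in missing:
                crown_fraction[(i, j)] = 0.0
                continue
            target = int(round(cover_arr[i, j] * cell_h * cell_w))
            # central ellipse sized to the target area (pi/4 correction),
            # then adjusted pixel-by-pixel to hit the count exactly
            s = min(1.0, np.sqrt(4.0 * cover_arr[i, j] / np.pi))
            ry, rx = max(s * cell_h / 2, 1.0), max(s * cell_w / 2, 1.0)
            inside = ((yy - cell_h / 2 + 0.5) / ry) ** 2 + (
                (xx - cell_w / 2 + 0.5) / rx
            ) ** 2 <= 1.0
            n_in = int(inside.sum())
            if n_in > target:
                on = np.flatnonzero(inside.ravel())
                inside.ravel()[rng.choice(on, size=n_in - target, replace=False)] = False
            elif n_in < target:
                off = np.flatnonzero(~inside.ravel())
                inside.ravel()[rng.choice(off, size=target - n_in, replace=False)] = True
            tile = img[i * cell_h : (i + 1) * cell_h, j * cell_w : (j + 1) * cell_w]
            crown = CROWN_RGB + rng.normal(0, noise, size=(cell_h, cell_w, 3))
            tile[inside] = crown[inside]
            crown_fraction[(i, j)] = float(inside.mean())
    img = np.clip(img, 0, 255).astype(np.uint8)
    layout = BlockLayout(
        corner_gps=_local_corners(n_rows, n_cols, tree_spacing, row_spacing),
        pixel_scale=pixel_scale,
        block_pixel_bounds=(0, 0, H, W),
        row_spacing=row_spacing,
        tree_spacing=tree_spacing,
    )
    truth = {
        "n_rows": n_rows,
        "n_cols": n_cols,
        "cover": cover_arr,
        "missing": set(missing),
        "crown_fraction": crown_fraction,
    }
    return img, layout, truth


@dataclass(frozen=True)
class TeacherMapping:
    """Fixed 6->6 canopy-to-aroma teacher with optional smooth nonlinearity.

    Features are affinely mapped to [-1, 1] over :data:`FEATURE_RANGES`,
    passed through a seeded random linear map (optionally squashed by
    ``tanh``), and rescaled into the GC peak-area window [0, 60e3].
    ``noise_sd`` is the per-output Gaussian noise in area units.
    """

    seed: int = 7
    nonlinear: bool = True
    gain: float = 1.2
    #: default calibrated so the noiseless teacher correlates with the noisy
    #: targets at roughly R = 0.85, the realistic canopy-to-aroma regime
    noise_sd: tuple[float, ...] | float = 10_000.0
    scale: tuple[float, float] = (0.0, 60_000.0)

    def _weights(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        W = rng.normal(0, 1, size=(6, 6))
        return W / np.linalg.norm(W, axis=1, keepdims=True)

    def _normalize_features(self, X: np.ndarray) -> np.ndarray:
        lo = np.array([FEATURE_RANGES[k][0] for k in FEATURE_RANGES])
        hi = np.array([FEATURE_RANGES[k][1] for k in FEATURE_RANGES])
        return 2.0 * (X - lo) / (hi - lo) - 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Noiseless teacher outputs (the oracle predictions)."""
        Xn = self._normalize_features(np.asarray(X, dtype=float))
        lin = Xn @ self._weights().T * self.gain
        out = np.tanh(lin) if self.nonlinear else np.clip(lin, -1.0, 1.0)
        lo, hi = self.scale
        return (out + 1.0) / 2.0 * (hi - lo) + lo


def gen_aroma_dataset(
    n_samples: int,
    teacher: TeacherMapping | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw canopy features, teacher aromas with noise, and the oracle.

    Features are internally consistent: crown cover, porosity, LAI and
    clumping index are drawn over the observed field ranges, then foliage
    cover and effective LAI are derived from the identities
    ``ff = fc (1 - phi)`` and ``lai_e = lai * omega0``.  Returns
    ``(features, noisy_targets, oracle_targets)`` with the feature column
    order (lai, lai_e, ff, fc, phi, omega0).
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    teacher = teacher or TeacherMapping()
    rng = np.random.default_rng(seed)
    lai = rng.uniform(*FEATURE_RANGES["lai"], n_samples)
    fc = rng.uniform(*FEATURE_RANGES["fc"], n_samples)
    phi = rng.uniform(*FEATURE_RANGES["phi"], n_samples)
    omega0 = rng.uniform(*FEATURE_RANGES["omega0"], n_samples)
    ff = fc * (1.0 - phi)
    lai_e = lai * omega0
    X = np.column_stack([lai, lai_e, ff, fc, phi, omega0])
    oracle = teacher.predict(X)
    sd = np.broadcast_to(np.asarray(teacher.noise_sd, dtype=float), (6,))
    y = oracle + rng.normal(0, 1, size=oracle.shape) * sd
    y = np.clip(y, teacher.scale[0], None)
    return X, y, oracle


def load_tree_summary() -> pd.DataFrame:
    """Per-tree canopy means/SD of the 24 field-sampled trees (packaged CSV)."""
    with resources.files("canopyaroma.data").joinpath(
        "tree_canopy_summary.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["block"] = [int(s[1]) for s in df["sample"]]
    return df
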