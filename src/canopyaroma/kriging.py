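"""Spatial mapping: semivariogram fitting, ordinary kriging, scatter layers.

Per-tree values (effective LAI or predicted aroma areas) become either a
scattered tree-by-tree layer or a continuous surface interpolated by
ordinary kriging.  The semivariogram is estimated from distance-binned
squared differences and fitted by weighted least squares with a spherical,
exponential or Gaussian model.  Ordinary kriging solves, for each target
location, the constrained system

    | Gamma  1 | | lambda |   | gamma_0 |
    | 1'     0 | |   mu   | = |    1    |

so the weights sum to 1 (unbiasedness) and the surface honours the data
exactly when the nugget is zero.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ScatterLayer",
    "VariogramModel",
    "RasterMap",
    "fit_variogram",
    "OrdinaryKriging",
    "krige_surface",
    "scatter_layer",
    "LAI_E_SCALE",
    "AROMA_SCALE",
]

Family = Literal["spherical", "exponential", "gaussian"]

#: Fixed rendering scales: effective LAI 0-6, aroma peak areas 0-60e3.
LAI_E_SCALE = (0.0, 6.0)
AROMA_SCALE = (0.0, 60_000.0)


@dataclass
class ScatterLayer:
    """Per-tree point values for one variable with its fixed colour scale."""

    coords: np.ndarray  # (n, 2) x/y or lon/lat
    values: np.ndarray  # (n,)
    variable: str
    scale: tuple[float, float] = LAI_E_SCALE

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape[0] != self.values.shape[0]:
            raise ValueError("coords and values must align")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.scale[0] >= self.scale[1]:
            raise ValueError("scale bounds must satisfy min < max")

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", self.variable])
            for (x, y), v in zip(self.coords, self.values):
                w.writerow([x, y, v])


@dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) rises from nugget to sill over range."""

    family: Family
    nugget: float
    sill: float  # total sill (nugget + partial sill)
    range_: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError("invalid variogram parameters")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.sill - self.nugget
        a = self.range_
        if self.family == "spherical":
            hr = np.minimum(h / a, 1.0)
            struct = c * (1.5 * hr - 0.5 * hr**3)
        elif self.family == "exponential":
            struct = c * (1.0 - np.exp(-3.0 * h / a))
        else:
            struct = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        return np.where(h > 0, self.nugget + struct, 0.0)


@dataclass
class RasterMap:
    """Regular grid of interpolated values with a simple geotransform."""

    values: np.ndarray  # (ny, nx), NaN = no data
    origin: tuple[float, float]  # (x0, y0) of the lower-left cell centre
    cell_size: float
    variable: str

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.values.shape[1]) * self.cell_size

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.values.shape[0]) * self.cell_size

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))

    def to_png(self, path: str | Path, scale: tuple[float, float] | None = None) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        vmin, vmax = scale if scale else (np.nanmin(self.values), np.nanmax(self.values))
        im = ax.imshow(self.values, origin="lower", vmin=vmin, vmax=vmax, cmap="viridis")
        fig.colorbar(im, ax=ax, label=self.variable)
        ax.set_title(self.variable)
        fig.savefig(path, dpi=100)
        plt.close(fig)


def _empirical_variogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 12, max_lag: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    lags = d[iu]
    semiv = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_lag is None:
        max_lag = 0.5 * lags.max()
    keep = (lags > 0) & (lags <= max_lag)
    lags, semiv = lags[keep], semiv[keep]
    edges = np.linspace(0, max_lag, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (lags > lo) & (lags <= hi)
        if sel.sum() > 0:
            centers.append(lags[sel].mean())
            gammas.append(semiv[sel].mean())
            counts.append(int(sel.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    layer: ScatterLayer,
    family: Family = "spherical",
    n_bins: int = 12,
    max_lag: float | None = None,
) -> VariogramModel:
    """Weighted least-squares fit of a variogram family to the empirical cloud.

    Bins are weighted by their pair counts.  Requires at least 5 points and
    at least two distinct locations.
    """
    if layer.coords.shape[0] < 5:
        raise ValueError("need at least 5 points to fit a variogram")
    d = cdist(layer.coords, layer.coords)
    if d.max() == 0:
        raise ValueError("all points share one location")
    centers, gammas, counts = _empirical_variogram(
        layer.coords, layer.values, n_bins=n_bins, max_lag=max_lag
    )
    if len(centers) < 3:
        centers, gammas, counts = _empirical_variogram(
            layer.coords, layer.values, n_bins=max(3, len(centers)), max_lag=d.max()
        )
    var = float(np.var(layer.values))
    if var == 0 or np.all(gammas == 0):
        return VariogramModel(family=family, nugget=0.0, sill=0.0 + 1e-12, range_=float(centers.max() or 1.0))
    w = np.sqrt(counts)

    def resid(p):
        nugget, psill, rng = p
        model = VariogramModel(family, max(nugget, 0.0), max(nugget, 0.0) + max(psill, 1e-12), max(rng, 1e-9))
        return w * (model(centers) - gammas)

    p0 = np.array([0.0, max(var, 1e-9), float(centers.max()) * 0.5])
    sol = least_squares(
        resid, p0,
        bounds=([0.0, 1e-12, 1e-9], [var * 2 + 1e-9, var * 10 + 1e-6, float(centers.max()) * 10]),
    )
    nugget, psill, rng = sol.x
    return VariogramModel(family=family, nugget=float(nugget), sill=float(nugget + psill), range_=float(rng))


class OrdinaryKriging(BaseEstimator, RegressorMixin):
    """Ordinary kriging interpolator with a fitted or supplied variogram.

    ``fit(coords, values)`` stores the data and (unless a ``variogram`` is
    given) fits one; ``predict(coords)`` solves the ordinary-kriging system
    per target point.  ``predict(..., return_weights=True)`` also returns
    the weight matrix so the unit-sum constraint can be checked.
    """

    def __init__(
        self,
        family: Family = "spherical",
        variogram: VariogramModel | None = None,
        jitter: float = 1e-10,
    ):
        self.family = family
        self.variogram = variogram
        self.jitter = jitter

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self.coords_ = X
        self.values_ = y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            self.variogram_ = fit_variogram(
                ScatterLayer(coords=X, values=y, variable="y", scale=(float(y.min()) - 1, float(y.max()) + 1))
            )
        n = X.shape[0]
        gamma_mat = self.variogram_(cdist(X, X))
        lhs = np.empty((n + 1, n + 1))
        lhs[:n, :n] = gamma_mat
        lhs[:n, n] = 1.0
        lhs[n, :n] = 1.0
        lhs[n, n] = 0.0
        self._lhs = lhs
        return self

    def _solve(self, rhs: np.ndarray) -> np.ndarray:
        lhs = self._lhs
        try:
            return np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system: jittering the diagonal", stacklevel=2)
            n = lhs.shape[0] - 1
            lhs = lhs.copy()
            lhs[:n, :n] += self.jitter * np.eye(n)
            return np.linalg.solve(lhs, rhs)

    def predict(self, X, return_weights: bool = False):
        check_is_fitted(self, "coords_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = self.coords_.shape[0]
        rhs = np.empty((n + 1, X.shape[0]))
        rhs[:n] = self.variogram_(cdist(self.coords_, X))
        rhs[n] = 1.0
        sol = self._solve(rhs)
        weights = sol[:n]
        pred = weights.T @ self.values_
        if return_weights:
            return pred, weights.T
        return pred


def krige_surface(
    layer: ScatterLayer,
    variogram: VariogramModel | None = None,
    cell_size: float = 0.5,
    clamp: bool = True,
) -> RasterMap:
    """Ordinary-kriged raster over the layer's bounding box (one-cell pad).

    Values are clamped to the layer's scale bounds when ``clamp`` is set.
    """
    ok = OrdinaryKriging(variogram=variogram).fit(layer.coords, layer.values)
    x0, y0 = layer.coords.min(axis=0) - cell_size
    x1, y1 = layer.coords.max(axis=0) + cell_size
    xs = np.arange(x0, x1 + cell_size / 2, cell_size)
    ys = np.arange(y0, y1 + cell_size / 2, cell_size)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = ok.predict(pts).reshape(gy.shape)
    if clamp:
        vals = np.clip(vals, layer.scale[0], layer.scale[1])
    return RasterMap(values=vals, origin=(float(xs[0]), float(ys[0])), cell_size=cell_size, variable=layer.variable)


def scatter_layer(
    matrix,
    variable: str,
    include_missing_as_zero: bool | None = None,
    use_latlon: bool = False,
) -> ScatterLayer:
    """Build a per-tree scatter layer from a plantation matrix.

    ``matrix`` is a plantation matrix or an equivalent DataFrame (columns
    ``row``, ``col``, ``missing``, plus the variable, e.g. with aroma
    predictions appended).  Missing trees enter as value 0 for
    effective-LAI maps (an unplanted position genuinely has zero canopy)
    and are excluded for aroma maps (no bean sample exists there); override
    with ``include_missing_as_zero``.
    """
    import pandas as pd

    df = matrix if isinstance(matrix, pd.DataFrame) else matrix.to_frame()
    is_arch = variable in {"lai", "lai_e", "ff", "fc", "phi", "omega0"}
    if include_missing_as_zero is None:
        include_missing_as_zero = variable == "lai_e"
    if use_latlon:
        coords = df[["lon", "lat"]].to_numpy(dtype=float)
    else:
        # field-frame metres from grid indices and spacing
        layout = getattr(matrix, "layout", None)
        ts = layout.tree_spacing if layout else 2.0
        rs = layout.row_spacing if layout else 5.0
        coords = np.column_stack(
            [(df["col"] + 0.5) * rs, (df["row"] + 0.5) * ts]
        )
    if variable in df.columns:
        vals = df[variable].to_numpy(dtype=float)
    else:
        raise KeyError(f"unknown variable {variable!r}")
    missing = df["missing"].to_numpy(dtype=bool)
    if include_missing_as_zero:
        vals = np.where(missing, 0.0, vals)
    else:
        coords, vals = coords[~missing], vals[~missing]
    scale = LAI_E_SCALE if is_arch else AROMA_SCALE
    if variable == "lai_e" or is_arch:
        scale = LAI_E_SCALE if variable in {"lai", "lai_e"} else (0.0, 1.0)
    return ScatterLayer(coords=coords, values=vals, variable=variable, scale=scale)
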