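"""End-to-end orchestration: aerial image -> per-tree canopy -> aromas -> maps."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .aerial import BlockLayout, analyze_plantation
from .ann import AROMA_NAMES, BayesRegNetRegressor, predict_aromas
from .gap import AnalysisSettings
from .kriging import AROMA_SCALE, LAI_E_SCALE, fit_variogram, krige_surface, scatter_layer

__all__ = ["PipelineConfig", "run_end_to_end", "layout_from_config"]

log = logging.getLogger("canopyaroma")

DEFAULT_CONFIG = {
    "grid_rows": 5,
    "grid_cols": 5,
    "big_gap_threshold": 0.75,
    "k": 0.7,
    "missing_threshold": 0.1,
    "variogram_family": "spherical",
    "cell_size": 0.5,
    "seed": 0,
    "hidden_sizes": [3, 5, 7, 10],
    "map_variables": ["lai_e"] + AROMA_NAMES,
}


class PipelineConfig(dict):
    """Validated flat config: defaults are the field-study settings."""

    def __init__(self, overrides: dict | None = None):
        super().__init__(DEFAULT_CONFIG)
        for key, value in (overrides or {}).items():
            if key not in DEFAULT_CONFIG and key != "layout":
                raise KeyError(f"unknown config key: {key}")
            self[key] = value

    @property
    def settings(self) -> AnalysisSettings:
        return AnalysisSettings(
            grid_rows=self["grid_rows"],
            grid_cols=self["grid_cols"],
            big_gap_threshold=self["big_gap_threshold"],
            k=self["k"],
        )

    def digest(self) -> str:
        body = json.dumps(
            {k: v for k, v in self.items() if k != "layout"}, sort_keys=True, default=str
        )
        return hashlib.sha256(body.encode()).hexdigest()[:12]


def layout_from_config(cfg: dict) -> BlockLayout:
    lay = cfg["layout"]
    return BlockLayout(
        corner_gps=tuple(tuple(c) for c in lay["corner_gps"]),
        pixel_scale=float(lay["pixel_scale"]),
        block_pixel_bounds=tuple(int(v) for v in lay["block_pixel_bounds"]),
        row_spacing=float(lay.get("row_spacing", 5.0)),
        tree_spacing=float(lay.get("tree_spacing", 2.0)),
    )


def run_end_to_end(
    config: PipelineConfig,
    image: np.ndarray,
    layout: BlockLayout,
    model: BayesRegNetRegressor,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Partition -> segment -> gap-analyze -> predict aromas -> map.

    Writes the per-tree CSV, a kriged raster (CSV + PNG) and a scatter CSV
    per mapped variable, and a provenance log; returns the per-tree frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "partition/assess"
    try:
        matrix = analyze_plantation(
            image, layout, config.settings, missing_threshold=config["missing_threshold"]
        )
        df = matrix.to_frame()
        stage = "predict"
        feats = df[["lai", "lai_e", "ff", "fc", "phi", "omega0"]].to_numpy(float)
        aromas = predict_aromas(model, feats)
        for name, col in zip(AROMA_NAMES, aromas.T):
            df[name] = col
        df.loc[df["missing"], AROMA_NAMES] = np.nan
        df.to_csv(out_dir / "per_tree.csv", index=False)
        stage = "map"
        df_map = df.copy()
        for var in config["map_variables"]:
            layer = scatter_layer(_with_layout(df_map, matrix), var)
            layer.to_csv(out_dir / f"scatter_{var}.csv")
            vg = fit_variogram(layer, family=config["variogram_family"])
            surface = krige_surface(layer, vg, cell_size=config["cell_size"])
            surface.to_csv(out_dir / f"kriged_{var}.csv")
            scale = LAI_E_SCALE if var == "lai_e" else AROMA_SCALE
            surface.to_png(out_dir / f"kriged_{var}.png", scale=scale)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out_dir / "run_log.json").write_text(
        json.dumps(
            {
                "config_digest": config.digest(),
                "seed": config["seed"],
                "n_rows": matrix.n_rows,
                "n_cols": matrix.n_cols,
                "n_missing": int(df["missing"].sum()),
                "variables_mapped": list(config["map_variables"]),
            },
            indent=2,
        )
    )
    log.info("pipeline complete: %d cells, %d missing", len(df), int(df["missing"].sum()))
    return df


class _FrameWithLayout(pd.DataFrame):
    _metadata = ["layout"]


def _with_layout(df: pd.DataFrame, matrix) -> pd.DataFrame:
    out = _FrameWithLayout(df)
    out.layout = matrix.layout
    return out
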