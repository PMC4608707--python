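"""Readers and writers: ASCII-grid rasters, WKT polylines, survival CSVs.

Rasters travel as ESRI ASCII grid text (plain-text, GIS-readable); vector
lines as one WKT geometry per line; tables as comma-separated UTF-8 CSV with
a header row and '.' decimal.  Dates are ISO-8601 where calendar dates
appear; internally time is day-of-year on a non-leap calendar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from .landscape import CategoricalRaster

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_wkt_lines",
    "read_wkt_lines",
    "read_survival_csv",
    "SEASONAL_SCHEMA",
    "DAILY_SCHEMA",
    "PipelineConfig",
]


def write_ascii_grid(path, values: np.ndarray, origin=(0.0, 0.0),
                     cell_size: float = 30.0, nodata: float = -9999) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 of the file = north)."""
    values = np.asarray(values)
    nr, nc = values.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\nxllcorner {origin[0]}\n"
                 f"yllcorner {origin[1]}\ncellsize {cell_size}\n"
                 f"NODATA_value {nodata}\n")
        for row in values[::-1]:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> CategoricalRaster:
    """Read an ESRI ASCII grid as a categorical raster (band 1 = class code)."""
    header: dict[str, float] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.asarray(rows)[::-1]
    return CategoricalRaster(
        values.astype(int),
        (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        header.get("cellsize", 30.0),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def write_wkt_lines(path, lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for geom in lines:
            fh.write(geom.wkt + "\n")


def read_wkt_lines(path) -> list:
    with open(path, encoding="utf-8") as fh:
        return [shapely_wkt.loads(line) for line in fh if line.strip()]


#: Default header mappings for study-style survival CSVs (seasonal: one row
#: per fawn; daily: one counting-process row per interval).
SEASONAL_SCHEMA = {
    "fawn_id": "fawn_id", "year": "year", "start": "start", "stop": "stop",
    "event": "event",
}
DAILY_SCHEMA = dict(SEASONAL_SCHEMA)


def read_survival_csv(
    path,
    schema: dict[str, str] | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a survival-interval CSV.

    ``schema`` maps the canonical column names (fawn_id, year, start, stop,
    event) to the file's headers.  Rows failing validation (stop <= start,
    event not in {0,1}, missing values in mapped columns) are dropped and
    reported in ``result.attrs['rejected']`` as (line number, reason) pairs;
    line numbers are 1-based including the header.
    """
    schema = dict(SEASONAL_SCHEMA if schema is None else schema)
    raw = pd.read_csv(path)
    missing = [src for src in schema.values() if src not in raw.columns]
    if missing:
        raise KeyError(f"mapped column(s) missing from {path}: {missing}")
    df = raw.rename(columns={v: k for k, v in schema.items()})
    keep_cols = list(schema) + [c for c in (covariates or []) if c in df.columns]
    df = df[keep_cols]

    rejected = []
    ok = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        line = i + 2
        if row[list(schema)].isna().any():
            rejected.append((line, "missing value"))
        elif not (float(row["start"]) < float(row["stop"])):
            rejected.append((line, "stop <= start"))
        elif int(row["event"]) not in (0, 1):
            rejected.append((line, "event not 0/1"))
        else:
            continue
        ok[df.index.get_loc(i)] = False
    out = df[ok].reset_index(drop=True)
    out["event"] = out["event"].astype(int)
    out.attrs["rejected"] = rejected
    return out


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (defaults mirror the study design)."""

    out_dir: str = "fawnscape_out"
    seed: int = 1
    cell_area_m2: float = 2115.0
    vif_threshold: float = 7.0
    alpha: float = 0.05
    n_fawns_per_year: tuple[int, ...] = (42, 35, 47)
    years: tuple[int, ...] = (2009, 2010, 2011)
    severity_levels: tuple[str, ...] = ("severe", "mild", "moderate")
    landscape_size: int = 100
    locs_per_fawn: tuple[int, int] = (8, 40)  # sampling range; study range 2-89
    seasonal_stat: str = "mean"

    def validate(self) -> None:
        if self.cell_area_m2 <= 0 or self.vif_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("thresholds must be positive (alpha in (0,1))")
        if len(self.n_fawns_per_year) != len(self.years):
            raise ValueError("n_fawns_per_year must match years")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        cfg.validate()
        return cfg
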