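"""Minimal georeferenced raster container used across the pipeline.

All layers in an analysis share one grid: pixel-is-area, origin at the
top-left corner, row-major storage (row 0 is the northernmost row).
Values are stored in the layer's native unit (carried as metadata); an
optional grid of per-pixel *relative* standard deviations rides along so
uncertainty can be propagated through the attribution algebra.

I/O is deliberately plain-text: ESRI ASCII grids for rasters (readable by
GDAL and the R ``raster`` package) and GeoJSON for vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA = -9999.0

#: default CRS label — UTM zone 37N, a projected metric system covering Kenya
DEFAULT_CRS = "EPSG:32637"

_GEOGRAPHIC_LABELS = {"EPSG:4326", "WGS84", "CRS84"}


def crs_is_projected(crs: str) -> bool:
    """Heuristic projected/geographic split on the CRS label.

    Anything in the well-known geographic set is geographic; everything
    else is taken as projected with metre units.
    """
    return crs.upper().replace(" ", "") not in _GEOGRAPHIC_LABELS


@dataclass
class GridSpec:
    """Shared georeference: origin (top-left corner), square pixel size."""

    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 1000.0  # metres; 1 km -> 100 ha pixels
    crs: str = DEFAULT_CRS

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size * self.pixel_size / 1e4

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates for every pixel, row-major."""
        rows, cols = shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


@dataclass
class RasterLayer:
    """A single-band raster with optional per-pixel relative SD.

    Parameters
    ----------
    values
        2-D float array; ``nodata`` marks invalid pixels.
    rel_sd
        Relative standard deviation (unitless, >= 0) on the same grid, or
        None when the layer carries no uncertainty.
    units
        Free-text unit label, e.g. ``"kg C ha-1 yr-1"``.
    """

    values: np.ndarray
    rel_sd: np.ndarray | None = None
    units: str = ""
    nodata: float = NODATA
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.rel_sd is not None:
            self.rel_sd = np.asarray(self.rel_sd, dtype=float)
            if self.rel_sd.shape != self.values.shape:
                raise ValueError("rel_sd grid must match values grid shape")
            bad = (self.rel_sd < 0) & self.valid_mask
            if np.any(bad):
                raise ValueError("rel_sd must be >= 0 on valid pixels")

    # -- basic queries -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    @property
    def sd(self) -> np.ndarray | None:
        """Absolute per-pixel SD (|value| × rel_sd); nodata where invalid."""
        if self.rel_sd is None:
            return None
        out = np.full(self.shape, self.nodata)
        m = self.valid_mask
        out[m] = np.abs(self.values[m]) * self.rel_sd[m]
        return out

    def copy(self, **changes) -> "RasterLayer":
        new = replace(self, **changes)
        if "values" not in changes:
            new.values = self.values.copy()
        if "rel_sd" not in changes and self.rel_sd is not None:
            new.rel_sd = self.rel_sd.copy()
        return new

    def with_values(self, values: np.ndarray, units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            values=np.asarray(values, dtype=float),
            rel_sd=None if self.rel_sd is None else self.rel_sd.copy(),
            units=self.units if units is None else units,
            nodata=self.nodata,
            grid=self.grid,
        )

    def require_same_grid(self, other: "RasterLayer", what: str = "layers") -> None:
        if self.shape != other.shape:
            raise ValueError(
                f"{what} are not co-registered: shapes {self.shape} vs {other.shape}"
            )
        if self.grid.pixel_size != other.grid.pixel_size or self.grid.crs != other.grid.crs:
            raise ValueError(f"{what} are not co-registered: differing grid spec")

    # -- summaries -----------------------------------------------------
    def area_weighted_total(self) -> float:
        """Σ value × pixel area (ha) over valid pixels, in value-unit × ha."""
        return float(self.valid_values().sum() * self.grid.pixel_area_ha)

    def total_co2eq_mg(self) -> float:
        """Study-area total in Mg CO2eq yr-1 for a kg C ha-1 yr-1 layer.

        Applies the 44/12 C→CO2 molar conversion at reporting time only.
        """
        return self.area_weighted_total() * (44.0 / 12.0) / 1000.0

    # -- text I/O ------------------------------------------------------
    def to_ascii(self, path) -> None:
        """Write an ESRI ASCII grid (text, GDAL/R-compatible)."""
        rows, cols = self.shape
        header = (
            f"ncols {cols}\n"
            f"nrows {rows}\n"
            f"xllcorner {self.grid.x_origin}\n"
            f"yllcorner {self.grid.y_origin - rows * self.grid.pixel_size}\n"
            f"cellsize {self.grid.pixel_size}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def from_ascii(cls, path, units: str = "", crs: str = DEFAULT_CRS) -> "RasterLayer":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        grid = GridSpec(
            x_origin=meta["xllcorner"],
            y_origin=meta["yllcorner"] + meta["nrows"] * meta["cellsize"],
            pixel_size=meta["cellsize"],
            crs=crs,
        )
        return cls(values=values, units=units, nodata=meta.get("nodata_value", NODATA), grid=grid)


def boolean_layer(mask: np.ndarray, grid: GridSpec) -> RasterLayer:
    """Wrap a boolean mask as a 0/1 raster layer."""
    return RasterLayer(values=np.asarray(mask, dtype=float), units="bool", grid=grid)
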