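"""Attribution of forest carbon loss to dairy-cattle grazing.

Starting from a net forest C loss raster, the pipeline (i) restricts to
natural forest (forest mask minus plantations), (ii) excludes burnt
pixels — fire losses cannot be attributed to cattle and are dropped from
both numerator and area, (iii) subtracts the nonrenewable-biomass (NRB)
fuelwood component, clamped at zero where fuelwood exceeds net loss, and
(iv) scales by each county's dairy proportion of the cattle herd. The
variance of the attributed loss combines the input variances as

    var(loss_cattle) = var(net_loss) + var(NRB) − 2·cov(net_loss, NRB)

with cov defaulting to 0 (configurable). All rasters stay in
kg C ha⁻¹ yr⁻¹; the 44/12 C→CO2 conversion is applied only in reported
study-area totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .raster import RasterLayer, boolean_layer


@dataclass
class AttributionResult:
    """Dairy-attributed forest C loss, its variance, and net forest C change."""

    c_loss_cattle: RasterLayer  # kg C ha-1 yr-1, nodata outside natural forest
    c_change_cattle: RasterLayer  # forest C gain minus attributed loss
    var_c_loss_cattle: RasterLayer  # (kg C ha-1 yr-1)^2

    def summary(self) -> dict[str, float]:
        """Study-area totals in Mg CO2eq yr-1 plus per-ha mean and SD."""
        loss = self.c_loss_cattle
        valid = loss.valid_mask
        total = loss.total_co2eq_mg()
        mean = float(loss.valid_values().mean()) if valid.any() else 0.0
        var = self.var_c_loss_cattle.values[valid]
        # SD of the total: independent pixels, Σ var × (area × 44/12 / 1000)^2
        scale = loss.grid.pixel_area_ha * (44.0 / 12.0) / 1000.0
        sd_total = float(np.sqrt(np.sum(var)) * scale)
        return {
            "total_mg_co2eq": total,
            "mean_kg_c_ha": mean,
            "sd_total_mg_co2eq": sd_total,
            "n_pixels": int(valid.sum()),
        }


def _as_mask(layer: RasterLayer | np.ndarray) -> np.ndarray:
    if isinstance(layer, RasterLayer):
        return layer.values.astype(bool) & layer.valid_mask
    return np.asarray(layer, dtype=bool)


def natural_forest_mask(
    forest_mask: RasterLayer | np.ndarray, plantation_mask: RasterLayer | np.ndarray
) -> np.ndarray:
    """Natural forest = forest AND NOT plantation."""
    f = _as_mask(forest_mask)
    p = _as_mask(plantation_mask)
    if f.shape != p.shape:
        raise ValueError(f"masks not co-registered: {f.shape} vs {p.shape}")
    return f & ~p


def exclude_burned(c_loss: RasterLayer, burn_mask: RasterLayer | np.ndarray) -> RasterLayer:
    """Set burnt pixels to nodata so they drop out of sums and areas."""
    b = _as_mask(burn_mask)
    if b.shape != c_loss.shape:
        raise ValueError(f"burn mask not co-registered: {b.shape} vs {c_loss.shape}")
    out = c_loss.copy()
    out.values[b] = out.nodata
    return out


def restrict_to_mask(layer: RasterLayer, mask: np.ndarray) -> RasterLayer:
    """Nodata everywhere outside ``mask``."""
    out = layer.copy()
    out.values[~np.asarray(mask, dtype=bool)] = out.nodata
    return out


def subtract_fuelwood(net_c_loss: RasterLayer, nrb: RasterLayer) -> RasterLayer:
    """Per-pixel max(net loss − NRB, 0); valid only where both inputs are.

    The clamp encodes that negative grazing-attributed loss is physically
    meaningless where fuelwood extraction exceeds the net loss signal.
    """
    net_c_loss.require_same_grid(nrb, "net C loss and NRB")
    if np.any(nrb.values[nrb.valid_mask] < 0):
        raise ValueError("NRB raster contains negative values")
    out = net_c_loss.copy()
    both = net_c_loss.valid_mask & nrb.valid_mask
    out.values[~both] = out.nodata
    out.values[both] = np.maximum(net_c_loss.values[both] - nrb.values[both], 0.0)
    return out


def propagate_variance(
    var_loss: np.ndarray | float, var_nrb: np.ndarray | float, cov: np.ndarray | float = 0.0
) -> np.ndarray | float:
    """var(loss − NRB) = var(loss) + var(NRB) − 2·cov, floored at 0.

    Raises if any input variance is negative or |cov| violates
    Cauchy–Schwarz.
    """
    var_loss = np.asarray(var_loss, dtype=float)
    var_nrb = np.asarray(var_nrb, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if np.any(var_loss < 0) or np.any(var_nrb < 0):
        raise ValueError("variances must be >= 0")
    bound = np.sqrt(var_loss * var_nrb)
    if np.any(np.abs(cov) > bound * (1 + 1e-12) + 1e-300):
        raise ValueError("covariance violates the Cauchy-Schwarz bound")
    out = np.maximum(var_loss + var_nrb - 2.0 * cov, 0.0)
    return float(out) if out.ndim == 0 else out


def county_scale_field(
    layer: RasterLayer,
    counties: list[tuple[shapely.Geometry, float]],
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-valid-pixel dairy proportion looked up by pixel centre.

    Raises (listing coordinates) when a valid pixel falls in no county.
    """
    valid = layer.valid_mask if valid is None else valid
    xs, ys = layer.grid.pixel_centers(layer.shape)
    px, py = xs[valid], ys[valid]
    scale = np.full(px.shape, np.nan)
    for geom, prop in counties:
        if not 0.0 <= prop <= 1.0:
            raise ValueError(f"dairy proportion {prop} outside [0,1]")
        inside = shapely.contains_xy(geom, px, py)
        scale[inside] = prop
    if np.any(np.isnan(scale)):
        rows, cols = np.where(valid)
        missing = [(int(r), int(c)) for r, c, s in zip(rows, cols, scale) if np.isnan(s)]
        raise ValueError(f"pixels not covered by any county: {missing[:20]}")
    return scale


def scale_by_dairy_proportion(
    c_loss_cattle: RasterLayer,
    counties: list[tuple[shapely.Geometry, float]],
) -> RasterLayer:
    """Scale each pixel by its county's dairy proportion of the cattle herd.

    ``counties`` is a list of (polygon, dairy_proportion) in the raster's
    CRS. Every valid pixel must fall in exactly one county (pixel-centre
    rule); uncovered pixels raise with their coordinates listed.
    """
    out = c_loss_cattle.copy()
    valid = out.valid_mask
    if not valid.any():
        return out
    scale = county_scale_field(out, counties, valid)
    out.values[valid] = out.values[valid] * scale
    return out


def forest_c_change(c_gain: RasterLayer, c_loss_cattle: RasterLayer) -> RasterLayer:
    """Forest C gain minus attributed loss; negative values mean net loss."""
    c_gain.require_same_grid(c_loss_cattle, "gain and loss layers")
    out = c_loss_cattle.copy(units=c_gain.units)
    m = c_loss_cattle.valid_mask
    gain = np.where(c_gain.valid_mask, c_gain.values, 0.0)
    out.values[m] = gain[m] - c_loss_cattle.values[m]
    out.values[~m] = out.nodata
    out.rel_sd = None
    return out


def attribute_grazing_loss(
    net_c_loss: RasterLayer,
    net_c_gain: RasterLayer,
    forest_mask: RasterLayer | np.ndarray,
    plantation_mask: RasterLayer | np.ndarray,
    burn_mask: RasterLayer | np.ndarray,
    nrb: RasterLayer,
    counties: list[tuple[shapely.Geometry, float]],
    cov: float | np.ndarray = 0.0,
    period_years: float = 1.0,
) -> AttributionResult:
    """Full attribution pipeline from net forest C loss to dairy-attributed loss.

    ``period_years`` divides cumulative change layers into annual rates
    (1.0 when inputs are already annual). ``cov`` is the per-pixel
    covariance between net loss and NRB entering the variance propagation.
    """
    if period_years <= 0:
        raise ValueError("period_years must be positive")
    nat = natural_forest_mask(forest_mask, plantation_mask)

    loss = net_c_loss.copy()
    nrb_l = nrb.copy()
    if period_years != 1.0:
        for lyr in (loss, nrb_l):
            m = lyr.valid_mask
            lyr.values[m] = lyr.values[m] / period_years

    loss = restrict_to_mask(loss, nat)
    loss = exclude_burned(loss, burn_mask)
    nrb_l = restrict_to_mask(nrb_l, nat)

    subtracted = subtract_fuelwood(loss, nrb_l)
    attributed = scale_by_dairy_proportion(subtracted, counties)

    # variance on the attributed grid: Eq-style combination of the absolute
    # input SDs, then scaled by the squared county proportion
    valid = attributed.valid_mask
    var_grid = np.full(attributed.shape, attributed.nodata)
    sd_loss = loss.sd
    sd_nrb = nrb_l.sd
    if sd_loss is not None and sd_nrb is not None and valid.any():
        vl = np.where(loss.valid_mask, sd_loss, 0.0) ** 2
        vn = np.where(nrb_l.valid_mask, sd_nrb, 0.0) ** 2
        scale = county_scale_field(attributed, counties, valid)
        var_grid[valid] = propagate_variance(vl[valid], vn[valid], cov) * scale**2
    else:
        var_grid[valid] = 0.0
    var_layer = RasterLayer(
        values=var_grid, units="(kg C ha-1 yr-1)^2", nodata=attributed.nodata, grid=attributed.grid
    )

    change = forest_c_change(net_c_gain, attributed)
    return AttributionResult(
        c_loss_cattle=attributed, c_change_cattle=change, var_c_loss_cattle=var_layer
    )


__all__ = [
    "AttributionResult",
    "natural_forest_mask",
    "exclude_burned",
    "restrict_to_mask",
    "subtract_fuelwood",
    "propagate_variance",
    "scale_by_dairy_proportion",
    "forest_c_change",
    "attribute_grazing_loss",
    "boolean_layer",
]
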