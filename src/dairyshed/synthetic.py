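"""Synthetic dairy-shed landscape and farm-survey generator.

Emulates the statistical structure of the study region's spatial inputs —
co-registered 1-km² rasters of forest C loss/gain, fuelwood (NRB), cattle
density, grazing land and livestock-production-system class, county
polygons with dairy proportions — plus a smallholder farm survey whose
indicators carry configurable Spearman rank correlations with the local
grazing-attributed forest C loss.

Spatially autocorrelated fields come from low-pass-filtered white noise,
so forest forms contiguous patches and land deficits cluster; the farm
survey uses a Gaussian copula (only rank structure is asserted) with
farms placed on the landscape by rank-matching so that measured
neighbourhood statistics reproduce the requested correlations. One global
integer seed drives named substreams for stage-level reproducibility.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import ndimage, stats
from shapely.geometry import mapping as geojson_mapping
from shapely.geometry import shape as geojson_shape

from . import attribution, tables
from .raster import DEFAULT_CRS, NODATA, GridSpec, RasterLayer, boolean_layer


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, stable child RNG of one global seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------
@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Carbon fields are in kg C ha⁻¹ yr⁻¹ with magnitudes in the range of
    the study region's farm-neighbourhood statistics (net loss ≈ 2,000,
    NRB ≈ 500). Cattle densities and grazing-land extents reflect the
    densely settled Kenyan highlands.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    pixel_area: float = 100.0  # ha (100 ha = 1 km² pixels)
    forest_fraction: float = 0.25
    plantation_fraction_of_forest: float = 0.10
    burn_fraction_of_forest: float = 0.05
    mean_net_c_loss: float = 2000.0  # kg C ha-1 yr-1
    mean_net_c_gain: float = 1500.0
    mean_nrb: float = 500.0
    relative_sd_loss: float = 0.30
    relative_sd_nrb: float = 0.30
    cattle_density_range: tuple[float, float] = (20.0, 150.0)  # head km-2
    grazing_land_range: tuple[float, float] = (10.0, 70.0)  # ha per pixel
    n_counties: int = 8
    dairy_proportion_range: tuple[float, float] = (0.5, 0.95)
    lps_classes: tuple[str, ...] = tuple(tables.LPS_CLASSES)
    edge_band_km: float = 5.0  # cattle-density boost band around forest
    edge_density_boost: float = 0.5  # multiplier-1 applied inside the band
    autocorr_sigma: float = 2.0  # Gaussian filter sigma, pixels
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        for name in ("forest_fraction", "plantation_fraction_of_forest", "burn_fraction_of_forest"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        lo, hi = self.dairy_proportion_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("dairy_proportion_range outside [0,1]")
        if self.grazing_land_range[1] > self.pixel_area:
            raise ValueError("grazing land per pixel cannot exceed the pixel area")
        if self.relative_sd_loss < 0 or self.relative_sd_nrb < 0:
            raise ValueError("relative SDs must be >= 0")

    @property
    def pixel_size_m(self) -> float:
        return float(np.sqrt(self.pixel_area * 1e4))

    @classmethod
    def from_yaml(cls, path) -> "LandscapeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cattle_density_range", "grazing_land_range", "dairy_proportion_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "lps_classes" in raw:
            raw["lps_classes"] = tuple(raw["lps_classes"])
        return cls(**raw)


@dataclass
class Landscape:
    """Bundle of co-registered synthetic layers plus county polygons."""

    config: LandscapeConfig
    grid: GridSpec
    net_c_loss: RasterLayer
    net_c_gain: RasterLayer
    forest_mask: RasterLayer
    plantation_mask: RasterLayer
    burn_mask: RasterLayer
    nrb: RasterLayer
    cattle_density: RasterLayer  # head km-2, 0 on forest
    grazing_land: RasterLayer  # ha available per pixel, 0 on forest
    lps_class: RasterLayer  # integer codes into config.lps_classes
    counties: list[tuple[shapely.Geometry, float]] = field(default_factory=list)

    @property
    def layers(self) -> dict[str, RasterLayer]:
        return {
            "net_c_loss": self.net_c_loss,
            "net_c_gain": self.net_c_gain,
            "forest_mask": self.forest_mask,
            "plantation_mask": self.plantation_mask,
            "burn_mask": self.burn_mask,
            "nrb": self.nrb,
            "cattle_density": self.cattle_density,
            "grazing_land": self.grazing_land,
            "lps_class": self.lps_class,
        }

    def dairy_proportion_field(self) -> np.ndarray:
        """Per-pixel county dairy proportion (full grid)."""
        full = np.ones(self.grid_shape, dtype=bool)
        scale = attribution.county_scale_field(self.net_c_loss, self.counties, full)
        return scale.reshape(self.grid_shape)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.net_c_loss.shape

    def cow_population_by_lps(self) -> pd.Series:
        """Dairy cows per LPS: density × pixel area × county dairy share."""
        dens = self.cattle_density.values
        km2 = self.config.pixel_area / 100.0
        dairy = self.dairy_proportion_field()
        codes = self.lps_class.values.astype(int)
        heads = dens * km2 * dairy
        out = {}
        for i, name in enumerate(self.config.lps_classes):
            out[name] = float(heads[codes == i].sum())
        return pd.Series(out, name="dairy_cows")

    def write(self, outdir) -> None:
        """Write all layers as ESRI ASCII grids and counties as GeoJSON."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            layer.to_ascii(outdir / f"{name}.asc")
        write_counties_geojson(self.counties, outdir / "counties.geojson")


def write_counties_geojson(counties, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": geojson_mapping(geom),
            "properties": {"dairy_proportion": prop},
        }
        for geom, prop in counties
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_counties_geojson(path) -> list[tuple[shapely.Geometry, float]]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        (geojson_shape(f["geometry"]), float(f["properties"]["dairy_proportion"]))
        for f in fc["features"]
    ]


# ---------------------------------------------------------------------------
# Field helpers
# ---------------------------------------------------------------------------
def _smooth_standard_normal(rng, shape, sigma) -> np.ndarray:
    """Low-pass-filtered white noise, re-standardised to unit variance."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
        s = z.std()
        if s > 0:
            z = (z - z.mean()) / s
    return z


def _threshold_top_fraction(fieldvals: np.ndarray, frac: float, within=None) -> np.ndarray:
    """Boolean mask of the top ``frac`` of field values (optionally within a mask)."""
    out = np.zeros(fieldvals.shape, dtype=bool)
    if frac <= 0:
        return out
    if within is None:
        within = np.ones(fieldvals.shape, dtype=bool)
    vals = fieldvals[within]
    if vals.size == 0:
        return out
    if frac >= 1:
        out[within] = True
        return out
    cut = np.quantile(vals, 1.0 - frac)
    out[within] = fieldvals[within] > cut
    return out


def _voronoi_counties(rng, grid: GridSpec, shape, n: int, prop_range) -> list:
    rows, cols = shape
    width = cols * grid.pixel_size
    height = rows * grid.pixel_size
    bounds = shapely.box(
        grid.x_origin, grid.y_origin - height, grid.x_origin + width, grid.y_origin
    )
    pts = shapely.points(
        grid.x_origin + rng.uniform(0, width, n),
        grid.y_origin - rng.uniform(0, height, n),
    )
    cells = shapely.voronoi_polygons(shapely.multipoints(pts), extend_to=bounds)
    polys = [shapely.intersection(g, bounds) for g in cells.geoms]
    # voronoi cell order is not tied to input point order; sort for stability
    polys.sort(key=lambda g: (g.centroid.x, g.centroid.y))
    props = rng.uniform(prop_range[0], prop_range[1], len(polys))
    return list(zip(polys, props.tolist()))


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------
def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate the co-registered synthetic raster bundle.

    Deterministic given ``config.seed``; forest pixels form contiguous
    patches; NRB never exceeds net C loss pointwise, so the fuelwood
    subtraction is non-negative; cattle density is boosted within
    ``edge_band_km`` of the forest edge.
    """
    shape = (config.grid_rows, config.grid_cols)
    grid = GridSpec(pixel_size=config.pixel_size_m, crs=DEFAULT_CRS)
    seed = config.seed
    sig = config.autocorr_sigma

    forest = _threshold_top_fraction(
        _smooth_standard_normal(substream(seed, "forest"), shape, sig),
        config.forest_fraction,
    )
    plantation = _threshold_top_fraction(
        _smooth_standard_normal(substream(seed, "plantation"), shape, sig),
        config.plantation_fraction_of_forest,
        within=forest,
    )
    burn = _threshold_top_fraction(
        _smooth_standard_normal(substream(seed, "burn"), shape, sig / 2 if sig else 0),
        config.burn_fraction_of_forest,
        within=forest,
    )

    z_loss = _smooth_standard_normal(substream(seed, "c_loss"), shape, sig)
    loss_vals = np.clip(config.mean_net_c_loss * (1.0 + config.relative_sd_loss * z_loss), 0, None)
    z_gain = _smooth_standard_normal(substream(seed, "c_gain"), shape, sig)
    gain_vals = np.clip(config.mean_net_c_gain * (1.0 + 0.3 * z_gain), 0, None)

    # NRB as a smooth fraction of the loss field: pointwise <= net loss,
    # with mean ratio mean_nrb / mean_net_c_loss
    ratio = 1.0 if config.mean_net_c_loss == 0 else config.mean_nrb / config.mean_net_c_loss
    z_nrb = _smooth_standard_normal(substream(seed, "nrb"), shape, sig)
    nrb_frac = np.clip(ratio * (1.0 + config.relative_sd_nrb * z_nrb), 0.0, 1.0)
    nrb_vals = loss_vals * nrb_frac

    # carbon layers only meaningful on forest; keep full fields (masking is
    # the attribution stage's job) but nodata the gain outside forest
    units = "kg C ha-1 yr-1"
    net_c_loss = RasterLayer(
        loss_vals, rel_sd=np.full(shape, config.relative_sd_loss), units=units, grid=grid
    )
    net_c_gain = RasterLayer(np.where(forest, gain_vals, NODATA), units=units, grid=grid)
    nrb = RasterLayer(
        nrb_vals, rel_sd=np.full(shape, config.relative_sd_nrb), units=units, grid=grid
    )

    # cattle density: zero on forest, boosted within the edge band
    rng_cattle = substream(seed, "cattle")
    u = stats.norm.cdf(_smooth_standard_normal(rng_cattle, shape, sig))
    lo, hi = config.cattle_density_range
    dens = lo + u * (hi - lo)
    if forest.any():
        dist_px = ndimage.distance_transform_edt(~forest)
    else:
        dist_px = np.full(shape, np.inf)
    band_px = config.edge_band_km * 1000.0 / config.pixel_size_m
    in_band = dist_px <= band_px
    dens = dens * (1.0 + config.edge_density_boost * in_band)
    dens[forest] = 0.0
    cattle_density = RasterLayer(dens, units="head km-2", grid=grid)

    rng_graze = substream(seed, "grazing")
    ug = stats.norm.cdf(_smooth_standard_normal(rng_graze, shape, sig))
    glo, ghi = config.grazing_land_range
    graze = glo + ug * (ghi - glo)
    graze[forest] = 0.0
    grazing_land = RasterLayer(graze, units="ha", grid=grid)

    # LPS classes: nearest of k random centres
    rng_lps = substream(seed, "lps")
    k = len(config.lps_classes)
    centers = np.column_stack(
        [rng_lps.uniform(0, config.grid_rows, k), rng_lps.uniform(0, config.grid_cols, k)]
    )
    rr, cc = np.meshgrid(np.arange(config.grid_rows), np.arange(config.grid_cols), indexing="ij")
    d2 = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
    codes = np.argmin(d2, axis=-1).astype(float)
    lps_class = RasterLayer(codes, units="class", grid=grid)

    counties = _voronoi_counties(
        substream(seed, "counties"), grid, shape, config.n_counties, config.dairy_proportion_range
    )

    return Landscape(
        config=config,
        grid=grid,
        net_c_loss=net_c_loss,
        net_c_gain=net_c_gain,
        forest_mask=boolean_layer(forest, grid),
        plantation_mask=boolean_layer(plantation, grid),
        burn_mask=boolean_layer(burn, grid),
        nrb=nrb,
        cattle_density=cattle_density,
        grazing_land=grazing_land,
        lps_class=lps_class,
        counties=counties,
    )


# ---------------------------------------------------------------------------
# Farm survey
# ---------------------------------------------------------------------------
#: default Spearman targets of each indicator against grazing-attributed
#: forest C loss; signs follow the study's correlation structure
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "n_cattle": 0.15,
    "n_improved_cattle": -0.37,
    "milk_yield": -0.26,
    "fodder_fraction_diet": -0.39,
    "concentrate_supplementation": -0.21,
    "area_fodder": -0.34,
    "farm_size": 0.0,
    "fuelwood_extraction": 0.10,
}

SURVEY_INDICATORS = list(DEFAULT_EFFECT_SIZES)


def _spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Gaussian-copula latent correlation giving target Spearman rho."""
    return 2.0 * np.sin(np.pi * np.asarray(rho) / 6.0)


def _copula_sample(
    rng: np.random.Generator,
    n: int,
    targets: dict[str, float],
    indicator_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Latent MVN sample: column 0 is the forest-loss factor."""
    names = list(targets)
    r = _spearman_to_pearson(np.array([targets[k] for k in names]))
    if np.any(np.abs(r) >= 1):
        raise ValueError("|rho| targets must be < 1")
    k = len(names)
    R = np.empty((k + 1, k + 1))
    R[0, 0] = 1.0
    R[0, 1:] = R[1:, 0] = r
    if indicator_corr is None:
        # single-factor construction: indicator_i = r_i * F + noise
        R[1:, 1:] = np.outer(r, r)
        np.fill_diagonal(R[1:, 1:], 1.0)
    else:
        R[1:, 1:] = indicator_corr
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "requested rank-correlation structure is not positive semidefinite"
        )
    cov = R + np.eye(k + 1) * max(0.0, -eigvals.min() + 1e-12)
    z = rng.multivariate_normal(np.zeros(k + 1), cov, size=n, method="cholesky")
    return pd.DataFrame(z, columns=["forest_loss_latent"] + names)


def _survey_marginals(z: pd.DataFrame) -> pd.DataFrame:
    """Map latent normals onto realistic survey marginals (rank-preserving)."""
    u = pd.DataFrame(stats.norm.cdf(z), columns=z.columns).clip(1e-9, 1 - 1e-9)
    out = pd.DataFrame(index=z.index)
    out["n_cattle"] = stats.poisson.ppf(u["n_cattle"], 8) + 1
    improved = stats.poisson.ppf(u["n_improved_cattle"], 3)
    out["n_improved_cattle"] = np.minimum(improved, out["n_cattle"])
    out["milk_yield"] = np.exp(np.log(1500.0) + 0.45 * z["milk_yield"])
    out["fodder_fraction_diet"] = stats.beta.ppf(u["fodder_fraction_diet"], 2, 3)
    out["concentrate_supplementation"] = stats.beta.ppf(u["concentrate_supplementation"], 1.5, 6)
    out["area_fodder"] = stats.gamma.ppf(u["area_fodder"], 2, scale=0.4)
    out["farm_size"] = stats.gamma.ppf(u["farm_size"], 3, scale=0.8)
    out["fuelwood_extraction"] = stats.gamma.ppf(u["fuelwood_extraction"], 2, scale=900.0)
    out["latent_forest_loss"] = z["forest_loss_latent"]
    return out


def _assign_farm_types(df: pd.DataFrame) -> pd.Series:
    """Three farm types; intensified = top third of milk+fodder ranks."""
    score = df["milk_yield"].rank() + df["fodder_fraction_diet"].rank()
    n = len(df)
    order = score.sort_values(ascending=False).index
    types = pd.Series("small", index=df.index)
    types.loc[order[: n // 3]] = "intensified"
    rest = order[n // 3 :]
    large = df.loc[rest, "farm_size"] >= df.loc[rest, "farm_size"].median()
    types.loc[rest[large.values]] = "large"
    return types


def _attributed_loss_proxy(landscape: Landscape) -> RasterLayer:
    """Grazing-attributed loss field used to place farms (full pipeline)."""
    res = attribution.attribute_grazing_loss(
        landscape.net_c_loss,
        landscape.net_c_gain,
        landscape.forest_mask,
        landscape.plantation_mask,
        landscape.burn_mask,
        landscape.nrb,
        landscape.counties,
    )
    return res.c_loss_cattle


def _neighbourhood_means(layer: RasterLayer, radius_m: float) -> np.ndarray:
    """Mean of valid pixels within a circular window, everywhere on the grid."""
    r_px = radius_m / layer.grid.pixel_size
    n = int(np.floor(r_px))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    kernel = (xx**2 + yy**2) <= r_px**2
    valid = layer.valid_mask
    vals = np.where(valid, layer.values, 0.0)
    s = ndimage.convolve(vals, kernel.astype(float), mode="constant")
    c = ndimage.convolve(valid.astype(float), kernel.astype(float), mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(c > 0, s / c, np.nan)


def generate_farm_survey(
    landscape: Landscape | LandscapeConfig,
    n_farms: int = 216,
    effect_sizes: dict[str, float] | None = None,
    seed: int | None = None,
    radius_m: float = 5000.0,
    indicator_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate a farm survey with the requested rank-correlation structure.

    Farms are placed on non-forest pixels near the forest edge; positions
    are rank-matched between the copula's latent forest-loss factor and
    the measured neighbourhood mean of grazing-attributed loss, so zonal
    statistics taken later recover the requested Spearman correlations.
    The ``latent_forest_loss`` column supports landscape-free round trips.
    """
    if isinstance(landscape, LandscapeConfig):
        landscape = generate_landscape(landscape)
    if n_farms < 30:
        raise ValueError("n_farms must be >= 30 for a meaningful survey")
    if effect_sizes is None:
        targets = dict(DEFAULT_EFFECT_SIZES)
    else:
        unknown = set(effect_sizes) - set(DEFAULT_EFFECT_SIZES)
        if unknown:
            raise ValueError(f"unknown survey indicators: {sorted(unknown)}")
        # partial specs mean: these correlations, all other indicators null
        targets = {k: effect_sizes.get(k, 0.0) for k in DEFAULT_EFFECT_SIZES}
    seed = landscape.config.seed if seed is None else seed
    rng = substream(seed, "survey")

    z = _copula_sample(rng, n_farms, targets, indicator_corr)
    df = _survey_marginals(z)
    df["farm_type"] = _assign_farm_types(df)
    df["farm_id"] = [f"farm_{i:04d}" for i in range(n_farms)]

    # candidate sites: non-forest pixels within the edge band, with forest
    # pixels inside the neighbourhood radius
    loss_layer = _attributed_loss_proxy(landscape)
    nb_mean = _neighbourhood_means(loss_layer, radius_m)
    forest = landscape.forest_mask.values.astype(bool)
    dist_px = (
        ndimage.distance_transform_edt(~forest) if forest.any() else np.full(forest.shape, np.inf)
    )
    band_px = max(radius_m / landscape.grid.pixel_size, 1.0)
    candidates = (~forest) & (dist_px <= band_px) & np.isfinite(nb_mean)
    rows, cols = np.where(candidates)
    if rows.size < n_farms:
        rows, cols = np.where(~forest & np.isfinite(nb_mean))
    if rows.size < n_farms:
        rows, cols = np.where(np.ones_like(forest))
    pick = rng.choice(rows.size, size=n_farms, replace=rows.size < n_farms)
    prow, pcol = rows[pick], cols[pick]
    site_loss = nb_mean[prow, pcol]

    # rank-match: farm with k-th ranked latent loss gets k-th ranked site
    site_order = np.argsort(site_loss, kind="stable")
    farm_order = np.argsort(df["latent_forest_loss"].to_numpy(), kind="stable")
    assigned = np.empty(n_farms, dtype=int)
    assigned[farm_order] = site_order
    xs, ys = landscape.grid.pixel_centers(forest.shape)
    df["x"] = xs[prow[assigned], pcol[assigned]]
    df["y"] = ys[prow[assigned], pcol[assigned]]

    cols_order = ["farm_id", "farm_type", "x", "y"] + SURVEY_INDICATORS + ["latent_forest_loss"]
    return df[cols_order].reset_index(drop=True)


__all__ = [
    "LandscapeConfig",
    "Landscape",
    "generate_landscape",
    "generate_farm_survey",
    "write_counties_geojson",
    "read_counties_geojson",
    "DEFAULT_EFFECT_SIZES",
    "SURVEY_INDICATORS",
    "substream",
]
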