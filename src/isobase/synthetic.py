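"""Synthetic study system: landscape, soil isotope fields, weather, badger hairs.

Emulates the statistical structure of a regional consumer-isotope survey over
a heterogeneous temperate landscape: a mosaic of seven land classes (A-G,
lowland farmland through high uplands), spatially autocorrelated soil d13C and
d15N fields (the environmental baseline), a late-winter weather series with a
cold/snow perturbation, and repeated hair samples from genotyped individuals
living at setts placed across the landscape.

The consumer generative model inverts the trophic-position relation
lambda = (d_consumer - d_base) / Dn:

    d_consumer = d_base(x) + lambda_true(individual) * Dn
                 + individual effect + weather effect * (14-day temperature
                 anomaly) + measurement noise

where lambda_true(individual) = lambda(class) + a per-individual trophic
deviation (individual foraging strategy), and the individual effect is a
smaller per-isotope residual.

so the exact baseline, individual effects, and per-individual lambda_true are
recorded in a truth table and every downstream stage has a recovery target.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, LinAlgError
from scipy.ndimage import gaussian_filter

from .isoscape import GridSpec, VariogramModel

LAND_CLASSES = ("A", "B", "C", "D", "E", "F", "G")

#: class -> mean elevation (m); lowland A-D low, upland E-G high
DEFAULT_CLASS_ELEVATION = {
    "A": 60.0, "B": 40.0, "C": 90.0, "D": 70.0,
    "E": 220.0, "F": 300.0, "G": 420.0,
}

#: class -> true trophic position; lowland lakelands/central lowlands (B, D)
#: highest, uplands lowest (protein-richer diets in lowland habitat)
DEFAULT_CLASS_TROPHIC = {
    "A": 2.2, "B": 2.8, "C": 2.4, "D": 2.7,
    "E": 2.0, "F": 1.9, "G": 1.8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic system (defaults are the reference)."""

    seed: int = 0
    n_cols: int = 40
    n_rows: int = 40
    cell_size: float = 1000.0
    grid_origin: tuple[float, float] = (0.0, 0.0)
    class_elevation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ELEVATION))
    class_trophic_level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TROPHIC))
    elevation_noise_sd: float = 30.0
    soil_variogram_C: VariogramModel = VariogramModel("spherical", 0.05, 0.5, 15000.0)
    soil_variogram_N: VariogramModel = VariogramModel("spherical", 0.05, 0.9, 15000.0)
    soil_mean_C: float = -28.0
    soil_mean_N: float = 5.0
    delta_n_N: float = 3.4
    delta_n_C: float = 1.0
    sd_lambda_individual: float = 0.12
    sd_individual: float = 0.15
    sd_measurement: float = 0.1
    n_setts: int = 40
    individuals_per_sett: int = 2
    samples_per_individual: int = 3
    weather_effect_C: float = 0.15
    weather_effect_N: float = 0.20
    n_soil_samples: int = 115
    n_stations: int = 5
    date_start: str = "2009-02-01"
    date_end: str = "2009-04-30"
    snow_event_window: tuple[str, str] = ("2009-02-20", "2009-03-05")
    weather_t_start: float = 4.0
    weather_t_end: float = 12.0
    weather_noise_sd: float = 1.2
    snow_t_drop: float = 6.0

    def __post_init__(self) -> None:
        for name in ("sd_individual", "sd_lambda_individual", "sd_measurement",
                     "weather_noise_sd", "elevation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta_n_N <= 0 or self.delta_n_C <= 0:
            raise ValueError("trophic discrimination factors must be > 0")
        if set(self.class_trophic_level) != set(self.class_elevation):
            raise ValueError("trophic and elevation maps must share the same classes")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_origin[0], self.grid_origin[1],
                        self.cell_size, self.n_cols, self.n_rows)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.class_trophic_level))


@dataclass
class Landscape:
    """Land-class mosaic plus elevation surface on a regular grid."""

    grid: GridSpec
    land_class: np.ndarray  # (n_rows, n_cols) of class labels
    elevation: np.ndarray   # (n_rows, n_cols) metres, >= 0

    def class_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r, c = self.grid.cell_index(x, y)
        return self.land_class[r, c]

    def elevation_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r, c = self.grid.cell_index(x, y)
        return self.elevation[r, c]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def generate_landscape(config: SimulationConfig) -> Landscape:
    """Voronoi land-class patches (one seed point per class) + elevation.

    Each class is a single convex Voronoi cell, so patches are contiguous.
    Elevation is the class-mean surface plus smoothed Gaussian noise, clipped
    at sea level; upland classes therefore sit higher than lowland ones on
    average.
    """
    classes = config.classes
    grid = config.grid
    n_cells = grid.n_cols * grid.n_rows
    if grid.n_cols < 8 or grid.n_rows < 8:
        raise ValueError("grid must be at least 8 x 8 cells")
    if n_cells < len(classes):
        raise ValueError(
            f"{n_cells} cells cannot host {len(classes)} land classes; enlarge the grid")
    rng = _rng(config.seed, 1)
    centers = grid.cell_centers()
    for _ in range(100):
        seeds = np.column_stack([
            rng.uniform(grid.x_origin, grid.x_origin + grid.n_cols * grid.cell_size,
                        len(classes)),
            rng.uniform(grid.y_origin, grid.y_origin + grid.n_rows * grid.cell_size,
                        len(classes)),
        ])
        d2 = ((centers[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        if len(np.unique(idx)) == len(classes):
            break
    else:
        raise RuntimeError("could not place one Voronoi seed per land class")
    labels = np.array(classes, dtype=object)[idx].reshape(grid.n_rows, grid.n_cols)

    base = np.vectorize(config.class_elevation.__getitem__)(labels).astype(float)
    noise = rng.standard_normal(base.shape)
    noise = gaussian_filter(noise, sigma=2.0, mode="nearest")
    noise *= config.elevation_noise_sd / max(noise.std(), 1e-12)
    elevation = np.clip(base + noise, 0.0, None)
    return Landscape(grid=grid, land_class=labels, elevation=elevation)


def simulate_soil_field(
    landscape: Landscape, model: VariogramModel, mean: float, seed: int,
) -> np.ndarray:
    """Stationary Gaussian random field on the grid with the given variogram.

    Exact simulation by Cholesky factorisation of the full cell-centre
    covariance matrix (grids here are at most a few thousand cells). A
    non-positive-definite covariance raises; there is no silent eigenvalue
    clipping.
    """
    grid = landscape.grid
    if model.sill == 0:
        return np.full((grid.n_rows, grid.n_cols), float(mean))
    pts = grid.cell_centers()
    h = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    cov = model.covariance(h)
    # tiny diagonal jitter guards rounding in the factorisation; it is ~1e-10
    # of the sill and does not alter the target covariance materially
    cov[np.diag_indices_from(cov)] += 1e-10 * model.sill
    try:
        L = cholesky(cov, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            f"covariance from {model} is not positive definite: {exc}") from exc
    z = _rng(seed, 2).standard_normal(len(pts))
    return (mean + L @ z).reshape(grid.n_rows, grid.n_cols)


def sample_soil(
    fields: dict[str, np.ndarray], landscape: Landscape, n: int, seed: int,
) -> pd.DataFrame:
    """Draw n soil point samples at distinct cell centres of the field rasters.

    ``fields`` maps column name ('d13C', 'd15N') to its raster. Values are the
    cell-centre field values (point support, no interpolation).
    """
    grid = landscape.grid
    n_cells = grid.n_cols * grid.n_rows
    if n < 3:
        raise ValueError("need n >= 3 soil samples")
    if n > n_cells:
        raise ValueError(f"cannot place {n} samples on {n_cells} distinct cells")
    rng = _rng(seed, 3)
    flat = rng.choice(n_cells, size=n, replace=False)
    rows, cols = np.divmod(flat, grid.n_cols)
    out = pd.DataFrame({
        "x": grid.x_origin + (cols + 0.5) * grid.cell_size,
        "y": grid.y_origin + (rows + 0.5) * grid.cell_size,
    })
    for name, raster in fields.items():
        out[name] = raster[rows, cols]
    return out


def generate_weather(config: SimulationConfig, stations: int | None = None) -> pd.DataFrame:
    """Daily weather series per station: linear seasonal warming plus noise,
    with temperatures depressed and sunshine cut inside the snow-event window.

    Row invariants are enforced by construction: t_min <= t_mean <= t_max,
    rainfall >= 0, sunshine in [0, 24].
    """
    n_st = config.n_stations if stations is None else stations
    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    if len(dates) == 0:
        raise ValueError("empty weather date range")
    snow_start, snow_end = (pd.Timestamp(d) for d in config.snow_event_window)
    if snow_start < dates[0] or snow_end > dates[-1]:
        raise ValueError("snow_event_window must lie inside the date range")
    rng = _rng(config.seed, 4)
    grid = config.grid
    sx = rng.uniform(grid.x_origin, grid.x_origin + grid.n_cols * grid.cell_size, n_st)
    sy = rng.uniform(grid.y_origin, grid.y_origin + grid.n_rows * grid.cell_size, n_st)
    t = np.arange(len(dates)) / max(len(dates) - 1, 1)
    seasonal = config.weather_t_start + (config.weather_t_end - config.weather_t_start) * t
    in_snow = (dates >= snow_start) & (dates <= snow_end)
    rows = []
    for s in range(n_st):
        offset = rng.normal(0.0, 0.5) * (config.weather_noise_sd > 0)
        tm = seasonal + offset + rng.normal(0.0, config.weather_noise_sd, len(dates))
        tm = tm - in_snow.astype(float) * config.snow_t_drop
        spread_hi = 3.0 + np.abs(rng.normal(0.0, 0.8, len(dates))) * (config.weather_noise_sd > 0)
        spread_lo = 3.0 + np.abs(rng.normal(0.0, 0.8, len(dates))) * (config.weather_noise_sd > 0)
        rain = rng.gamma(0.8, 3.0, len(dates))
        rain = rain + in_snow.astype(float) * rng.gamma(1.5, 2.0, len(dates))
        sun_base = 2.5 + 4.5 * t
        sun = sun_base + rng.normal(0.0, 1.5, len(dates)) * (config.weather_noise_sd > 0)
        sun = np.where(in_snow, sun * 0.3, sun)
        rows.append(pd.DataFrame({
            "station_id": s,
            "x": sx[s], "y": sy[s],
            "date": dates,
            "t_mean": tm,
            "t_max": tm + spread_hi,
            "t_min": tm - spread_lo,
            "rain_mm": np.clip(rain, 0.0, None),
            "sun_hrs": np.clip(sun, 0.0, 24.0),
        }))
    return pd.concat(rows, ignore_index=True)


def _nearest_station(weather: pd.DataFrame, x: float, y: float) -> int:
    st = weather[["station_id", "x", "y"]].drop_duplicates("station_id")
    d2 = (st["x"] - x) ** 2 + (st["y"] - y) ** 2
    # equidistant stations: lowest station_id wins (documented tie-break)
    best = d2.min()
    return int(st.loc[d2 <= best + 1e-9, "station_id"].min())


def _window_tmean_anomaly(weather: pd.DataFrame, station: int, date: pd.Timestamp) -> float:
    """Mean t_mean over the 14 days before ``date`` minus the station's
    whole-series mean (degC anomaly; the generator's weather score)."""
    w = weather[weather["station_id"] == station]
    window = w[(w["date"] >= date - pd.Timedelta(days=14))
               & (w["date"] <= date - pd.Timedelta(days=1))]
    if len(window) < 14:
        raise ValueError(f"weather does not cover the 14 days before {date.date()}")
    return float(window["t_mean"].mean() - w["t_mean"].mean())


def generate_consumers(
    landscape: Landscape,
    soil_fields: dict[str, np.ndarray],
    weather: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hair-sample table plus truth table.

    Setts are placed on distinct cells excluding the highest-elevation class
    (mountain tops are not badger habitat); each individual carries a genotype
    id reused across its repeated samples (deliberate pseudo-replication).
    The truth table records per-individual lambda_true, individual effects and
    the exact cell baseline — the targets for parameter recovery.
    """
    rng = _rng(config.seed, 5)
    grid = landscape.grid
    classes = config.classes
    highest = max(classes, key=lambda k: config.class_elevation[k])
    eligible = np.flatnonzero((landscape.land_class != highest).ravel())
    if len(eligible) < config.n_setts:
        raise ValueError("not enough non-mountain cells for the requested setts")
    cells = rng.choice(eligible, size=config.n_setts, replace=False)
    rows_idx, cols_idx = np.divmod(cells, grid.n_cols)
    sett_x = grid.x_origin + (cols_idx + 0.5) * grid.cell_size
    sett_y = grid.y_origin + (rows_idx + 0.5) * grid.cell_size
    in_x = (sett_x >= grid.x_origin) & (sett_x <= grid.x_origin + grid.n_cols * grid.cell_size)
    in_y = (sett_y >= grid.y_origin) & (sett_y <= grid.y_origin + grid.n_rows * grid.cell_size)
    if not (in_x.all() and in_y.all()):
        raise ValueError("sett placed outside the landscape grid")

    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    first_ok = dates[0] + pd.Timedelta(days=14)
    sampling_dates = dates[dates >= first_ok]

    hair_rows, truth_rows = [], []
    sample_no = 0
    for s in range(config.n_setts):
        r, c = rows_idx[s], cols_idx[s]
        cls = landscape.land_class[r, c]
        station = _nearest_station(weather, sett_x[s], sett_y[s])
        for i in range(config.individuals_per_sett):
            gid = f"G{s:03d}_{i}"
            # individual foraging strategy: a trophic deviation moving both
            # isotopes along the enrichment slope, plus smaller per-isotope
            # residuals (routing/physiology) off the slope
            lam = config.class_trophic_level[cls] + (
                rng.normal(0.0, config.sd_lambda_individual)
                if config.sd_lambda_individual else 0.0)
            ind_C = rng.normal(0.0, config.sd_individual) if config.sd_individual else 0.0
            ind_N = rng.normal(0.0, config.sd_individual) if config.sd_individual else 0.0
            base_C = float(soil_fields["d13C"][r, c])
            base_N = float(soil_fields["d15N"][r, c])
            truth_rows.append({
                "genotype_id": gid, "sett_id": f"S{s:03d}", "land_class": cls,
                "lambda_true": lam, "ind_effect_C": ind_C, "ind_effect_N": ind_N,
                "base_d13C": base_C, "base_d15N": base_N,
            })
            for _ in range(config.samples_per_individual):
                date = sampling_dates[rng.integers(len(sampling_dates))]
                score = _window_tmean_anomaly(weather, station, date)
                eps_C = rng.normal(0.0, config.sd_measurement) if config.sd_measurement else 0.0
                eps_N = rng.normal(0.0, config.sd_measurement) if config.sd_measurement else 0.0
                d13C = (base_C + lam * config.delta_n_C + ind_C
                        + config.weather_effect_C * score + eps_C)
                d15N = (base_N + lam * config.delta_n_N + ind_N
                        + config.weather_effect_N * score + eps_N)
                sample_no += 1
                hair_rows.append({
                    "sample_id": f"H{sample_no:04d}",
                    "sett_id": f"S{s:03d}",
                    "x": sett_x[s], "y": sett_y[s],
                    "date": date,
                    "d13C": d13C, "d15N": d15N,
                    "genotype_id": gid,
                    "land_class": cls,
                    "elevation_m": float(landscape.elevation[r, c]),
                })
    return pd.DataFrame(hair_rows), pd.DataFrame(truth_rows)


def simulate_tables(
    config: SimulationConfig,
) -> dict[str, object]:
    """Run the full generator: landscape, fields, soil/hair/weather/truth tables."""
    landscape = generate_landscape(config)
    field_C = simulate_soil_field(landscape, config.soil_variogram_C,
                                  config.soil_mean_C, seed=config.seed * 2 + 11)
    field_N = simulate_soil_field(landscape, config.soil_variogram_N,
                                  config.soil_mean_N, seed=config.seed * 2 + 12)
    fields = {"d13C": field_C, "d15N": field_N}
    soil = sample_soil(fields, landscape, config.n_soil_samples, seed=config.seed)
    weather = generate_weather(config)
    hair, truth = generate_consumers(landscape, fields, weather, config)
    return {
        "landscape": landscape,
        "fields": fields,
        "soil": soil,
        "weather": weather,
        "hair": hair,
        "truth": truth,
    }


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of the config with every stochastic consumer term switched off."""
    return replace(config, sd_individual=0.0, sd_lambda_individual=0.0,
                   sd_measurement=0.0, weather_effect_C=0.0, weather_effect_N=0.0)
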