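"""Baseline extraction and trophic correction of consumer isotope values.

The soil isoscape gives the environmental baseline under each consumer; the
correction is the plain deduction corrected = consumer - baseline, and the
trophic position estimate is lambda = (d15N_consumer - d15N_base) / Dn. The
deduction is lossless (uncorrected = corrected + baseline to machine
precision), so downstream statistics can always be traced back.

Two baseline routes exist: the reference route kriges at the exact consumer
coordinates from the fitted variogram model; the raster route reads the
containing cell of a pre-computed isoscape grid (an approximation recorded in
the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .isoscape import IsoscapeRaster, VariogramModel, krige_points

logger = logging.getLogger(__name__)


@dataclass
class BaselineExtraction:
    values: np.ndarray
    kriging_variance: np.ndarray | None
    extrapolated: np.ndarray  # True where the point lies outside the sample bbox
    route: str  # "model" or "raster"


def extract_baseline(
    source,
    coords: np.ndarray,
    soil_samples: pd.DataFrame | None = None,
    value_column: str = "d15N",
) -> BaselineExtraction:
    """Baseline isotope value at each coordinate.

    ``source`` is either a fitted :class:`VariogramModel` (then
    ``soil_samples`` must be given and kriging is evaluated at the exact
    coordinates — the reference route) or an :class:`IsoscapeRaster` (then the
    containing cell is read — the raster approximation). Points outside the
    soil-sample bounding box are still predicted but flagged as extrapolation.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("empty coordinate list")
    if isinstance(source, VariogramModel):
        if soil_samples is None:
            raise ValueError("the model route needs the soil sample table")
        pred, var = krige_points(soil_samples, source, coords, value_column)
        bbox = soil_samples[["x", "y"]].agg(["min", "max"])
        outside = (
            (coords[:, 0] < bbox.loc["min", "x"]) | (coords[:, 0] > bbox.loc["max", "x"])
            | (coords[:, 1] < bbox.loc["min", "y"]) | (coords[:, 1] > bbox.loc["max", "y"])
        )
        if outside.any():
            logger.warning("%d baseline points lie outside the soil-sample bounding box "
                           "(extrapolation)", int(outside.sum()))
        return BaselineExtraction(pred, var, outside, "model")
    if isinstance(source, IsoscapeRaster):
        grid = source.grid
        r, c = grid.cell_index(coords[:, 0], coords[:, 1])
        x_max = grid.x_origin + grid.n_cols * grid.cell_size
        y_max = grid.y_origin + grid.n_rows * grid.cell_size
        outside = (
            (coords[:, 0] < grid.x_origin) | (coords[:, 0] > x_max)
            | (coords[:, 1] < grid.y_origin) | (coords[:, 1] > y_max)
        )
        return BaselineExtraction(
            source.prediction[r, c], source.kriging_variance[r, c], outside, "raster")
    raise TypeError("source must be a VariogramModel or an IsoscapeRaster")


def correct_values(consumer: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Element-wise deduction consumer - baseline; nothing else."""
    consumer = np.asarray(consumer, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if consumer.shape != baseline.shape:
        raise ValueError(
            f"length mismatch: consumer {consumer.shape} vs baseline {baseline.shape}")
    if not (np.all(np.isfinite(consumer)) and np.all(np.isfinite(baseline))):
        raise ValueError("inputs must be finite")
    return consumer - baseline


def trophic_position(
    d15N_consumer: np.ndarray,
    d15N_base: np.ndarray,
    delta_n: float = 3.4,
    base_trophic_level: float = 0.0,
) -> np.ndarray:
    """Trophic position lambda = (d15N_consumer - d15N_base) / Dn.

    By default no baseline trophic level is added — the deduction-only form.
    Pass ``base_trophic_level`` to use the additive convention
    lambda = base_level + (consumer - base) / Dn instead.
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be > 0")
    return base_trophic_level + correct_values(d15N_consumer, d15N_base) / delta_n


def correct_table(
    hair: pd.DataFrame,
    base_d13C: np.ndarray,
    base_d15N: np.ndarray,
    delta_n: float = 3.4,
    base_variance_d13C: np.ndarray | None = None,
    base_variance_d15N: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach baselines and corrected columns to a hair-sample table."""
    out = hair.copy()
    out["base_d13C"] = np.asarray(base_d13C, dtype=float)
    out["base_d15N"] = np.asarray(base_d15N, dtype=float)
    out["corr_d13C"] = correct_values(out["d13C"].to_numpy(), out["base_d13C"].to_numpy())
    out["corr_d15N"] = correct_values(out["d15N"].to_numpy(), out["base_d15N"].to_numpy())
    out["trophic_position"] = trophic_position(
        out["d15N"].to_numpy(), out["base_d15N"].to_numpy(), delta_n)
    if base_variance_d13C is not None:
        out["base_var_d13C"] = np.asarray(base_variance_d13C, dtype=float)
    if base_variance_d15N is not None:
        out["base_var_d15N"] = np.asarray(base_variance_d15N, dtype=float)
    return out


_MEAN_COLUMNS = ("d13C", "d15N", "base_d13C", "base_d15N", "corr_d13C",
                 "corr_d15N", "trophic_position", "elevation_m")


def aggregate_by_individual(
    samples: pd.DataFrame, allow_multiclass: bool = False,
) -> pd.DataFrame:
    """Collapse repeated hair samples to one row per genotyped individual.

    Unweighted arithmetic mean of the isotope (and any baseline/corrected)
    columns per genotype; sett, land class and coordinates come from the
    individual's modal sett. Rows without a genotype id are excluded with a
    logged count. A genotype spanning several land classes is treated as a
    data error unless ``allow_multiclass`` (then the modal class is used).
    """
    if "genotype_id" not in samples.columns:
        raise ValueError("genotype_id column required for individual aggregation")
    missing = samples["genotype_id"].isna()
    if missing.any():
        logger.warning("excluding %d rows without a genotype id", int(missing.sum()))
    df = samples.loc[~missing]
    if df.empty:
        raise ValueError("no rows carry a genotype id")
    rows = []
    for gid, grp in df.groupby("genotype_id", sort=True):
        classes = grp["land_class"].unique()
        if len(classes) > 1 and not allow_multiclass:
            raise ValueError(
                f"genotype {gid!r} spans land classes {sorted(classes)}; "
                "likely a data error (pass allow_multiclass=True to use the modal class)")
        modal_sett = grp["sett_id"].mode().iloc[0]
        at_sett = grp[grp["sett_id"] == modal_sett].iloc[0]
        row = {
            "genotype_id": gid,
            "sett_id": modal_sett,
            "x": at_sett["x"], "y": at_sett["y"],
            "land_class": grp["land_class"].mode().iloc[0],
            "n_samples": len(grp),
        }
        for col in _MEAN_COLUMNS:
            if col in grp.columns:
                row[col] = float(grp[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


WEATHER_VARS = ("t_mean", "t_max", "t_min", "rain_mm", "sun_hrs")


def attach_weather(samples: pd.DataFrame, weather: pd.DataFrame) -> pd.DataFrame:
    """Append trailing 14-day means of the five weather variables per sample.

    The station is the nearest by Euclidean distance (ties: lowest
    station_id); the window is days -14 .. -1 relative to the collection
    date, inclusive. A coverage gap raises, naming the sample and dates.
    """
    stations = weather[["station_id", "x", "y"]].drop_duplicates("station_id")
    st_xy = stations[["x", "y"]].to_numpy(dtype=float)
    st_ids = stations["station_id"].to_numpy()
    order = np.argsort(st_ids)
    st_xy, st_ids = st_xy[order], st_ids[order]
    by_station = {sid: g.set_index("date") for sid, g in weather.groupby("station_id")}
    out = samples.copy()
    means = {v: np.empty(len(samples)) for v in WEATHER_VARS}
    dates = pd.to_datetime(out["date"])
    for i, (_, row) in enumerate(out.iterrows()):
        d2 = ((st_xy - np.array([row["x"], row["y"]])) ** 2).sum(axis=1)
        sid = st_ids[int(np.argmin(d2))]  # argmin takes the first (= lowest id) on ties
        w = by_station[sid]
        date = dates.iloc[i]
        want = pd.date_range(date - pd.Timedelta(days=14), date - pd.Timedelta(days=1))
        missing = want.difference(w.index)
        if len(missing):
            raise ValueError(
                f"sample {row.get('sample_id', i)!r}: weather station {sid} lacks "
                f"dates {[str(d.date()) for d in missing]}")
        window = w.loc[want]
        for v in WEATHER_VARS:
            means[v][i] = window[v].mean()
    for v in WEATHER_VARS:
        out[f"w14_{v}"] = means[v]
    return out
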