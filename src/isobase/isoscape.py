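"""Ordinary-kriging isoscapes from soil point samples.

The environmental baseline surface is estimated in three steps: an empirical
(Matheron) semivariogram of the soil isotope values, a weighted least-squares
fit of a permissible variogram model (spherical, exponential or Gaussian),
and global ordinary kriging — the best linear unbiased predictor whose
weights are constrained to sum to one — evaluated at arbitrary points or over
a grid. Kriging is global (every sample enters every system): with at most a
few hundred soil samples there is no need for a search neighbourhood, and
global systems avoid neighbourhood-boundary artefacts.

Semivariogram convention: gamma_model(0) = 0; the nugget c0 enters as the
limit h -> 0+. All three families are monotone nondecreasing in lag h.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

logger = logging.getLogger(__name__)

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram: nugget + partial sill + range.

    gamma(h) = c0 + c * g(h / a) for h > 0, gamma(0) = 0, where g is the
    unit-sill correlation-complement of the chosen family.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(
                f"unknown variogram family {self.family!r}; "
                f"choose one of {VARIOGRAM_FAMILIES}"
            )
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        """Total sill c0 + c (the field variance)."""
        return self.nugget + self.partial_sill

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """Semivariance gamma(h); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        hr = h / self.range_
        if self.family == "spherical":
            g = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
        elif self.family == "exponential":
            g = 1.0 - np.exp(-3.0 * hr)
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * hr**2)
        gamma = self.nugget + self.partial_sill * g
        return np.where(h == 0.0, 0.0, gamma)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) (C(0) = sill)."""
        h = np.asarray(h, dtype=float)
        return np.where(h == 0.0, self.sill, self.sill - self(h))


@dataclass
class EmpiricalVariogram:
    """Binned Matheron semivariogram estimate."""

    lag_center: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    max_lag: float

    def __post_init__(self) -> None:
        if np.any(self.gamma < 0):
            raise ValueError("semivariance must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported bin needs >= 1 pair")
        if np.any(np.diff(self.lag_center) <= 0):
            raise ValueError("lag centers must be strictly increasing")


@dataclass
class GridSpec:
    """Regular grid: origin at the lower-left corner, row 0 = southmost row."""

    x_origin: float
    y_origin: float
    cell_size: float
    n_cols: int
    n_rows: int

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of cell-centre coordinates, row-major."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing the points; clipped to the grid."""
        col = np.clip(((np.asarray(x) - self.x_origin) // self.cell_size).astype(int),
                      0, self.n_cols - 1)
        row = np.clip(((np.asarray(y) - self.y_origin) // self.cell_size).astype(int),
                      0, self.n_rows - 1)
        return row, col


@dataclass
class IsoscapeRaster:
    """Kriged prediction surface plus kriging variance for one isotope."""

    grid: GridSpec
    prediction: np.ndarray
    kriging_variance: np.ndarray
    isotope: str = ""

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.prediction.shape != shape or self.kriging_variance.shape != shape:
            raise ValueError(f"raster shape must be {shape}")
        if np.any(self.kriging_variance < 0):
            raise ValueError("kriging variance must be >= 0 everywhere")


def _coords_values(samples: pd.DataFrame, value_column: str) -> tuple[np.ndarray, np.ndarray]:
    coords = samples[["x", "y"]].to_numpy(dtype=float)
    values = samples[value_column].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("sample coordinates must be finite")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"column {value_column!r} contains non-finite values")
    return coords, values


def dedupe_samples(samples: pd.DataFrame, value_columns: tuple[str, ...] = ("d13C", "d15N")) -> pd.DataFrame:
    """Average rows that share identical coordinates (logged when it happens)."""
    n0 = len(samples)
    cols = [c for c in value_columns if c in samples.columns]
    out = samples.groupby(["x", "y"], as_index=False, sort=False)[cols].mean()
    if len(out) < n0:
        logger.warning("averaged %d duplicate-coordinate soil samples", n0 - len(out))
    return out


def empirical_semivariogram(
    samples: pd.DataFrame,
    value_column: str,
    n_lags: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator gamma_hat(h) = (1/2N(h)) * sum (z_i - z_j)^2 per lag bin.

    Bins with zero pairs are omitted; the reported lag of a bin is the mean
    pair distance inside it (not the bin midpoint), so sparse or gridded
    geometries are represented faithfully. Default ``max_lag`` is half the
    maximum pairwise distance.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    coords, values = _coords_values(samples, value_column)
    d = pdist(coords)
    if np.all(d == 0):
        raise ValueError("all sample coordinates identical: no pair distances")
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if max_lag <= 0:
        raise ValueError("max_lag must be > 0")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    # pairs at exactly zero distance would be duplicates; include h in (0, max_lag]
    which = np.digitize(d, edges[1:], right=True)
    keep = (d > 0) & (d <= max_lag)
    gamma, centers, counts = [], [], []
    for b in range(n_lags):
        m = keep & (which == b)
        n = int(m.sum())
        if n == 0:
            continue
        gamma.append(sq[m].mean())
        centers.append(d[m].mean())
        counts.append(n)
    return EmpiricalVariogram(
        lag_center=np.array(centers),
        gamma=np.array(gamma),
        n_pairs=np.array(counts),
        max_lag=float(max_lag),
    )


@dataclass
class VariogramFit:
    model: VariogramModel
    objective: float
    pure_nugget: bool
    n_bins: int
    message: str = ""


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramFit:
    """Weighted least-squares variogram fit with Cressie weights n_pairs(h)/h^2.

    Multi-start trust-region optimisation over (c0, c, a) with the positivity
    constraints built in. Raises if no start converges.
    """
    h = emp.lag_center
    g = emp.gamma
    npairs = emp.n_pairs
    if len(h) < 3:
        raise ValueError("need >= 3 occupied lag bins to fit a variogram")
    w = np.sqrt(npairs / h**2)

    def resid(p: np.ndarray) -> np.ndarray:
        m = VariogramModel(family, p[0], p[1], p[2])
        return w * (m(h) - g)

    sill0 = max(float(g[-3:].mean()), 1e-12)
    c0_0 = min(max(float(g[0]) * 0.5, 0.0), sill0)
    a_cands = [h.max() * f for f in (0.25, 0.5, 0.9, 1.5)]
    best = None
    for a0 in a_cands:
        try:
            res = least_squares(
                resid,
                x0=np.array([c0_0, max(sill0 - c0_0, 1e-12), a0]),
                bounds=([0.0, 0.0, 1e-12 * h.max()], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # singular jacobian etc.; try the next start
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"variogram fit failed to converge for family={family!r} "
            f"(bins={len(h)}, sill guess={sill0:.4g})"
        )
    c0, c, a = best.x
    sill = c0 + c
    pure_nugget = sill > 0 and c < 1e-6 * sill
    if pure_nugget:
        logger.warning("variogram fit is pure nugget (c ~ 0); range is unidentified")
    model = VariogramModel(family, float(c0), float(c), float(max(a, 1e-12)))
    return VariogramFit(
        model=model,
        objective=float(2.0 * best.cost),
        pure_nugget=pure_nugget,
        n_bins=len(h),
        message=best.message,
    )


def _check_no_duplicates(coords: np.ndarray) -> None:
    if len(np.unique(coords, axis=0)) < len(coords):
        raise ValueError(
            "duplicate sample coordinates make the kriging matrix singular; "
            "deduplicate first (see dedupe_samples)"
        )


def _kriging_lhs(coords: np.ndarray, model: VariogramModel):
    n = len(coords)
    gamma = model(squareform(pdist(coords)))
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = gamma
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    return lu_factor(lhs)


def krige_points(
    samples: pd.DataFrame,
    model: VariogramModel,
    targets: np.ndarray,
    value_column: str = "value",
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging at arbitrary target coordinates.

    Solves [Gamma 1; 1' 0][w; mu] = [gamma0; 1] per target. Returns
    (prediction, kriging variance) arrays. Weights sum to one by construction;
    tiny negative variances (numerical) are clamped to zero with a warning.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to krige")
    coords, values = _coords_values(samples, value_column)
    _check_no_duplicates(coords)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(coords)
    factor = _kriging_lhs(coords, model)
    g0 = model(cdist(coords, targets))  # (n, m)
    rhs = np.vstack([g0, np.ones(targets.shape[0])])
    sol = lu_solve(factor, rhs)  # (n+1, m)
    w, mu = sol[:n, :], sol[n, :]
    pred = w.T @ values
    var = np.einsum("ij,ij->j", w, g0) + mu
    neg = var < 0
    if np.any(neg):
        worst = float(var.min())
        if worst < -1e-6 * max(model.sill, 1.0):
            raise RuntimeError(f"kriging variance substantially negative ({worst:.3g})")
        warnings.warn(f"clamping {int(neg.sum())} slightly negative kriging variances to 0")
        var = np.where(neg, 0.0, var)
    return pred, var


def kriging_weights(
    samples: pd.DataFrame, model: VariogramModel, target: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Kriging weights and Lagrange multiplier for a single target (diagnostic)."""
    coords = samples[["x", "y"]].to_numpy(dtype=float)
    _check_no_duplicates(coords)
    factor = _kriging_lhs(coords, model)
    g0 = model(cdist(coords, np.atleast_2d(target))).ravel()
    sol = lu_solve(factor, np.append(g0, 1.0))
    return sol[:-1], float(sol[-1])


def krige_grid(
    samples: pd.DataFrame,
    model: VariogramModel,
    grid: GridSpec,
    value_column: str = "value",
    isotope: str = "",
) -> IsoscapeRaster:
    """Ordinary kriging at every cell centre of a regular grid."""
    pred, var = krige_points(samples, model, grid.cell_centers(), value_column)
    shape = (grid.n_rows, grid.n_cols)
    return IsoscapeRaster(
        grid=grid,
        prediction=pred.reshape(shape),
        kriging_variance=var.reshape(shape),
        isotope=isotope,
    )


@dataclass
class CrossValidation:
    predicted: np.ndarray
    observed: np.ndarray
    kriging_variance: np.ndarray
    standardized_error: np.ndarray
    rmse: float
    mean_standardized_error: float


def loo_cross_validate(
    samples: pd.DataFrame, model: VariogramModel, value_column: str = "value",
) -> CrossValidation:
    """Leave-one-out kriging: each sample predicted from the remaining n-1."""
    if len(samples) < 4:
        raise ValueError("need at least 4 samples for leave-one-out validation")
    coords, values = _coords_values(samples, value_column)
    _check_no_duplicates(coords)
    n = len(coords)
    preds = np.empty(n)
    variances = np.empty(n)
    for i in range(n):
        rest = samples.drop(samples.index[i])
        p, v = krige_points(rest, model, coords[i], value_column)
        preds[i], variances[i] = p[0], v[0]
    err = preds - values
    with np.errstate(divide="ignore", invalid="ignore"):
        std_err = np.where(variances > 0, err / np.sqrt(variances), 0.0)
    return CrossValidation(
        predicted=preds,
        observed=values,
        kriging_variance=variances,
        standardized_error=std_err,
        rmse=float(np.sqrt(np.mean(err**2))),
        mean_standardized_error=float(std_err.mean()),
    )


def write_ascii_grid(path, raster: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid writer (row 0 of the file is the northmost row)."""
    arr = np.where(np.isfinite(raster), raster, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin}\n")
        fh.write(f"yllcorner {grid.y_origin}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in arr[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back into (array, GridSpec); NODATA -> NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    grid = GridSpec(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    return arr, grid
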