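"""Evaluation chain: OLS, weather PCA, K-means, penalized-spline smooths.

These are the statistics used to judge whether deducting the soil baseline
sharpens the ecological signal: the d15N ~ d13C regression R-squared, the
number and composition of K-means clusters of (elevation, d13C, d15N), and
smooth-term fits of each isotope against date, elevation and the two weather
principal components — each computed for the uncorrected and corrected tables
and compared.

The smooth is a penalized cubic regression spline (uniform-knot cubic
B-splines, exact integrated-squared-second-derivative penalty, smoothing
parameter by GCV). The penalty null space is the linear functions, so the
infinite-smoothing limit is the OLS line and the spline can never explain
less deviance than OLS on the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import splev
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


# --------------------------------------------------------------------------- OLS

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_se: float


def ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple least squares of y on x with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    dof = len(x) - 2
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=r2, n=len(x),
        residual_se=float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan"),
    )


# --------------------------------------------------------------------------- PCA

@dataclass
class WeatherComponents:
    loadings: np.ndarray          # 5x5, columns orthonormal, PC order
    scores: np.ndarray            # n x 5, centered
    variance_explained: np.ndarray  # eigenvalues, sum = 5 (correlation total)
    columns: tuple[str, ...]

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.scores[:, 1]


def pca_weather(
    weather_means: pd.DataFrame,
    temperature_column: str = "w14_t_mean",
    rainfall_column: str = "w14_rain_mm",
) -> WeatherComponents:
    """PCA of the five 14-day weather means on the correlation matrix.

    The correlation matrix (rather than covariance) puts degC, mm and hours on
    a common footing. Sign convention: PC1 is oriented positively with mean
    temperature ("Temperature" axis), PC2 positively with rainfall ("Climate"
    axis); remaining axes get a max-|loading|-positive convention.
    """
    X = weather_means.to_numpy(dtype=float)
    n, p = X.shape
    if n < 6:
        raise ValueError("need n >= 6 rows for the weather PCA")
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant column {weather_means.columns[j]!r}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cols = tuple(weather_means.columns)
    i_t = cols.index(temperature_column)
    i_r = cols.index(rainfall_column)
    if eigvec[i_t, 0] < 0:
        eigvec[:, 0] *= -1
    if eigvec[i_r, 1] < 0:
        eigvec[:, 1] *= -1
    for j in range(2, p):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    scores = Z @ eigvec
    return WeatherComponents(
        loadings=eigvec, scores=scores,
        variance_explained=np.clip(eigval, 0.0, None), columns=cols,
    )


# ----------------------------------------------------------------------- K-means

@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray       # labels in 1..k
    centers: np.ndarray           # in standardized feature space
    total_within_ss: float
    silhouette_mean: float
    crosstab: pd.DataFrame | None


def _standardize(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    sd = features.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (features - features.mean(axis=0)) / sd


def kmeans_cluster(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    land_class: np.ndarray | None = None,
) -> ClusterResult:
    """Best-of-restarts Lloyd K-means on z-standardized features."""
    Z = _standardize(features)
    n = len(Z)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31),
                algorithm="lloyd")
    labels = km.fit_predict(Z) + 1
    sil = float(silhouette_score(Z, labels)) if 1 < k < n else float("nan")
    crosstab = None
    if land_class is not None:
        crosstab = pd.crosstab(pd.Series(land_class, name="land_class"),
                               pd.Series(labels, name="cluster"))
    return ClusterResult(
        k=k, assignments=labels, centers=km.cluster_centers_,
        total_within_ss=float(km.inertia_), silhouette_mean=sil, crosstab=crosstab,
    )


def select_k(
    features: np.ndarray,
    k_max: int = 10,
    seed: int = 0,
    n_restarts: int = 25,
) -> tuple[int, dict]:
    """Choose K by mean-silhouette maximization over k = 2..k_max.

    Also returns the within-cluster-SS curve (the elbow diagnostic) for
    inspection; the silhouette decides.
    """
    Z = _standardize(features)
    n = len(Z)
    if not 2 <= k_max < n:
        raise ValueError(f"need n > k_max >= 2 (n={n}, k_max={k_max})")
    ks = np.arange(2, k_max + 1)
    sil = np.empty(len(ks))
    wss = np.empty(len(ks))
    for i, k in enumerate(ks):
        res = kmeans_cluster(Z, int(k), seed=seed, n_restarts=n_restarts)
        sil[i] = res.silhouette_mean
        wss[i] = res.total_within_ss
    best = int(ks[int(np.argmax(sil))])
    return best, {"k": ks, "silhouette": sil, "wss": wss}


# ---------------------------------------------------------- penalized spline fit

@dataclass
class SmoothFitResult:
    fitted: np.ndarray
    effective_df: float
    f_value: float
    p_value: float
    deviance_explained: float
    smoothing_parameter: float
    basis_dim: int
    grid_x: np.ndarray
    grid_fit: np.ndarray
    degenerate: bool = False


def _bspline_knots(basis_dim: int) -> np.ndarray:
    """Clamped uniform cubic knot vector on [0, 1] for ``basis_dim`` bases."""
    n_interior = basis_dim - 4
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    return np.concatenate([[0.0] * 4, interior, [1.0] * 4])


def _design(t: np.ndarray, knots: np.ndarray, basis_dim: int, der: int = 0) -> np.ndarray:
    B = np.empty((len(t), basis_dim))
    for j in range(basis_dim):
        coef = np.zeros(basis_dim)
        coef[j] = 1.0
        B[:, j] = splev(t, (knots, coef, 3), der=der)
    return B


def _second_derivative_penalty(knots: np.ndarray, basis_dim: int) -> np.ndarray:
    """Exact P_ij = integral of B_i'' B_j'' over [0, 1].

    Second derivatives of cubic B-splines are piecewise linear, so 2-point
    Gauss-Legendre per knot interval integrates their products exactly.
    """
    P = np.zeros((basis_dim, basis_dim))
    breaks = np.unique(knots)
    gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        pts = mid + half * gauss_x
        D2 = _design(pts, knots, basis_dim, der=2)
        P += half * (D2.T @ D2)  # both Gauss weights are 1
    return P


def fit_smooth(x: np.ndarray, y: np.ndarray, basis_dim: int = 10) -> SmoothFitResult:
    """Penalized cubic regression spline of y on x with GCV-chosen smoothing.

    The smooth term is tested against the intercept-only model with a
    Wald-type approximate F statistic using the effective degrees of freedom
    (trace of the smoother matrix minus one) as numerator df. Deviance
    explained is 1 - RSS/TSS. Exactly linear data collapse to the OLS line
    (effective df -> 1): ties in GCV are broken toward heavier smoothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    n_distinct = len(np.unique(x))
    if basis_dim < 4:
        raise ValueError("cubic spline needs basis_dim >= 4")
    if n_distinct < basis_dim:
        new_dim = max(n_distinct, 4)
        warnings.warn(
            f"only {n_distinct} distinct x values; reducing basis_dim "
            f"{basis_dim} -> {new_dim}")
        basis_dim = new_dim
    if n < basis_dim + 2:
        raise ValueError(f"need n >= basis_dim + 2 = {basis_dim + 2}")
    span = x.max() - x.min()
    if span == 0:
        raise ValueError("x is constant")
    t = (x - x.min()) / span
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    knots = _bspline_knots(basis_dim)
    B = _design(t, knots, basis_dim)
    P = _second_derivative_penalty(knots, basis_dim)
    BtB = B.T @ B
    Bty = B.T @ y
    lam_scale = np.trace(BtB) / max(np.trace(P), 1e-300)
    lam_grid = lam_scale * np.logspace(8, -8, 65)  # descending: smoother wins ties
    best = None
    for lam in lam_grid:
        A = BtB + lam * P
        try:
            coef = np.linalg.solve(A, Bty)
            tr_S = float(np.trace(np.linalg.solve(A, BtB)))
        except np.linalg.LinAlgError:
            continue
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        denom = max(n - tr_S, 1e-8)
        # floor RSS so that numerically perfect fits tie across lambda and the
        # descending grid resolves the tie toward the heaviest smoothing
        gcv = n * max(rss, 1e-12 * ss_tot) / denom**2
        if best is None or gcv < best["gcv"] * (1.0 - 1e-9):
            best = {"gcv": gcv, "lam": lam, "coef": coef, "tr_S": tr_S,
                    "fitted": fitted, "rss": rss}
    if best is None:
        raise RuntimeError("penalized spline fit failed at every smoothing value")
    tr_S = min(max(best["tr_S"], 2.0), float(basis_dim))
    edf = tr_S - 1.0
    rss = best["rss"]
    degenerate = ss_tot <= 1e-12 * max(1.0, float(np.sum(y**2)))
    if degenerate:
        dev_expl, f_value, p_value = 0.0, 0.0, 1.0
    else:
        dev_expl = min(max(1.0 - rss / ss_tot, 0.0), 1.0)
        df_den = max(n - tr_S, 1e-8)
        if rss <= 1e-14 * ss_tot:
            f_value, p_value = float("inf"), 0.0
        else:
            f_value = max(((ss_tot - rss) / edf) / (rss / df_den), 0.0)
            p_value = float(sps.f.sf(f_value, edf, df_den))
    grid_t = np.linspace(0.0, 1.0, 200)
    grid_fit = _design(grid_t, knots, basis_dim) @ best["coef"]
    return SmoothFitResult(
        fitted=best["fitted"], effective_df=float(edf), f_value=float(f_value),
        p_value=float(p_value), deviance_explained=float(dev_expl),
        smoothing_parameter=float(best["lam"]), basis_dim=basis_dim,
        grid_x=x.min() + grid_t * span, grid_fit=grid_fit, degenerate=degenerate,
    )


def fit_linear_term(x: np.ndarray, y: np.ndarray) -> SmoothFitResult:
    """Unpenalized linear-term fit reported in the same shape as a smooth.

    The 'correlating' counterpart of the smooth: a one-df linear effect with
    the standard regression F-test against the intercept-only model.
    """
    reg = ols(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = reg.intercept + reg.slope * x
    rss = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(x)
    degenerate = ss_tot <= 0
    if degenerate or rss <= 1e-14 * ss_tot:
        f_value = float("inf") if not degenerate else 0.0
        p_value = 0.0 if not degenerate else 1.0
    else:
        f_value = ((ss_tot - rss) / 1.0) / (rss / (n - 2))
        p_value = float(sps.f.sf(f_value, 1, n - 2))
    grid_x = np.linspace(x.min(), x.max(), 200)
    return SmoothFitResult(
        fitted=fitted, effective_df=1.0, f_value=float(f_value), p_value=p_value,
        deviance_explained=float(min(max(1.0 - rss / ss_tot, 0.0), 1.0)) if ss_tot > 0 else 0.0,
        smoothing_parameter=float("inf"), basis_dim=2,
        grid_x=grid_x, grid_fit=reg.intercept + reg.slope * grid_x,
        degenerate=degenerate,
    )


# ------------------------------------------------------------------- comparison

ISOTOPES = ("d13C", "d15N")
DEFAULT_COVARIATES = ("date", "elevation_m", "PC1", "PC2")


@dataclass
class DatasetEvaluation:
    r_squared: float
    regression: RegressionResult
    k: int
    cluster: ClusterResult | None
    smooths: dict[tuple[str, str], SmoothFitResult] = field(default_factory=dict)
    linear_terms: dict[tuple[str, str], SmoothFitResult] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    uncorrected: DatasetEvaluation
    corrected: DatasetEvaluation
    covariates: tuple[str, ...]
    improved: dict[str, bool] = field(default_factory=dict)

    def flag_improvements(self) -> None:
        self.improved["r_squared"] = (
            self.corrected.r_squared > self.uncorrected.r_squared)
        for key, fit in self.corrected.smooths.items():
            self.improved[f"smooth_F:{key[0]}:{key[1]}"] = (
                fit.f_value > self.uncorrected.smooths[key].f_value)


def _covariate_vector(table: pd.DataFrame, name: str) -> np.ndarray:
    col = table[name]
    if name == "date":
        return (pd.to_datetime(col) - pd.to_datetime(col).min()).dt.days.to_numpy(float)
    return col.to_numpy(dtype=float)


def evaluate_dataset(
    table: pd.DataFrame,
    d13C_col: str,
    d15N_col: str,
    covariates: tuple[str, ...],
    k_max: int = 10,
    basis_dim: int = 10,
    seed: int = 0,
    with_clusters: bool = True,
) -> DatasetEvaluation:
    """All evaluation statistics for one dataset (one correction state)."""
    d13C = table[d13C_col].to_numpy(dtype=float)
    d15N = table[d15N_col].to_numpy(dtype=float)
    reg = ols(d13C, d15N)  # d15N regressed on d13C; R^2 is orientation-free
    k, cluster = 0, None
    if with_clusters:
        feats = np.column_stack([table["elevation_m"].to_numpy(float), d13C, d15N])
        k, _ = select_k(feats, k_max=min(k_max, len(table) - 1), seed=seed)
        cluster = kmeans_cluster(feats, k, seed=seed,
                                 land_class=table["land_class"].to_numpy())
    ev = DatasetEvaluation(r_squared=reg.r_squared, regression=reg, k=k, cluster=cluster)
    for cov in covariates:
        xv = _covariate_vector(table, cov)
        for iso_name, yv in (("d13C", d13C), ("d15N", d15N)):
            ev.smooths[(iso_name, cov)] = fit_smooth(xv, yv, basis_dim=basis_dim)
            ev.linear_terms[(iso_name, cov)] = fit_linear_term(xv, yv)
    return ev


def compare_signal(
    uncorrected: pd.DataFrame,
    corrected: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    k_max: int = 10,
    basis_dim: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Paired uncorrected-vs-corrected evaluation of one dataset.

    ``uncorrected`` and ``corrected`` must be row-aligned views of the same
    samples; ``corrected`` carries the baseline-deducted isotope columns.
    """
    if len(uncorrected) != len(corrected):
        raise ValueError("uncorrected and corrected tables must be row-aligned")
    ev_u = evaluate_dataset(uncorrected, "d13C", "d15N", covariates,
                            k_max=k_max, basis_dim=basis_dim, seed=seed)
    ev_c = evaluate_dataset(corrected, "corr_d13C", "corr_d15N", covariates,
                            k_max=k_max, basis_dim=basis_dim, seed=seed)
    report = EvaluationReport(uncorrected=ev_u, corrected=ev_c, covariates=covariates)
    report.flag_improvements()
    return report
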