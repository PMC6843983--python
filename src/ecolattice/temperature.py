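"""Year-over-year temperature variation, multi-year trend, and interpolation.

The variation statistic for day k of year t is T(k, t) - T(k, t-1), the
difference from the same calendar day one year earlier (Feb 29 has no such
counterpart and is dropped). Variations are averaged over the study period,
optionally stratified by meteorological season.

The trend model decomposes each daily series into a station intercept, an
annual harmonic, and a shared linear trend; it is fit as an exact conjugate
Bayesian linear regression (Jeffreys prior), so the trend posterior is a
Student-t and credible intervals are closed form.

Station-level variation means are carried to lattice-cell centroids by
Gaussian-process prediction (kriging) under a smoothness-1 Matern
covariance with a nugget.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
    NumericalConditioningError,
)
from .spde import MaternSpec, matern1_correlation

__all__ = [
    "SEASONS",
    "season_of",
    "yoy_differences",
    "summarize_variation",
    "fit_trend",
    "krige_to_cells",
    "TrendFit",
]

SEASONS = ("spring", "summer", "autumn", "winter")
_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

_VARIABLE_COL = {"max": "tmax_c", "min": "tmin_c"}


def season_of(date) -> str:
    """Meteorological season: MAM spring, JJA summer, SON autumn, DJF winter."""
    month = pd.Timestamp(date).month
    return _MONTH_SEASON[month]


def _value_column(variable: str) -> str:
    if variable not in _VARIABLE_COL:
        raise ConfigError(f"variable must be 'max' or 'min', got {variable!r}")
    return _VARIABLE_COL[variable]


def yoy_differences(series: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Same-calendar-day differences year t minus year t-1 for one station.

    Parameters
    ----------
    series
        Frame with columns ``date`` and ``tmax_c``/``tmin_c`` for a single
        station; values may be missing (NaN).
    variable
        ``"max"`` or ``"min"``.

    Returns a frame with columns ``date`` (the day in year t) and ``diff``
    in deg C. Feb 29 is excluded; a pair is emitted only when both years
    have a non-missing value on that calendar day.
    """
    col = _value_column(variable)
    d = pd.to_datetime(series["date"])
    if d.dt.year.nunique() < 2:
        raise InsufficientDataError("series must span at least 2 calendar years")
    work = pd.DataFrame(
        {
            "year": d.dt.year,
            "month": d.dt.month,
            "day": d.dt.day,
            "value": pd.to_numeric(series[col], errors="coerce"),
        }
    )
    work = work[~((work["month"] == 2) & (work["day"] == 29))]
    work = work.dropna(subset=["value"])
    prev = work.rename(columns={"value": "value_prev"}).copy()
    prev["year"] = prev["year"] + 1
    merged = work.merge(prev, on=["year", "month", "day"], how="inner")
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(merged[["year", "month", "day"]]),
            "diff": merged["value"] - merged["value_prev"],
        }
    )
    return out.sort_values("date").reset_index(drop=True)


def summarize_variation(
    differences: pd.DataFrame, stratify: bool = True
) -> pd.DataFrame:
    """Average the daily variations per season and annually.

    Returns one row per stratum with columns ``season`` (the four seasons
    plus ``annual``), ``mean_variation`` (NaN when the stratum is empty)
    and ``n_pairs``.
    """
    if differences is None or "diff" not in differences:
        raise ConfigError("differences frame with a 'diff' column required")
    diffs = differences["diff"].to_numpy(dtype=float)
    seasons = np.array([season_of(x) for x in differences["date"]])
    rows = []
    strata = list(SEASONS) if stratify else []
    for s in strata:
        vals = diffs[seasons == s]
        rows.append(
            {
                "season": s,
                "mean_variation": float(np.mean(vals)) if len(vals) else np.nan,
                "n_pairs": int(len(vals)),
            }
        )
    rows.append(
        {
            "season": "annual",
            "mean_variation": float(np.mean(diffs)) if len(diffs) else np.nan,
            "n_pairs": int(len(diffs)),
        }
    )
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """Posterior summary of the linear temperature trend (Student-t marginal)."""

    variable: str
    trend_mean: float  # deg C per year
    trend_sd: float
    trend_q025: float
    trend_q975: float
    trend5_mean: float  # deg C per 5 years
    trend5_sd: float
    trend5_q025: float
    trend5_q975: float
    harmonic_coefs: dict[str, float]
    station_sd: float
    resid_sd: float
    n_obs: int
    dof: int


def fit_trend(
    stations: pd.DataFrame,
    variable: str,
    n_harmonics: int = 1,
    station_effects: bool = True,
) -> TrendFit:
    """Fit temperature = station intercept + annual harmonic + linear trend.

    Exact Bayesian linear regression under the Jeffreys reference prior
    p(beta, s2) propto 1/s2: the trend's marginal posterior is a Student-t
    centred at the least-squares estimate. Requires >= 2 stations and >= 2
    calendar years of data.
    """
    col = _value_column(variable)
    df = stations.dropna(subset=[col])
    d = pd.to_datetime(df["date"])
    if station_effects and df["station_id"].nunique() < 2:
        raise InsufficientDataError("need at least 2 stations")
    if d.dt.year.nunique() < 2:
        raise InsufficientDataError("need at least 2 calendar years")
    y = df[col].to_numpy(dtype=float)
    t_years = (d - d.min()).dt.days.to_numpy() / 365.25
    t_centered = t_years - t_years.mean()
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if station_effects:
        codes, uniq = pd.factorize(df["station_id"])
        for i in range(len(uniq)):
            cols.append((codes == i).astype(float))
        labels += [f"station[{s}]" for s in uniq]
    else:
        cols.append(np.ones(len(y)))
        labels.append("intercept")
    doy_phase = 2.0 * np.pi * d.dt.dayofyear.to_numpy() / 365.25
    for k in range(1, n_harmonics + 1):
        cols += [np.sin(k * doy_phase), np.cos(k * doy_phase)]
        labels += [f"sin{k}", f"cos{k}"]
    cols.append(t_centered)
    labels.append("trend")
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p:
        raise DegenerateInputError("more parameters than observations")
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        factor = cho_factor(XtX)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("rank-deficient trend design") from exc
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateInputError("rank-deficient trend design")
    bhat = cho_solve(factor, Xty)
    resid = y - X @ bhat
    dof = n - p
    s2 = float(resid @ resid) / dof
    cov = s2 * cho_solve(factor, np.eye(p))
    it = labels.index("trend")
    se = float(np.sqrt(cov[it, it]))
    tdist = stats.t(df=dof, loc=bhat[it], scale=se)
    post_sd = se * np.sqrt(dof / (dof - 2)) if dof > 2 else np.inf
    q025, q975 = tdist.ppf([0.025, 0.975])
    harm = {lab: float(bhat[labels.index(lab)]) for lab in labels if lab[:3] in ("sin", "cos")}
    if station_effects:
        st = np.array([bhat[i] for i, lab in enumerate(labels) if lab.startswith("station[")])
        station_sd = float(np.std(st, ddof=1)) if len(st) > 1 else 0.0
    else:
        station_sd = 0.0
    return TrendFit(
        variable=variable,
        trend_mean=float(bhat[it]),
        trend_sd=post_sd,
        trend_q025=float(q025),
        trend_q975=float(q975),
        trend5_mean=float(5.0 * bhat[it]),
        trend5_sd=5.0 * post_sd,
        trend5_q025=float(5.0 * q025),
        trend5_q975=float(5.0 * q975),
        harmonic_coefs=harm,
        station_sd=station_sd,
        resid_sd=float(np.sqrt(s2)),
        n_obs=n,
        dof=dof,
    )


def _kriging_system(pts: np.ndarray, z: np.ndarray, spec: MaternSpec, nugget_sd: float):
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    K = spec.sd**2 * matern1_correlation(d, spec.range_m)
    K[np.diag_indices(len(pts))] = spec.sd**2 + nugget_sd**2
    try:
        factor = cho_factor(K)
    except np.linalg.LinAlgError as exc:
        raise NumericalConditioningError(
            "kriging covariance is singular (duplicate stations with zero nugget?)"
        ) from exc
    ones = np.ones(len(pts))
    Ki1 = cho_solve(factor, ones)
    mean = float(ones @ cho_solve(factor, z) / (ones @ Ki1))
    alpha = cho_solve(factor, z - mean)
    return factor, mean, alpha


def _neg_log_marglik(logpar, pts, z):
    rho, sd, nug = np.exp(logpar)
    try:
        spec = MaternSpec(range_m=rho, sd=sd)
        factor, mean, alpha = _kriging_system(pts, z, spec, nug)
    except (NumericalConditioningError, ConfigError):
        return 1e10
    resid = z - mean
    quad = float(resid @ alpha)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return 0.5 * (quad + logdet + len(z) * np.log(2.0 * np.pi))


def krige_to_cells(
    station_values: pd.DataFrame,
    cells: pd.DataFrame,
    spec: MaternSpec | None = None,
    nugget_sd: float = 0.0,
    estimate: bool = False,
) -> pd.DataFrame:
    """Predict a station-level quantity at cell centroids by kriging.

    Parameters
    ----------
    station_values
        Frame with columns ``x``, ``y``, ``value`` (one row per station).
    cells
        Frame with centroid columns ``x``, ``y``.
    spec, nugget_sd
        Matern covariance hyperparameters; required unless ``estimate``.
    estimate
        Maximum-likelihood estimation of (range, sd, nugget) from the
        station values (the supplied values, if any, are the initial guess).

    The spatial mean is a constant estimated by generalised least squares
    and then treated as known, so the conditional sd is 0 at a station when
    the nugget is 0 and never exceeds the prior sd.

    Returns a frame with columns ``mean`` and ``sd`` aligned with ``cells``.
    """
    pts = station_values[["x", "y"]].to_numpy(dtype=float)
    z = station_values["value"].to_numpy(dtype=float)
    if len(pts) < 3:
        raise InsufficientDataError("kriging needs at least 3 stations")
    if estimate:
        span = float(np.ptp(pts, axis=0).max()) or 1.0
        sd0 = float(np.std(z, ddof=1)) or 1.0
        x0 = np.log(
            [
                spec.range_m if spec else span / 3.0,
                spec.sd if spec and spec.sd > 0 else sd0,
                nugget_sd if nugget_sd > 0 else 0.3 * sd0,
            ]
        )
        res = minimize(_neg_log_marglik, x0, args=(pts, z), method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400})
        rho, sd, nugget_sd = np.exp(res.x)
        spec = MaternSpec(range_m=float(rho), sd=float(sd))
    if spec is None:
        raise ConfigError("a MaternSpec is required when estimate=False")
    if spec.sd <= 0:
        raise ConfigError("kriging requires positive field sd")
    factor, mean, alpha = _kriging_system(pts, z, spec, nugget_sd)
    cx = cells[["x", "y"]].to_numpy(dtype=float)
    dcross = np.linalg.norm(cx[:, None] - pts[None, :], axis=2)
    kstar = spec.sd**2 * matern1_correlation(dcross, spec.range_m)
    pred = mean + kstar @ alpha
    var = spec.sd**2 - np.einsum("ij,ji->i", kstar, cho_solve(factor, kstar.T))
    var = np.clip(var, 0.0, None)
    return pd.DataFrame({"mean": pred, "sd": np.sqrt(var)}, index=cells.index)
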