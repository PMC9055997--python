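"""Model evaluation: fit statistics, standardized residuals, crown-width
curve simulation across covariate levels, and the SRD-SHGN cross-index
regression.

Fit statistics follow the usual conventions:

* ``AIC = -2 ln L + 2 p``
* ``R_a^2 = 1 - (n - 1) / (n - p - 1) * RSS / TSS``
* ``RMSE = sqrt(RSS / n)``, ``MAE = mean |e|``,
  ``MAPE = mean |e| / observed`` (reported as a fraction, not percent).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stem_map import PlotSummary, ValidationError

__all__ = [
    "FitStats",
    "fit_stats",
    "standardized_residuals",
    "simulate_cw_curves",
    "cross_index_regression",
]


@dataclass
class FitStats:
    """Goodness-of-fit summary for one fitted model."""

    aic: float | None
    r2_adj: float
    rmse: float
    mae: float
    mape: float  # fraction; NaN when any observed value is zero
    n: int
    p: int

    def as_dict(self) -> dict[str, float]:
        return {
            "aic": np.nan if self.aic is None else self.aic,
            "r2_adj": self.r2_adj,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "n": self.n,
            "p": self.p,
        }


def fit_stats(
    observed: Sequence[float],
    predicted: Sequence[float],
    p: int,
    loglik: float | None = None,
) -> FitStats:
    """Compute AIC (when ``loglik`` is given), adjusted R^2, RMSE, MAE and
    MAPE for paired observed/predicted values.

    For a fitted model (``p >= 1``) requires ``n > p + 1`` so the adjusted
    R^2 denominator is positive; with ``p = 0`` the error summaries are
    computed for any n and the adjusted R^2 is NaN when undefined.
    MAPE is undefined (NaN) when any observed value is zero.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = obs.size
    if p >= 1 and n <= p + 1:
        raise ValidationError(f"need n > p + 1 (n={n}, p={p})")
    resid = obs - pred
    rss = float(resid @ resid)
    tss = float(((obs - obs.mean()) ** 2).sum())
    r2_adj = (
        1.0 - (n - 1) / (n - p - 1) * (rss / tss) if tss > 0 and n > p + 1 else np.nan
    )
    mape = float(np.mean(np.abs(resid) / np.abs(obs))) if np.all(obs != 0) else np.nan
    return FitStats(
        aic=None if loglik is None else float(-2.0 * loglik + 2.0 * p),
        r2_adj=float(r2_adj),
        rmse=float(np.sqrt(rss / n)),
        mae=float(np.mean(np.abs(resid))),
        mape=mape,
        n=n,
        p=p,
    )


def gaussian_loglik(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Maximized Gaussian log-likelihood with sigma^2 profiled at RSS/n."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    n = obs.size
    s2 = float(np.mean((obs - pred) ** 2))
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def standardized_residuals(model: Any, frame: pd.DataFrame) -> pd.DataFrame:
    """Residuals divided by their modeled standard deviation.

    ``model`` is any fitted object exposing ``predict(frame)`` and
    ``residual_sd(frame)`` — a plain nonlinear least-squares fit divides by
    its single sigma, a mixed model with a variance function divides by
    ``sigma * sqrt(lambda(D))`` and predicts at the group level.
    Returns a table of (fitted, std_resid) pairs ready for plotting.
    """
    try:
        fitted = model.predict(frame, mode="group")
    except TypeError:
        fitted = model.predict(frame)
    sd = np.asarray(model.residual_sd(frame), dtype=float)
    resid = frame["cw"].to_numpy(float) - np.asarray(fitted, float)
    return pd.DataFrame({"fitted": fitted, "std_resid": resid / sd})


def simulate_cw_curves(
    model: Any,
    vary: str,
    levels: Sequence[float],
    held: dict[str, float] | None = None,
    d_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Predicted crown-width vs DBH curves at several levels of one
    covariate, the others held fixed.

    ``vary`` is one of ``ci``, ``th``, ``hcb``; defaults hold TH = 25 m,
    CI = 45 and HCB = 4 m while six roughly equal-interval levels of the
    varied covariate are traced over the DBH grid.  Output is one row per
    (level, d) pair with the predicted CW, produced by the model's own
    ``predict`` (population mode for mixed models).
    """
    vary = vary.lower()
    if vary not in ("ci", "th", "hcb"):
        raise ValidationError(f"vary must be one of ci/th/hcb, got {vary!r}")
    base = {"th": 25.0, "ci": 45.0, "hcb": 4.0}
    base.update({k.lower(): v for k, v in (held or {}).items()})
    if d_grid is None:
        d_grid = np.linspace(1.0, 46.3, 100)
    d_grid = np.asarray(d_grid, dtype=float)
    rows = []
    for lev in levels:
        cov = dict(base)
        cov[vary] = float(lev)
        frame = pd.DataFrame(
            {
                "d": d_grid,
                "th": np.full_like(d_grid, cov["th"]),
                "hcb": np.full_like(d_grid, cov["hcb"]),
                "ci": np.full_like(d_grid, cov["ci"]),
            }
        )
        try:
            cw = model.predict(frame, mode="population")
        except TypeError:
            cw = model.predict(frame)
        rows.append(
            pd.DataFrame({"level": float(lev), "d": d_grid, "cw": np.asarray(cw, float)})
        )
    return pd.concat(rows, ignore_index=True)


def cross_index_regression(
    summaries: pd.DataFrame | Sequence[PlotSummary],
    x: str = "SRD",
    y: str = "SHGN",
) -> tuple[float, float, float]:
    """Ordinary least squares of one plot-level competition index on
    another (default SHGN on SRD); returns (slope, intercept, r2).

    The distance-free SRD tracks the spatially explicit SHGN closely in
    practice, which is what makes the non-spatial index a usable surrogate.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame(
            [{x: s.ci_values[x], y: s.ci_values[y]} for s in summaries]
        )
    if len(summaries) < 3:
        raise ValidationError("need at least 3 plots for the cross-index regression")
    xv = summaries[x].to_numpy(float)
    yv = summaries[y].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValidationError(f"{x} is constant across plots; regression degenerate")
    res = sps.linregress(xv, yv)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
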