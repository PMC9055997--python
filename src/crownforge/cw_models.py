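"""Crown-width vs diameter model forms and nonlinear least-squares fitting.

Twelve classical CW-D shapes are available (linear, power, monomolecular,
Hossfeld, compound/growth/exponential, quadratic, Richards, two logistic
variants, Weibull), identified F1...F12, plus the generalized form G

    CW = (phi1 + phi3*CI + phi4*TH + phi5*HCB) * D^phi2

which augments the power law with a plot competition index (SRD or SHGN),
tree height and height to crown base.  Every form carries an analytic
parameter gradient (used both here and by the mixed-effects machinery) and
a documented self-starting rule, mostly linearizations solved by ordinary
least squares.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stem_map import ConfigurationError, StemMap, ValidationError
from .evaluation import FitStats, fit_stats, gaussian_loglik

__all__ = [
    "ModelForm",
    "FitResult",
    "FORM_IDS",
    "form_arity",
    "evaluate_form",
    "fit_nls",
    "rank_candidates",
    "model_frame",
]


# ---------------------------------------------------------------------------
# Form registry: evaluation, analytic gradient, self-start
# ---------------------------------------------------------------------------
# Each eval/grad takes (phi, d, th, hcb, ci); phi entries may be scalars or
# per-observation arrays (the mixed model substitutes group-specific
# parameters), everything broadcasts.

def _f1(p, d, th, hcb, ci):
    return p[0] + p[1] * d


def _g1(p, d, th, hcb, ci):
    one = np.ones_like(d)
    return [one, d]


def _f2(p, d, th, hcb, ci):
    return p[0] * d ** p[1]


def _g2(p, d, th, hcb, ci):
    dp = d ** p[1]
    return [dp, p[0] * dp * np.log(d)]


def _f3(p, d, th, hcb, ci):
    return p[0] * (1.0 - np.exp(-p[1] * d))


def _g3(p, d, th, hcb, ci):
    e = np.exp(-p[1] * d)
    return [1.0 - e, p[0] * d * e]


def _f4(p, d, th, hcb, ci):
    return (d / (p[0] + p[1] * d)) ** 2


def _g4(p, d, th, hcb, ci):
    s = p[0] + p[1] * d
    return [-2.0 * d**2 / s**3, -2.0 * d**3 / s**3]


def _f5(p, d, th, hcb, ci):
    return p[0] * p[1] ** d


def _g5(p, d, th, hcb, ci):
    return [p[1] ** d, p[0] * d * p[1] ** (d - 1.0)]


def _f6(p, d, th, hcb, ci):
    return np.exp(p[0] + p[1] * d)


def _g6(p, d, th, hcb, ci):
    f = np.exp(p[0] + p[1] * d)
    return [f, d * f]


def _f7(p, d, th, hcb, ci):
    return p[0] * np.exp(p[1] * d)


def _g7(p, d, th, hcb, ci):
    e = np.exp(p[1] * d)
    return [e, p[0] * d * e]


def _f8(p, d, th, hcb, ci):
    return p[0] + p[1] * d + p[2] * d**2


def _g8(p, d, th, hcb, ci):
    return [np.ones_like(d), d, d**2]


def _f9(p, d, th, hcb, ci):
    return p[0] * (1.0 - np.exp(-p[1] * d)) ** p[2]


def _g9(p, d, th, hcb, ci):
    e = np.exp(-p[1] * d)
    base = np.clip(1.0 - e, 1e-12, None)
    f = p[0] * base ** p[2]
    return [base ** p[2], p[0] * p[2] * base ** (p[2] - 1.0) * d * e, f * np.log(base)]


def _f10(p, d, th, hcb, ci):
    return p[0] / (1.0 + p[1] * np.exp(-p[2] * d))


def _g10(p, d, th, hcb, ci):
    e = np.exp(-p[2] * d)
    s = 1.0 + p[1] * e
    return [1.0 / s, -p[0] * e / s**2, p[0] * p[1] * d * e / s**2]


def _f11(p, d, th, hcb, ci):
    return p[0] / (1.0 + np.exp(p[1] + p[2] * np.log(d + 1.0)))


def _g11(p, d, th, hcb, ci):
    L = np.log(d + 1.0)
    e = np.exp(p[1] + p[2] * L)
    s = 1.0 + e
    return [1.0 / s, -p[0] * e / s**2, -p[0] * e * L / s**2]


def _f12(p, d, th, hcb, ci):
    return p[0] * (1.0 - np.exp(-p[1] * d ** p[2]))


def _g12(p, d, th, hcb, ci):
    dp = d ** p[2]
    e = np.exp(-p[1] * dp)
    return [1.0 - e, p[0] * e * dp, p[0] * e * p[1] * dp * np.log(d)]


def _fg(p, d, th, hcb, ci):
    return (p[0] + p[2] * ci + p[3] * th + p[4] * hcb) * d ** p[1]


def _gg(p, d, th, hcb, ci):
    dp = d ** p[1]
    bracket = p[0] + p[2] * ci + p[3] * th + p[4] * hcb
    return [dp, bracket * dp * np.log(d), ci * dp, th * dp, hcb * dp]


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _init_f1(cw, d, th, hcb, ci):
    return _ols(np.column_stack([np.ones_like(d), d]), cw)


def _init_f2(cw, d, th, hcb, ci):
    # log-log linearization: ln CW = ln phi1 + phi2 ln D
    m = cw > 0
    b = _ols(np.column_stack([np.ones_like(d[m]), np.log(d[m])]), np.log(cw[m]))
    return np.array([np.exp(b[0]), b[1]])


def _init_f3(cw, d, th, hcb, ci):
    a = 1.05 * cw.max()
    z = np.clip(1.0 - cw / a, 1e-6, None)
    b = _ols(d[:, None], -np.log(z))
    return np.array([a, max(b[0], 1e-3)])


def _init_f4(cw, d, th, hcb, ci):
    # sqrt linearization: d / sqrt(CW) = phi1 + phi2 d
    b = _ols(np.column_stack([np.ones_like(d), d]), d / np.sqrt(cw))
    return b


def _init_loglinear(cw, d, th, hcb, ci):
    m = cw > 0
    return _ols(np.column_stack([np.ones_like(d[m]), d[m]]), np.log(cw[m]))


def _init_f5(cw, d, th, hcb, ci):
    a, b = _init_loglinear(cw, d, th, hcb, ci)
    return np.array([np.exp(a), np.exp(b)])


def _init_f7(cw, d, th, hcb, ci):
    a, b = _init_loglinear(cw, d, th, hcb, ci)
    return np.array([np.exp(a), b])


def _init_f8(cw, d, th, hcb, ci):
    return _ols(np.column_stack([np.ones_like(d), d, d**2]), cw)


def _init_f9(cw, d, th, hcb, ci):
    a, b = _init_f3(cw, d, th, hcb, ci)
    return np.array([a, b, 1.0])


def _init_f10(cw, d, th, hcb, ci):
    a = 1.05 * cw.max()
    z = np.clip(a / cw - 1.0, 1e-6, None)
    b = _ols(np.column_stack([np.ones_like(d), d]), np.log(z))
    return np.array([a, np.exp(b[0]), max(-b[1], 1e-3)])


def _init_f11(cw, d, th, hcb, ci):
    a = 1.05 * cw.max()
    z = np.clip(a / cw - 1.0, 1e-6, None)
    b = _ols(np.column_stack([np.ones_like(d), np.log(d + 1.0)]), np.log(z))
    return np.array([a, b[0], b[1]])


def _init_f12(cw, d, th, hcb, ci):
    a, b = _init_f3(cw, d, th, hcb, ci)
    return np.array([a, b, 1.0])


def _init_g(cw, d, th, hcb, ci):
    p1, p2 = _init_f2(cw, d, th, hcb, ci)
    return np.array([p1, p2, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class _FormSpec:
    arity: int
    fn: Callable
    grad: Callable
    init: Callable
    requires: tuple[str, ...] = ("d",)
    linear: bool = False  # exactly solvable by ordinary least squares


FORMS: dict[str, _FormSpec] = {
    "F1": _FormSpec(2, _f1, _g1, _init_f1, linear=True),
    "F2": _FormSpec(2, _f2, _g2, _init_f2),
    "F3": _FormSpec(2, _f3, _g3, _init_f3),
    "F4": _FormSpec(2, _f4, _g4, _init_f4),
    "F5": _FormSpec(2, _f5, _g5, _init_f5),
    "F6": _FormSpec(2, _f6, _g6, _init_loglinear),
    "F7": _FormSpec(2, _f7, _g7, _init_f7),
    "F8": _FormSpec(3, _f8, _g8, _init_f8, linear=True),
    "F9": _FormSpec(3, _f9, _g9, _init_f9),
    "F10": _FormSpec(3, _f10, _g10, _init_f10),
    "F11": _FormSpec(3, _f11, _g11, _init_f11),
    "F12": _FormSpec(3, _f12, _g12, _init_f12),
    "G": _FormSpec(5, _fg, _gg, _init_g, requires=("d", "th", "hcb", "ci")),
}

FORM_IDS = tuple(FORMS)
CANDIDATE_IDS = tuple(f"F{i}" for i in range(1, 13))


def form_arity(form_id: str) -> int:
    if form_id not in FORMS:
        raise ConfigurationError(f"unknown form id {form_id!r}")
    return FORMS[form_id].arity


# ---------------------------------------------------------------------------
# Model objects
# ---------------------------------------------------------------------------

@dataclass
class ModelForm:
    """A CW-D function shape with its parameter vector phi.

    ``ci_kind`` records which plot competition index the generalized form's
    CI slot refers to (SRD or SHGN); it is "none" for pure CW-D shapes.
    """

    form_id: str
    phi: np.ndarray = field(default_factory=lambda: np.array([]))
    ci_kind: str = "none"

    def __post_init__(self) -> None:
        spec = FORMS.get(self.form_id)
        if spec is None:
            raise ConfigurationError(f"unknown form id {self.form_id!r}")
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size and self.phi.size != spec.arity:
            raise ConfigurationError(
                f"{self.form_id} needs {spec.arity} parameters, got {self.phi.size}"
            )
        if self.ci_kind not in ("none", "SRD", "SHGN"):
            raise ConfigurationError(f"unknown ci_kind {self.ci_kind!r}")

    @property
    def arity(self) -> int:
        return FORMS[self.form_id].arity

    @property
    def covariates_required(self) -> tuple[str, ...]:
        return FORMS[self.form_id].requires

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return evaluate_form(
            self,
            frame["d"].to_numpy(float),
            th=frame["th"].to_numpy(float) if "th" in frame else None,
            hcb=frame["hcb"].to_numpy(float) if "hcb" in frame else None,
            ci=frame["ci"].to_numpy(float) if "ci" in frame else None,
        )


def evaluate_form(
    model: ModelForm,
    d: np.ndarray | float,
    th: np.ndarray | float | None = None,
    hcb: np.ndarray | float | None = None,
    ci: np.ndarray | float | None = None,
) -> np.ndarray | float:
    """Closed-form evaluation of a model at given covariates (elementwise
    over vector inputs).  Raises if a required covariate is missing."""
    spec = FORMS[model.form_id]
    if model.phi.size != spec.arity:
        raise ConfigurationError(f"{model.form_id} has no fitted parameters")
    supplied = {"d": d, "th": th, "hcb": hcb, "ci": ci}
    for name in spec.requires:
        if supplied[name] is None:
            raise ConfigurationError(f"{model.form_id} requires covariate {name!r}")
    d = np.asarray(d, dtype=float)
    out = spec.fn(model.phi, d, *(np.asarray(v, float) if v is not None else None for v in (th, hcb, ci)))
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares fit."""

    model: ModelForm
    converged: bool
    sigma2: float | None  # residual variance RSS/n
    stats: FitStats | None
    n: int
    message: str = ""

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.model.predict(frame)

    def residual_sd(self, frame: pd.DataFrame) -> np.ndarray:
        return np.full(len(frame), np.sqrt(self.sigma2))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _frame_arrays(data: pd.DataFrame) -> tuple[np.ndarray, ...]:
    cw = data["cw"].to_numpy(float)
    d = data["d"].to_numpy(float)
    th = data["th"].to_numpy(float) if "th" in data else np.zeros_like(d)
    hcb = data["hcb"].to_numpy(float) if "hcb" in data else np.zeros_like(d)
    ci = data["ci"].to_numpy(float) if "ci" in data else np.zeros_like(d)
    return cw, d, th, hcb, ci


def fit_nls(
    form_id: str,
    data: pd.DataFrame,
    init: Sequence[float] | None = None,
    ci_kind: str = "none",
    *,
    with_stats: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """Fit one model form by (weighted-free) nonlinear least squares.

    ``data`` is a model frame with columns cw, d and, for the generalized
    form, th, hcb and ci.  Starting values default to the form's
    self-start linearization; the linear forms F1/F8 are solved exactly.
    Non-convergence is reported in the result, never raised.
    """
    spec = FORMS.get(form_id)
    if spec is None:
        raise ConfigurationError(f"unknown form id {form_id!r}")
    cw, d, th, hcb, ci = _frame_arrays(data)
    n = cw.size
    if n <= spec.arity:
        raise ValidationError(f"need more than {spec.arity} observations, got {n}")

    try:
        phi0 = np.asarray(init, float) if init is not None else spec.init(cw, d, th, hcb, ci)
    except Exception as exc:  # degenerate self-start
        return FitResult(ModelForm(form_id, ci_kind=ci_kind), False, None, None, n, f"init failed: {exc}")

    if spec.linear and init is None:
        phi = phi0  # ordinary least squares is already the global optimum
        success, message = True, "linear least squares"
    else:
        def resid(p):
            with np.errstate(all="ignore"):
                r = spec.fn(p, d, th, hcb, ci) - cw
            return np.where(np.isfinite(r), r, 1e6)

        def jac(p):
            with np.errstate(all="ignore"):
                cols = spec.grad(p, d, th, hcb, ci)
            J = np.column_stack([np.broadcast_to(c, d.shape) for c in cols])
            return np.where(np.isfinite(J), J, 0.0)

        try:
            res = least_squares(
                resid, phi0, jac=jac, method="trf", xtol=tol, ftol=tol, gtol=tol,
                max_nfev=max_iter,
            )
            phi, success, message = res.x, bool(res.success), res.message
            if not np.all(np.isfinite(spec.fn(phi, d, th, hcb, ci))):
                success = False
        except Exception as exc:
            return FitResult(ModelForm(form_id, ci_kind=ci_kind), False, None, None, n, str(exc))

    model = ModelForm(form_id, phi, ci_kind=ci_kind)
    pred = spec.fn(phi, d, th, hcb, ci)
    sigma2 = float(np.mean((cw - pred) ** 2))
    stats = None
    if success and with_stats and n > spec.arity + 2:
        stats = fit_stats(cw, pred, p=spec.arity + 1, loglik=gaussian_loglik(cw, pred))
    return FitResult(model, success, sigma2, stats, n, message)


def rank_candidates(
    calibration: pd.DataFrame,
    validation: pd.DataFrame | None = None,
    forms: Sequence[str] = CANDIDATE_IDS,
) -> pd.DataFrame:
    """Fit every candidate CW-D form on the calibration frame and report
    calibration AIC / R_a^2 / RMSE / MAE / MAPE plus validation statistics.

    Rows are ordered by calibration AIC with non-converged forms last
    (their statistics left as NaN, rendered as dashes downstream).
    """
    rows = []
    for form_id in forms:
        fit = fit_nls(form_id, calibration)
        row: dict[str, object] = {"form_id": form_id, "converged": fit.converged}
        if fit.converged and fit.stats is not None:
            row.update({f"cal_{k}": v for k, v in fit.stats.as_dict().items()
                        if k in ("aic", "r2_adj", "rmse", "mae", "mape")})
            for i, v in enumerate(fit.model.phi, start=1):
                row[f"phi{i}"] = v
            if validation is not None and len(validation):
                vs = fit_stats(
                    validation["cw"].to_numpy(float),
                    fit.model.predict(validation),
                    p=fit.model.arity + 1,
                )
                row.update({f"val_{k}": v for k, v in vs.as_dict().items()
                            if k in ("r2_adj", "rmse", "mae", "mape")})
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table["cal_aic"].fillna(np.inf) if "cal_aic" in table else np.arange(len(table))
    return table.iloc[np.argsort(order, kind="mergesort")].reset_index(drop=True)


def model_frame(
    stem_map: StemMap,
    ci_table: pd.DataFrame | None = None,
    ci_kind: str = "none",
) -> pd.DataFrame:
    """Assemble the per-tree model frame (cw, d, th, hcb, ci, species_group)
    by joining the plot-level competition index onto each tree's plot."""
    df = stem_map.df
    out = pd.DataFrame(
        {
            "cw": df["cw"].to_numpy(float),
            "d": df["dbh"].to_numpy(float),
            "th": df["th"].to_numpy(float),
            "hcb": df["hcb"].to_numpy(float),
            "species_group": df["species_group"].to_numpy(),
            "plot_id": df["plot_id"].to_numpy(),
        }
    )
    if ci_kind != "none":
        if ci_table is None or ci_kind not in ci_table.columns:
            raise ConfigurationError(f"ci_table with column {ci_kind!r} required")
        ci_map = ci_table.set_index("plot_id")[ci_kind]
        out["ci"] = out["plot_id"].map(ci_map).to_numpy(float)
        if out["ci"].isna().any():
            raise ValidationError("trees in plots missing from ci_table")
    return out
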