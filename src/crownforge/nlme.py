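"""Nonlinear mixed-effects estimation with species-level random effects.

The model for tree j of species group i is

    CW_ij = f(phi_i, x_ij) + eps_ij,        phi_i = beta + B b_i,
    b_i ~ N(0, psi),                        eps_ij ~ N(0, sigma^2 * lambda_ij),

where ``f`` is one of the crown-width forms, ``B`` selects the subset of
parameters that carry a random effect, and ``lambda`` is a variance
function of DBH (power ``D^delta``, exponential ``exp(delta*D)``,
constant-plus-power ``(c + D^delta)^2``, or constant).

Estimation alternates two steps until the (linearized, profiled) maximum
likelihood stabilizes, in the spirit of the classical alternating
algorithm for NLME models:

1. **PNLS** — with the variance parameters held fixed, the fixed effects
   and the per-group random effects are the joint penalized weighted
   least-squares minimizer of
   ``sum (y - f)^2 / lambda + sigma^2 * sum b_i' psi^-1 b_i``.
2. **LME** — the model is linearized about the current estimates and the
   resulting linear mixed model's ML criterion, with beta and sigma^2
   profiled out, is maximized over the relative covariance
   ``psi / sigma^2`` (log-Cholesky parameterized, so psi stays positive
   semi-definite) and the variance-function parameters.

A plain maximum-likelihood (not REML) objective is used throughout so AIC
values are comparable across fixed-effects specifications.  The returned
``blups`` are the posterior modes of the group effects from the final
PNLS step.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import least_squares, minimize

from .stem_map import ConfigurationError, ValidationError
from .cw_models import FORMS, ModelForm

logger = logging.getLogger("crownforge")

__all__ = [
    "RandomSpec",
    "VarianceFunction",
    "NLMEControl",
    "FittedMixedModel",
    "nlme_fit",
    "enumerate_random_structures",
    "select_structure",
    "predict_mixed",
]

PARAM_NAMES = ("phi1", "phi2", "phi3", "phi4", "phi5")


@dataclass(frozen=True)
class RandomSpec:
    """Which parameters carry a species-group random effect.

    ``random_subset`` holds parameter names ("phi1".."phi5") or 0-based
    indices; it must be non-empty, giving 2^k - 1 possible specs for a
    k-parameter form (31 for the 5-parameter generalized form).
    """

    random_subset: tuple[int, ...]
    grouping: str = "species_group"

    def __init__(self, random_subset: Sequence[int | str], grouping: str = "species_group"):
        idx = sorted(
            PARAM_NAMES.index(s) if isinstance(s, str) else int(s) for s in random_subset
        )
        if not idx:
            raise ConfigurationError("random_subset must be non-empty")
        if len(set(idx)) != len(idx):
            raise ConfigurationError("random_subset has duplicates")
        object.__setattr__(self, "random_subset", tuple(idx))
        object.__setattr__(self, "grouping", grouping)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(PARAM_NAMES[i] for i in self.random_subset)

    @property
    def q(self) -> int:
        return len(self.random_subset)


@dataclass
class VarianceFunction:
    """Residual heteroscedasticity model var(eps) = sigma^2 * lambda(D).

    kinds: ``constant`` (lambda = 1), ``power`` (D^delta), ``exponential``
    (exp(delta*D)), ``constant_plus_power`` ((c + D^delta)^2).
    """

    kind: str = "power"
    delta: float = 0.0
    const: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "power", "exponential", "constant_plus_power"):
            raise ConfigurationError(f"unknown variance function {self.kind!r}")

    @property
    def n_params(self) -> int:
        return {"constant": 0, "power": 1, "exponential": 1, "constant_plus_power": 2}[self.kind]

    def lam(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.kind == "constant":
            return np.ones_like(d)
        if self.kind == "power":
            if np.any(d <= 0):
                raise ValidationError("power variance function requires D > 0")
            return d**self.delta
        if self.kind == "exponential":
            return np.exp(self.delta * d)
        return (self.const + d**self.delta) ** 2

    # packing for the optimizer -------------------------------------------
    def pack(self) -> np.ndarray:
        if self.kind in ("power", "exponential"):
            return np.array([self.delta])
        if self.kind == "constant_plus_power":
            return np.array([np.log(self.const), self.delta])
        return np.array([])

    def with_packed(self, v: np.ndarray) -> "VarianceFunction":
        if self.kind in ("power", "exponential"):
            return VarianceFunction(self.kind, delta=float(v[0]))
        if self.kind == "constant_plus_power":
            return VarianceFunction(self.kind, delta=float(v[1]), const=float(np.exp(v[0])))
        return VarianceFunction(self.kind)

    def bounds(self) -> list[tuple[float, float]]:
        if self.kind in ("power", "exponential"):
            return [(-8.0, 8.0)]
        if self.kind == "constant_plus_power":
            return [(-8.0, 5.0), (-8.0, 8.0)]
        return []


@dataclass(frozen=True)
class NLMEControl:
    """Convergence control for the alternating estimation."""

    outer_tol: float = 1e-6  # relative log-likelihood change
    max_outer: int = 200
    pnls_tol: float = 1e-9
    pnls_max_nfev: int = 50
    lme_maxiter: int = 100
    ridge: float = 1e-10  # stabilizer for singular relative-covariance updates
    # the alternating scheme is not strictly monotone (inner optimizations
    # stop at finite precision); a sustained no-improvement plateau is
    # treated as convergence
    stall_tol: float = 1e-3
    stall_limit: int = 3


# ---------------------------------------------------------------------------
# log-Cholesky parameterization of the relative covariance psi / sigma^2
# ---------------------------------------------------------------------------

def _chol_unpack(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular L with exp() diagonal from a packed vector."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def _chol_pack(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.array(out)


def _theta_bounds(q: int) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for i in range(q):
        for j in range(i + 1):
            out.append((-12.0, 6.0) if i == j else (-50.0, 50.0))
    return out


# ---------------------------------------------------------------------------
# Fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedMixedModel:
    """A fitted nonlinear mixed-effects crown-width model."""

    form: ModelForm  # phi holds the fixed effects beta
    random_spec: RandomSpec
    varfn: VarianceFunction
    psi: np.ndarray  # q x q random-effects covariance
    sigma2: float
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    loglik: float = np.nan
    aic: float = np.nan
    n_params: int = 0
    n_obs: int = 0
    converged: bool = False
    n_iter: int = 0
    message: str = ""
    ridged: bool = False

    @property
    def fixed(self) -> np.ndarray:
        return self.form.phi

    def predict(self, frame: pd.DataFrame, mode: str = "population") -> np.ndarray:
        return predict_mixed(self, frame, mode=mode)

    def residual_sd(self, frame: pd.DataFrame) -> np.ndarray:
        return np.sqrt(self.sigma2 * self.varfn.lam(frame["d"].to_numpy(float)))

    def to_dict(self) -> dict:
        return {
            "form_id": self.form.form_id,
            "ci_kind": self.form.ci_kind,
            "fixed": self.fixed.tolist(),
            "random_subset": list(self.random_spec.names),
            "psi": self.psi.tolist(),
            "sigma2": self.sigma2,
            "varfn": {"kind": self.varfn.kind, "delta": self.varfn.delta, "const": self.varfn.const},
            "blups": {k: v.tolist() for k, v in self.blups.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedMixedModel":
        return cls(
            form=ModelForm(d["form_id"], np.asarray(d["fixed"]), ci_kind=d.get("ci_kind", "none")),
            random_spec=RandomSpec(d["random_subset"]),
            varfn=VarianceFunction(**d["varfn"]),
            psi=np.asarray(d["psi"]),
            sigma2=float(d["sigma2"]),
            blups={k: np.asarray(v) for k, v in d["blups"].items()},
            loglik=float(d["loglik"]),
            aic=float(d["aic"]),
            n_params=int(d["n_params"]),
            n_obs=int(d["n_obs"]),
            converged=True,
        )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _prepare(data: pd.DataFrame, grouping: str):
    y = data["cw"].to_numpy(float)
    d = data["d"].to_numpy(float)
    th = data["th"].to_numpy(float) if "th" in data else np.zeros_like(d)
    hcb = data["hcb"].to_numpy(float) if "hcb" in data else np.zeros_like(d)
    ci = data["ci"].to_numpy(float) if "ci" in data else np.zeros_like(d)
    if grouping not in data:
        raise ConfigurationError(f"grouping column {grouping!r} missing from data")
    labels, codes = np.unique(data[grouping].to_numpy(), return_inverse=True)
    return y, d, th, hcb, ci, labels, codes


def _phi_obs(beta: np.ndarray, b: np.ndarray, codes: np.ndarray, subset: tuple[int, ...]) -> np.ndarray:
    phi = np.tile(beta, (codes.size, 1))
    phi[:, list(subset)] += b[codes]
    return phi


def _eval_grad(spec, phi: np.ndarray, d, th, hcb, ci):
    p = [phi[:, j] for j in range(phi.shape[1])]
    with np.errstate(all="ignore"):
        f = spec.fn(p, d, th, hcb, ci)
        g = spec.grad(p, d, th, hcb, ci)
    G = np.column_stack([np.broadcast_to(c, d.shape) for c in g])
    return f, G


_BIG = 1e10  # finite sentinel for infeasible variance parameters


def _moment_delta(resid: np.ndarray, d: np.ndarray, kind: str) -> float:
    """Crude variance-function exponent from a log-residual regression,
    used only to seed the LME optimizer away from poor local optima."""
    r2 = np.log(np.clip(resid**2, 1e-12, None))
    x = np.log(d) if kind == "power" else d
    X = np.column_stack([np.ones_like(x), x])
    slope = float(np.linalg.lstsq(X, r2, rcond=None)[0][1])
    return float(np.clip(slope, -7.5, 7.5))


def _profiled_negll(
    params: np.ndarray,
    q: int,
    varfn: VarianceFunction,
    w: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    codes: np.ndarray,
    d: np.ndarray,
    group_slices: list[np.ndarray],
    with_grad: bool = False,
):
    """-loglik of the linearized mixed model with beta, sigma^2 profiled.

    Returns (negll, beta_gls, sigma2, logdet_total), or (negll, grad) when
    ``with_grad`` is set; uses the Woodbury identity so only q x q
    factorizations are needed per group, and the envelope theorem for the
    analytic gradient in (log-Cholesky psi, variance-function) parameters.
    """
    n, p = X.shape
    theta = params[: q * (q + 1) // 2]
    vf = varfn.with_packed(params[q * (q + 1) // 2:])
    L = _chol_unpack(theta, q)
    bad = (_BIG, np.zeros_like(params)) if with_grad else (_BIG, None, None, None)
    try:
        lam = vf.lam(d)
    except ValidationError:
        return bad
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        return bad

    XtMX = np.zeros((p, p))
    XtMw = np.zeros(p)
    wtMw = 0.0
    logdet = 0.0
    cache = []
    for idx in group_slices:
        Zi = Z[idx]
        lam_i = lam[idx]
        U = Zi @ L  # ni x q
        Ul = U / lam_i[:, None]
        S = np.eye(q) + U.T @ Ul
        try:
            cS = cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            return bad
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            return bad
        logdet += ld + np.sum(np.log(lam_i))
        A = np.column_stack([w[idx], X[idx]])
        Al = A / lam_i[:, None]
        UtA = Ul.T @ A  # q x (p+1)
        MA = Al - Ul @ cho_solve(cS, UtA)
        AtMA = A.T @ MA
        wtMw += AtMA[0, 0]
        XtMw += AtMA[1:, 0]
        XtMX += AtMA[1:, 1:]
        cache.append((idx, Zi, lam_i, Ul, cS, MA))
    try:
        beta = np.linalg.solve(XtMX, XtMw)
    except np.linalg.LinAlgError:
        return bad
    rss = wtMw - XtMw @ beta
    if rss <= 0 or not np.isfinite(rss):
        return bad
    sigma2 = rss / n
    negll = 0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
    if not with_grad:
        return negll, beta, sigma2, logdet

    # ---- analytic gradient (envelope theorem: beta, sigma^2 profiled) ----
    # d negll / dt = 0.5 * [ tr(M^-1 dM/dt) - (1/sigma2) * a' (dM/dt) a ],
    # summed over groups, with a = M^-1 (w - X beta).
    dlams = _dlam(vf, d, lam)
    Bsum = np.zeros((q, q))  # sum of Z' M^-1 Z
    Csum = np.zeros((q, q))  # sum of (Z'a)(Z'a)'
    tr_lam = np.zeros(len(dlams))
    quad_lam = np.zeros(len(dlams))
    for idx, Zi, lam_i, Ul, cS, MA in cache:
        a = MA[:, 0] - MA[:, 1:] @ beta  # M^-1 r for this group
        T = (Zi / lam_i[:, None]).T @ Zi  # Z' Lam^-1 Z
        TL = T @ L
        B = T - TL @ cho_solve(cS, TL.T)
        c = Zi.T @ a
        Bsum += B
        Csum += np.outer(c, c)
        # diag(M^-1) = 1/lam - rowsum((Ul @ inv(chol S)')^2)
        Wm = solve_triangular(cS[0], Ul.T, lower=True).T
        diag_Minv = 1.0 / lam_i - np.sum(Wm * Wm, axis=1)
        for k, dl in enumerate(dlams):
            tr_lam[k] += float(diag_Minv @ dl[idx])
            quad_lam[k] += float((a * a) @ dl[idx])

    scale = 1.0 / sigma2
    GL = Bsum @ L - scale * (Csum @ L)
    grad = np.zeros_like(params)
    k = 0
    for i in range(q):
        for j in range(i + 1):
            g = GL[i, j]
            if i == j:
                g *= L[i, i]  # chain rule for the log-diagonal
            grad[k] = g
            k += 1
    for kk in range(len(dlams)):
        grad[k + kk] = 0.5 * (tr_lam[kk] - scale * quad_lam[kk])
    return negll, grad


def _dlam(vf: VarianceFunction, d: np.ndarray, lam: np.ndarray) -> list[np.ndarray]:
    """Derivatives of lambda(d) w.r.t. the packed variance parameters."""
    if vf.kind == "power":
        return [lam * np.log(d)]
    if vf.kind == "exponential":
        return [lam * d]
    if vf.kind == "constant_plus_power":
        root = vf.const + d**vf.delta
        return [2.0 * root * vf.const, 2.0 * root * d**vf.delta * np.log(d)]
    return []


def nlme_fit(
    form: ModelForm | str,
    data: pd.DataFrame,
    random_spec: RandomSpec,
    varfn: str | VarianceFunction = "power",
    control: NLMEControl | None = None,
    init_beta: np.ndarray | None = None,
) -> FittedMixedModel:
    """Fit a nonlinear mixed-effects model by alternating PNLS and
    linearized-ML steps.

    Requires at least 2 groups each with at least 2 observations.  The fit
    is deterministic given the data and starting values; non-convergence
    at ``control.max_outer`` iterations is reported via the ``converged``
    flag with the last iterate retained.
    """
    control = control or NLMEControl()
    if isinstance(form, str):
        form = ModelForm(form)
    spec = FORMS[form.form_id]
    varfn = VarianceFunction(varfn) if isinstance(varfn, str) else varfn
    if max(random_spec.random_subset) >= spec.arity:
        raise ConfigurationError("random_subset indexes beyond the form's parameters")

    y, d, th, hcb, ci, labels, codes = _prepare(data, random_spec.grouping)
    m, q, n = labels.size, random_spec.q, y.size
    if m < 2:
        raise ValidationError("random effects need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 observations")
    group_slices = [np.flatnonzero(codes == g) for g in range(m)]
    subset = random_spec.random_subset

    # ---- initialization: pooled NLS for beta, small relative covariance
    if init_beta is not None:
        beta = np.asarray(init_beta, float).copy()
    else:
        from .cw_models import fit_nls

        pooled = fit_nls(form.form_id, data, with_stats=False)
        if not pooled.converged:
            raise ValidationError("pooled NLS initialization failed")
        beta = pooled.model.phi.copy()
    b = np.zeros((m, q))
    theta = _chol_pack(0.05 * np.eye(q))
    vpar = varfn.pack()
    nvar = vpar.size

    prev_ll = -np.inf
    ll = -np.inf
    best_ll = -np.inf
    stall = 0
    beta_gls = beta
    sigma2 = float(np.mean((y - _eval_grad(spec, _phi_obs(beta, b, codes, subset), d, th, hcb, ci)[0]) ** 2))
    converged = False
    ridged = False
    it = 0

    for it in range(1, control.max_outer + 1):
        vf = varfn.with_packed(vpar)
        lam = vf.lam(d)
        sqrt_lam = np.sqrt(lam)
        L = _chol_unpack(theta, q)
        # guard against an exactly singular relative covariance
        if np.linalg.cond(L) > 1e12:
            L = L + np.sqrt(control.ridge) * np.eye(q)
            theta = _chol_pack(L)
            ridged = True
        Linv = solve_triangular(L, np.eye(q), lower=True)

        # ---- PNLS step: joint (beta, b) penalized weighted least squares
        def resid(params):
            beta_ = params[: spec.arity]
            b_ = params[spec.arity:].reshape(m, q)
            phi = _phi_obs(beta_, b_, codes, subset)
            f, _ = _eval_grad(spec, phi, d, th, hcb, ci)
            r1 = (y - f) / sqrt_lam
            r2 = (Linv @ b_.T).T.ravel()
            return np.concatenate([np.where(np.isfinite(r1), r1, 1e6), r2])

        def jac(params):
            beta_ = params[: spec.arity]
            b_ = params[spec.arity:].reshape(m, q)
            phi = _phi_obs(beta_, b_, codes, subset)
            _, G = _eval_grad(spec, phi, d, th, hcb, ci)
            G = np.where(np.isfinite(G), G, 0.0)
            J = np.zeros((n + m * q, spec.arity + m * q))
            J[:n, : spec.arity] = -G / sqrt_lam[:, None]
            for g, idx in enumerate(group_slices):
                cols = spec.arity + g * q + np.arange(q)
                J[idx[:, None], cols[None, :]] = -G[idx][:, list(subset)] / sqrt_lam[idx, None]
            for g in range(m):
                rows = n + g * q + np.arange(q)
                cols = spec.arity + g * q + np.arange(q)
                J[rows[:, None], cols[None, :]] = Linv
            return J

        p0 = np.concatenate([beta, b.ravel()])
        res = least_squares(
            resid, p0, jac=jac, method="trf",
            xtol=control.pnls_tol, ftol=control.pnls_tol, gtol=control.pnls_tol,
            max_nfev=control.pnls_max_nfev,
        )
        beta = res.x[: spec.arity]
        b = res.x[spec.arity:].reshape(m, q)

        # ---- LME step: linearize and maximize profiled ML over (theta, vpar)
        phi = _phi_obs(beta, b, codes, subset)
        f, G = _eval_grad(spec, phi, d, th, hcb, ci)
        X = np.where(np.isfinite(G), G, 0.0)
        Z = X[:, list(subset)]
        w = y - f + X @ beta + np.sum(Z * b[codes], axis=1)

        def negll(params):
            return _profiled_negll(params, q, varfn, w, X, Z, codes, d, group_slices)[0]

        def negll_grad(params):
            return _profiled_negll(
                params, q, varfn, w, X, Z, codes, d, group_slices, with_grad=True
            )

        bounds = _theta_bounds(q) + varfn.bounds()
        # The (theta, delta) surface can hold a spurious large-psi basin;
        # restarting from a near-zero covariance with a moment-matched
        # variance exponent keeps the search honest.
        starts = [np.concatenate([theta, vpar])]
        if it == 1:  # later iterations continue from an already-vetted point
            vpar_seed = vpar
            if varfn.kind in ("power", "exponential"):
                vpar_seed = np.array([_moment_delta(y - f, d, varfn.kind)])
            elif varfn.kind == "constant_plus_power":
                vpar_seed = np.array([0.0, _moment_delta(y - f, d, "power")])
            starts.append(np.concatenate([_chol_pack(0.01 * np.eye(q)), vpar_seed]))

        best_x, best_val = None, np.inf
        for x0 in starts:
            opt = minimize(
                negll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": control.lme_maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            val = negll(opt.x)
            if val < best_val:
                best_x, best_val = opt.x, val
        theta = best_x[: q * (q + 1) // 2]
        vpar = best_x[q * (q + 1) // 2:]
        nll, beta_gls, sigma2, _ = _profiled_negll(
            best_x, q, varfn, w, X, Z, codes, d, group_slices
        )
        if not np.isfinite(nll) or nll >= _BIG or beta_gls is None:
            return FittedMixedModel(
                form=ModelForm(form.form_id, beta, ci_kind=form.ci_kind),
                random_spec=random_spec, varfn=varfn.with_packed(vpar),
                psi=np.zeros((q, q)), sigma2=sigma2, n_obs=n, n_iter=it,
                converged=False, message="likelihood evaluation failed", ridged=ridged,
            )
        ll = -nll
        beta = beta_gls

        if np.isfinite(prev_ll) and abs(ll - prev_ll) < control.outer_tol * (abs(ll) + 1.0):
            converged = True
            break
        if ll > best_ll + control.stall_tol:
            best_ll = ll
            stall = 0
        else:
            stall += 1
            if stall >= control.stall_limit:
                converged = True
                break
        prev_ll = ll

    vf = varfn.with_packed(vpar)
    Lfin = _chol_unpack(theta, q)
    psi = sigma2 * (Lfin @ Lfin.T)
    p_count = spec.arity + q * (q + 1) // 2 + 1 + nvar
    fitted = FittedMixedModel(
        form=ModelForm(form.form_id, beta, ci_kind=form.ci_kind),
        random_spec=random_spec,
        varfn=vf,
        psi=psi,
        sigma2=float(sigma2),
        blups={str(lab): b[g].copy() for g, lab in enumerate(labels)},
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * p_count),
        n_params=p_count,
        n_obs=n,
        converged=converged,
        n_iter=it,
        message="" if converged else "max outer iterations reached",
        ridged=ridged,
    )
    logger.debug(
        "nlme_fit %s random=%s varfn=%s: ll=%.3f aic=%.1f iters=%d converged=%s",
        form.form_id, random_spec.names, vf.kind, ll, fitted.aic, it, converged,
    )
    return fitted


def enumerate_random_structures(form: ModelForm | str) -> list[RandomSpec]:
    """All non-empty random-effect subsets of the form's parameters,
    ordered by subset size then lexicographically (2^k - 1 specs)."""
    arity = FORMS[form.form_id if isinstance(form, ModelForm) else form].arity
    specs = []
    for size in range(1, arity + 1):
        for combo in itertools.combinations(range(arity), size):
            specs.append(RandomSpec(combo))
    return specs


def select_structure(
    form: ModelForm | str,
    data: pd.DataFrame,
    varfn_kinds: Sequence[str] = ("power",),
    control: NLMEControl | None = None,
) -> tuple[FittedMixedModel | None, pd.DataFrame]:
    """Exhaustive random-structure search: fit every non-empty subset of
    random effects crossed with every variance-function kind, and return
    the minimum-AIC converged fit plus the full report table.

    Non-converged fits are kept in the report without an AIC.  If nothing
    converges the best model is None.
    """
    if isinstance(form, str):
        form = ModelForm(form)
    if control is None:
        # screening control: overparameterized structures crawl toward a
        # flat optimum, so the search trades the last ~1 log-likelihood
        # unit for an order-of-magnitude shorter scan; AIC gaps between
        # competitive and uncompetitive structures dwarf that slack
        control = NLMEControl(
            max_outer=40, stall_tol=0.05, lme_maxiter=60, pnls_max_nfev=30
        )
    from .cw_models import fit_nls

    pooled = fit_nls(form.form_id, data, with_stats=False)
    init_beta = pooled.model.phi if pooled.converged else None

    rows = []
    best: FittedMixedModel | None = None
    for rs in enumerate_random_structures(form):
        for kind in varfn_kinds:
            row = {"random_subset": "+".join(rs.names), "varfn": kind}
            try:
                fit = nlme_fit(form, data, rs, varfn=kind, control=control, init_beta=init_beta)
                row["converged"] = fit.converged
                row["aic"] = fit.aic if fit.converged else np.nan
                if fit.converged and (best is None or fit.aic < best.aic):
                    best = fit
            except (ValidationError, ConfigurationError, np.linalg.LinAlgError) as exc:
                row["converged"] = False
                row["aic"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
    report = pd.DataFrame(rows)
    if best is None:
        logger.warning("select_structure: no random structure converged")
    return best, report


def predict_mixed(
    model: FittedMixedModel, frame: pd.DataFrame, mode: str = "population"
) -> np.ndarray:
    """Predict crown width from a fitted mixed model.

    ``population`` mode sets random effects to zero; ``group`` mode adds
    each tree's species BLUP, falling back to the population prediction
    (with a logged note) for species unseen during fitting.
    """
    if mode not in ("population", "group"):
        raise ConfigurationError(f"unknown prediction mode {mode!r}")
    spec = FORMS[model.form.form_id]
    n = len(frame)
    d = frame["d"].to_numpy(float)
    th = frame["th"].to_numpy(float) if "th" in frame else np.zeros(n)
    hcb = frame["hcb"].to_numpy(float) if "hcb" in frame else np.zeros(n)
    ci = frame["ci"].to_numpy(float) if "ci" in frame else np.zeros(n)
    phi = np.tile(model.fixed, (n, 1))
    if mode == "group":
        if model.random_spec.grouping not in frame:
            raise ConfigurationError("group mode requires the grouping column")
        groups = frame[model.random_spec.grouping].astype(str).to_numpy()
        unseen = sorted(set(groups) - set(model.blups))
        if unseen:
            logger.info("predict_mixed: unseen groups %s get population prediction", unseen)
        for g in set(groups):
            if g in model.blups:
                rows = groups == g
                phi[np.ix_(rows, list(model.random_spec.random_subset))] += model.blups[g]
    f, _ = _eval_grad(spec, phi, d, th, hcb, ci)
    return f
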