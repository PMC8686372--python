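"""Maximum-likelihood structural equation modelling for CTG interpretation.

The model follows the classical LISREL formulation.  Observed indicators x
measure exogenous latents xi and indicators y measure endogenous latents
eta::

    x = Lambda_x xi + delta
    y = Lambda_y eta + epsilon
    eta = Beta eta + Gamma xi + zeta

with exogenous latent covariance Phi, structural disturbance covariance Psi,
and diagonal unique-error variances Theta.  Each latent is scaled by fixing
one reference loading at 1.  Fitting minimises the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free parameters, with Wald standard errors from the inverse
Hessian scaled by 2/(n-1), the convention of covariance-structure software.

Two presets mirror the CTG application: a five-construct confirmatory
factor model (baseline BCat, variability VCat, acceleration ACat,
deceleration DCat, uterine-contraction UCat over 17 indicators) and a
structural model in which VCat drives BCat, UCat drives DCat, and
ACat/BCat/DCat carry direct paths to the observed fetal-status score NSP.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "SEMModel",
    "SEMData",
    "SEMFit",
    "build_model",
    "measurement_model",
    "structural_model",
    "implied_covariance",
    "fml_discrepancy",
    "fit_ml",
    "standardize_solution",
    "wald_statistics",
    "effect_decomposition",
    "fit_indices",
]


class ModelSpecError(ValueError):
    """Ill-formed model specification."""


class NumericModelError(ValueError):
    """Singular or non-positive-definite matrix encountered."""


FREE = "free"


@dataclasses.dataclass
class SEMModel:
    """Latent-variable model: loadings, structural paths and covariances.

    ``lam``, ``beta``, ``gamma``, ``phi``, ``psi``, ``theta`` map entry keys
    to either the sentinel ``"free"`` or a fixed float.  ``phi``/``psi`` keys
    are unordered latent pairs; ``theta`` keys are observed names (diagonal
    unique variances).
    """

    observed: list[str]
    latents_exo: list[str]
    latents_endo: list[str]
    lam: dict[tuple[str, str], object]
    beta: dict[tuple[str, str], object]
    gamma: dict[tuple[str, str], object]
    phi: dict[tuple[str, str], object]
    psi: dict[tuple[str, str], object]
    theta: dict[str, object]
    reference: dict[str, str]

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for (obs, lat) in self.lam:
            if obs in owner and owner[obs] != lat:
                raise ModelSpecError(f"indicator {obs} claimed by both {owner[obs]} and {lat}")
            owner[obs] = lat
        for lat in self.latents:
            ref = self.reference.get(lat)
            if ref is None:
                raise ModelSpecError(f"latent {lat} has no scaling constraint")
            if self.lam.get((ref, lat)) == FREE:
                raise ModelSpecError(f"reference loading {ref}<-{lat} must be fixed")
        self._labels = self._enumerate_free()

    # -- parameter bookkeeping ------------------------------------------------

    @property
    def latents(self) -> list[str]:
        return self.latents_exo + self.latents_endo

    def _enumerate_free(self) -> list[tuple[str, tuple]]:
        labels: list[tuple[str, tuple]] = []
        for (obs, lat), v in self.lam.items():
            if v == FREE:
                labels.append((f"lambda:{obs}<-{lat}", ("lam", obs, lat)))
        for (tgt, src), v in self.beta.items():
            if v == FREE:
                labels.append((f"beta:{tgt}<-{src}", ("beta", tgt, src)))
        for (tgt, src), v in self.gamma.items():
            if v == FREE:
                labels.append((f"gamma:{tgt}<-{src}", ("gamma", tgt, src)))
        for (a, b), v in self.phi.items():
            if v == FREE:
                labels.append((f"phi:{a}~~{b}", ("phi", a, b)))
        for (a, b), v in self.psi.items():
            if v == FREE:
                labels.append((f"psi:{a}~~{b}", ("psi", a, b)))
        for obs, v in self.theta.items():
            if v == FREE:
                labels.append((f"theta:{obs}", ("theta", obs, obs)))
        return labels

    @property
    def param_names(self) -> list[str]:
        return [name for name, _ in self._labels]

    @property
    def n_free(self) -> int:
        return len(self._labels)

    @property
    def df(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free

    def pack(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([values[name] for name in self.param_names], float)

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        # dtype preserved: complex values flow through for complex-step
        # differentiation of the discrepancy
        return dict(zip(self.param_names, np.asarray(theta)))

    # -- matrix realisation ---------------------------------------------------

    def matrices(self, theta: np.ndarray | Mapping[str, float]):
        """Materialise (Lambda, B, Gamma, Phi, Psi, Theta) at parameter values."""
        if isinstance(theta, Mapping):
            vals = dict(theta)
        else:
            vals = self.unpack(theta)
        p = len(self.observed)
        nx, ne = len(self.latents_exo), len(self.latents_endo)
        oi = {o: i for i, o in enumerate(self.observed)}
        xi = {l: i for i, l in enumerate(self.latents_exo)}
        ei = {l: i for i, l in enumerate(self.latents_endo)}
        li = {l: i for i, l in enumerate(self.latents)}

        def val(spec, label):
            return vals[label] if spec == FREE else float(spec)

        dt = complex if any(np.iscomplexobj(v) for v in vals.values()) else float
        Lam = np.zeros((p, nx + ne), dt)
        for (obs, lat), v in self.lam.items():
            Lam[oi[obs], li[lat]] = val(v, f"lambda:{obs}<-{lat}")
        B = np.zeros((ne, ne), dt)
        for (tgt, src), v in self.beta.items():
            B[ei[tgt], ei[src]] = val(v, f"beta:{tgt}<-{src}")
        G = np.zeros((ne, nx), dt)
        for (tgt, src), v in self.gamma.items():
            G[ei[tgt], xi[src]] = val(v, f"gamma:{tgt}<-{src}")
        Phi = np.zeros((nx, nx), dt)
        for (a, b), v in self.phi.items():
            x = val(v, f"phi:{a}~~{b}")
            Phi[xi[a], xi[b]] = Phi[xi[b], xi[a]] = x
        Psi = np.zeros((ne, ne), dt)
        for (a, b), v in self.psi.items():
            x = val(v, f"psi:{a}~~{b}")
            Psi[ei[a], ei[b]] = Psi[ei[b], ei[a]] = x
        Th = np.zeros((p, p), dt)
        for obs, v in self.theta.items():
            Th[oi[obs], oi[obs]] = val(v, f"theta:{obs}")
        return Lam, B, G, Phi, Psi, Th

    def latent_covariance(self, theta) -> np.ndarray:
        """Model-implied covariance of the full latent vector [xi; eta]."""
        _, B, G, Phi, Psi, _ = self.matrices(theta)
        ne = len(self.latents_endo)
        ident = np.eye(ne)
        try:
            M = linalg.inv(ident - B)
        except linalg.LinAlgError as exc:  # pragma: no cover - degenerate
            raise NumericModelError("(I - beta) is singular") from exc
        C_ex = M @ G @ Phi
        C_ee = M @ (G @ Phi @ G.T + Psi) @ M.T
        top = np.hstack([Phi, C_ex.T])
        bot = np.hstack([C_ex, C_ee])
        C = np.vstack([top, bot])
        return (C + C.T) / 2.0


@dataclasses.dataclass
class SEMData:
    """Sample covariance matrix with its size and variable order."""

    S: np.ndarray
    n: int
    variables: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, float)
        if self.S.shape != (len(self.variables), len(self.variables)):
            raise ValueError("covariance shape does not match variable list")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("sample covariance is not symmetric")
        if self.n <= len(self.variables):
            raise ValueError("n must exceed the number of observed variables")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variables: Sequence[str]) -> "SEMData":
        sub = frame[list(variables)]
        if sub.isna().any().any():
            raise ValueError("missing values are not supported")
        return cls(sub.cov().to_numpy(), len(sub), list(variables))


@dataclasses.dataclass
class SEMFit:
    """Result of an ML fit: estimates, implied covariance, SEs, diagnostics."""

    model: SEMModel
    data: SEMData
    estimates: dict[str, float]
    sigma: np.ndarray
    fml: float
    se: dict[str, float]
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: list[str]

    @property
    def theta(self) -> np.ndarray:
        return self.model.pack(self.estimates)


def build_model(spec: Mapping) -> SEMModel:
    """Build an :class:`SEMModel` from a declarative mapping.

    Keys: ``latents`` (latent -> list of indicators), ``references``
    (latent -> reference indicator, loading fixed at 1), optional ``paths``
    (list of ``(target, source)`` latent pairs), ``covariances`` (list of
    latent pairs with free covariance; defaults to all exogenous pairs),
    ``fixed_theta`` (observed -> fixed unique variance).
    """
    latents: Mapping[str, Sequence[str]] = spec["latents"]
    references: Mapping[str, str] = spec.get("references", {})
    paths: Sequence[tuple[str, str]] = list(spec.get("paths", []))
    fixed_theta: Mapping[str, float] = spec.get("fixed_theta", {})

    endo = sorted({t for t, _ in paths}, key=list(latents).index)
    exo = [l for l in latents if l not in endo]
    observed: list[str] = []
    lam: dict[tuple[str, str], object] = {}
    theta: dict[str, object] = {}
    for lat, inds in latents.items():
        ref = references.get(lat)
        if ref is None:
            raise ModelSpecError(f"latent {lat} has no scaling constraint")
        for obs in inds:
            if obs in observed:
                raise ModelSpecError(f"indicator {obs} appears under two latents")
            observed.append(obs)
            lam[(obs, lat)] = 1.0 if obs == ref else FREE
            theta[obs] = float(fixed_theta[obs]) if obs in fixed_theta else FREE

    beta: dict[tuple[str, str], object] = {}
    gamma: dict[tuple[str, str], object] = {}
    for tgt, src in paths:
        (beta if src in endo else gamma)[(tgt, src)] = FREE

    default_cov = spec.get("covariances")
    phi: dict[tuple[str, str], object] = {(l, l): FREE for l in exo}
    if default_cov is None:
        for a, b in itertools.combinations(exo, 2):
            phi[(a, b)] = FREE
    else:
        for a, b in default_cov:
            phi[(a, b)] = FREE
    psi: dict[tuple[str, str], object] = {(l, l): FREE for l in endo}

    return SEMModel(
        observed=observed, latents_exo=exo, latents_endo=endo,
        lam=lam, beta=beta, gamma=gamma, phi=phi, psi=psi, theta=theta,
        reference=dict(references),
    )


#: Indicator assignment for the five clinical constructs (full CFA version).
MEASUREMENT_LATENTS = {
    "VCat": ["Variance", "MLTV", "MSTV", "ALTV", "ASTV", "Width"],
    "BCat": ["LB", "Mean", "Median", "Mode"],
    "DCat": ["DP", "DL", "Nzeros"],
    "ACat": ["AC", "Nmax", "FM"],
    "UCat": ["UC"],
}
MEASUREMENT_REFERENCES = {
    "VCat": "Variance", "BCat": "LB", "DCat": "DP", "ACat": "AC", "UCat": "UC",
}

STRUCTURAL_LATENTS = {
    "VCat": ["Variance", "MSTV", "ALTV", "ASTV", "Width"],
    "UCat": ["UC"],
    "ACat": ["AC", "Nmax", "FM"],
    "BCat": ["LB", "Mean", "Median", "Mode"],
    "DCat": ["DP", "DL", "Nzeros"],
    "Fetal": ["NSP"],
}
STRUCTURAL_REFERENCES = {
    "VCat": "ALTV", "UCat": "UC", "ACat": "AC",
    "BCat": "LB", "DCat": "DP", "Fetal": "NSP",
}
STRUCTURAL_PATHS = [
    ("BCat", "VCat"),
    ("DCat", "UCat"),
    ("Fetal", "ACat"),
    ("Fetal", "BCat"),
    ("Fetal", "DCat"),
]


def measurement_model() -> SEMModel:
    """Five-construct oblique CFA over 17 indicators; all latent pairs correlated.

    The single-indicator uterine-contraction construct is identified by
    fixing its unique error variance at zero.
    """
    return build_model({
        "latents": MEASUREMENT_LATENTS,
        "references": MEASUREMENT_REFERENCES,
        "fixed_theta": {"UC": 0.0},
    })


def structural_model(uc_error_variance: float = 0.0) -> SEMModel:
    """Structural model: VCat->BCat, UCat->DCat, ACat/BCat/DCat->NSP.

    MLTV is dropped (non-significant in the CFA).  NSP enters as a
    continuous observed outcome, the sole indicator of an endogenous block
    with zero unique error.  ``uc_error_variance`` exposes the
    single-indicator UC identification constraint.
    """
    return build_model({
        "latents": STRUCTURAL_LATENTS,
        "references": STRUCTURAL_REFERENCES,
        "paths": STRUCTURAL_PATHS,
        "covariances": [("UCat", "VCat")],
        "fixed_theta": {"UC": float(uc_error_variance), "NSP": 0.0},
    })


def implied_covariance(model: SEMModel, theta) -> np.ndarray:
    """Model-implied covariance over the observed variables."""
    Lam, *_ = model.matrices(theta)
    Th = model.matrices(theta)[5]
    C = model.latent_covariance(theta)
    Sigma = Lam @ C @ Lam.T + Th
    return (Sigma + Sigma.T) / 2.0


def fml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Zero iff Sigma equals S; requires both matrices positive definite.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise NumericModelError("sample covariance S is not positive definite")
    try:
        chol = linalg.cho_factor(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericModelError("implied covariance Sigma is not positive definite") from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(chol[0])))
    trace = np.trace(linalg.cho_solve(chol, S))
    return float(logdet_sigma + trace - logdet_s - p)


def _objective(model: SEMModel, S: np.ndarray):
    big = 1e8

    def f(theta: np.ndarray) -> float:
        try:
            Sigma = implied_covariance(model, theta)
        except NumericModelError:
            return big
        try:
            chol = linalg.cho_factor(Sigma, lower=True)
        except linalg.LinAlgError:
            # push back toward the PD region smoothly
            w = linalg.eigvalsh(Sigma)
            return big + float(np.sum(np.minimum(w, 0.0) ** 2))
        p = S.shape[0]
        logdet_sigma = 2.0 * np.sum(np.log(np.diag(chol[0])))
        trace = np.trace(linalg.cho_solve(chol, S))
        sign_s, logdet_s = np.linalg.slogdet(S)
        return float(logdet_sigma + trace - logdet_s - p)

    return f


def _sym_chol(Sigma: np.ndarray) -> np.ndarray:
    """Complex-symmetric LL^T factorisation, analytic in the entries.

    Unlike the Hermitian Cholesky, every operation here is complex-analytic,
    which is what complex-step differentiation of the discrepancy requires.
    On real positive-definite input it reduces to the ordinary Cholesky.
    """
    p = Sigma.shape[0]
    L = np.zeros_like(Sigma)
    for j in range(p):
        d = Sigma[j, j] - L[j, :j] @ L[j, :j]
        if d.real <= 0:
            raise NumericModelError("matrix is not positive definite")
        L[j, j] = np.sqrt(d)
        if j + 1 < p:
            L[j + 1:, j] = (Sigma[j + 1:, j] - L[j + 1:, :j] @ L[j, :j]) / L[j, j]
    return L


def _fml_analytic(model: SEMModel, S: np.ndarray, logdet_s: float, theta):
    """F_ML evaluated through analytic primitives only (complex-safe)."""
    Sigma = implied_covariance(model, theta)
    L = _sym_chol(Sigma)
    Z = linalg.solve_triangular(L, S.astype(L.dtype), lower=True)
    W = linalg.solve_triangular(L, Z.T, lower=True)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    return logdet_sigma + np.trace(W) - logdet_s - S.shape[0]


def _cs_grad(model: SEMModel, S: np.ndarray, theta: np.ndarray,
             h: float = 1e-100) -> np.ndarray:
    """Machine-precision gradient of F_ML via complex-step differentiation."""
    _, logdet_s = np.linalg.slogdet(S)
    g = np.zeros(len(theta))
    base = np.asarray(theta, float).astype(complex)
    for i in range(len(theta)):
        th = base.copy()
        th[i] += 1j * h
        g[i] = float(_fml_analytic(model, S, logdet_s, th).imag / h)
    return g


def _start_values(model: SEMModel, data: SEMData) -> np.ndarray:
    """Deterministic data-driven starting point.

    Each latent is proxied by its reference indicator: free loadings start at
    the regression slope of the indicator on the reference, latent
    (co)variances at half the reference (co)variances, paths at the slope of
    the target's reference on the source's reference.  This places loading
    and path signs in the right basin, which fixed positive starts do not.
    """
    idx = {v: i for i, v in enumerate(data.variables)}
    S = data.S
    ref = {lat: idx[model.reference[lat]] for lat in model.latents}

    def slope(i: int, j: int) -> float:
        return float(np.clip(S[i, j] / max(S[j, j], 1e-12), -3.0, 3.0))

    start: dict[str, float] = {}
    for name in model.param_names:
        kind, rest = name.split(":", 1)
        if kind == "lambda":
            obs, lat = rest.split("<-")
            s = slope(idx[obs], ref[lat])
            start[name] = s if abs(s) > 0.05 else 0.1
        elif kind in ("beta", "gamma"):
            tgt, src = rest.split("<-")
            start[name] = slope(ref[tgt], ref[src])
        elif kind in ("phi", "psi"):
            a, b = rest.split("~~")
            start[name] = 0.5 * float(S[ref[a], ref[b]] if a != b
                                      else max(S[ref[a], ref[a]], 1e-6))
        elif kind == "theta":
            start[name] = 0.5 * float(max(S[idx[rest], idx[rest]], 1e-6))
    return model.pack(start)


def _fallback_start(model: SEMModel, data: SEMData) -> np.ndarray:
    """Conservative start with a guaranteed positive-definite implied Sigma.

    Uncorrelated latents, zero paths, moderate loadings and half-variance
    unique errors: Lambda C Lambda' is then positive semi-definite and Theta
    positive definite, so the start never sits on the non-PD penalty
    plateau.
    """
    idx = {v: i for i, v in enumerate(data.variables)}
    S = data.S
    ref = {lat: idx[model.reference[lat]] for lat in model.latents}
    start: dict[str, float] = {}
    for name in model.param_names:
        kind, rest = name.split(":", 1)
        if kind == "lambda":
            start[name] = 0.5
        elif kind in ("beta", "gamma"):
            start[name] = 0.0
        elif kind in ("phi", "psi"):
            a, b = rest.split("~~")
            start[name] = (0.5 * float(max(S[ref[a], ref[a]], 1e-6))
                           if a == b else 0.0)
        else:
            start[name] = 0.5 * float(max(S[idx[rest], idx[rest]], 1e-6))
    return model.pack(start)


def fit_ml(model: SEMModel, data: SEMData, start="auto",
           maxiter: int = 2000) -> SEMFit:
    """Fit the model by minimising the ML discrepancy (quasi-Newton).

    Non-convergence and Heywood cases (negative variance estimates) are
    returned flagged, never silently.
    """
    if list(data.variables) != model.observed:
        data = SEMData(
            pd.DataFrame(data.S, index=data.variables, columns=data.variables)
            .loc[model.observed, model.observed].to_numpy(),
            data.n, list(model.observed),
        )
    if np.linalg.eigvalsh(data.S).min() <= 0:
        raise NumericModelError("sample covariance is not positive definite")
    if model.df < 0:
        raise ModelSpecError(f"model is not identified (df = {model.df})")

    x0 = _start_values(model, data) if isinstance(start, str) else np.asarray(start, float)
    f = _objective(model, data.S)
    res = optimize.minimize(f, x0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-14,
                                     "gtol": 1e-9, "maxfun": 10 * maxiter})
    # polish: a second pass from the optimum tightens the gradient
    res2 = optimize.minimize(f, res.x, method="L-BFGS-B",
                             options={"maxiter": maxiter, "ftol": 1e-16,
                                      "gtol": 1e-10})
    if res2.fun <= res.fun:
        res = res2
    # The non-PD penalty region is nearly flat, so a quasi-Newton run that
    # starts (or strays) there can stall at the penalty value.  Restart once
    # from a conservative start whose implied Sigma is positive definite.
    if not np.isfinite(res.fun) or res.fun >= 1e7:
        res_fb = optimize.minimize(f, _fallback_start(model, data),
                                   method="L-BFGS-B",
                                   options={"maxiter": maxiter, "ftol": 1e-14,
                                            "gtol": 1e-9,
                                            "maxfun": 10 * maxiter})
        res_fb2 = optimize.minimize(f, res_fb.x, method="L-BFGS-B",
                                    options={"maxiter": maxiter, "ftol": 1e-16,
                                             "gtol": 1e-10})
        if res_fb2.fun <= res_fb.fun:
            res_fb = res_fb2
        if res_fb.fun < res.fun:
            res = res_fb
    x_hat, f_hat = res.x, float(res.fun)

    def grad_fn(x: np.ndarray) -> np.ndarray:
        try:
            return _cs_grad(model, data.S, x)
        except NumericModelError:
            return _central_grad(f, x)

    # Newton polish: complex-step gradients are exact to machine precision,
    # so iterating against the finite-difference Hessian converges to the
    # true stationary point, not to the FD gradient's noise floor.
    H = _fd_hessian(f, x_hat)
    for it in range(30):
        grad = grad_fn(x_hat)
        if np.max(np.abs(grad)) < 1e-13:
            break
        try:
            step = linalg.solve(H, grad, assume_a="sym")
        except linalg.LinAlgError:
            break
        x_new = x_hat - step
        f_new = f(x_new)
        if f_new > f_hat + 1e-14:
            break
        x_hat, f_hat = x_new, f_new
        if np.max(np.abs(step)) < 1e-13:
            break
        if (it + 1) % 5 == 0:
            H = _fd_hessian(f, x_hat)
    grad = grad_fn(x_hat)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(res.success or grad_norm < 1e-5)

    estimates = model.unpack(x_hat)
    heywood = [name for name, v in estimates.items()
               if (name.startswith("theta:") or
                   (name.startswith(("phi:", "psi:")) and
                    name.split(":", 1)[1].split("~~")[0] == name.split(":", 1)[1].split("~~")[1]))
               and v < 0]

    se = _wald_se(model, data, _fd_hessian(f, x_hat))
    return SEMFit(model=model, data=data, estimates=estimates,
                  sigma=implied_covariance(model, x_hat), fml=f_hat,
                  se=se, converged=converged, n_iter=int(res.nit),
                  grad_norm=grad_norm, heywood=heywood)


def _central_grad(f, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = h * max(abs(theta[i]), 1.0)
        g[i] = (f(theta + e) - f(theta - e)) / (2 * e[i])
    return g


def _fd_hessian(f, theta: np.ndarray) -> np.ndarray:
    k = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = f(theta)
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        fp[i] = f(theta + e)
        fm[i] = f(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    return H


def _wald_se(model: SEMModel, data: SEMData, H: np.ndarray) -> dict[str, float]:
    """SEs from the inverse Hessian of F_ML, scaled by 2/(n-1)."""
    se: dict[str, float] = {}
    try:
        acov = (2.0 / (data.n - 1)) * linalg.inv(H)
        diag = np.diag(acov)
        for name, v in zip(model.param_names, diag):
            se[name] = float(np.sqrt(v)) if v > 0 else float("nan")
    except linalg.LinAlgError:
        for name in model.param_names:
            se[name] = float("nan")
    return se


def _resolved_matrices(fit: SEMFit):
    model = fit.model
    Lam, B, G, Phi, Psi, Th = model.matrices(fit.estimates)
    C = model.latent_covariance(fit.estimates)
    return Lam, B, G, Phi, Psi, Th, C


def standardize_solution(fit: SEMFit) -> dict[str, float]:
    """Standardized loadings, paths and latent correlations.

    Every coefficient is rescaled by sd(source)/sd(target) using
    model-implied standard deviations, making the solution invariant to
    affine rescaling of any indicator.  Each latent whose reference
    indicator would carry a negative standardized loading is sign-flipped
    together with all its loadings, paths and covariances.
    """
    model = fit.model
    Lam, B, G, Phi, Psi, Th, C = _resolved_matrices(fit)
    lat_sd = np.sqrt(np.maximum(np.diag(C), 1e-300))
    obs_sd = np.sqrt(np.maximum(np.diag(fit.sigma), 1e-300))
    if np.any(np.diag(fit.sigma) <= 0):
        raise NumericModelError("zero implied variance; cannot standardize")
    li = {l: i for i, l in enumerate(model.latents)}
    oi = {o: i for i, o in enumerate(model.observed)}

    sign = {lat: 1.0 for lat in model.latents}
    for lat in model.latents:
        ref = model.reference[lat]
        raw = Lam[oi[ref], li[lat]] * lat_sd[li[lat]]
        if raw < 0:
            sign[lat] = -1.0

    out: dict[str, float] = {}
    for (obs, lat), v in model.lam.items():
        coef = Lam[oi[obs], li[lat]]
        out[f"{obs}<-{lat}"] = sign[lat] * coef * lat_sd[li[lat]] / obs_sd[oi[obs]]
    for (tgt, src) in list(model.beta) + list(model.gamma):
        mats = model.matrices(fit.estimates)
        Bm, Gm = mats[1], mats[2]
        ei = {l: i for i, l in enumerate(model.latents_endo)}
        xi = {l: i for i, l in enumerate(model.latents_exo)}
        coef = Bm[ei[tgt], ei[src]] if src in ei else Gm[ei[tgt], xi[src]]
        out[f"{tgt}<-{src}"] = (sign[tgt] * sign[src] * coef *
                                lat_sd[li[src]] / lat_sd[li[tgt]])
    for (a, b) in model.phi:
        if a != b:
            out[f"{a}~~{b}"] = (sign[a] * sign[b] * C[li[a], li[b]] /
                                (lat_sd[li[a]] * lat_sd[li[b]]))
    return out


def wald_statistics(fit: SEMFit) -> pd.DataFrame:
    """Wald table: estimate, SE, critical ratio, two-sided normal p-value.

    Fixed (reference) parameters carry no test statistic; p < 0.001 is
    rendered as ``***`` in the ``stars`` column.
    """
    rows = []
    for name in fit.model.param_names:
        est = fit.estimates[name]
        se = fit.se.get(name, float("nan"))
        if se and np.isfinite(se) and se > 0:
            cr = est / se
            p = 2.0 * (1.0 - stats.norm.cdf(abs(cr)))
        else:
            cr, p = float("nan"), float("nan")
        stars = "***" if np.isfinite(p) and p < 0.001 else ""
        rows.append({"parameter": name, "estimate": est, "se": se,
                     "cr": cr, "p": p, "stars": stars})
    return pd.DataFrame(rows)


def effect_decomposition(fit: SEMFit, outcome: str) -> pd.DataFrame:
    """Standardized direct, indirect and total effects on ``outcome``.

    The outcome may be a latent or an observed single-indicator variable;
    totals come from (I - A)^-1 accumulation over the standardized path
    matrix A, so a two-step chain's indirect effect is exactly the product
    of its two standardized paths.  Cyclic path systems are rejected.
    """
    model = fit.model
    std = standardize_solution(fit)
    latents = model.latents
    li = {l: i for i, l in enumerate(latents)}
    k = len(latents)
    A = np.zeros((k, k))
    for (tgt, src) in list(model.beta) + list(model.gamma):
        A[li[tgt], li[src]] = std[f"{tgt}<-{src}"]
    # recursive check: repeated powers must vanish
    P = A.copy()
    for _ in range(k):
        P = P @ A
    if np.max(np.abs(P)) > 1e-10:
        raise NumericModelError("cyclic structural system; effects undefined")

    target = outcome
    if target not in li:
        for (obs, lat), _ in model.lam.items():
            if obs == outcome:
                target = lat
                break
    if target not in li:
        raise ValueError(f"outcome {outcome!r} not reachable in the model")

    total_mat = linalg.inv(np.eye(k) - A) - np.eye(k)
    rows = []
    t = li[target]
    for lat in latents:
        if lat == target:
            continue
        direct = A[t, li[lat]]
        total = total_mat[t, li[lat]]
        rows.append({"source": lat, "target": outcome, "direct": direct,
                     "indirect": total - direct, "total": total})
    return pd.DataFrame(rows)


def independence_fml(S: np.ndarray) -> tuple[float, int]:
    """ML discrepancy and df of the independence (diagonal) baseline model."""
    p = S.shape[0]
    f = float(np.sum(np.log(np.diag(S))) - np.linalg.slogdet(S)[1])
    return f, p * (p - 1) // 2


def fit_indices(fit: SEMFit) -> dict[str, float]:
    """Chi-square, CFI, TLI, RMSEA (with 90% interval) and SRMR."""
    S, n = fit.data.S, fit.data.n
    df = fit.model.df
    chi2 = (n - 1) * fit.fml
    fb, dfb = independence_fml(S)
    chi2_b = (n - 1) * fb

    d = max(chi2 - df, 0.0)
    db = max(chi2_b - dfb, 0.0)
    cfi = 1.0 - d / max(db, d, np.finfo(float).tiny)
    if dfb > 0 and df > 0 and chi2_b / dfb != 1.0:
        tli = ((chi2_b / dfb) - (chi2 / df)) / ((chi2_b / dfb) - 1.0)
    else:
        tli = float("nan")
    just_identified = df == 0
    rmsea = 0.0 if just_identified else float(np.sqrt(d / (df * (n - 1))))
    lo, hi = _rmsea_interval(chi2, df, n) if not just_identified else (0.0, 0.0)

    sd = np.sqrt(np.diag(S))
    resid = (S - fit.sigma) / np.outer(sd, sd)
    tri = np.tril_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    return {"chi2": float(chi2), "df": int(df), "cfi": float(cfi),
            "tli": float(tli), "rmsea": rmsea, "rmsea_lo": lo, "rmsea_hi": hi,
            "srmr": srmr, "just_identified": just_identified}


def _rmsea_interval(chi2: float, df: int, n: int, level: float = 0.90):
    """90% RMSEA interval by inverting the noncentral chi-square cdf."""
    a = (1.0 - level) / 2.0

    def solve(target_cdf):
        if stats.ncx2.cdf(chi2, df, 0.0) < target_cdf:
            return 0.0
        lo_l, hi_l = 0.0, max(4 * chi2, 10.0)
        for _ in range(200):
            mid = (lo_l + hi_l) / 2
            if stats.ncx2.cdf(chi2, df, mid) > target_cdf:
                lo_l = mid
            else:
                hi_l = mid
        return (lo_l + hi_l) / 2

    lam_hi = solve(a)          # upper bound of noncentrality
    lam_lo = solve(1.0 - a)    # lower bound
    to_rmsea = lambda lam: float(np.sqrt(max(lam, 0.0) / (df * (n - 1))))
    return to_rmsea(lam_lo), to_rmsea(lam_hi)
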