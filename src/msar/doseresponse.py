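"""Two-parameter log-logistic exposure-response models.

The workhorse of the framework is the sigmoid

    Y(c) = 1 - 1 / (1 + (c/C50)^beta)

where ``C50`` is the half-maximal effective concentration (EC50 for
reproduction, LC50 for survival) and ``beta`` the Hill slope.  Survival and
reproduction endpoints are fitted to this form directly; abundance and
population-growth endpoints (algae) are fitted to the population-level
transform

    K(c)/K(0) = 1 - ln(1 + (c/C50)^beta) / ln(R0)

which expresses the relative carrying capacity of a logistically growing
population with undisturbed lifetime fecundity R0.

Parameters are optimized on log scale (log C50, log beta), which enforces
positivity and stabilizes the reported covariance; a deterministic
multistart over Hill slopes replaces reliance on a single initial guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .io_toxdata import EndpointClass, ToxRecord

__all__ = [
    "DoseResponseFit",
    "FitError",
    "FitConvergenceError",
    "loglogistic_response",
    "fit_response",
    "fit_abundance_direct",
    "ec10_from_fit",
    "ecx_from_fit",
    "fit_to_dict",
    "fit_from_dict",
]

#: Deterministic multistart grid over the Hill slope.
_BETA_STARTS = (1.0, 0.5, 2.0, 4.0, 8.0)
_FTOL = 1e-10  # cost tolerance; tight so Monte-Carlo reruns are reproducible
_ZERO_COST = 1e-16  # an essentially perfect fit; remaining starts are skipped


class FitError(ValueError):
    """Precondition violation on the data handed to a fit."""


class FitConvergenceError(RuntimeError):
    """No multistart converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


def loglogistic_response(c, c50: float, beta: float):
    """Fraction affected at concentration ``c`` under the log-logistic model.

    Total on c >= 0: returns 0 at c = 0, 0.5 at c = C50, and approaches 1 as
    c grows.  Accepts scalars or arrays.
    """
    if c50 <= 0 or beta <= 0:
        raise ValueError("C50 and beta must be positive")
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 - 1.0 / (1.0 + (c / c50) ** beta)
    return out if out.ndim else float(out)


def _abundance_model(c, c50: float, beta: float, r0: float):
    """K(c)/K(0) for a directly fitted abundance/growth endpoint.

    Clamped at 0: observed abundances cannot be negative, and the growth
    model's negative branch means the population is simply absent there.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore"):
        out = np.clip(1.0 - np.log1p((c / c50) ** beta) / math.log(r0), 0.0, None)
    return out if out.ndim else float(out)


def _loglogistic_jac(c, c50: float, beta: float) -> np.ndarray:
    """d(response)/d(log C50, log beta); rows for c = 0 are zero."""
    c = np.asarray(c, dtype=float)
    out = np.zeros((c.size, 2))
    pos = c > 0
    with np.errstate(over="ignore"):
        u = (c[pos] / c50) ** beta
        denom = (1.0 + u) ** 2
        g = np.where(np.isfinite(denom) & (denom > 0), u / denom, 0.0)
        out[pos, 0] = -beta * g
        with np.errstate(invalid="ignore", divide="ignore"):
            lnu = np.where(u > 0, np.log(u), 0.0)
        out[pos, 1] = g * lnu
    return out


def _abundance_jac(c, c50: float, beta: float, r0: float) -> np.ndarray:
    """d(K-ratio)/d(log C50, log beta); zero in the clamped (nonviable) region."""
    c = np.asarray(c, dtype=float)
    out = np.zeros((c.size, 2))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        u = (c / c50) ** beta
        raw = 1.0 - np.log1p(u) / math.log(r0)
        active = (c > 0) & (raw > 0) & np.isfinite(u)
        ua = u[active]
        g = ua / ((1.0 + ua) * math.log(r0))
        out[active, 0] = beta * g
        out[active, 1] = -g * np.where(ua > 0, np.log(ua), 0.0)
    return out


@dataclass
class DoseResponseFit:
    """A fitted 2-parameter log-logistic exposure-response curve.

    ``covariance`` is the asymptotic least-squares covariance on
    (log C50, log beta); it is what the Monte-Carlo uncertainty module
    samples from.  ``r0_used`` is set only for direct abundance/growth fits.
    """

    species: str
    endpoint_class: EndpointClass
    c50: float
    beta: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    residual_sse: float = 0.0
    n_points: int = 0
    r0_used: float | None = None

    def __post_init__(self) -> None:
        if self.c50 <= 0 or self.beta <= 0:
            raise ValueError("C50 and beta must be positive")
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")

    @property
    def is_direct(self) -> bool:
        """True for abundance/population-growth fits (K-ratio model)."""
        return self.r0_used is not None

    def predict(self, c):
        """Predicted fraction affected (or K-ratio for direct fits) at c."""
        if self.is_direct:
            return _abundance_model(c, self.c50, self.beta, self.r0_used)
        return loglogistic_response(c, self.c50, self.beta)


def _extract_xy(records: Sequence[ToxRecord]):
    conc = np.array([r.concentration for r in records], dtype=float)
    resp = np.array([r.response for r in records], dtype=float)
    ns = np.array(
        [r.n_subjects if r.n_subjects is not None else np.nan for r in records]
    )
    return conc, resp, ns


def _check_preconditions(conc: np.ndarray, resp: np.ndarray) -> None:
    if len(np.unique(conc)) < 3:
        raise FitError(
            f"need >= 3 distinct concentrations, got {len(np.unique(conc))}"
        )
    if np.ptp(resp) == 0:
        if np.all(resp == 0):
            raise FitError("no effect observed, C50 unidentifiable")
        raise FitError("all responses identical, parameters unidentifiable")


def _c50_start(conc: np.ndarray, resp: np.ndarray, half: float = 0.5) -> float:
    """Geometric mean of the concentrations bracketing the half response.

    Falls back to the median positive tested concentration when the data do
    not cross the half-effect level.
    """
    pos = conc > 0
    order = np.argsort(conc)
    c_s, r_s = conc[order], resp[order]
    below = c_s[(r_s < half) & (c_s > 0)]
    above = c_s[r_s >= half]
    if below.size and above.size and above.max() > below.min():
        lo = below.max()
        hi = above[above >= lo]
        hi = hi.min() if hi.size else above.max()
        if lo > 0 and hi > 0:
            return float(np.sqrt(lo * hi))
    if pos.any():
        return float(np.median(conc[pos]))
    raise FitError("no positive concentrations in data")


def _ls_fit(conc, resp, model, theta0_list, weights=None, jac=None):
    """Run the multistart least-squares on (log C50, log beta); best wins."""
    w = np.ones_like(resp) if weights is None else np.sqrt(weights)

    def residuals(theta):
        c50, beta = np.exp(theta)
        return w * (model(conc, c50, beta) - resp)

    if jac is not None:
        def jacobian(theta):
            c50, beta = np.exp(theta)
            return w[:, None] * jac(conc, c50, beta)
    else:
        jacobian = "2-point"

    best = None
    diagnostics = []
    for theta0 in theta0_list:
        try:
            res = least_squares(
                residuals, theta0, jac=jacobian, method="lm",
                ftol=_FTOL, xtol=_FTOL, gtol=_FTOL, max_nfev=2000,
            )
        except Exception as err:  # pragma: no cover - scipy internal failures
            diagnostics.append(f"start {np.exp(theta0)}: {err}")
            continue
        if not np.all(np.isfinite(res.x)):
            diagnostics.append(f"start {np.exp(theta0)}: non-finite optimum")
            continue
        if best is None or res.cost < best.cost:
            best = res
        diagnostics.append(
            f"start {np.exp(theta0)}: cost={res.cost:.3e} status={res.status}"
        )
        if best.cost < _ZERO_COST:
            break
    if best is None:
        raise FitConvergenceError("no multistart converged", diagnostics)
    return best


def _covariance_from_jacobian(res, n_points: int) -> tuple[np.ndarray, float]:
    sse = 2.0 * res.cost
    dof = n_points - 2
    sigma2 = sse / dof if dof > 0 else 0.0
    jtj = res.jac.T @ res.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(jtj)
    cov = 0.5 * (cov + cov.T)
    # numerical cleanup: clip tiny negative eigenvalues to keep the matrix PSD
    eigval, eigvec = np.linalg.eigh(cov)
    cov = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    return 0.5 * (cov + cov.T), sse


def fit_response(
    records: Sequence[ToxRecord], weight_by_n: bool = False
) -> DoseResponseFit:
    """Fit the log-logistic response to survival/reproduction records.

    Unweighted nonlinear least squares on the mean response fractions by
    default; ``weight_by_n`` weights residuals by the per-point number of
    test subjects where recorded.
    """
    conc, resp, ns = _extract_xy(records)
    _check_preconditions(conc, resp)
    weights = None
    if weight_by_n and np.isfinite(ns).any():
        weights = np.where(np.isfinite(ns), ns, np.nanmean(ns))
    c50_0 = _c50_start(conc, resp)
    starts = [np.log([c50_0, b]) for b in _BETA_STARTS]
    res = _ls_fit(conc, resp, loglogistic_response, starts, weights, jac=_loglogistic_jac)
    cov, sse = _covariance_from_jacobian(res, len(records))
    c50, beta = np.exp(res.x)
    return DoseResponseFit(
        species=records[0].species,
        endpoint_class=records[0].endpoint_class,
        c50=float(c50),
        beta=float(beta),
        covariance=cov,
        residual_sse=float(sse),
        n_points=len(records),
    )


def fit_abundance_direct(
    records: Sequence[ToxRecord], r0: float, weight_by_n: bool = False
) -> DoseResponseFit:
    """Fit the carrying-capacity transform to abundance/growth records.

    Records carry fraction affected (``1 - K-ratio``); the model is fitted
    against the K-ratios.  Requires R0 > 1 (ln R0 must be positive).
    """
    if r0 <= 1:
        raise FitError(f"R0 must exceed 1 for the abundance model, got {r0}")
    for r in records:
        if not r.endpoint_class.is_fraction_of_control:
            raise FitError(
                f"record with endpoint {r.endpoint_class.value} is not an "
                "abundance/population-growth observation"
            )
    conc, resp, ns = _extract_xy(records)
    _check_preconditions(conc, resp)
    kratio = 1.0 - resp
    weights = None
    if weight_by_n and np.isfinite(ns).any():
        weights = np.where(np.isfinite(ns), ns, np.nanmean(ns))
    # the half-effect heuristic operates on fraction affected
    c50_0 = _c50_start(conc, resp)
    starts = [np.log([c50_0, b]) for b in _BETA_STARTS]
    res = _ls_fit(
        conc, kratio, lambda c, c50, beta: _abundance_model(c, c50, beta, r0), starts,
        weights, jac=lambda c, c50, beta: _abundance_jac(c, c50, beta, r0),
    )
    cov, sse = _covariance_from_jacobian(res, len(records))
    c50, beta = np.exp(res.x)
    return DoseResponseFit(
        species=records[0].species,
        endpoint_class=records[0].endpoint_class,
        c50=float(c50),
        beta=float(beta),
        covariance=cov,
        residual_sse=float(sse),
        n_points=len(records),
        r0_used=float(r0),
    )


def ecx_from_fit(fit: DoseResponseFit, x: float) -> float:
    """Concentration producing an effect fraction ``x`` under an Eq.-type fit.

    Closed form: ``C50 * (x / (1 - x))^(1/beta)``.
    """
    if fit.is_direct:
        raise FitError("ECx closed form applies to response fits, not direct abundance fits")
    if not 0 < x < 1:
        raise ValueError("effect fraction must lie strictly in (0, 1)")
    return float(fit.c50 * (x / (1.0 - x)) ** (1.0 / fit.beta))


def ec10_from_fit(fit: DoseResponseFit) -> float:
    """The 10%-effect concentration: ``C50 * (1/9)^(1/beta)``."""
    return ecx_from_fit(fit, 0.10)


def fit_to_dict(fit: DoseResponseFit) -> dict:
    return {
        "species": fit.species,
        "endpoint_class": fit.endpoint_class.value,
        "c50": fit.c50,
        "beta": fit.beta,
        "covariance": fit.covariance.tolist(),
        "residual_sse": fit.residual_sse,
        "n_points": fit.n_points,
        "r0_used": fit.r0_used,
    }


def fit_from_dict(d: dict) -> DoseResponseFit:
    return DoseResponseFit(
        species=d["species"],
        endpoint_class=EndpointClass(d["endpoint_class"]),
        c50=d["c50"],
        beta=d["beta"],
        covariance=np.asarray(d["covariance"]),
        residual_sse=d["residual_sse"],
        n_points=d["n_points"],
        r0_used=d.get("r0_used"),
    )
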