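"""Nonlinear least-squares estimation of gas-production kinetics.

Two solvers are provided, mirroring common statistical-package defaults
for this kind of curve: a modified Gauss–Newton method (step-halving
line search, 100-iteration cap) and a Levenberg–Marquardt damped
least-squares method (300-iteration cap). The dispatching :func:`fit`
uses Gauss–Newton by default but routes the Richards family — and any
Gauss–Newton failure — to Levenberg–Marquardt, which is more robust for
highly nonlinear sigmoids.

Both solvers share the convergence rule *relative SSE change < tol*
(default 1e−8) on accepted steps, record the trace of accepted SSE
values, and never raise on numerical failure: a singular system or an
exhausted line search yields a ``FitResult`` with ``converged=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import (
    ModelSpec,
    _jacobian,
    _predict,
    as_param_array,
    get_model,
    validate_times,
)

__all__ = [
    "GasCurve",
    "FitConfig",
    "FitResult",
    "default_start",
    "fit_gauss_newton",
    "fit_lm",
    "fit",
]


@dataclass(frozen=True)
class GasCurve:
    """One blank-corrected cumulative gas time series.

    times are hours from inoculation (strictly increasing, t = 0
    allowed); gas is mL per 100 mg incubated DM. Small negative readings
    are tolerated (blank-correction noise) but a minimum below −0.5 mL
    is rejected as a sign of mis-corrected data.
    """

    treatment_id: str
    replicate_id: str
    times: np.ndarray
    gas: np.ndarray

    def __post_init__(self):
        t = validate_times(self.times)
        y = np.asarray(self.gas, dtype=float)
        if y.shape != t.shape:
            raise ValueError("times and gas must have equal length")
        if not np.all(np.isfinite(y)):
            raise ValueError("gas values must be finite")
        if y.size and y.min() < -0.5:
            warnings.warn(
                f"gas minimum {y.min():.3f} mL/100 mg DM below -0.5; "
                "check blank correction",
                RuntimeWarning,
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "gas", y)

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FitConfig:
    """Solver options (all serializable in the pipeline config file)."""

    tolerance: float = 1e-8
    max_iter_gn: int = 100
    max_iter_lm: int = 300
    max_halvings: int = 20
    lm_lambda0: float = 1e-3
    lm_lambda_up: float = 10.0
    lm_lambda_down: float = 10.0
    fallback_to_lm: bool = True


@dataclass
class FitResult:
    """Estimates and diagnostics for one model fitted to one dataset."""

    model_id: str
    estimates: np.ndarray
    standard_errors: np.ndarray
    sse: float
    rmse: float
    n_obs: int
    n_iter: int
    converged: bool
    algorithm: str
    sse_trace: list[float] = field(default_factory=list)
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(get_model(self.model_id).param_names, self.estimates))

    def predict(self, times) -> np.ndarray:
        return _predict(self.model_id, self.estimates, np.asarray(times, float))


# Soft lower bounds projected onto trial steps so the optimizer stays in
# the model's real-valued domain; orskov_mcdonald A is sign-free.
_EPS = 1e-8


def _lower_bounds(spec: ModelSpec) -> np.ndarray:
    lo = {
        "gompertz": [_EPS, _EPS, _EPS],
        "orskov_mcdonald": [-np.inf, _EPS, _EPS],
        "brody": [_EPS, _EPS, _EPS],
        "richards": [_EPS, _EPS, _EPS, _EPS],
        "dual_pool_logistic": [0.0, _EPS, _EPS, 0.0, _EPS],
    }[spec.model_id]
    return np.asarray(lo, dtype=float)


def _upper_bounds(spec: ModelSpec) -> np.ndarray:
    hi = np.full(spec.n_params, np.inf)
    if spec.model_id == "richards":
        # cap the inflection exponent: as D -> inf with B -> 0 the family
        # degenerates into its Gompertz limit along a flat ridge with no
        # finite minimizer; reported exponents for fermentation curves are
        # O(1), so 50 is far outside the biologically meaningful range
        hi[3] = 50.0
    return hi


def default_start(
    curve: GasCurve, model: str | ModelSpec
) -> np.ndarray:
    """Data-driven starting values for one curve.

    A0 = 1.05·max(gas) (total-gas families) with C0 = 0.1 h⁻¹;
    B0 = 1 for brody/richards, 2 for gompertz, D0 = 1.5 for richards;
    orskov_mcdonald starts at A0 = first reading, B0 = remaining span;
    the dual-pool start splits the asymptote 30/70 between the non-fiber
    and fiber pools with rates 0.2 and 0.05 h⁻¹ and lag 2 h.
    """
    spec = get_model(model)
    gmax = float(np.max(curve.gas)) if curve.n_obs else 0.0
    if gmax <= 0:
        raise ValueError("degenerate curve (no positive gas readings): nothing to fit")
    a0 = 1.05 * gmax
    if spec.model_id == "gompertz":
        return np.array([a0, 2.0, 0.1])
    if spec.model_id == "brody":
        return np.array([a0, 1.0, 0.1])
    if spec.model_id == "richards":
        return np.array([a0, 1.0, 0.1, 1.5])
    if spec.model_id == "orskov_mcdonald":
        g0 = float(curve.gas[0])
        return np.array([g0, max(a0 - g0, _EPS), 0.1])
    if spec.model_id == "dual_pool_logistic":
        return np.array([0.3 * a0, 0.2, 2.0, 0.7 * a0, 0.05])
    raise ValueError(spec.model_id)


def _sse(model_id: str, theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    r = y - _predict(model_id, theta, t)
    return float(r @ r)


def _standard_errors(
    model_id: str, theta: np.ndarray, t: np.ndarray, sse: float, n: int
) -> np.ndarray:
    """(J'J)⁻¹ · SSE/(n − p) Gauss–Newton approximation at the optimum."""
    p = theta.size
    if n <= p or sse < 0:
        return np.full(p, np.nan)
    jac = _jacobian(model_id, theta, t)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.pinv(jtj) * (sse / (n - p))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    d = np.diag(cov)
    return np.sqrt(np.where(d >= 0, d, np.nan))


def _finish(
    model_id, theta, t, y, sse, n_iter, converged, algorithm, trace, message=""
) -> FitResult:
    n = t.size
    return FitResult(
        model_id=model_id,
        estimates=theta.copy(),
        standard_errors=_standard_errors(model_id, theta, t, sse, n),
        sse=sse,
        rmse=float(np.sqrt(sse / n)) if n else np.nan,
        n_obs=n,
        n_iter=n_iter,
        converged=converged,
        algorithm=algorithm,
        sse_trace=trace,
        message=message,
    )


def _prepare(curve: GasCurve, model, start) -> tuple[ModelSpec, np.ndarray, np.ndarray, np.ndarray]:
    spec = get_model(model)
    t, y = curve.times, curve.gas
    if t.size < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} observations to fit {spec.model_id}"
        )
    theta = (
        default_start(curve, spec)
        if start is None
        else as_param_array(spec, start)
    )
    return spec, t, y, np.clip(theta, _lower_bounds(spec), _upper_bounds(spec))


def fit_gauss_newton(
    curve: GasCurve,
    model: str | ModelSpec,
    start: Mapping[str, float] | Sequence[float] | None = None,
    max_iter: int = 100,
    tolerance: float = 1e-8,
    max_halvings: int = 20,
) -> FitResult:
    """Modified Gauss–Newton: full GN step with step-halving line search."""
    spec, t, y, theta = _prepare(curve, model, start)
    lo, hi = _lower_bounds(spec), _upper_bounds(spec)
    sse = _sse(spec.model_id, theta, t, y)
    trace = [sse]
    for it in range(1, max_iter + 1):
        jac = _jacobian(spec.model_id, theta, t)
        r = y - _predict(spec.model_id, theta, t)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        try:
            delta = np.linalg.solve(jtj, jtr)
        except np.linalg.LinAlgError:
            return _finish(
                spec.model_id, theta, t, y, sse, it, False, "gauss_newton",
                trace, "singular normal equations",
            )
        if not np.all(np.isfinite(delta)):
            return _finish(
                spec.model_id, theta, t, y, sse, it, False, "gauss_newton",
                trace, "non-finite step",
            )
        # step-halving until SSE decreases
        step = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            cand = np.clip(theta + step * delta, lo, hi)
            cand_sse = _sse(spec.model_id, cand, t, y)
            if np.isfinite(cand_sse) and cand_sse <= sse:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return _finish(
                spec.model_id, theta, t, y, sse, it, False, "gauss_newton",
                trace, "line search failed to reduce SSE",
            )
        rel = (sse - cand_sse) / sse if sse > 0 else 0.0
        theta, sse = cand, cand_sse
        trace.append(sse)
        if rel < tolerance or sse == 0.0:
            return _finish(
                spec.model_id, theta, t, y, sse, it, True, "gauss_newton", trace
            )
    return _finish(
        spec.model_id, theta, t, y, sse, max_iter, False, "gauss_newton",
        trace, "iteration limit reached",
    )


def fit_lm(
    curve: GasCurve,
    model: str | ModelSpec,
    start: Mapping[str, float] | Sequence[float] | None = None,
    max_iter: int = 300,
    tolerance: float = 1e-8,
    lambda0: float = 1e-3,
    lambda_up: float = 10.0,
    lambda_down: float = 10.0,
) -> FitResult:
    """Levenberg–Marquardt damped least squares (Marquardt diagonal scaling)."""
    spec, t, y, theta = _prepare(curve, model, start)
    lo, hi = _lower_bounds(spec), _upper_bounds(spec)
    sse = _sse(spec.model_id, theta, t, y)
    trace = [sse]
    lam = lambda0
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        jac = _jacobian(spec.model_id, theta, t)
        r = y - _predict(spec.model_id, theta, t)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        diag = np.diag(jtj).copy()
        diag[diag <= 0] = 1.0  # guard flat directions
        accepted = False
        for _ in range(50):  # inner damping escalation
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(diag), jtr)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None and np.all(np.isfinite(delta)):
                cand = np.clip(theta + delta, lo, hi)
                cand_sse = _sse(spec.model_id, cand, t, y)
                if np.isfinite(cand_sse) and cand_sse <= sse:
                    accepted = True
                    break
            lam *= lambda_up
            if lam > 1e14:
                break
        if not accepted:
            # damping exhausted: treat current point as the solution if the
            # last relative improvement was already inside tolerance
            converged = len(trace) >= 2 and trace[-2] > 0 and (
                (trace[-2] - trace[-1]) / trace[-2] < tolerance
            )
            return _finish(
                spec.model_id, theta, t, y, sse, it, converged,
                "levenberg_marquardt", trace,
                "" if converged else "damping exhausted without SSE reduction",
            )
        rel = (sse - cand_sse) / sse if sse > 0 else 0.0
        theta, sse = cand, cand_sse
        trace.append(sse)
        lam = max(lam / lambda_down, 1e-14)
        if rel < tolerance or sse == 0.0:
            return _finish(
                spec.model_id, theta, t, y, sse, it, True,
                "levenberg_marquardt", trace,
            )
    return _finish(
        spec.model_id, theta, t, y, sse, n_iter, False, "levenberg_marquardt",
        trace, "iteration limit reached",
    )


def fit(
    curve: GasCurve,
    model: str | ModelSpec,
    config: FitConfig | None = None,
    start: Mapping[str, float] | Sequence[float] | None = None,
) -> FitResult:
    """Fit one model to one curve under the standard dispatch policy.

    Gauss–Newton is the default solver; the Richards family always uses
    Levenberg–Marquardt, and a Gauss–Newton failure falls back to it.
    """
    cfg = config or FitConfig()
    spec = get_model(model)
    lm_kwargs = dict(
        max_iter=cfg.max_iter_lm,
        tolerance=cfg.tolerance,
        lambda0=cfg.lm_lambda0,
        lambda_up=cfg.lm_lambda_up,
        lambda_down=cfg.lm_lambda_down,
    )
    if spec.model_id == "richards":
        return fit_lm(curve, spec, start, **lm_kwargs)
    res = fit_gauss_newton(
        curve, spec, start,
        max_iter=cfg.max_iter_gn,
        tolerance=cfg.tolerance,
        max_halvings=cfg.max_halvings,
    )
    if not res.converged and cfg.fallback_to_lm:
        lm_res = fit_lm(curve, spec, start, **lm_kwargs)
        if lm_res.converged or lm_res.sse < res.sse:
            return lm_res
    return res
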