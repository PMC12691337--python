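"""Kinetic model families for cumulative in vitro gas production curves.

Five classical nonlinear families are supported, each mapping incubation
time t (hours) to cumulative gas P(t) (mL per 100 mg incubated DM):

====================  =======================================================
id                    P(t)
====================  =======================================================
gompertz              A·exp(−B·exp(−C·t))
orskov_mcdonald       A + B·(1 − exp(−C·t))
brody                 A·(1 − B·exp(−C·t))
richards              A·(1 − B·exp(−C·t))^D
dual_pool_logistic    A/(1 + exp(2 − 4B(t−C))) + D/(1 + exp(2 − 4E(t−C)))
====================  =======================================================

Parameter semantics follow the gas-production literature: A is the
asymptotic gas volume (for orskov_mcdonald the soluble-fraction gas, for
the dual-pool model the non-fiber pool volume), B a shape/lag-related
term (for orskov_mcdonald the degradable-fraction gas, for the dual-pool
model the non-fiber fermentation rate per hour), C a fractional rate per
hour (for the dual-pool model the common lag time in hours), D the
Richards inflection exponent or the dual-pool fiber pool volume, and E
the fiber pool rate per hour.

For Brody/Richards with B > 1 the base 1 − B·exp(−Ct) is negative before
t = ln(B)/C; the base is clamped at zero there (an explicit lag phase),
which keeps the non-integer Richards power real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "MODELS",
    "MODEL_IDS",
    "get_model",
    "as_param_array",
    "validate_params",
    "evaluate",
    "jacobian",
    "asymptote",
]

# LM/GN trial steps can wander; exponent arguments are clipped so that
# exp() never overflows and the closed-form limit value is returned.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class ModelSpec:
    """One kinetic model family: stable id, ordered parameter symbols."""

    model_id: str
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MODELS: dict[str, ModelSpec] = {
    "gompertz": ModelSpec("gompertz", ("A", "B", "C")),
    "orskov_mcdonald": ModelSpec("orskov_mcdonald", ("A", "B", "C")),
    "brody": ModelSpec("brody", ("A", "B", "C")),
    "richards": ModelSpec("richards", ("A", "B", "C", "D")),
    "dual_pool_logistic": ModelSpec("dual_pool_logistic", ("A", "B", "C", "D", "E")),
}

#: Accepted spellings for each family ("dual_pool" is the short config id).
_ALIASES = {"dual_pool": "dual_pool_logistic"}

MODEL_IDS = tuple(MODELS)


def get_model(model: str | ModelSpec) -> ModelSpec:
    """Resolve a model id (or alias, or ModelSpec) to its ModelSpec."""
    if isinstance(model, ModelSpec):
        return model
    key = _ALIASES.get(model, model)
    try:
        return MODELS[key]
    except KeyError:
        raise ValueError(
            f"unknown model id {model!r}; expected one of {sorted(MODELS)}"
        ) from None


def as_param_array(
    model: str | ModelSpec, params: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Coerce a mapping or sequence of parameters to canonical order."""
    spec = get_model(model)
    if isinstance(params, Mapping):
        missing = set(spec.param_names) - set(params)
        if missing:
            raise ValueError(f"{spec.model_id}: missing parameters {sorted(missing)}")
        theta = np.array([float(params[k]) for k in spec.param_names])
    else:
        theta = np.asarray(params, dtype=float)
        if theta.shape != (spec.n_params,):
            raise ValueError(
                f"{spec.model_id} expects {spec.n_params} parameters "
                f"{spec.param_names}, got shape {theta.shape}"
            )
    return theta


def validate_params(model: str | ModelSpec, params) -> np.ndarray:
    """Validate parameter domain constraints; return the canonical array.

    C > 0 for every family; D > 0 for richards; E > 0 and the pool sizes
    A, D ≥ 0 for dual_pool_logistic; A may be negative only for
    orskov_mcdonald (its A is the soluble-fraction intercept).
    """
    spec = get_model(model)
    theta = as_param_array(spec, params)
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"{spec.model_id}: non-finite parameters {theta}")
    p = dict(zip(spec.param_names, theta))
    if p["C"] <= 0:
        raise ValueError(f"{spec.model_id}: rate C must be > 0, got {p['C']}")
    if spec.model_id == "orskov_mcdonald":
        pass  # A unconstrained in sign (soluble fraction may be slightly negative)
    elif spec.model_id == "dual_pool_logistic":
        if p["A"] < 0 or p["D"] < 0:
            raise ValueError("dual_pool_logistic: pool volumes A, D must be >= 0")
        if p["B"] <= 0 or p["E"] <= 0:
            raise ValueError("dual_pool_logistic: pool rates B, E must be > 0")
    else:
        if p["A"] <= 0:
            raise ValueError(f"{spec.model_id}: asymptote A must be > 0, got {p['A']}")
        if p["B"] <= 0:
            raise ValueError(f"{spec.model_id}: shape B must be > 0, got {p['B']}")
    if spec.model_id == "richards" and p["D"] <= 0:
        raise ValueError(f"richards: exponent D must be > 0, got {p['D']}")
    return theta


def validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and (not np.all(np.isfinite(t)) or t[0] < 0 or np.any(np.diff(t) <= 0)):
        raise ValueError("times must be finite, non-negative and strictly increasing")
    return t


def _exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def _predict(model_id: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Closed-form P(t) without domain validation (total on finite inputs)."""
    if model_id == "gompertz":
        a, b, c = theta
        return a * _exp(-b * _exp(-c * t))
    if model_id == "orskov_mcdonald":
        a, b, c = theta
        return a + b * (1.0 - _exp(-c * t))
    if model_id == "brody":
        a, b, c = theta
        return a * np.maximum(1.0 - b * _exp(-c * t), 0.0)
    if model_id == "richards":
        a, b, c, d = theta
        base = np.maximum(1.0 - b * _exp(-c * t), 0.0)
        return a * np.power(base, d)
    if model_id == "dual_pool_logistic":
        a, b, c, d, e = theta
        s1 = _sigmoid(4.0 * b * (t - c) - 2.0)
        s2 = _sigmoid(4.0 * e * (t - c) - 2.0)
        return a * s1 + d * s2
    raise ValueError(f"unknown model id {model_id!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def _jacobian(model_id: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic ∂P/∂θ, one row per time point, columns in canonical order."""
    if model_id == "gompertz":
        a, b, c = theta
        ect = _exp(-c * t)
        p = a * _exp(-b * ect)
        return np.column_stack([p / a, -p * ect, p * b * t * ect])
    if model_id == "orskov_mcdonald":
        a, b, c = theta
        ect = _exp(-c * t)
        return np.column_stack([np.ones_like(t), 1.0 - ect, b * t * ect])
    if model_id == "brody":
        a, b, c = theta
        ect = _exp(-c * t)
        base = 1.0 - b * ect
        active = base > 0  # clamped lag region contributes zero gradient
        return np.column_stack(
            [
                np.where(active, base, 0.0),
                np.where(active, -a * ect, 0.0),
                np.where(active, a * b * t * ect, 0.0),
            ]
        )
    if model_id == "richards":
        a, b, c, d = theta
        ect = _exp(-c * t)
        base = 1.0 - b * ect
        active = base > 0
        safe = np.where(active, base, 1.0)
        pow_d = np.where(active, np.power(safe, d), 0.0)
        pow_dm1 = np.where(active, np.power(safe, d - 1.0), 0.0)
        return np.column_stack(
            [
                pow_d,
                -a * d * pow_dm1 * ect,
                a * d * pow_dm1 * b * t * ect,
                a * pow_d * np.where(active, np.log(safe), 0.0),
            ]
        )
    if model_id == "dual_pool_logistic":
        a, b, c, d, e = theta
        s1 = _sigmoid(4.0 * b * (t - c) - 2.0)
        s2 = _sigmoid(4.0 * e * (t - c) - 2.0)
        w1 = s1 * (1.0 - s1)
        w2 = s2 * (1.0 - s2)
        return np.column_stack(
            [
                s1,
                4.0 * a * (t - c) * w1,
                -4.0 * (a * b * w1 + d * e * w2),
                s2,
                4.0 * d * (t - c) * w2,
            ]
        )
    raise ValueError(f"unknown model id {model_id!r}")


def evaluate(model: str | ModelSpec, params, times) -> np.ndarray:
    """Predicted cumulative gas P(t), mL/100 mg DM, at each time point."""
    spec = get_model(model)
    theta = validate_params(spec, params)
    t = validate_times(times)
    return _predict(spec.model_id, theta, t)


def jacobian(model: str | ModelSpec, params, times) -> np.ndarray:
    """Analytic Jacobian of P(t) with respect to the parameters.

    Returns an (n_times, n_params) matrix; columns follow the model's
    canonical parameter order.
    """
    spec = get_model(model)
    theta = validate_params(spec, params)
    t = validate_times(times)
    return _jacobian(spec.model_id, theta, t)


def asymptote(model: str | ModelSpec, params) -> float:
    """Total potential gas production as t → ∞ (mL/100 mg DM).

    A for gompertz/brody/richards; A + B for orskov_mcdonald (soluble
    plus potentially degradable fractions); A + D for dual_pool_logistic
    (non-fiber plus fiber pools).
    """
    spec = get_model(model)
    theta = validate_params(spec, params)
    p = dict(zip(spec.param_names, theta))
    if spec.model_id == "orskov_mcdonald":
        return p["A"] + p["B"]
    if spec.model_id == "dual_pool_logistic":
        return p["A"] + p["D"]
    return p["A"]
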