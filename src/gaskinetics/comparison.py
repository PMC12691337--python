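"""Identity testing of gas-production curves across treatment groups.

Whether two (or more) treatments share one degradation curve is decided
by the classical full-vs-reduced construction for nonlinear models: the
*full* model fits a separate parameter set to each group (equivalently a
dummy-variable parameterization), the *reduced* model fits a single
global parameter set to the pooled observations, and the extra sum of
squares is referred to an F distribution,

    F = [(SSE_r − SSE_f) / (df_r − df_f)] / (SSE_f / df_f),

with (df_r − df_f, df_f) degrees of freedom. Replicate flasks enter as
independent observations within their group; pairwise tests refit the
full and reduced models on each pair's pooled data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, FitResult, GasCurve, fit
from .models import get_model

__all__ = [
    "IdentityTestResult",
    "fit_full",
    "fit_reduced",
    "identity_f_test",
    "pairwise_identity",
]

_NEST_RTOL = 1e-8


@dataclass(frozen=True)
class _Pooled:
    """Stacked observations from several flasks (order-free for LS)."""

    times: np.ndarray
    gas: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.times.size


def _pool(curves: Sequence[GasCurve]) -> _Pooled:
    if not curves:
        raise ValueError("empty pool: no curves to fit")
    t = np.concatenate([c.times for c in curves])
    y = np.concatenate([c.gas for c in curves])
    return _Pooled(t, y)


def _as_group(group) -> list[GasCurve]:
    return [group] if isinstance(group, GasCurve) else list(group)


@dataclass(frozen=True)
class IdentityTestResult:
    """Full-vs-reduced extra-sum-of-squares F test for one comparison."""

    pair: tuple[str, ...]
    sse_full: float
    sse_reduced: float
    df_full: int
    df_reduced: int
    f_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def fit_full(
    groups: Mapping[str, GasCurve | Sequence[GasCurve]],
    model,
    config: FitConfig | None = None,
) -> tuple[dict[str, FitResult], float, int]:
    """Separate fits per treatment group (the dummy-variable full model).

    Returns (per-group FitResults, sse_full, df_full) with
    sse_full = Σ group SSEs and df_full = N − G·p.
    """
    if len(groups) < 2:
        raise ValueError("full model needs at least 2 treatment groups")
    spec = get_model(model)
    results: dict[str, FitResult] = {}
    n_total = 0
    for label, group in groups.items():
        curves = _as_group(group)
        pooled = _pool(curves)
        res = fit(pooled, spec, config)
        if not res.converged:
            raise RuntimeError(
                f"full-model fit did not converge for group {label!r}: {res.message}"
            )
        results[label] = res
        n_total += pooled.n_obs
    sse_full = sum(r.sse for r in results.values())
    df_full = n_total - len(groups) * spec.n_params
    return results, sse_full, df_full


def fit_reduced(
    groups: Mapping[str, GasCurve | Sequence[GasCurve]],
    model,
    config: FitConfig | None = None,
) -> tuple[FitResult, float, int]:
    """Single global fit across all groups (the reduced model)."""
    spec = get_model(model)
    curves = [c for group in groups.values() for c in _as_group(group)]
    pooled = _pool(curves)
    res = fit(pooled, spec, config)
    if not res.converged:
        raise RuntimeError(f"reduced-model fit did not converge: {res.message}")
    return res, res.sse, pooled.n_obs - spec.n_params


def identity_f_test(
    sse_full: float,
    df_full: int,
    sse_reduced: float,
    df_reduced: int,
    pair: tuple[str, ...] = ("all",),
) -> IdentityTestResult:
    """Extra-sum-of-squares F test of curve identity between nested fits."""
    if df_reduced <= df_full or df_full <= 0:
        raise ValueError(
            f"invalid degrees of freedom: df_reduced={df_reduced}, df_full={df_full}"
        )
    if sse_reduced < sse_full * (1.0 - _NEST_RTOL) - 1e-12:
        raise ValueError(
            f"sse_reduced ({sse_reduced:.6g}) < sse_full ({sse_full:.6g}): "
            "nesting violated, the reduced fit likely failed"
        )
    num = max(sse_reduced - sse_full, 0.0) / (df_reduced - df_full)
    den = sse_full / df_full
    f_stat = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f_stat, df_reduced - df_full, df_full))
    return IdentityTestResult(
        pair=pair, sse_full=sse_full, sse_reduced=sse_reduced,
        df_full=df_full, df_reduced=df_reduced, f_statistic=float(f_stat),
        p_value=p,
    )


def compare_groups(
    groups: Mapping[str, GasCurve | Sequence[GasCurve]],
    model,
    config: FitConfig | None = None,
    pair: tuple[str, ...] | None = None,
) -> IdentityTestResult:
    """Run the full-vs-reduced identity test on a set of groups."""
    _, sse_f, df_f = fit_full(groups, model, config)
    _, sse_r, df_r = fit_reduced(groups, model, config)
    return identity_f_test(
        sse_f, df_f, sse_r, df_r, pair=pair or tuple(groups),
    )


def pairwise_identity(
    groups: Mapping[str, GasCurve | Sequence[GasCurve]],
    model,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], IdentityTestResult]]:
    """Identity tests for every unordered pair of treatment groups.

    Returns an upper-triangular p-value table (NaN below the diagonal
    and for pairs whose fits failed) plus the per-pair results. Per-pair
    failures are recorded and the remaining pairs still run.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("pairwise identity testing needs at least 2 groups")
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    results: dict[tuple[str, str], IdentityTestResult] = {}
    errors: dict[tuple[str, str], str] = {}
    for a, b in itertools.combinations(labels, 2):
        try:
            res = compare_groups(
                {a: groups[a], b: groups[b]}, model, config, pair=(a, b)
            )
        except (RuntimeError, ValueError) as exc:
            errors[(a, b)] = str(exc)
            continue
        results[(a, b)] = res
        table.loc[a, b] = res.p_value
    if errors and not results:
        raise RuntimeError(f"all pairwise identity tests failed: {errors}")
    table.attrs["errors"] = errors
    return table, results
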