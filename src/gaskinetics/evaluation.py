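"""Model-adequacy criteria and multi-model ranking.

Implements the evaluation battery commonly used for gas-production
curves: Gaussian-likelihood AIC, the R² of a linear regression of
predicted on observed values, Lin's concordance correlation coefficient
(CCC), the mean squared prediction error (MSPE) with its
mean-bias / systematic-bias / random-error decomposition, pairwise
paired-MSPE accuracy tests, and AIC evidence ratios exp(ΔAIC/2)
interpreted as how many times more likely the lowest-AIC model is to be
the minimum-information-loss model.

AIC is computed as n·ln(SSE/n) + 2(p + 1), counting the residual
variance as an estimated parameter. Only AIC *differences* are
transportable across software, so evidence ratios — not absolute AIC
values — are the comparable quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult, GasCurve
from .models import get_model

__all__ = [
    "aic",
    "evidence_ratio",
    "r2_pred_obs",
    "ccc",
    "mspe",
    "MSPEDecomposition",
    "paired_mspe_test",
    "EvaluationReport",
    "ModelComparison",
    "evaluate_fit",
    "rank_models",
]


def aic(sse: float, n_obs: int, n_params: int) -> float:
    """Gaussian AIC = n·ln(SSE/n) + 2(p + 1)."""
    if n_obs <= n_params:
        raise ValueError("AIC requires n_obs > n_params")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        warnings.warn("perfect fit (SSE = 0): AIC is -inf", RuntimeWarning)
        return -math.inf
    return n_obs * math.log(sse / n_obs) + 2.0 * (n_params + 1)


def evidence_ratio(aic_candidate: float, aic_best: float) -> float:
    """exp(ΔAIC/2): how many times more likely the best model is."""
    if aic_candidate < aic_best:
        raise ValueError(
            "evidence ratio is defined against the best (lowest-AIC) model; "
            f"got candidate AIC {aic_candidate} < best AIC {aic_best}"
        )
    half_delta = (aic_candidate - aic_best) / 2.0
    if half_delta > 700.0:  # beyond float range: report as infinite evidence
        return math.inf
    return math.exp(half_delta)


def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("non-finite values in predicted/observed")
    return p, o


def r2_pred_obs(predicted, observed) -> float:
    """R² of the simple linear regression of predicted on observed.

    Equals the squared Pearson correlation of the pairs, hence invariant
    to linear rescaling of either axis.
    """
    p, o = _paired(predicted, observed)
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(o) == 0 or np.ptp(p) == 0:
        raise ValueError("R^2 undefined for a constant vector")
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def ccc(predicted, observed) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2·cov(p, o) / (var(p) + var(o) + (mean(p) − mean(o))²), with 1/n
    variances and covariance.
    """
    p, o = _paired(predicted, observed)
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    vp, vo = p.var(), o.var()
    if vp == 0 or vo == 0:
        raise ValueError("CCC undefined for a constant vector")
    cov = np.mean((p - p.mean()) * (o - o.mean()))
    return float(2.0 * cov / (vp + vo + (p.mean() - o.mean()) ** 2))


@dataclass(frozen=True)
class MSPEDecomposition:
    """MSPE split into mean bias, systematic (slope) bias, random error."""

    mean_bias: float
    systematic_bias: float
    random_error: float

    @property
    def total(self) -> float:
        return self.mean_bias + self.systematic_bias + self.random_error


def mspe(predicted, observed) -> tuple[float, MSPEDecomposition]:
    """Mean squared prediction error and its exact decomposition.

    mean((o − p)²) = (ō − p̄)² + (s_p − r·s_o)² + (1 − r²)·s_o²
    with population standard deviations and Pearson r; the three
    components sum to the total identically.
    """
    p, o = _paired(predicted, observed)
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    total = float(np.mean((o - p) ** 2))
    mean_bias = float((o.mean() - p.mean()) ** 2)
    sp, so = p.std(), o.std()
    if sp == 0 or so == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(p, o)[0, 1])
    systematic = float((sp - r * so) ** 2)
    random_err = float((1.0 - r * r) * so * so)
    return total, MSPEDecomposition(mean_bias, systematic, random_err)


def paired_mspe_test(errors_a, errors_b) -> float:
    """Two-sided paired t-test on per-observation squared errors.

    The two error vectors must come from two models predicting the same
    observations; the test statistic is built on d_i = e²_{a,i} − e²_{b,i}.
    Returns the p-value.
    """
    ea = np.asarray(errors_a, dtype=float)
    eb = np.asarray(errors_b, dtype=float)
    if ea.shape != eb.shape or ea.ndim != 1 or ea.size < 3:
        raise ValueError("need two equal-length 1-D error vectors, length >= 3")
    d = ea**2 - eb**2
    if np.all(d == 0):
        return 1.0
    if d.std() == 0:
        raise ValueError("degenerate paired test: constant non-zero differences")
    return float(stats.ttest_rel(ea**2, eb**2).pvalue)


@dataclass
class EvaluationReport:
    """One adequacy row: a model's fit statistics on one curve."""

    model_id: str
    aic: float
    r2: float
    ccc: float
    mspe: float
    mspe_decomposition: MSPEDecomposition
    n_obs: int
    n_params: int
    converged: bool


@dataclass
class ModelComparison:
    """Best-model selection with evidence ratios and pairwise accuracy tests."""

    reference_model_id: str
    evidence_ratios: dict[str, float]
    pmspe_pvalues: pd.DataFrame


def evaluate_fit(result: FitResult, curve: GasCurve) -> EvaluationReport:
    """Adequacy criteria for one fitted model on the curve it was fit to."""
    pred = result.predict(curve.times)
    total, decomp = mspe(pred, curve.gas)
    return EvaluationReport(
        model_id=result.model_id,
        aic=aic(result.sse, result.n_obs, get_model(result.model_id).n_params),
        r2=r2_pred_obs(pred, curve.gas),
        ccc=ccc(pred, curve.gas),
        mspe=total,
        mspe_decomposition=decomp,
        n_obs=result.n_obs,
        n_params=get_model(result.model_id).n_params,
        converged=result.converged,
    )


def rank_models(
    fits: list[FitResult], curve: GasCurve
) -> tuple[pd.DataFrame, ModelComparison]:
    """Rank ≥ 2 fitted models on one curve by AIC with accuracy tests.

    Returns an adequacy table (one row per model: parameters ± SE, AIC,
    R², CCC, MSPE) and a :class:`ModelComparison` holding the lowest-AIC
    reference among converged fits, per-model evidence ratios, and the
    symmetric matrix of pairwise paired-MSPE p-values. Non-converged
    fits are reported but excluded from best-model selection.
    """
    if len(fits) < 2:
        raise ValueError("model ranking needs at least 2 fits to compare")
    ids = [f.model_id for f in fits]
    labels = [
        mid if ids.count(mid) == 1 else f"{mid}#{k}"
        for k, mid in enumerate(ids)
    ]
    reports = {lab: evaluate_fit(f, curve) for lab, f in zip(labels, fits)}
    rows = []
    for lab, f in zip(labels, fits):
        rep = reports[lab]
        row: dict[str, object] = {"model": lab}
        for name, est, se in zip(
            get_model(f.model_id).param_names, f.estimates, f.standard_errors
        ):
            row[name] = est
            row[f"se_{name}"] = se
        row.update(
            aic=rep.aic, r2=rep.r2, ccc=rep.ccc, mspe=rep.mspe,
            mean_bias=rep.mspe_decomposition.mean_bias,
            systematic_bias=rep.mspe_decomposition.systematic_bias,
            random_error=rep.mspe_decomposition.random_error,
            converged=f.converged, algorithm=f.algorithm,
        )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")

    converged = [lab for lab, f in zip(labels, fits) if f.converged]
    if not converged:
        raise ValueError("no converged fit available for best-model selection")
    best = min(converged, key=lambda lab: reports[lab].aic)
    best_aic = reports[best].aic
    ratios = {
        lab: evidence_ratio(max(reports[lab].aic, best_aic), best_aic)
        for lab in converged
    }

    errs = {
        lab: curve.gas - f.predict(curve.times) for lab, f in zip(labels, fits)
    }
    pmat = pd.DataFrame(
        np.ones((len(labels), len(labels))), index=labels, columns=labels
    )
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            p = paired_mspe_test(errs[a], errs[b])
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return table, ModelComparison(best, ratios, pmat)
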