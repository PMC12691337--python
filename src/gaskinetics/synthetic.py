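"""Synthetic ANKOM-style cumulative gas-production experiments.

The generator emulates the design of a wireless pressure-sensor in
vitro incubation: four silage treatments (0/10/20/30 % additive
inclusion) with replicate flasks, a handful of substrate-free blank
flasks, and readings every 5 minutes over 24 h. Each treatment's truth
is a Richards curve; the default truths are the per-treatment equations
estimated in the study this pipeline reproduces:

    0 %:  P(t) = 4.87·(1 − 1.09·exp(−0.10t))^2.05
    10 %: P(t) = 4.61·(1 − 1.06·exp(−0.12t))^2.30
    20 %: P(t) = 5.66·(1 − 1.04·exp(−0.13t))^2.50
    30 %: P(t) = 6.18·(1 − 0.97·exp(−0.17t))^1.99

Noise model: the recorded signal is cumulative, so noise is applied to
per-interval increments — Gaussian steps with standard deviation
noise_sd/√(n_intervals), so the cumulative deviation at the end of the
incubation has scale ``noise_sd`` (mL/100 mg DM) — and any
transiently negative increment carries its deficit forward
(equivalently, the series is the running maximum of the noisy
cumulative path). This keeps every raw series monotone non-decreasing
and near-unbiased for the truth. Blank flasks follow a zero-substrate
drift process built the same way; sample flasks include an independent
background of the same distribution, so subtracting the mean blank is
unbiased in expectation.

Raw flask volumes are in mL for the whole flask; dividing the
blank-corrected volume by (mass_mg/100) converts to mL per 100 mg
incubated DM (the study incubated 500 mg, hence a factor of 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import GasCurve
from .models import evaluate, get_model

__all__ = [
    "TREATMENT_TRUTHS",
    "ExperimentConfig",
    "generate_flask",
    "generate_experiment",
    "blank_correct",
    "default_grid",
]

#: Per-treatment Richards truths (A, B, C, D) by inclusion level (%).
TREATMENT_TRUTHS: dict[str, tuple[float, ...]] = {
    "0": (4.87, 1.09, 0.10, 2.05),
    "10": (4.61, 1.06, 0.12, 2.30),
    "20": (5.66, 1.04, 0.13, 2.50),
    "30": (6.18, 0.97, 0.17, 1.99),
}

SAMPLE_MASS_MG = 500.0  # incubated substrate per flask


def default_grid(sampling_interval_min: float = 5.0, duration_h: float = 24.0) -> np.ndarray:
    """Reading times in hours: t = 0 to duration, every sampling interval."""
    step = sampling_interval_min / 60.0
    n = duration_h / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration must be an integer number of sampling intervals")
    return np.arange(round(n) + 1) * step


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one synthetic incubation run."""

    treatments: tuple[tuple[str, str, tuple[float, ...]], ...] = tuple(
        (label, "richards", params) for label, params in TREATMENT_TRUTHS.items()
    )
    n_flasks_per_treatment: int = 6
    n_blanks: int = 3
    sampling_interval: float = 5.0  # minutes
    duration: float = 24.0  # hours
    noise_sd: float = 0.1  # mL/100 mg DM, cumulative scale
    blank_drift_sd: float = 0.05  # mL, cumulative scale (whole flask)
    sample_mass_mg: float = SAMPLE_MASS_MG
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.blank_drift_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_flasks_per_treatment < 0 or self.n_blanks < 0:
            raise ValueError("flask counts must be >= 0")
        if self.sample_mass_mg <= 0:
            raise ValueError("sample mass must be > 0")
        for label, model_id, params in self.treatments:
            get_model(model_id)  # validates the id

    @property
    def grid(self) -> np.ndarray:
        return default_grid(self.sampling_interval, self.duration)


def _noisy_cumulative(truth: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone noisy version of a cumulative truth series.

    Gaussian noise on per-interval increments (step sd = sd/√n), with
    negative-increment deficits carried forward: the result is the
    running maximum of truth + random walk, floored at zero.
    """
    if sd == 0 or truth.size < 2:
        return truth.copy()
    n_steps = truth.size - 1
    steps = rng.normal(0.0, sd / np.sqrt(n_steps), size=n_steps)
    walk = np.concatenate([[0.0], np.cumsum(steps)])
    return np.maximum(np.maximum.accumulate(truth + walk), 0.0)


def generate_flask(
    model_id: str,
    params,
    grid: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One flask's cumulative gas series (truth units) on the grid."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = evaluate(model_id, params, grid)
    return _noisy_cumulative(truth, noise_sd, rng)


def generate_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Full long-format raw gas table for one synthetic run.

    Columns: treatment, flask, is_blank, time_h, gas (raw mL, whole
    flask). Sample flasks carry mass_factor × noisy truth plus an
    independent blank-like background; blanks carry background only.
    Provenance (config echo and seed) is attached as ``df.attrs``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    mass_factor = config.sample_mass_mg / 100.0
    zeros = np.zeros_like(grid)
    frames = []
    for label, model_id, params in config.treatments:
        for k in range(config.n_flasks_per_treatment):
            signal = mass_factor * generate_flask(
                model_id, params, grid, config.noise_sd, rng
            )
            background = _noisy_cumulative(zeros, config.blank_drift_sd, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "treatment": label,
                        "flask": f"{label}_f{k + 1}",
                        "is_blank": False,
                        "time_h": grid,
                        "gas": signal + background,
                    }
                )
            )
    for k in range(config.n_blanks):
        background = _noisy_cumulative(zeros, config.blank_drift_sd, rng)
        frames.append(
            pd.DataFrame(
                {
                    "treatment": "blank",
                    "flask": f"blank_f{k + 1}",
                    "is_blank": True,
                    "time_h": grid,
                    "gas": background,
                }
            )
        )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["treatment", "flask", "is_blank", "time_h", "gas"]
        )
    table.attrs["provenance"] = {
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "blank_drift_sd": config.blank_drift_sd,
        "sampling_interval_min": config.sampling_interval,
        "duration_h": config.duration,
        "n_flasks_per_treatment": config.n_flasks_per_treatment,
        "n_blanks": config.n_blanks,
        "sample_mass_mg": config.sample_mass_mg,
        "treatments": [
            {"label": lab, "model": mid, "params": list(par)}
            for lab, mid, par in config.treatments
        ],
    }
    return table


def blank_correct(
    table: pd.DataFrame, sample_mass_mg: float = SAMPLE_MASS_MG
) -> list[GasCurve]:
    """Blank-correct raw flask series and normalize to mL/100 mg DM.

    The mean blank series is subtracted pointwise from each sample
    flask, then volumes are divided by sample_mass_mg/100 (÷5 for the
    500 mg standard load). Requires every flask to share one time grid.
    """
    if sample_mass_mg <= 0:
        raise ValueError("sample mass must be > 0")
    required = {"treatment", "flask", "is_blank", "time_h", "gas"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"raw gas table missing columns: {sorted(missing)}")
    blanks = table[table["is_blank"].astype(bool)]
    samples = table[~table["is_blank"].astype(bool)]
    if blanks.empty:
        raise ValueError("no blank flasks present: cannot blank-correct")
    grids = {
        flask: g["time_h"].to_numpy()
        for flask, g in table.groupby("flask", sort=False)
    }
    ref = next(iter(grids.values()))
    for flask, g in grids.items():
        if g.shape != ref.shape or not np.allclose(g, ref):
            raise ValueError(f"flask {flask!r} time grid differs: grids must align")
    mean_blank = (
        blanks.groupby("time_h", sort=True)["gas"].mean().to_numpy()
    )
    mass_factor = sample_mass_mg / 100.0
    curves = []
    for (treatment, flask), g in samples.groupby(["treatment", "flask"], sort=False):
        g = g.sort_values("time_h")
        corrected = (g["gas"].to_numpy() - mean_blank) / mass_factor
        curves.append(
            GasCurve(
                treatment_id=str(treatment),
                replicate_id=str(flask),
                times=g["time_h"].to_numpy(),
                gas=corrected,
            )
        )
    return curves
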