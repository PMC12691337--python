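import numpy as np
import pytest

from gaskinetics import GasCurve, TREATMENT_TRUTHS, default_grid, evaluate

#: A representative valid parameter set per model family (values in the
#: range reported for tropical silage fermentation curves).
EXAMPLE_PARAMS = {
    "gompertz": (5.03, 3.89, 0.19),
    "orskov_mcdonald": (-0.50, 7.48, 0.06),
    "brody": (6.98, 1.0, 0.06),
    "richards": (5.36, 1.03, 0.13, 2.03),
    "dual_pool_logistic": (1.20, 0.25, 3.50, 3.76, 0.07),
}


@pytest.fixture(scope="session")
def grid():
    """5-minute readings over 24 h (289 points), the study design."""
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """30-minute grid, for cheap repeated fits."""
    return default_grid(sampling_interval_min=30.0)


@pytest.fixture(scope="session")
def noiseless_curves(grid):
    """One noiseless GasCurve per model family from EXAMPLE_PARAMS."""
    return {
        mid: GasCurve("t", "1", grid, evaluate(mid, params, grid))
        for mid, params in EXAMPLE_PARAMS.items()
    }


@pytest.fixture(scope="session")
def treatment_truth_curves(grid):
    """Noiseless per-treatment Richards curves from the treatment-level truths."""
    return {
        label: GasCurve(label, "1", grid, evaluate("richards", params, grid))
        for label, params in TREATMENT_TRUTHS.items()
    }
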