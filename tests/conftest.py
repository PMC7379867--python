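import numpy as np
import pytest

from nirsfda import (
    BSplineBasis,
    FunctionalPCA,
    PenalizedBSplineSmoother,
    SimulationParams,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def basis():
    return BSplineBasis()


@pytest.fixture(scope="session")
def cohort500(basis):
    """Full-scale synthetic cohort (500 x 12,001 samples) with its fitted
    smoother and functional PCA, shared across the suite."""
    params = SimulationParams(n_subjects=500, seed=0)
    subjects = simulate_cohort(params)
    X = np.stack([s.curve.values for s in subjects])
    grid = subjects[0].curve.grid
    smoother = PenalizedBSplineSmoother(basis=basis).fit(X, grid=grid)
    model = FunctionalPCA(basis=basis).fit(smoother.coefficients_)
    return {
        "params": params,
        "subjects": subjects,
        "X": X,
        "grid": grid,
        "smoother": smoother,
        "model": model,
        "features": np.array(
            [[s.true_baseline, s.true_depth, s.true_nadir_time] for s in subjects]
        ),
    }


@pytest.fixture(scope="session")
def small_cohort(basis):
    """Cheap 60-subject cohort at 10 Hz for structural tests."""
    params = SimulationParams(n_subjects=60, sampling_rate=10.0, seed=3)
    subjects = simulate_cohort(params)
    X = np.stack([s.curve.values for s in subjects])
    grid = subjects[0].curve.grid
    smoother = PenalizedBSplineSmoother(basis=basis).fit(X, grid=grid)
    model = FunctionalPCA(basis=basis).fit(smoother.coefficients_)
    return {
        "params": params,
        "subjects": subjects,
        "X": X,
        "grid": grid,
        "smoother": smoother,
        "model": model,
    }
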