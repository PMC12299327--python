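import numpy as np
import pytest

import ferncast as fc


@pytest.fixture(scope="session")
def small_landscape():
    """A small landscape with known logistic truth, shared across tests."""
    lc = fc.LandscapeConfig(
        grid_rows=60,
        grid_cols=60,
        n_vars=8,
        scenario_deltas={
            "SSP126-2050": np.r_[0.3, 0.3, np.zeros(6)],
            "SSP585-2090": np.r_[2.0, 2.0, np.zeros(6)],
        },
        seed=11,
    )
    stack = fc.generate_env_stack(lc)
    truth = fc.default_truth(8)
    return lc, stack, truth


@pytest.fixture(scope="session")
def presence_absence(small_landscape):
    """Presences, pseudo-absences and their covariate matrix."""
    _, stack, truth = small_landscape
    pres = fc.generate_occurrences(stack, truth, 176, seed=12)
    pa = fc.sample_pseudo_absences(stack, pres, 600, seed=13)
    pts = fc.OccurrenceSet.concat(pres, pa)
    X = stack.values_at(pts.lon, pts.lat).to_numpy()
    y = pts.is_presence.astype(int)
    return pts, X, y


@pytest.fixture(scope="session")
def fitted_ensemble(presence_absence):
    """One ensemble fit reused by every test that needs a trained model."""
    import warnings

    _, X, y = presence_absence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fc.EnsembleSDM(repeats=3, random_state=0).fit(X, y)
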