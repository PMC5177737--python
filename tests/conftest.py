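import numpy as np
import pytest

from hemopk.estimation import fit_population
from hemopk.simulate import default_fviii_spec, simulate_cohort


@pytest.fixture(scope="session")
def rich_cohort():
    """20-subject rich (11-sample) FVIII-like cohort with known truth."""
    spec = default_fviii_spec(n_subjects=20, seed=101)
    ds, gt = simulate_cohort(spec)
    return spec, ds, gt


@pytest.fixture(scope="session")
def rich_fit(rich_cohort):
    spec, ds, _ = rich_cohort
    fit = fit_population(ds, spec.truth, compute_se=True)
    assert fit.converged
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
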