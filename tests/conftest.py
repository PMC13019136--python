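import numpy as np
import pytest

import fedprint as fp


@pytest.fixture(scope="session")
def small_cohort():
    """200 x 30 cohort without injections; both classes present."""
    spec = fp.CohortSpec(n_samples=200, n_loci=30, seed=123)
    return fp.generate_cohort(spec, inject=False)


@pytest.fixture(scope="session")
def injected_cohort():
    """300 x 40 cohort with default duplicate/outlier injections."""
    spec = fp.CohortSpec(n_samples=300, n_loci=40, seed=7)
    return fp.generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort where the phenotype is a deterministic function of one locus."""
    rng = np.random.default_rng(5)
    values = rng.integers(0, 3, size=(120, 10)).astype(float)
    labels = (values[:, 3] >= 1).astype(int)
    return fp.GenotypeMatrix(values), fp.PhenotypeVector(labels)
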