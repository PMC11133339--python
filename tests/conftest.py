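import warnings

import numpy as np
import pandas as pd
import pytest

from triaxis.synthetic import (CohortDesign, default_effects, generate_cohort,
                               write_bundle)


def small_design(seed=0, n_cases=60, n_controls=70):
    """Three-site design small enough for per-test generation."""
    sites = (("SiteA", 0.5, 0.4), ("SiteB", 0.45, 0.3), ("SiteC", 0.45, 0.3))
    return CohortDesign(n_cases=n_cases, n_controls=n_controls, sites=sites,
                        seed=seed, n_batches=2)


@pytest.fixture(scope="session")
def cohort():
    design = small_design(seed=11)
    samples, records = generate_cohort(design)
    return design, samples, records


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full-size synthetic bundle on disk, shared across pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    design = CohortDesign(seed=7)
    effects = default_effects(seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = write_bundle(design, effects, out)
    return out, design, effects, bundle


@pytest.fixture
def rng():
    return np.random.default_rng(0)
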