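import warnings

import numpy as np
import pytest

from mediablend.composition import CompositionMatrix
from mediablend.synthetic import SyntheticSpec, synth_composition, synth_response
from mediablend.workflow import design_conditions, synthetic_screening_run


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_composition(rng):
    """6 media x 10 components, strictly positive, no constant columns."""
    values = rng.uniform(0.1, 5.0, size=(6, 10))
    return CompositionMatrix(
        media_ids=tuple(f"M{i}" for i in range(6)),
        component_ids=tuple(f"c{j}" for j in range(10)),
        values=values,
    )


@pytest.fixture(scope="session")
def case_study_pipeline():
    """One reduced-size screening run shared across test modules.

    Synthetic 11x67 composition, 120-condition design (2000 search
    iterations), VCC-like response, the four linear models, adjusted-PFI
    consensus. Seed frozen so downstream assertions are deterministic.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic_screening_run(
            SyntheticSpec(), seed=11, design_iters=2000
        )


@pytest.fixture(scope="session")
def designed_conditions():
    """A composition + designed condition matrix, reused where the
    regression/importance stages are not needed."""
    spec = SyntheticSpec()
    rng = np.random.default_rng(7)
    comp, achieved = synth_composition(spec, rng=rng)
    sel, enum, proj, x_cond = design_conditions(comp, design_iters=2000, rng=rng)
    return {
        "spec": spec,
        "composition": comp,
        "achieved": achieved,
        "selection": sel,
        "enumeration": enum,
        "projection": proj,
        "x_cond": x_cond,
        "rng_seed": 7,
    }
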