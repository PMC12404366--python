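import numpy as np
import pytest

import fruitqual as fq
from fruitqual import synthetic


@pytest.fixture(scope="session")
def config_path():
    return fq.default_config_path()

@pytest.fixture(scope="session")
def study(config_path):
    """Packaged pineapple study: (hierarchy, first-level matrix, group matrices)."""
    hierarchy, first, groups, extras = fq.load_config(config_path)
    return hierarchy, first, groups, extras


@pytest.fixture(scope="session")
def hierarchy(study):
    return study[0]


@pytest.fixture(scope="session")
def samples23():
    """Synthetic 23 x 15 pineapple-style table, fixed seed."""
    return synthetic.generate(synthetic.default_generator_spec(n_samples=23, seed=7))


@pytest.fixture(scope="session")
def fitted(study, samples23):
    hierarchy, first, groups, _ = study
    return fq.QualityModel(hierarchy, first, groups, samples23).fit()


@pytest.fixture
def toy_hierarchy():
    """Minimal single-group system with two benefit indicators."""
    return fq.Hierarchy(
        first_level=("g",),
        indicators=(
            fq.IndicatorSpec(id="a", label="a", group="g", orientation="benefit"),
            fq.IndicatorSpec(id="b", label="b", group="g", orientation="benefit"),
        ),
    )


def make_oriented(values, columns=None, sample_ids=None):
    """Build an OrientedMatrix directly from an array of values in [0, 1]."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    columns = columns or [f"c{j}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return fq.OrientedMatrix(
        values=values,
        columns=list(columns),
        sample_ids=list(sample_ids),
        transforms={c: "benefit" for c in columns},
    )
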