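import warnings

import pytest

from lcckit import fixtures, run_efa, run_ism
from lcckit.synth import default_scenario, gen_efa_panels, gen_ism_panel


@pytest.fixture(scope="session")
def reference():
    """Bundled case-study constants (factors, weights/NV, grades, meta)."""
    return fixtures.load_reference_tables()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=7)


@pytest.fixture(scope="session")
def efa_panels(scenario):
    return gen_efa_panels(scenario)


@pytest.fixture(scope="session")
def ledger(efa_panels, reference):
    consumption, areas, registry = efa_panels
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_efa(consumption, areas, registry, reference.factors)


@pytest.fixture(scope="session")
def ism_inputs(scenario):
    return gen_ism_panel(scenario)


@pytest.fixture(scope="session")
def lcc_series(ism_inputs, reference):
    matrix, meta = ism_inputs
    return run_ism(
        matrix, meta, target_years=(2015, 2020, 2030),
        scale=reference.grade_scale,
    )
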