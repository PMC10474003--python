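import numpy as np
import pytest

from timeco import ModelParameters, load_fixture


@pytest.fixture(scope="session")
def killing_sweep():
    return load_fixture("killing_sweep").parameters


@pytest.fixture(scope="session")
def fold_sweep():
    return load_fixture("fold_sweep").parameters


@pytest.fixture(scope="session")
def basin_ref():
    return load_fixture("basin_ref").parameters


@pytest.fixture(scope="session")
def variant_ref():
    return load_fixture("variant_ref").parameters


@pytest.fixture(scope="session")
def runaway_ref():
    return load_fixture("runaway_ref").parameters


def random_parameters(rng, *, omega=None, enforce_tp_feasibility=True):
    """One log-uniform parameter draw in [0.05, 5], optionally rejecting
    draws that violate the TP feasibility (bounded-growth) condition."""
    names = [n for n in ModelParameters.field_names() if n != "omega"]
    while True:
        values = {n: float(np.exp(rng.uniform(np.log(0.05), np.log(5)))) for n in names}
        values["omega"] = (
            float(np.exp(rng.uniform(np.log(0.05), np.log(5))))
            if omega is None
            else float(omega)
        )
        p = ModelParameters(**values)
        if not enforce_tp_feasibility:
            return p
        if p.r_T / p.K_T > p.alpha_TP * p.alpha_PT / p.d_P:
            return p


@pytest.fixture()
def rng():
    return np.random.default_rng(20230901)
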