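import numpy as np
import pytest

from nanopbpk import (DoseEvent, Physiology, load_pd_parameters, load_physiology,
                      load_pk_parameters)


@pytest.fixture(scope="session")
def mouse():
    return load_physiology("mouse")


@pytest.fixture(scope="session")
def human():
    return load_physiology("human")


@pytest.fixture(scope="session")
def taxol():
    return load_pk_parameters("taxol")


@pytest.fixture(scope="session")
def f68():
    return load_pk_parameters("f68-ptx-nc")


@pytest.fixture(scope="session")
def mouse_dose():
    # 20 mg/kg for a 20 g animal
    return DoseEvent.per_kg(20.0, 20.0)


@pytest.fixture(scope="session")
def human_dose():
    return DoseEvent(316.0 * 1000.0)


@pytest.fixture(scope="session")
def balanced_physiology():
    """Synthetic physiology whose venous return equals cardiac output exactly.

    The printed species tables do not balance; conservation unit tests use
    this one so that any residual is attributable to the solver.
    """
    Q = {"li": 0.10, "sp": 0.006, "ht": 0.017, "kd": 0.078, "tu": 0.001, "rm": 0.258}
    Q_he = 0.02
    # venous return to the lung: splenic flow is part of the portal flow
    # (blood -> spleen -> liver), so it is not counted separately
    co = Q_he + sum(Q[c] for c in ("li", "ht", "kd", "tu", "rm"))
    Q.update({"bl": co, "lu": co})
    V = {"bl": 0.0017, "lu": 0.0001, "li": 0.0015, "sp": 0.0000847,
         "ht": 0.0000678, "kd": 0.00027, "tu": 0.0016, "rm": 0.013}
    return Physiology(species="synthetic-balanced", Q=Q, V=V, Q_he=Q_he)


@pytest.fixture(scope="session")
def control_pd():
    return load_pd_parameters(None, species="mouse")
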