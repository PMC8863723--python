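import pytest

from dualconcept import standard_experiment


@pytest.fixture(scope="session")
def plan_x():
    return standard_experiment("X", seed=0)


@pytest.fixture(scope="session")
def plan_y():
    return standard_experiment("Y", seed=0)


@pytest.fixture(scope="session")
def plans(plan_x, plan_y):
    return {"X": plan_x, "Y": plan_y}


@pytest.fixture(scope="session")
def trial1(plan_x):
    return plan_x.trial(1)


@pytest.fixture(scope="session")
def trial6(plan_x):
    return plan_x.trial(6)
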