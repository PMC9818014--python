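import hypothesis
import pytest

import fjordweb as fw

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def coloane():
    """The bundled 21-group Magellan Strait fjord model."""
    return fw.load_coloane()


@pytest.fixture(scope="session")
def balanced(coloane):
    return fw.solve_mass_balance(coloane)


@pytest.fixture(scope="session")
def trophic(balanced):
    return fw.trophic_levels(balanced)


@pytest.fixture(scope="session")
def scenario_report(balanced):
    """The seven standard removal scenarios (run once per session)."""
    return fw.run_scenarios(balanced)


def make_model(groups, diet, **kwargs):
    """Convenience builder for hand-made toy webs in tests."""
    import pandas as pd

    names = [g.name for g in groups]
    consumers = [g.name for g in groups if g.role == "consumer"]
    frame = pd.DataFrame(0.0, index=names, columns=consumers)
    for (prey, pred), frac in diet.items():
        frame.loc[prey, pred] = frac
    return fw.FoodWebModel(groups=groups, diet=frame, **kwargs)
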