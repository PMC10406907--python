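import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cwboost.data_model import VariableSpec, build_design

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dictionary():
    """One binary, one 3-category, one 4-category and two more binaries."""
    return [
        VariableSpec("irrigation", "binary", ("no", "yes"), group="biophysical",
                     is_moderator=True),
        VariableSpec("education", "categorical", ("low", "mid", "high"),
                     group="human"),
        VariableSpec("region", "categorical",
                     ("CentralChile", "CentralTunisia", "NorthernTunisia",
                      "SouthernChile"), group="natural", is_moderator=True),
        VariableSpec("debt", "binary", ("no", "yes"), group="economic"),
        VariableSpec("tradition", "binary", ("no", "yes"), group="goals"),
    ]


@pytest.fixture
def small_data(small_dictionary, rng):
    n = 60
    cols = {}
    for spec in small_dictionary:
        probs = np.full(len(spec.categories), 1.0 / len(spec.categories))
        cols[spec.name] = rng.choice(spec.categories, size=n, p=probs)
    return pd.DataFrame(cols)


@pytest.fixture
def small_design(small_data, small_dictionary):
    return build_design(small_data, small_dictionary)


def random_binary_design(rng, n=60, p=8, n_cat=0):
    """A quick random design: p binary variables plus n_cat 3-level ones."""
    specs, cols = [], {}
    for i in range(p):
        name = f"b{i}"
        specs.append(VariableSpec(name, "binary", ("no", "yes"), group=f"g{i % 3}"))
        cols[name] = rng.choice(["no", "yes"], size=n)
    for i in range(n_cat):
        name = f"c{i}"
        specs.append(
            VariableSpec(name, "categorical", ("a", "b", "c"), group="gc")
        )
        cols[name] = rng.choice(["a", "b", "c"], size=n)
    data = pd.DataFrame(cols)
    # re-draw any constant column (tiny n can produce one)
    for name in data.columns:
        spec = next(s for s in specs if s.name == name)
        while data[name].nunique() < 2:
            data[name] = rng.choice(spec.categories, size=n)
    return data, specs
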