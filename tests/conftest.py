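import numpy as np
import pytest

from pteroevo import (RegimeScheme, SimulationConfig, read_newick,
                      simulate_trait, simulate_yule)

# the study conditions: a ~56-tip clade with crown age ~8.7 Myr and a
# four-optimum OU truth on the scale of the fitted Hansen model
OU4_TRUTH = {"alpha": 0.60, "sigma2": 52.0,
             "theta": {"L": 93.4, "M": 65.1, "S": 47.5, "I": 54.4}}
OU3_TRUTH = {"alpha": 0.60, "sigma2": 52.0,
             "theta": {"L": 93.4, "M": 65.1, "S": 47.5}}


@pytest.fixture(scope="session")
def small_tree():
    return read_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture()
def small_traits():
    return {"A": 2.0, "B": 4.0, "C": 3.0}


@pytest.fixture(scope="session")
def yule56():
    return simulate_yule(56, crown_age=8.7, seed=101)


@pytest.fixture(scope="session")
def scheme4_56(yule56):
    """Planted four-category painting on the 56-tip tree."""
    rng = np.random.default_rng(101)
    cats = ["S", "M", "L", "I"]
    labels = [cats[i] for i in rng.integers(0, 4, yule56.n_tips)]
    return RegimeScheme("four_cat",
                        dict(zip(yule56.tip_labels, labels)),
                        internal_category="M")


@pytest.fixture(scope="session")
def scheme3_56(scheme4_56):
    cats = {t: ("M" if c == "I" else c)
            for t, c in scheme4_56.tip_categories.items()}
    return RegimeScheme("three_cat", cats, internal_category="M")


def simulate_ou4(tree, scheme, seed):
    cfg = SimulationConfig(seed=seed, model="OU", **OU4_TRUTH)
    return simulate_trait(tree, cfg, regimes=scheme)


def simulate_ou3(tree, scheme, seed):
    cfg = SimulationConfig(seed=seed, model="OU", **OU3_TRUTH)
    return simulate_trait(tree, cfg, regimes=scheme)


def simulate_bm(tree, seed, sigma2=33.9, z0=200.0):
    # default z0 sits far from zero so Brownian excursions at the fitted
    # rate cannot cross the positivity bound of the trait table; the
    # calibration statistics computed from these draws are location- and
    # scale-invariant
    cfg = SimulationConfig(seed=seed, model="BM", sigma2=sigma2, alpha=0.0,
                           theta={"M": z0}, z0=z0)
    return simulate_trait(tree, cfg)
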