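import numpy as np
import pandas as pd
import pytest

from physdens import synth, ztnb

SMALL_SPEC_NAMES = ("population_density", "hospital_beds", "city")


def small_specs():
    return [s for s in synth.default_covariate_specs() if s.name in SMALL_SPEC_NAMES]


SMALL_COEFS = {
    "gp": {
        "intercept": 1.7,
        "population_density": -0.15,
        "hospital_beds": 0.1,
        "city": 0.1,
    },
    "sp": {
        "intercept": 1.9,
        "population_density": 0.3,
        "hospital_beds": 0.2,
        "city": 0.15,
    },
}


@pytest.fixture(scope="session")
def small_table():
    """412-district table with a compact covariate set, fixed seed."""
    cfg = synth.GeneratorConfig(
        seed=11,
        specs=small_specs(),
        coefficients=SMALL_COEFS,
        sigma={"gp": 0.05, "sp": 0.05},
        n_regions=5,
    )
    table, truth = synth.generate_table(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_fit(small_table):
    table, _ = small_table
    spec = ztnb.ModelSpec(
        response="gp_count",
        metric=("population_density", "hospital_beds"),
        binary=("city",),
    )
    return ztnb.fit_table(table, spec)


@pytest.fixture(scope="session")
def default_table_5000():
    """Large table with the full default covariate set and truth record."""
    cfg = synth.GeneratorConfig(seed=1, n_districts=5000, n_regions=17)
    return synth.generate_table(cfg)


def make_fake_fit(term_pvalues, spec=None, interactions=()):
    """ZTNBFit with prescribed two-sided p-values for selection-rule tests."""
    from scipy import stats

    names = list(term_pvalues)
    binary_parents = {b for _, b in interactions}
    metric = tuple(n for n in names if ":" not in n and n not in binary_parents)
    binary = tuple(n for n in names if ":" not in n and n in binary_parents)
    if spec is None:
        spec = ztnb.ModelSpec(
            response="gp_count",
            metric=metric,
            binary=binary,
            interactions=interactions,
        )
    columns = ("intercept", *spec.term_names)
    coefs = [1.0]
    for name in spec.term_names:
        z = stats.norm.isf(term_pvalues[name] / 2.0)
        coefs.append(z)  # with unit SE, |z| reproduces the wanted p
    cov = np.eye(len(columns) + 1)
    return ztnb.ZTNBFit(
        spec=spec,
        columns=columns,
        coefficients=np.array(coefs),
        log_sigma=0.0,
        cov=cov,
        loglik=-1.0,
        n=100,
        convergence={"converged": True},
        scaling={name: (0.0, 1.0) for name in metric},
    )
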