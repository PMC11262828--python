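"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest


def records_from(y, *, site="S", seed=0, **covariates):
    """Assemble a survey-record table from raw arrays."""
    y = np.asarray(y)
    n = y.size
    rng = np.random.default_rng(seed)
    data = {
        "site": site,
        "x": rng.uniform(0, 10_000, n),
        "y": rng.uniform(0, 10_000, n),
    }
    for name, vals in covariates.items():
        data[name] = np.asarray(vals, dtype=float)
    data["response"] = y.astype(int)
    return pd.DataFrame(data)


def logistic_records(n, seed, effect=None, **extra_covariates):
    """Records with one covariate 'a' driving the response through `effect`.

    `effect` maps the covariate to a log-odds contribution (default zero).
    Extra covariates are independent uniforms named as given.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, n)
    eta = np.zeros(n) if effect is None else np.asarray(effect(a), dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=n) < p).astype(int)
    covs = {"a": a}
    for name in extra_covariates:
        covs[name] = rng.uniform(0, 1, n)
    return records_from(y, seed=seed + 1, **covs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
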