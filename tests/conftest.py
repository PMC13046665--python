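import numpy as np
import pytest

from knowretain.blueprint import (
    default_specialties,
    default_systems,
    example_label_map,
)
from knowretain.irt import Item


@pytest.fixture(scope="session")
def systems():
    return default_systems()


@pytest.fixture(scope="session")
def specialties():
    return default_specialties()


@pytest.fixture(scope="session")
def label_map():
    return example_label_map()


@pytest.fixture(scope="session")
def small_bank():
    """20 items, difficulties equally spaced on [-2, 2], one system."""
    diffs = np.linspace(-2, 2, 20)
    return [Item(f"q{j:02d}", "cardiovascular", float(d)) for j, d in enumerate(diffs)]


def eap_dense_oracle(responses, difficulties, lo=-9.0, hi=9.0, n=12001):
    """Posterior mean/SD by brute-force trapezoid integration on a dense grid."""
    from scipy.special import expit
    from scipy.stats import norm

    theta = np.linspace(lo, hi, n)
    p = expit(theta[:, None] - np.asarray(difficulties)[None, :])
    x = np.asarray(responses)
    loglik = (x * np.log(p) + (1 - x) * np.log1p(-p)).sum(axis=1)
    post = norm.pdf(theta) * np.exp(loglik - loglik.max())
    z = np.trapezoid(post, theta)
    mean = np.trapezoid(theta * post, theta) / z
    var = np.trapezoid((theta - mean) ** 2 * post, theta) / z
    return mean, np.sqrt(var)


def simulate_rasch_responses(theta, difficulties, rng):
    """Bernoulli Rasch response matrix for given abilities and difficulties."""
    from scipy.special import expit

    p = expit(theta[:, None] - difficulties[None, :])
    return (rng.random(p.shape) < p).astype(int)


def long_format(x, person_prefix="P", item_prefix="q", timepoint=1):
    """Turn a dense 0/1 matrix into long-format response records."""
    import pandas as pd

    n, k = x.shape
    return pd.DataFrame(
        {
            "person_id": np.repeat([f"{person_prefix}{i:05d}" for i in range(n)], k),
            "item_id": np.tile([f"{item_prefix}{j:02d}" for j in range(k)], n),
            "timepoint": timepoint,
            "response": x.ravel(),
        }
    )
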