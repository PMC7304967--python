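import numpy as np
import pytest

from savor import ModelParams, stability_bound


@pytest.fixture
def boosting_params() -> ModelParams:
    """Parameters with substantial boosting, weak discounting: the regime in
    which anticipation of delayed rewards drives information seeking."""
    base = ModelParams(R_minus=-0.5, eta0=0.5, C=0.0, nu_plus=0.05,
                       nu_minus=0.05, gamma=0.01, sigma=0.25)
    return base.replace(C=0.3 * stability_bound(base))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_admissible_params(rng: np.random.Generator) -> ModelParams:
    """A random parameter draw guaranteed to satisfy the stability bound."""
    base = ModelParams(
        R_minus=-float(rng.uniform(0.0, 1.5)),
        eta0=float(rng.uniform(0.0, 2.0)),
        C=0.0,
        nu_plus=float(rng.uniform(0.02, 1.0)),
        nu_minus=float(rng.uniform(0.02, 1.0)),
        gamma=float(rng.uniform(0.001, 0.5)),
        sigma=float(rng.uniform(0.05, 2.0)),
    )
    frac = float(rng.uniform(0.0, 0.95))
    return base.replace(C=frac * stability_bound(base))
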