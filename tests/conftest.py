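import numpy as np
import pandas as pd
import pytest

from beechtrial.simulate import TraitEffectSpec, TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def balanced_trial() -> pd.DataFrame:
    """A balanced 10×3×10 trial with one trait of known variance structure."""
    design = TrialDesign(10, 3, 10, seed=7)
    return simulate_trial(design, {"y": TraitEffectSpec(10.0, 2.0, 1.0, 1.5)})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def dense_gaussian_loglik(variances, y, provenance, block, method="REML"):
    """Brute-force (restricted) log-likelihood via the explicit n×n covariance.

    Independent oracle for the Woodbury-based implementation; only usable for
    small n.
    """
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1))
    Zp = pd.get_dummies(pd.Series(provenance)).to_numpy(float)
    Zb = pd.get_dummies(pd.Series(block)).to_numpy(float)
    V = variances[2] * np.eye(n) + variances[0] * Zp @ Zp.T + variances[1] * Zb @ Zb.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    quad = r @ Vi @ r
    if method == "REML":
        _, logdet_x = np.linalg.slogdet(X.T @ Vi @ X)
        return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet_v + logdet_x + quad)
    return -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
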