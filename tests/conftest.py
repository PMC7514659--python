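import numpy as np
import pytest

from infotherm import BLRMParams, RLParams, SimConfig, simulate_receptor_ligand

#: reference parameter sets used throughout the suite
REF_BLRM = BLRMParams(trel=10.0, D=1.0, alpha=1.0, beta=0.2)
REF_RL = RLParams(kon=5.0, koff=1.0, h=2.0)


@pytest.fixture(scope="session")
def blrm_params() -> BLRMParams:
    return REF_BLRM


@pytest.fixture(scope="session")
def rl_params() -> RLParams:
    return REF_RL


@pytest.fixture(scope="session")
def rl_series_small(rl_params):
    """A modest receptor-ligand run shared across estimator tests.

    20 replicas x 50 time units (10^6 Euler steps) sampled every 0.05.
    """
    cfg = SimConfig(
        dt=1e-3, n_steps=50_000, burn_in=10.0, seed=101,
        n_replicas=20, store_every=0.05,
    )
    return simulate_receptor_ligand(rl_params, cfg)


def random_spd(dim: int, seed: int, cond_scale: float = 1.0) -> np.ndarray:
    """A reproducible random symmetric positive-definite matrix."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((dim, dim))
    S = A @ A.T + dim * cond_scale * np.eye(dim)
    return S
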