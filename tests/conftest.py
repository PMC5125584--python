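import numpy as np
import pytest

from gentrust import GameConfig, PayoffParams, SimConfig


@pytest.fixture(scope="session")
def params() -> PayoffParams:
    """Benchmark stage payoffs P=1, R=4, T=6."""
    return PayoffParams()


@pytest.fixture()
def game_cfg():
    """Factory for benchmark repeated-game configs (d=0.1, n=100)."""

    def make(a: float, d: float = 0.1, n_rounds: int = 100) -> GameConfig:
        return GameConfig(a=a, d=d, n_rounds=n_rounds)

    return make


@pytest.fixture()
def small_sim_cfg():
    """Factory for quick, small evolutionary configs used in unit tests."""

    def make(**kw) -> SimConfig:
        defaults = dict(
            a=0.65,
            n_donors=20,
            n_recipients=20,
            rounds_per_generation=20,
            generations=3,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
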