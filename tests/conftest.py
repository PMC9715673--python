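import numpy as np
import pytest

from igcbir.pipeline import RunConfig, run_benchmark


@pytest.fixture(scope="session")
def bench():
    """One full default-condition benchmark run shared across the suite.

    Trains CNN, IG and ATT on the default phantom conditions and ranks all
    ten query/catalogue splits under the five methods.
    """
    return run_benchmark(RunConfig().with_seed(0))


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration for fast structural/CLI tests."""
    import dataclasses
    from igcbir.phantoms import PhantomConfig
    from igcbir.backbone import TrainConfig
    tc = TrainConfig(optimizer="adam", learning_rate=1e-3, epochs=2, seed=0)
    return RunConfig(
        phantom=PhantomConfig(image_size=32, seed=0),
        train_cnn=tc, train_ig=tc, train_att=tc,
        n_train=24, n_val=12, n_test=36, n_queries=3, p=8, p_evals=(8, 3),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
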