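import numpy as np
import pytest

import pinndesign as P


@pytest.fixture(scope="session")
def world():
    return P.SyntheticWorld.from_seed(0)


@pytest.fixture(scope="session")
def corpus(world):
    """The benchmark corpus: 300 random designs of length 25, 50 frames each."""
    return P.make_dataset(300, 25, world, frames=50, seed=0)


@pytest.fixture(scope="session")
def trained(world, corpus):
    """Surrogate trained once per session on the benchmark corpus.

    Returns (model, history, dataset, world, validation_examples).
    """
    cfg = P.RunConfig(seed=0)
    model, history, dataset, _ = P.run_train(cfg, dataset=corpus, world=world)
    examples = P.dataset_to_examples(dataset)
    std, _ = P.standardize_targets(examples)
    rng = np.random.default_rng(cfg.train.seed)
    order = rng.permutation(len(std))
    n_val = max(1, int(round(cfg.train.validation_fraction * len(std))))
    val = [std[i] for i in order[:n_val]]
    return model, history, dataset, world, val


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_trace(rng):
    coords = np.cumsum(
        3.8 * (rng.standard_normal((10, 3)) * 0.2 + np.array([1.0, 0.1, 0.0])), axis=0
    )
    return P.CaTrace(sequence="ACDEFGHIKL", coords=coords, id="small")
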