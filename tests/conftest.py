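import numpy as np
import pandas as pd
import pytest

import dcnlearn as d
from dcnlearn.features import extract_table, feature_columns


@pytest.fixture(scope="session")
def small_config():
    """A reduced, high-SNR cohort (3 animals x 10 trials/nerve): small
    enough for fast tests, quiet enough that every signal component is
    visible above the noise floor."""
    return d.GeneratorConfig(
        n_animals=3, n_sets=2, trials_per_set=5, noise_sd=4.0, rng_seed=11
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    return extract_table(d.generate_dataset(small_config))


def gaussian_feature_table(
    nerve_means: dict,
    n_per_nerve: int,
    rng: np.random.Generator,
    sd: float = 1.0,
    animal: str = "a1",
) -> pd.DataFrame:
    """Feature table drawn directly from per-nerve Gaussian models.

    ``nerve_means`` maps nerve -> either a scalar (applied to every feature
    column) or a dict column -> mean.  Used to calibrate the statistics
    layer against known nulls and effects without the trace pipeline.
    """
    cols = feature_columns()
    frames = []
    for nerve in d.NERVES:
        spec = nerve_means.get(nerve, 0.0)
        df = pd.DataFrame(
            {
                "animal": animal,
                "nerve": nerve,
                "trial": np.arange(n_per_nerve),
            }
        )
        for c in cols:
            mean = spec[c] if isinstance(spec, dict) else spec
            df[c] = rng.normal(mean, sd, n_per_nerve)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def separable_feature_table(
    n_per_nerve: int, rng: np.random.Generator, animals=("a1",), sd: float = 0.3
) -> pd.DataFrame:
    """Four cleanly separated point clouds, one per nerve."""
    frames = []
    for animal in animals:
        means = {nerve: 10.0 * i for i, nerve in enumerate(d.NERVES)}
        frames.append(
            gaussian_feature_table(means, n_per_nerve, rng, sd=sd, animal=animal)
        )
    return pd.concat(frames, ignore_index=True)
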