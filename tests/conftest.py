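import numpy as np
import pytest

from baroque.evaluation import FunctionObjective
from baroque.synthetic import PlantedFeatureSpec, gen_feature_table

TOY_TARGET = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)


def toy_match_fraction(mask: np.ndarray) -> float:
    """Fraction of bits agreeing with the hidden 8-bit target.

    Enumerating all 256 masks shows the unique optimum is the target
    itself with fitness 1.0, and the landscape has no non-global local
    optimum under single-bit flips.
    """
    return float((np.asarray(mask, dtype=np.uint8) == TOY_TARGET).mean())


@pytest.fixture
def toy_objective():
    return FunctionObjective(toy_match_fraction, 8)


@pytest.fixture(scope="session")
def small_planted():
    """Small planted table (fast): 120 samples, 3 classes, 20 features."""
    spec = PlantedFeatureSpec(n_samples=120, n_classes=3, n_informative=5,
                              n_redundant=2, n_noise=13, effect_size=1.5,
                              seed=7)
    return gen_feature_table(spec)
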