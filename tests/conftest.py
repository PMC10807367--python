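import itertools

import numpy as np
import pytest

from bscso.data import SplitSpec, SyntheticSpec, generate_synthetic, normalize_minmax, split
from bscso.fitness import EvaluationContext, fitness_function


@pytest.fixture(scope="session")
def small_wrapper_problem():
    """A d=10 synthetic KNN wrapper problem small enough to enumerate.

    Returns the evaluation context, the fitness closure, and the sorted
    fitness values of all 1023 non-empty subsets (exhaustive oracle).
    """
    synth = generate_synthetic(
        SyntheticSpec(n_samples=100, n_features=10, n_informative=3,
                      effect_size=2.0, seed=42)
    )
    train, val, _test = split(synth.dataset, SplitSpec(seed=42))
    val = normalize_minmax(val, reference=train)
    train = normalize_minmax(train)
    ctx = EvaluationContext(
        train.features, train.labels, val.features, val.labels, k=5
    )
    fn = fitness_function(ctx)
    values = sorted(
        fn(np.array(bits, dtype=np.int8))
        for bits in itertools.product([0, 1], repeat=10)
        if any(bits)
    )
    return ctx, fn, np.array(values)
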