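import numpy as np
import pytest

from ipdinfer import archetype, simulate


@pytest.fixture
def planted_three_group():
    """FP cohort of AllC pairs, AllD pairs and Random pairs (noise 0.05).

    Returns a factory: seed -> (SimulationResult, ground-truth group labels).
    The three groups occupy well-separated regions of context space
    (all-CC, all-DD, and uniformly mixed experiences), so contextual
    clustering should recover the planted partition.
    """

    def build(seed: int, n_per_group: int = 30):
        cohort = [archetype("AllC", noise=0.05)] * n_per_group
        cohort += [archetype("AllD", noise=0.05)] * n_per_group
        cohort += [archetype("Random", noise=0.05)] * n_per_group
        groups = np.repeat([0, 1, 2], n_per_group)
        result = simulate(cohort, n_rounds=100, mode="FP", seed=seed)
        return result, groups

    return build
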