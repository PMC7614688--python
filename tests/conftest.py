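import numpy as np
import pytest

from dynalign import synth
from dynalign.signal import StimulusEnsemble


@pytest.fixture
def toy_ensemble() -> StimulusEnsemble:
    """Two-neuron ensemble with correlated noise and a hand-solvable
    discriminant (w proportional to [1, -1])."""
    return StimulusEnsemble(
        g1=[1.0, 2.0], g2=[2.0, 1.0], noise_cov=[[2.0, 1.0], [1.0, 2.0]]
    )


@pytest.fixture
def mode_ensemble() -> StimulusEnsemble:
    """Two-neuron ensemble used for the two-mode network illustrations."""
    return StimulusEnsemble(
        g1=[6.0, 6.0], g2=[5.0, 7.0],
        noise_cov=[[20.0, 10.0], [10.0, 20.0]],
    )


def make_scenario_recordings(
    scenario: str,
    seed: int,
    n_neurons: int = 30,
    n_trials: int = 150,
    n_replicates: int = 1,
):
    """Ground-truth pairs plus simulated pre/post sessions."""
    pairs, recs_pre, recs_post = [], [], []
    for r in range(n_replicates):
        spec = synth.ScenarioSpec(
            scenario, n_neurons=n_neurons,
            n_trials_per_condition=n_trials, seed=seed + 97 * r,
        )
        pair = synth.make_ground_truth_pair(spec)
        pairs.append(pair)
        recs_pre.append(
            synth.generate_recording(pair["pre"], n_trials,
                                     seed=seed + 1000 + r)
        )
        recs_post.append(
            synth.generate_recording(pair["post"], n_trials,
                                     seed=seed + 2000 + r)
        )
    return pairs, recs_pre, recs_post


@pytest.fixture(scope="session")
def realignment_small():
    return make_scenario_recordings("realignment", seed=7)


@pytest.fixture(scope="session")
def small_recording():
    _, recs_pre, _ = make_scenario_recordings("null", seed=3, n_neurons=25,
                                              n_trials=60)
    return recs_pre[0]


def small_ring(**overrides):
    """Scaled-down ring for structural/identity tests.

    Weight strengths are scaled up by the population-size ratio so the
    small ring keeps a comparable recurrent drive per cell.
    """
    scale = 1000 / 80
    base = dict(
        N_E=80, N_I=16,
        W0_EE=0.019 * scale, W0_II=-1.1 * 0.019 * scale,
        W0_EI=-0.04 * scale, W0_IE=0.04 * scale,
    )
    base.update(overrides)
    from dynalign.ring import RingConfig

    return RingConfig(**base)


@pytest.fixture
def ring_small():
    return small_ring()


@pytest.fixture(autouse=True)
def _seed_numpy_legacy():
    # some scipy internals consume global state; keep runs reproducible
    np.random.seed(0)
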