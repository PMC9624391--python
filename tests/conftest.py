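import numpy as np
import pytest

from seqmr.model import TASKS
from seqmr.pwm import PWM, bundled_motifs
from seqmr.simulate import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def pwms():
    return bundled_motifs()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_pwm():
    # sharp 3-wide motif with consensus ACG
    return PWM(
        name="toy",
        matrix=np.array(
            [
                [0.91, 0.03, 0.03, 0.03],
                [0.03, 0.91, 0.03, 0.03],
                [0.03, 0.03, 0.91, 0.03],
            ]
        ),
    )


@pytest.fixture(scope="session")
def small_dataset(pwms):
    """A small unconfounded dataset with fixed run coefficients."""
    config = ScenarioConfig.for_scenario(
        "unconfounded", seed=42, n_train=150, n_test=60
    )
    return generate_dataset(config, pwms)


class LinearEnsemble:
    """Deterministic stand-in ensemble: linear functions of base content.

    Member i predicts, for each task t, ``offset[i, t] + w[t] . counts``
    where counts are the per-base totals of the one-hot sequence.  Linear
    in the sequence, exactly reproducible, and with controllable member
    spread — convenient for exercising mutagenesis and MR without
    training a CNN.
    """

    tasks = TASKS

    def __init__(self, offsets=None, weights=None):
        self.offsets = np.asarray(
            offsets if offsets is not None else [[0.0, 0.0], [0.1, -0.1], [-0.1, 0.1]]
        )
        self.weights = np.asarray(
            weights
            if weights is not None
            else [[0.5, -0.2, 0.1, 0.0], [1.0, -0.4, 0.2, 0.0]]
        )

    def member_predictions(self, X):
        counts = X.sum(axis=1)  # (B, 4) per-base totals
        base = counts @ self.weights.T  # (B, T)
        return base[None, :, :] + self.offsets[:, None, :]


@pytest.fixture()
def linear_ensemble():
    return LinearEnsemble()
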