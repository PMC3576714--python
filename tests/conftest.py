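import numpy as np
import pytest

import lvcontrol as lv


@pytest.fixture(scope="session")
def default_basis():
    """Package-default basis (alpha=0.95, L=3, M=1000, dt=1 ms)."""
    return lv.build_basis()


@pytest.fixture(scope="session")
def small_basis():
    """A short-memory basis cheap enough for brute-force kernel sums."""
    return lv.build_basis(alpha=0.8, n_basis=3, n_lags=120, dt=0.001)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_coefficients(rng, basis, scale=1.0):
    """Random but physically scaled second-order coefficients."""
    L = basis.n_basis
    c2 = rng.normal(0, 1e-5 * scale, (L, L))
    return lv.LVCoefficients(
        c0=0.1 * scale,
        c1_present=rng.uniform(2e-3, 6e-3) * scale,
        c2_present=-rng.uniform(2e-6, 8e-6) * scale,
        c1=rng.normal(0, 1e-2 * scale, L),
        c2=0.5 * (c2 + c2.T),
        c2_cross=rng.normal(0, 1e-5 * scale, L),
        basis_spec=basis.to_spec())


def random_train(rng, n_events=100, amp_range=(50.0, 250.0),
                 interval_range=(0.002, 0.3), train_id="t"):
    times = np.cumsum(rng.uniform(*interval_range, n_events))
    amps = rng.uniform(*amp_range, n_events)
    return lv.EventTrain(times, amps, train_id=train_id)


@pytest.fixture()
def mixed_plant(default_basis):
    return lv.make_ground_truth_model("mixed", default_basis, noise_sd=0.0)


@pytest.fixture()
def rarit_trains(default_basis, mixed_plant):
    """Four noiseless RARIT trains simulated through the mixed plant."""
    spec = lv.TrainSpec(amplitude_mode="gaussian",
                        amplitude_params=(150.0, 45.0), seed=3)
    trains = lv.generate_rarit(spec, np.random.default_rng(3))
    return [lv.simulate_plant(mixed_plant, t) for t in trains]
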