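import numpy as np
import pytest

from catcircuit.fixtures import FixtureSpec, NeuronSpec, generate_dataset


@pytest.fixture(scope="session")
def mixed_fixture():
    """Synthetic dataset with every tuning kind and known CP/CTI truth."""
    rng = np.random.default_rng(7)
    specs = []
    # direction-dominated mixture, like the recorded populations the
    # two-pass width constraint was designed for
    kinds = ["direction", "direction", "direction", "mixed",
             "direction", "category", "direction", "flat"]
    cps = [0.35, 0.45, 0.5, 0.55, 0.65, 0.76]
    for j in range(24):
        specs.append(NeuronSpec(
            kind=kinds[j % len(kinds)],
            theta0_deg=float(rng.uniform(0, 360)),
            rmax=12.0, cat_step=6.0,
            cp=cps[j % len(cps)],
        ))
    spec = FixtureSpec(neurons=specs, trials_per_stimulus=50, noise_sd=2.5,
                       seed=20240)
    ds, truth = generate_dataset(spec)
    return ds, truth
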